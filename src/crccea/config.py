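"""Model-parameter configuration: schema, defaults, and YAML/JSON I/O.

The configuration mirrors the published input-parameter table of the
economic evaluation: per-cycle transition probabilities for three
parameter sets (chemotherapy from the systematic review, chemotherapy
from real-world records, chemotherapy+bevacizumab from real-world
records), pooled risk ratios for progression-free and overall survival,
per-cycle per-state cost components in Indonesian rupiah (IDR), EQ-5D-5L
utility index values, and discount rates.  Validation is strict: unknown
keys are rejected so a misspelt parameter cannot silently fall back to a
default.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

Arm = Literal["chemo", "chemo_bev"]
DataSource = Literal["secondary", "real_world"]
PerspectiveLabel = Literal["healthcare", "societal"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class TpEntry(_Strict):
    """One transition probability with optional beta-distribution parameters.

    ``alpha``/``beta`` are carried verbatim from the source table for use
    in probabilistic sensitivity analysis; they are not required to be
    numerically consistent with ``value`` and the engine never reconciles
    the two.
    """

    value: float = Field(ge=0.0, le=1.0)
    alpha: Optional[float] = Field(default=None, gt=0.0)
    beta: Optional[float] = Field(default=None, gt=0.0)

    @model_validator(mode="after")
    def _paired(self) -> "TpEntry":
        if (self.alpha is None) != (self.beta is None):
            raise ValueError("alpha and beta must be given together")
        return self


class TransitionBlock(_Strict):
    """Raw per-cycle transition probabilities for one arm/data source.

    Backward transitions (progressive -> progression-free) are structurally
    zero; the death row is always absorbing and is not configured.
    """

    progression_free_to_progression_free: TpEntry
    progression_free_to_progressive: TpEntry
    progression_free_to_death: TpEntry
    progressive_to_progressive: TpEntry
    progressive_to_death: TpEntry


class TransitionProbabilities(_Strict):
    chemo_secondary: TransitionBlock
    chemo_real_world: TransitionBlock
    chemo_bev_real_world: TransitionBlock


class RiskRatioEntry(_Strict):
    value: float = Field(gt=0.0)
    se: float = Field(gt=0.0)


class RiskRatios(_Strict):
    progression_free_survival: RiskRatioEntry
    overall_survival: RiskRatioEntry


class CostEntry(_Strict):
    """Per-cycle cost in IDR with its standard error."""

    mean: float = Field(ge=0.0)
    se: float = Field(ge=0.0)


class StateCosts(_Strict):
    direct_medical: CostEntry
    direct_nonmedical: CostEntry
    indirect: CostEntry


class ArmCosts(_Strict):
    progression_free: StateCosts
    progressive: StateCosts


class Costs(_Strict):
    chemo: ArmCosts
    chemo_bev: ArmCosts


class UtilityEntry(_Strict):
    mean: float = Field(ge=-1.0, le=1.0)
    se: float = Field(ge=0.0)


class ArmUtilities(_Strict):
    progression_free: UtilityEntry
    progressive: UtilityEntry


class Utilities(_Strict):
    chemo: ArmUtilities
    chemo_bev: ArmUtilities


class Settings(_Strict):
    """Run-level settings: cycle structure, horizon, discounting, reporting.

    ``normalization_policy`` decides how raw rows that do not sum to one
    are repaired (the published rows sum to 0.999): ``proportional``
    rescales every entry, ``residual_to_death`` assigns the shortfall to
    the death transition.  ``risk_ratio_mode`` selects how pooled risk
    ratios derive the bevacizumab matrix from the chemotherapy matrix:
    ``hazard`` applies p' = 1 - (1-p)^rr, ``direct`` multiplies p' = rr*p.
    ``discount_compounding`` ``annual`` uses (1+r)^(-cycle/cycles_per_year);
    ``per_cycle`` is a legacy mode applying r directly per cycle.
    """

    cycle_length_months: float = 2.0
    start_age_years: float = 50.0
    max_age_years: float = 100.0
    residual_alive_tol: float = Field(default=1e-4, gt=0.0)
    discount_rate_costs: float = Field(default=0.03, ge=0.0)
    discount_rate_outcomes: float = Field(default=0.03, ge=0.0)
    half_cycle_correction: bool = False
    normalization_policy: Literal["proportional", "residual_to_death"] = "proportional"
    risk_ratio_mode: Literal["hazard", "direct"] = "hazard"
    discount_compounding: Literal["annual", "per_cycle"] = "annual"
    exchange_rate_idr_per_usd: float = Field(default=14250.0, gt=0.0)
    wtp_usd_per_qaly: float = Field(default=10800.0, gt=0.0)
    background_mortality_per_cycle: float = Field(default=0.0, ge=0.0, lt=1.0)

    @property
    def cycles_per_year(self) -> float:
        return 12.0 / self.cycle_length_months

    @model_validator(mode="after")
    def _ages(self) -> "Settings":
        if self.max_age_years <= self.start_age_years:
            raise ValueError("max_age_years must exceed start_age_years")
        return self


class ScenarioSpec(_Strict):
    data_source: DataSource = "secondary"
    perspective: PerspectiveLabel = "societal"


class ModelConfig(_Strict):
    """Complete parameterization of the cost-utility model."""

    settings: Settings = Settings()
    scenario: ScenarioSpec = ScenarioSpec()
    transition_probabilities: TransitionProbabilities
    risk_ratios: RiskRatios
    costs_idr: Costs
    utilities: Utilities

    def digest(self) -> str:
        """SHA-256 digest of the canonical JSON form, for run provenance."""
        blob = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()


def default_config(
    data_source: DataSource = "secondary",
    perspective: PerspectiveLabel = "societal",
) -> ModelConfig:
    """The published base-case parameter set.

    Transition probabilities are raw as printed (progression-free rows sum
    to 0.999 and are normalized downstream).  Costs are per 2-month cycle
    per state per arm, in IDR.  Utilities are arm-specific EQ-5D-5L index
    values as printed — the bevacizumab arm's are lower, and the engine
    deliberately does not "correct" that.
    """
    return ModelConfig(
        scenario=ScenarioSpec(data_source=data_source, perspective=perspective),
        transition_probabilities=TransitionProbabilities(
            chemo_secondary=TransitionBlock(
                progression_free_to_progression_free=TpEntry(value=0.877, alpha=125, beta=15),
                progression_free_to_progressive=TpEntry(value=0.116),
                progression_free_to_death=TpEntry(value=0.006),
                progressive_to_progressive=TpEntry(value=0.963),
                progressive_to_death=TpEntry(value=0.037, alpha=124, beta=33),
            ),
            chemo_real_world=TransitionBlock(
                progression_free_to_progression_free=TpEntry(value=0.950),
                progression_free_to_progressive=TpEntry(value=0.043, alpha=124, beta=33),
                progression_free_to_death=TpEntry(value=0.006),
                progressive_to_progressive=TpEntry(value=0.974),
                progressive_to_death=TpEntry(value=0.026, alpha=3, beta=13),
            ),
            chemo_bev_real_world=TransitionBlock(
                progression_free_to_progression_free=TpEntry(value=0.955),
                progression_free_to_progressive=TpEntry(value=0.038, alpha=35, beta=61),
                progression_free_to_death=TpEntry(value=0.006),
                progressive_to_progressive=TpEntry(value=0.957),
                progressive_to_death=TpEntry(value=0.043, alpha=7, beta=28),
            ),
        ),
        risk_ratios=RiskRatios(
            progression_free_survival=RiskRatioEntry(value=0.720, se=0.0306),
            overall_survival=RiskRatioEntry(value=0.840, se=0.0357),
        ),
        costs_idr=Costs(
            chemo=ArmCosts(
                progression_free=StateCosts(
                    direct_medical=CostEntry(mean=14_671_335, se=2_001_108),
                    direct_nonmedical=CostEntry(mean=1_585_498, se=1_585_498),
                    indirect=CostEntry(mean=225_150, se=225_150),
                ),
                progressive=StateCosts(
                    direct_medical=CostEntry(mean=11_002_640, se=3_215_142),
                    direct_nonmedical=CostEntry(mean=1_585_498, se=1_585_498),
                    indirect=CostEntry(mean=225_150, se=225_150),
                ),
            ),
            chemo_bev=ArmCosts(
                progression_free=StateCosts(
                    direct_medical=CostEntry(mean=16_581_540, se=1_297_381),
                    direct_nonmedical=CostEntry(mean=1_635_927, se=1_635_927),
                    indirect=CostEntry(mean=137_468, se=137_468),
                ),
                progressive=StateCosts(
                    direct_medical=CostEntry(mean=13_571_535, se=3_045_121),
                    direct_nonmedical=CostEntry(mean=1_635_927, se=1_635_927),
                    indirect=CostEntry(mean=137_468, se=137_468),
                ),
            ),
        ),
        utilities=Utilities(
            chemo=ArmUtilities(
                progression_free=UtilityEntry(mean=0.864, se=0.070),
                progressive=UtilityEntry(mean=0.724, se=0.070),
            ),
            chemo_bev=ArmUtilities(
                progression_free=UtilityEntry(mean=0.793, se=0.107),
                progressive=UtilityEntry(mean=0.659, se=0.131),
            ),
        ),
    )


def packaged_config(
    data_source: DataSource = "secondary",
    perspective: PerspectiveLabel = "societal",
) -> ModelConfig:
    """Load one of the four shipped scenario configurations.

    The packaged YAML files mirror :func:`default_config`; they exist so
    runs can reference an on-disk, diffable artifact.
    """
    from importlib.resources import files

    res = files("crccea") / "configs" / f"{data_source}_{perspective}.yaml"
    data = yaml.safe_load(res.read_text())
    return ModelConfig.model_validate(data)


def load_config(path: str | Path) -> ModelConfig:
    """Load and strictly validate a YAML or JSON configuration file."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} does not contain a mapping")
    return ModelConfig.model_validate(data)


def dump_config(config: ModelConfig, path: str | Path) -> None:
    """Write a configuration to YAML."""
    Path(path).write_text(
        yaml.safe_dump(config.model_dump(mode="json"), sort_keys=False)
    )
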