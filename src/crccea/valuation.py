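"""Economic valuation of cohort traces.

Attaches per-cycle, per-state costs (IDR) and EQ-5D utilities to a cohort
trace, discounts both streams, and computes comparative economics between
two strategy arms: incremental cost, incremental QALYs, the incremental
cost-effectiveness ratio (ICER), net monetary benefit (NMB) and dominance
labels, under either a healthcare perspective (direct medical costs only)
or a societal perspective (direct medical + direct non-medical + indirect
costs).

Costs accrue against beginning-of-cycle state occupancy for cycles
0..N-1; an optional half-cycle correction averages adjacent-cycle
occupancies instead.  All arithmetic is done in IDR; USD values are
conversions at reporting time.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from . import markov
from .config import Arm, DataSource, ModelConfig, PerspectiveLabel
from .markov import (
    DEATH,
    PD,
    PF,
    CohortTrace,
    RiskRatioPair,
    TransitionMatrix,
    ValidationError,
    add_background_mortality,
    apply_risk_ratios,
    build_matrix,
    default_horizon,
    run_cohort,
)


class Perspective(enum.Enum):
    """Which cost components count."""

    HEALTHCARE = "healthcare"
    SOCIETAL = "societal"

    @property
    def components(self) -> tuple[str, ...]:
        if self is Perspective.HEALTHCARE:
            return ("direct_medical",)
        return ("direct_medical", "direct_nonmedical", "indirect")


@dataclass(frozen=True)
class StateValues:
    """Per-cycle cost components (IDR) and utility for one health state."""

    direct_medical: float = 0.0
    direct_nonmedical: float = 0.0
    indirect: float = 0.0
    utility: float = 0.0

    def __post_init__(self) -> None:
        for name in ("direct_medical", "direct_nonmedical", "indirect"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} cost must be non-negative")
        if not -1.0 <= self.utility <= 1.0:
            raise ValidationError("utility must lie in [-1, 1]")

    def cost(self, perspective: Perspective) -> float:
        return sum(getattr(self, c) for c in perspective.components)


@dataclass(frozen=True)
class EconSummary:
    """Discounted totals for one strategy arm."""

    arm: str
    total_cost_idr: float
    total_cost_usd: float
    total_qaly: float
    life_years_undiscounted: float


@dataclass(frozen=True)
class Comparison:
    """Incremental economics of intervention vs. reference."""

    delta_cost_idr: float
    delta_cost_usd: float
    delta_qaly: float
    icer_idr_per_qaly: Optional[float]
    icer_usd_per_qaly: Optional[float]
    dominance: Optional[str]  # None in a trade-off quadrant
    wtp_idr_per_qaly: float
    nmb_idr: float
    cost_effective: bool

    def nmb_at(self, wtp_idr: float) -> float:
        """Net monetary benefit lambda*dQALY - dCost at a given WTP (IDR)."""
        return wtp_idr * self.delta_qaly - self.delta_cost_idr


def discount_factor(
    cycle: int | np.ndarray,
    annual_rate: float,
    cycles_per_year: float = 6.0,
    compounding: str = "annual",
) -> float | np.ndarray:
    """Discount multiplier for a cash flow or outcome at a cycle boundary.

    Default ``annual`` compounding returns ``(1+rate)^(-cycle/cycles_per_year)``
    so that a flow one year out (cycle 6 for 2-month cycles) is discounted
    by exactly 1/(1+rate).  The ``per_cycle`` legacy mode applies the
    annual rate once per cycle, ``(1+rate)^(-cycle)``, as some
    spreadsheet-origin models do.
    """
    if annual_rate < 0:
        raise ValidationError("discount rate must be non-negative")
    if compounding == "annual":
        return (1.0 + annual_rate) ** (-np.asarray(cycle, dtype=float) / cycles_per_year)
    if compounding == "per_cycle":
        return (1.0 + annual_rate) ** (-np.asarray(cycle, dtype=float))
    raise ValidationError(f"unknown discount compounding '{compounding}'")


def convert_currency(amount_idr: float, rate_idr_per_usd: float) -> float:
    """IDR -> USD at the given exchange rate."""
    if rate_idr_per_usd <= 0:
        raise ValidationError("exchange rate must be positive")
    return amount_idr / rate_idr_per_usd


def wtp_threshold(gdp_per_capita: float, multiplier: float = 3) -> float:
    """Willingness-to-pay threshold as a multiple of GDP per capita."""
    if gdp_per_capita <= 0 or multiplier <= 0:
        raise ValidationError("GDP per capita and multiplier must be positive")
    return gdp_per_capita * multiplier


def accumulate(
    trace: CohortTrace,
    values: Mapping[str, StateValues],
    perspective: Perspective,
    discount_rate_costs: float = 0.03,
    discount_rate_outcomes: float = 0.03,
    half_cycle: bool = False,
    exchange_rate_idr_per_usd: float = 14250.0,
    compounding: str = "annual",
    arm: str = "",
) -> EconSummary:
    """Weight the trace by per-state costs and utilities and discount.

    ``values`` must provide entries for ``progression_free`` and
    ``progressive``; death carries zero cost and zero utility by
    construction.  QALYs accrue at ``utility * cycle_length/12`` years per
    cycle occupied.
    """
    for state in ("progression_free", "progressive"):
        if state not in values:
            raise ValidationError(f"missing state values for '{state}'")
    sv = [values["progression_free"], values["progressive"], StateValues()]
    cost_vec = np.array([v.cost(perspective) for v in sv])
    util_vec = np.array([v.utility for v in sv])

    occ = trace.occupancy
    if half_cycle:
        occ = 0.5 * (occ[:-1] + occ[1:])
    else:
        occ = occ[:-1]
    n = occ.shape[0]
    cycles = np.arange(n)
    cpy = 12.0 / trace.cycle_length_months
    df_cost = discount_factor(cycles, discount_rate_costs, cpy, compounding)
    df_out = discount_factor(cycles, discount_rate_outcomes, cpy, compounding)

    year_per_cycle = trace.cycle_length_months / 12.0
    total_cost = float(df_cost @ (occ @ cost_vec))
    total_qaly = float(df_out @ (occ @ util_vec)) * year_per_cycle
    life_years = float((occ[:, PF] + occ[:, PD]).sum()) * year_per_cycle
    return EconSummary(
        arm=arm,
        total_cost_idr=total_cost,
        total_cost_usd=convert_currency(total_cost, exchange_rate_idr_per_usd),
        total_qaly=total_qaly,
        life_years_undiscounted=life_years,
    )


def compare(
    reference: EconSummary,
    intervention: EconSummary,
    wtp_idr_per_qaly: float,
    exchange_rate_idr_per_usd: float = 14250.0,
    qaly_tol: float = 1e-12,
) -> Comparison:
    """Incremental comparison of two arms at a willingness-to-pay threshold.

    The ICER is reported only in trade-off quadrants (more costly and more
    effective, or cheaper and less effective).  Dominance labels replace it
    otherwise: "dominant" (cheaper, more effective), "dominated" (costlier,
    less effective), or a by-cost label when the QALY difference is zero.
    The cost-effective flag is NMB >= 0 at the threshold, which reduces to
    ICER <= threshold in the north-east quadrant.
    """
    d_cost = intervention.total_cost_idr - reference.total_cost_idr
    d_qaly = intervention.total_qaly - reference.total_qaly
    icer: Optional[float] = None
    dominance: Optional[str] = None
    if abs(d_qaly) <= qaly_tol:
        dominance = (
            "dominated (equal effect)" if d_cost > 0 else "dominant (equal effect)"
        )
    elif d_qaly > 0 and d_cost < 0:
        dominance = "dominant"
    elif d_qaly < 0 and d_cost > 0:
        dominance = "dominated"
    else:
        icer = d_cost / d_qaly
    nmb = wtp_idr_per_qaly * d_qaly - d_cost
    return Comparison(
        delta_cost_idr=d_cost,
        delta_cost_usd=convert_currency(d_cost, exchange_rate_idr_per_usd),
        delta_qaly=d_qaly,
        icer_idr_per_qaly=icer,
        icer_usd_per_qaly=(
            None if icer is None else icer / exchange_rate_idr_per_usd
        ),
        dominance=dominance,
        wtp_idr_per_qaly=wtp_idr_per_qaly,
        nmb_idr=nmb,
        cost_effective=nmb >= 0,
    )


# ---------------------------------------------------------------------------
# Scenario assembly: config -> matrices, values -> traces -> economics
# ---------------------------------------------------------------------------

REFERENCE_ARM: Arm = "chemo"
INTERVENTION_ARM: Arm = "chemo_bev"


def arm_matrices(
    config: ModelConfig, data_source: DataSource
) -> dict[Arm, TransitionMatrix]:
    """Per-arm transition matrices for a data source.

    Real-world data provides both arms' probabilities directly.  The
    secondary (systematic-review) source provides only the chemotherapy
    matrix; the bevacizumab matrix is derived from it by applying the
    pooled risk ratios.
    """
    s = config.settings
    tp = config.transition_probabilities

    def _build(block) -> TransitionMatrix:
        raw = {name: entry.value for name, entry in block}
        m = build_matrix(raw, policy=s.normalization_policy)
        return add_background_mortality(m, s.background_mortality_per_cycle)

    if data_source == "real_world":
        return {
            "chemo": _build(tp.chemo_real_world),
            "chemo_bev": _build(tp.chemo_bev_real_world),
        }
    chemo = _build(tp.chemo_secondary)
    rr = RiskRatioPair(
        rr_pfs=config.risk_ratios.progression_free_survival.value,
        rr_os=config.risk_ratios.overall_survival.value,
        se_pfs=config.risk_ratios.progression_free_survival.se,
        se_os=config.risk_ratios.overall_survival.se,
    )
    return {
        "chemo": chemo,
        "chemo_bev": apply_risk_ratios(chemo, rr, mode=s.risk_ratio_mode),
    }


def arm_values(config: ModelConfig, arm: Arm) -> dict[str, StateValues]:
    """Per-state cost components and utilities for one arm."""
    costs = getattr(config.costs_idr, arm)
    utils = getattr(config.utilities, arm)
    out = {}
    for state in ("progression_free", "progressive"):
        c = getattr(costs, state)
        out[state] = StateValues(
            direct_medical=c.direct_medical.mean,
            direct_nonmedical=c.direct_nonmedical.mean,
            indirect=c.indirect.mean,
            utility=getattr(utils, state).mean,
        )
    return out


@dataclass(frozen=True)
class ScenarioResult:
    """Deterministic run of one scenario (data source x perspective)."""

    data_source: str
    perspective: str
    horizon_cycles: int
    traces: dict[str, CohortTrace]
    summaries: dict[str, EconSummary]
    comparison: Comparison


def evaluate_scenario(
    config: ModelConfig,
    data_source: Optional[DataSource] = None,
    perspective: Optional[PerspectiveLabel] = None,
    matrices: Optional[Mapping[Arm, TransitionMatrix]] = None,
    values: Optional[Mapping[Arm, Mapping[str, StateValues]]] = None,
    horizon_cycles: Optional[int] = None,
) -> ScenarioResult:
    """Run the full deterministic model for one scenario.

    ``matrices``/``values`` override the config-derived inputs (used by the
    probabilistic sensitivity analysis to evaluate parameter draws through
    the identical pipeline).  The horizon defaults to the lifetime rule
    applied to both arms (the longer of the two), so the arms are always
    compared over a common horizon.
    """
    s = config.settings
    ds: DataSource = data_source or config.scenario.data_source
    pl: PerspectiveLabel = perspective or config.scenario.perspective
    persp = Perspective(pl)
    mats = dict(matrices) if matrices is not None else arm_matrices(config, ds)
    vals = (
        {arm: dict(values[arm]) for arm in values}
        if values is not None
        else {arm: arm_values(config, arm) for arm in ("chemo", "chemo_bev")}
    )
    if horizon_cycles is None:
        horizon_cycles = max(
            default_horizon(
                m,
                s.start_age_years,
                s.max_age_years,
                s.residual_alive_tol,
                s.cycle_length_months,
            )
            for m in mats.values()
        )
    traces = {
        arm: run_cohort(
            mats[arm],
            horizon_cycles,
            cycle_length_months=s.cycle_length_months,
            start_age_years=s.start_age_years,
        )
        for arm in mats
    }
    summaries = {
        arm: accumulate(
            traces[arm],
            vals[arm],
            persp,
            s.discount_rate_costs,
            s.discount_rate_outcomes,
            s.half_cycle_correction,
            s.exchange_rate_idr_per_usd,
            s.discount_compounding,
            arm=arm,
        )
        for arm in traces
    }
    wtp_idr = s.wtp_usd_per_qaly * s.exchange_rate_idr_per_usd
    comparison = compare(
        summaries[REFERENCE_ARM],
        summaries[INTERVENTION_ARM],
        wtp_idr,
        s.exchange_rate_idr_per_usd,
    )
    return ScenarioResult(
        data_source=ds,
        perspective=pl,
        horizon_cycles=horizon_cycles,
        traces=traces,
        summaries=summaries,
        comparison=comparison,
    )
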