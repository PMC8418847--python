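"""Synthetic patient-level records with the structure the analysis assumes.

Emulates a retrospective multi-hospital cohort: per-patient state
trajectories simulated from a discrete-time three-state Markov chain,
per-cycle billing amounts with right-skewed (gamma) noise, interview
utility index values with interval-bounded (beta) noise, and independent
uniform censoring.  The default configuration mirrors the study cohort:
43 chemotherapy-alone and 96 chemotherapy+bevacizumab patients, with the
real-world transition probabilities, costs and utilities of the published
input table as the generating truth.

The emitted table is exactly the long format consumed by
:mod:`crccea.rwd`, so generator truth -> estimation -> model forms a
closed, testable loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .config import Arm, DataSource, ModelConfig, default_config
from .markov import DEATH, PD, PF, STATES, TransitionMatrix, ValidationError
from .psa import DistributionSpec, fit_moments
from .rwd import REQUIRED_COLUMNS
from .valuation import arm_matrices

_COST_COMPONENTS = ("direct_medical", "direct_nonmedical", "indirect")
_COST_COLS = {
    "direct_medical": "direct_medical_idr",
    "direct_nonmedical": "direct_nonmedical_idr",
    "indirect": "indirect_idr",
}

#: study cohort sizes: 139 patients, 96 of them on bevacizumab
DEFAULT_N_PATIENTS: dict[str, int] = {"chemo": 43, "chemo_bev": 96}


@dataclass(frozen=True)
class GeneratorConfig:
    """Generating truth for one synthetic cohort.

    ``costs[arm][state][component]`` and ``utilities[arm][state]`` are
    ``(mean, se)`` pairs on the per-cycle scale; cost noise is gamma and
    utility noise beta, fitted by method of moments, matching the
    distribution vocabulary of the probabilistic sensitivity analysis.
    ``censoring_fraction`` of patients are censored at a uniformly random
    cycle within follow-up.  ``seed`` is mandatory: every record is
    reproducible from the configuration alone.
    """

    matrices: Mapping[str, TransitionMatrix]
    n_patients: Mapping[str, int]
    costs: Mapping[str, Mapping[str, Mapping[str, tuple[float, float]]]]
    utilities: Mapping[str, Mapping[str, tuple[float, float]]]
    seed: int
    follow_up_cycles: int = 36
    censoring_fraction: float = 0.2
    cycle_months: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.censoring_fraction < 1.0:
            raise ValidationError("censoring_fraction must lie in [0, 1)")
        if self.follow_up_cycles < 1:
            raise ValidationError("follow_up_cycles must be at least 1")
        for arm, n in self.n_patients.items():
            if n < 1:
                raise ValidationError(f"n_patients for arm '{arm}' must be positive")


def generator_config_from_model(
    config: Optional[ModelConfig] = None,
    data_source: DataSource = "real_world",
    n_patients: Optional[Mapping[str, int]] = None,
    seed: int = 0,
    follow_up_cycles: int = 36,
    censoring_fraction: float = 0.2,
) -> GeneratorConfig:
    """Generating truth taken from a model configuration.

    Defaults reproduce the study conditions: real-world transition
    probabilities, the published cost and utility means/SEs, and the
    study's 43 + 96 patient arms.
    """
    cfg = config or default_config()
    mats = arm_matrices(cfg, data_source)
    costs = {
        arm: {
            state: {
                comp: (
                    getattr(getattr(getattr(cfg.costs_idr, arm), state), comp).mean,
                    getattr(getattr(getattr(cfg.costs_idr, arm), state), comp).se,
                )
                for comp in _COST_COMPONENTS
            }
            for state in ("progression_free", "progressive")
        }
        for arm in ("chemo", "chemo_bev")
    }
    utilities = {
        arm: {
            state: (
                getattr(getattr(cfg.utilities, arm), state).mean,
                getattr(getattr(cfg.utilities, arm), state).se,
            )
            for state in ("progression_free", "progressive")
        }
        for arm in ("chemo", "chemo_bev")
    }
    return GeneratorConfig(
        matrices=mats,
        n_patients=dict(n_patients or DEFAULT_N_PATIENTS),
        costs=costs,
        utilities=utilities,
        seed=seed,
        follow_up_cycles=follow_up_cycles,
        censoring_fraction=censoring_fraction,
    )


def _value_spec(family: str, mean: float, se: float) -> DistributionSpec:
    try:
        return fit_moments(family, mean, se)
    except ValidationError as exc:
        raise ValidationError(f"infeasible {family} moments (mean={mean}, se={se}): {exc}")


def _simulate_paths(
    matrix: TransitionMatrix, n: int, cycles: int, rng: np.random.Generator
) -> np.ndarray:
    """State paths, shape (n, cycles+1); everyone starts progression-free."""
    states = np.full((n, cycles + 1), PF, dtype=np.int64)
    cum = matrix.p.cumsum(axis=1)
    for k in range(cycles):
        u = rng.random(n)
        states[:, k + 1] = (u[:, None] > cum[states[:, k]]).sum(axis=1)
    return states


def generate(config: GeneratorConfig) -> pd.DataFrame:
    """Simulate one cohort of patient records.

    Per patient: the state path follows the arm's true chain from
    progression-free at cycle 0; every observed alive cycle yields a
    billing/interview row (gamma cost components, beta utility) at the
    cycle-boundary month; death adds a terminal row flagged ``death=1``;
    censored patients stop early with ``censored=1`` on their last row.
    """
    rng = np.random.default_rng(config.seed)
    frames: list[pd.DataFrame] = []
    pid_offset = 0
    for arm in sorted(config.n_patients):
        n = config.n_patients[arm]
        T = config.follow_up_cycles
        paths = _simulate_paths(config.matrices[arm], n, T, rng)

        # death cycle (first cycle in state death), or T+1 if none in window
        is_dead = paths == DEATH
        death_cycle = np.where(is_dead.any(axis=1), is_dead.argmax(axis=1), T + 1)

        censored = rng.random(n) < config.censoring_fraction
        censor_cycle = np.where(censored, rng.integers(1, T + 1, size=n), T)
        # censoring only bites if it precedes observed death
        effective_censor = np.where(censor_cycle < death_cycle, censor_cycle, T + 1)

        last_alive = np.minimum(
            np.where(effective_censor <= T, effective_censor, T),
            np.minimum(death_cycle - 1, T),
        )
        rows: list[dict] = []
        specs_cost = {
            state: {
                comp: _value_spec("gamma", *config.costs[arm][state][comp])
                for comp in _COST_COMPONENTS
            }
            for state in ("progression_free", "progressive")
        }
        specs_util = {
            state: _value_spec("beta", *config.utilities[arm][state])
            for state in ("progression_free", "progressive")
        }
        for i in range(n):
            pid = f"pt{pid_offset + i:05d}"
            for k in range(int(last_alive[i]) + 1):
                rows.append(
                    {
                        "patient_id": pid,
                        "arm": arm,
                        "obs_month": k * config.cycle_months,
                        "state": STATES[paths[i, k]],
                        "death": 0,
                        "censored": int(
                            effective_censor[i] <= T and k == last_alive[i]
                        ),
                    }
                )
            if death_cycle[i] <= T and effective_censor[i] > T:
                rows.append(
                    {
                        "patient_id": pid,
                        "arm": arm,
                        "obs_month": death_cycle[i] * config.cycle_months,
                        "state": "death",
                        "death": 1,
                        "censored": 0,
                    }
                )
        frame = pd.DataFrame(rows)
        for col in (*_COST_COLS.values(), "eq5d_index"):
            frame[col] = np.nan
        # fill billing and interview noise vectorized per alive state
        for state in ("progression_free", "progressive"):
            mask = (frame["state"] == state).to_numpy()
            m = int(mask.sum())
            if m == 0:
                continue
            for comp in _COST_COMPONENTS:
                frame.loc[mask, _COST_COLS[comp]] = specs_cost[state][comp].sample(
                    rng, m
                )
            frame.loc[mask, "eq5d_index"] = np.clip(
                specs_util[state].sample(rng, m), 0.0, 1.0
            )
        frames.append(frame)
        pid_offset += n
    out = pd.concat(frames, ignore_index=True)
    return out[list(REQUIRED_COLUMNS)]


# ---------------------------------------------------------------------------
# Worked fixture: a hand-countable golden dataset for the estimator
# ---------------------------------------------------------------------------

# ten patients, at most six cycles, chemotherapy arm; F = progression_free,
# P = progressive; a trailing "D" is a death at the next cycle boundary
_FIXTURE_PATHS: dict[str, str] = {
    "fx00": "FFPPD",
    "fx01": "FFFPP",
    "fx02": "FPPD",
    "fx03": "FFFFF",
    "fx04": "FFP",
    "fx05": "FFF",
    "fx06": "FFF",
    "fx07": "F",
    "fx08": "FFF",
    "fx09": "FFD",
}

#: hand-counted expected estimates for the fixture under a Beta(1,1) prior:
#: progression-free at-risk 20 (15 stay, 4 progress, 1 die),
#: progressive at-risk 5 (3 stay, 2 die)
FIXTURE_EXPECTED: dict[tuple[str, str], dict[str, float]] = {
    ("progression_free", "progression_free"): {"point": 0.75, "alpha": 16, "beta": 6},
    ("progression_free", "progressive"): {"point": 0.20, "alpha": 5, "beta": 17},
    ("progression_free", "death"): {"point": 0.05, "alpha": 2, "beta": 20},
    ("progressive", "progressive"): {"point": 0.60, "alpha": 4, "beta": 3},
    ("progressive", "death"): {"point": 0.40, "alpha": 3, "beta": 4},
}

_FIXTURE_VALUES = {
    "progression_free": {
        "direct_medical_idr": 10_000_000.0,
        "direct_nonmedical_idr": 1_000_000.0,
        "indirect_idr": 200_000.0,
        "eq5d_index": 0.8,
    },
    "progressive": {
        "direct_medical_idr": 8_000_000.0,
        "direct_nonmedical_idr": 1_000_000.0,
        "indirect_idr": 200_000.0,
        "eq5d_index": 0.6,
    },
}


def worked_fixture() -> tuple[pd.DataFrame, dict[tuple[str, str], dict[str, float]]]:
    """Deterministic 10-patient dataset with hand-countable transitions.

    Returns the record table and the expected per-transition estimates
    (point, alpha, beta under the uniform prior).  Regeneration is
    bit-identical: the fixture is a constant, not a simulation.
    """
    rows = []
    for pid, path in _FIXTURE_PATHS.items():
        cycle = 0
        for ch in path:
            if ch == "D":
                rows.append(
                    {
                        "patient_id": pid,
                        "arm": "chemo",
                        "obs_month": cycle * 2.0,
                        "state": "death",
                        "death": 1,
                        "censored": 0,
                        "eq5d_index": np.nan,
                        "direct_medical_idr": np.nan,
                        "direct_nonmedical_idr": np.nan,
                        "indirect_idr": np.nan,
                    }
                )
            else:
                state = "progression_free" if ch == "F" else "progressive"
                row = {
                    "patient_id": pid,
                    "arm": "chemo",
                    "obs_month": cycle * 2.0,
                    "state": state,
                    "death": 0,
                    "censored": 0,
                }
                row.update(_FIXTURE_VALUES[state])
                rows.append(row)
            cycle += 1
    df = pd.DataFrame(rows)[list(REQUIRED_COLUMNS)]
    return df, {k: dict(v) for k, v in FIXTURE_EXPECTED.items()}
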