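"""Discrete-time three-state Markov cohort engine.

States are progression-free (PF), progressive disease (PD) and death,
in that order.  Death is absorbing and PD never reverts to PF: the
transition structure is

    PF -> PF | PD | death
    PD ->      PD | death
    death ->        death

The cohort moves in fixed 2-month cycles; a cohort trace records the
fraction of the cohort occupying each state at every cycle boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

STATES: tuple[str, str, str] = ("progression_free", "progressive", "death")
PF, PD, DEATH = 0, 1, 2

#: maximum tolerated raw row sum before the input is treated as mis-entered
MAX_RAW_ROW_SUM = 1.05


class ValidationError(ValueError):
    """Raised when inputs violate the model's structural constraints."""


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic 3x3 matrix of per-cycle transition probabilities."""

    p: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.p, dtype=float)
        if arr.shape != (3, 3):
            raise ValidationError(f"transition matrix must be 3x3, got {arr.shape}")
        if np.any(arr < 0) or np.any(arr > 1):
            raise ValidationError("transition probabilities must lie in [0, 1]")
        if not np.allclose(arr.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("transition matrix rows must sum to 1")
        if not np.array_equal(arr[DEATH], [0.0, 0.0, 1.0]):
            raise ValidationError("death row must be absorbing (0, 0, 1)")
        if arr[PD, PF] != 0.0:
            raise ValidationError("backward transition progressive->progression_free must be 0")
        object.__setattr__(self, "p", arr)

    def __getitem__(self, idx):
        return self.p[idx]


@dataclass(frozen=True)
class RiskRatioPair:
    """Pooled risk ratios (intervention vs. comparator) with standard errors.

    ``rr_pfs`` acts on the progression transition, ``rr_os`` on both death
    transitions.
    """

    rr_pfs: float
    rr_os: float
    se_pfs: float = 0.0
    se_os: float = 0.0

    def __post_init__(self) -> None:
        if self.rr_pfs <= 0 or self.rr_os <= 0:
            raise ValidationError("risk ratios must be strictly positive")


@dataclass(frozen=True)
class CohortTrace:
    """State-occupancy fractions by cycle; the engine's central output."""

    occupancy: np.ndarray  # shape (n_cycles + 1, 3)
    cycle_length_months: float = 2.0
    start_age_years: float = 50.0

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def alive(self) -> np.ndarray:
        """Fraction alive (PF + PD) at each cycle boundary."""
        return self.occupancy[:, PF] + self.occupancy[:, PD]

    def ages(self) -> np.ndarray:
        cycles = np.arange(self.occupancy.shape[0])
        return self.start_age_years + cycles * self.cycle_length_months / 12.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle": np.arange(self.occupancy.shape[0]),
                "age_years": self.ages(),
                "occupancy_progression_free": self.occupancy[:, PF],
                "occupancy_progressive": self.occupancy[:, PD],
                "occupancy_death": self.occupancy[:, DEATH],
            }
        )


def build_matrix(
    raw_rows: Mapping[str, float],
    policy: str = "proportional",
) -> TransitionMatrix:
    """Assemble a valid transition matrix from raw named probabilities.

    Parameters
    ----------
    raw_rows
        Mapping with keys ``progression_free_to_progression_free``,
        ``progression_free_to_progressive``, ``progression_free_to_death``,
        ``progressive_to_progressive``, ``progressive_to_death``.  The
        published rows sum to 0.999, so each row is repaired to sum to
        exactly 1.
    policy
        ``proportional`` rescales every entry of a row by its sum;
        ``residual_to_death`` leaves non-death entries untouched and
        assigns the shortfall (or excess) to the death transition.

    Raises
    ------
    ValidationError
        If any probability is negative or a row's raw sum exceeds 1.05
        (treated as a mis-entered configuration) or is not positive.
    """
    pf_row = np.array(
        [
            raw_rows["progression_free_to_progression_free"],
            raw_rows["progression_free_to_progressive"],
            raw_rows["progression_free_to_death"],
        ],
        dtype=float,
    )
    pd_row = np.array(
        [
            0.0,
            raw_rows["progressive_to_progressive"],
            raw_rows["progressive_to_death"],
        ],
        dtype=float,
    )
    rows = {"progression_free": pf_row, "progressive": pd_row}
    out = np.zeros((3, 3))
    for i, (name, row) in enumerate(rows.items()):
        if np.any(row < 0):
            raise ValidationError(f"negative probability in row '{name}'")
        total = row.sum()
        if total <= 0:
            raise ValidationError(f"row '{name}' has non-positive sum {total}")
        if total > MAX_RAW_ROW_SUM:
            raise ValidationError(
                f"row '{name}' sums to {total:.4g} > {MAX_RAW_ROW_SUM}; "
                "probabilities are likely mis-entered"
            )
        if policy == "proportional":
            out[i] = row / total
        elif policy == "residual_to_death":
            residual = 1.0 - (total - row[DEATH])
            if residual < 0:
                raise ValidationError(
                    f"row '{name}': non-death entries sum to more than 1 "
                    "under residual_to_death policy"
                )
            out[i] = row
            out[i, DEATH] = residual
        else:
            raise ValidationError(f"unknown normalization policy '{policy}'")
    out[DEATH] = (0.0, 0.0, 1.0)
    return TransitionMatrix(out)


def _adjust(p: float, rr: float, mode: str) -> float:
    if mode == "hazard":
        # treat the ratio as acting on the per-cycle hazard:
        # p' = 1 - (1-p)^rr, the standard probability/rate conversion
        return 1.0 - (1.0 - p) ** rr
    if mode == "direct":
        return rr * p
    raise ValidationError(f"unknown risk-ratio mode '{mode}'")


def apply_risk_ratios(
    base: TransitionMatrix,
    rr: RiskRatioPair,
    mode: str = "hazard",
) -> TransitionMatrix:
    """Derive an intervention arm's matrix from a comparator matrix.

    The progression transition (PF->PD) is adjusted by ``rr_pfs`` and both
    death transitions (PF->death, PD->death) by ``rr_os``; the diagonal
    entries absorb the change so rows still sum to 1.  Under the default
    ``hazard`` mode, p' = 1 - (1-p)^rr, which maps [0,1] into [0,1] for
    any rr > 0; the ``direct`` mode (p' = rr*p) can push probabilities
    above 1 for rr > 1 and then raises.
    """
    p = base.p.copy()
    p[PF, PD] = _adjust(base[PF, PD], rr.rr_pfs, mode)
    p[PF, DEATH] = _adjust(base[PF, DEATH], rr.rr_os, mode)
    p[PD, DEATH] = _adjust(base[PD, DEATH], rr.rr_os, mode)
    p[PF, PF] = 1.0 - p[PF, PD] - p[PF, DEATH]
    p[PD, PD] = 1.0 - p[PD, DEATH]
    if np.any(p < 0) or np.any(p > 1):
        raise ValidationError(
            "risk-ratio adjustment pushed a probability outside [0, 1]"
        )
    return TransitionMatrix(p)


def add_background_mortality(
    matrix: TransitionMatrix, hazard_per_cycle: float
) -> TransitionMatrix:
    """Overlay an other-cause per-cycle death probability on both alive states.

    The background risk competes independently with disease-specific death:
    p_death' = 1 - (1 - p_death)(1 - h); surviving transitions are scaled
    down proportionally.  A zero hazard returns the matrix unchanged.
    """
    if hazard_per_cycle == 0.0:
        return matrix
    if not 0.0 < hazard_per_cycle < 1.0:
        raise ValidationError("background hazard must lie in [0, 1)")
    p = matrix.p.copy()
    for state in (PF, PD):
        survive = 1.0 - hazard_per_cycle
        p[state, :DEATH] *= survive
        p[state, DEATH] = 1.0 - p[state, :DEATH].sum()
    return TransitionMatrix(p)


def run_cohort(
    matrix: TransitionMatrix,
    horizon_cycles: int,
    start: Sequence[float] = (1.0, 0.0, 0.0),
    cycle_length_months: float = 2.0,
    start_age_years: float = 50.0,
) -> CohortTrace:
    """Propagate the cohort through ``horizon_cycles`` transitions.

    ``occupancy[k+1] = occupancy[k] @ matrix``; the trace has
    ``horizon_cycles + 1`` rows and each row sums to 1 up to floating
    error (conservation of the cohort).
    """
    if horizon_cycles < 1:
        raise ValidationError("horizon_cycles must be at least 1")
    start = np.asarray(start, dtype=float)
    if start.shape != (3,) or np.any(start < 0) or not np.isclose(start.sum(), 1.0):
        raise ValidationError("start occupancy must be 3 non-negative fractions summing to 1")
    occ = np.empty((horizon_cycles + 1, 3))
    occ[0] = start
    for k in range(horizon_cycles):
        occ[k + 1] = occ[k] @ matrix.p
    return CohortTrace(occ, cycle_length_months, start_age_years)


def default_horizon(
    matrix: TransitionMatrix,
    start_age_years: float = 50.0,
    max_age_years: float = 100.0,
    residual_alive_tol: float = 1e-4,
    cycle_length_months: float = 2.0,
) -> int:
    """Operationalize a "lifetime" horizon.

    Returns the smaller of (a) the number of cycles until ``max_age_years``
    and (b) the first cycle at which the surviving fraction of the cohort
    falls below ``residual_alive_tol``; always at least 1 cycle.
    """
    if max_age_years <= start_age_years:
        raise ValidationError("max_age_years must exceed start_age_years")
    cycles_per_year = 12.0 / cycle_length_months
    upper = int(np.ceil((max_age_years - start_age_years) * cycles_per_year))
    occ = np.array([1.0, 0.0, 0.0])
    for k in range(1, upper + 1):
        occ = occ @ matrix.p
        if occ[PF] + occ[PD] < residual_alive_tol:
            return max(k, 1)
    return max(upper, 1)


def microsimulate(
    matrix: TransitionMatrix,
    n_patients: int,
    horizon_cycles: int,
    seed: int,
    start_state: int = PF,
) -> np.ndarray:
    """Empirical state distribution from per-patient simulation of the chain.

    Returns an array of shape ``(horizon_cycles + 1, 3)`` with the fraction
    of simulated patients in each state at each cycle.  Serves as an
    independent Monte-Carlo oracle for :func:`run_cohort`: the cohort trace
    is the exact expectation of this empirical distribution.
    """
    rng = np.random.default_rng(seed)
    states = np.full(n_patients, start_state, dtype=np.int64)
    counts = np.empty((horizon_cycles + 1, 3))
    cum = matrix.p.cumsum(axis=1)
    for k in range(horizon_cycles + 1):
        counts[k] = np.bincount(states, minlength=3) / n_patients
        if k == horizon_cycles:
            break
        u = rng.random(n_patients)
        states = (u[:, None] > cum[states]).sum(axis=1)
    return counts
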