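"""Estimation of model inputs from patient-level records.

Consumes a long table of per-visit observations (one row per patient per
observation: state, billed cost components, optional EQ-5D-5L index) and
produces the quantities the Markov model needs:

* per-cycle transition probabilities with Beta uncertainty parameters,
  by discretizing each patient's trajectory onto the 2-month cycle grid
  (last observation carried forward) and counting transitions;
* Kaplan-Meier median overall survival per arm;
* per-state, per-arm mean cost components and utilities with standard
  errors, shaped for direct feeding into the model configuration.

Expected input columns: ``patient_id``, ``arm`` (``chemo`` |
``chemo_bev``), ``obs_month``, ``state`` (``progression_free`` |
``progressive`` | ``death``), ``direct_medical_idr``,
``direct_nonmedical_idr``, ``indirect_idr``, ``eq5d_index`` (blank
allowed), ``death`` (0/1 event flag), ``censored`` (0/1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .markov import STATES, TransitionMatrix, ValidationError, build_matrix

ALIVE_STATES = ("progression_free", "progressive")
TRANSITIONS = (
    ("progression_free", "progression_free"),
    ("progression_free", "progressive"),
    ("progression_free", "death"),
    ("progressive", "progressive"),
    ("progressive", "death"),
)

#: below this many at-risk cycles (or records) per state, estimates are
#: flagged as under the study's minimum-sample guidance
MIN_RECORDS_PER_STATE = 75

REQUIRED_COLUMNS = (
    "patient_id",
    "arm",
    "obs_month",
    "state",
    "direct_medical_idr",
    "direct_nonmedical_idr",
    "indirect_idr",
    "eq5d_index",
    "death",
    "censored",
)


@dataclass(frozen=True)
class TransitionEstimate:
    """One transition probability estimated from cycle counts.

    ``point`` is the raw event fraction; ``alpha``/``beta`` include the
    prior (uniform Beta(1,1) by default) so they are always valid inputs
    for probabilistic sensitivity analysis.
    """

    point: float
    alpha: float
    beta: float
    events: int
    at_risk: int

    def credible_interval(self, level: float = 0.95) -> tuple[float, float]:
        """Central posterior credible interval of the probability."""
        lo = (1.0 - level) / 2.0
        dist = stats.beta(self.alpha, self.beta)
        return float(dist.ppf(lo)), float(dist.ppf(1.0 - lo))


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValidationError(f"records table missing columns: {missing}")
    bad_state = set(records["state"]) - set(STATES)
    if bad_state:
        raise ValidationError(f"unknown states in records: {sorted(bad_state)}")
    df = records.sort_values(["patient_id", "obs_month"], kind="stable")
    conflicts = (
        df.groupby(["patient_id", "obs_month"])["state"].nunique().loc[lambda s: s > 1]
    )
    if len(conflicts):
        ids = sorted({pid for pid, _ in conflicts.index})
        raise ValidationError(
            f"conflicting observations at the same month for patients: {ids}"
        )
    for pid, grp in df.groupby("patient_id", sort=False):
        states = grp["state"].to_numpy()
        dead = np.flatnonzero(states == "death")
        if dead.size and dead[0] < len(states) - 1:
            raise ValidationError(f"patient {pid!r} has observations after death")
    return df


def discretize(records: pd.DataFrame, cycle_months: float = 2.0) -> pd.DataFrame:
    """Map irregular observation dates onto cycle-boundary states.

    The state assigned to cycle ``k`` is the last observed alive state
    before the end of that cycle's interval (month ``< cycle_months*(k+1)``,
    i.e. last observation carried forward).  A death at month ``m`` is
    recorded at the boundary of the cycle containing it,
    ``ceil(m / cycle_months)``, with alive states carried forward up to the
    preceding cycle.  Censoring simply truncates the sequence at the last
    observed cycle.

    Returns a tidy frame with columns ``patient_id``, ``arm``, ``cycle``,
    ``state``.
    """
    df = _validate_records(records)
    out_rows: list[tuple] = []
    for (pid, arm), grp in df.groupby(["patient_id", "arm"], sort=False):
        alive = grp[grp["state"] != "death"]
        months = alive["obs_month"].to_numpy(dtype=float)
        states = alive["state"].to_numpy()
        death = grp[grp["state"] == "death"]
        death_cycle: Optional[int] = None
        if len(death):
            death_cycle = int(math.ceil(float(death["obs_month"].iloc[0]) / cycle_months))
        if len(alive):
            if death_cycle is not None:
                # alive (by carry-forward) through the cycle before death
                last_alive_cycle = death_cycle - 1
            else:
                last_alive_cycle = int(math.floor(months[-1] / cycle_months))
            for k in range(last_alive_cycle + 1):
                idx = np.searchsorted(months, cycle_months * (k + 1), side="left") - 1
                if idx < 0:
                    continue  # no observation yet covers this cycle
                out_rows.append((pid, arm, k, states[idx]))
        if death_cycle is not None:
            out_rows.append((pid, arm, death_cycle, "death"))
    return pd.DataFrame(out_rows, columns=["patient_id", "arm", "cycle", "state"])


def count_transitions(sequences: pd.DataFrame) -> pd.DataFrame:
    """Count observed cycle-to-cycle transitions, per arm.

    Only strictly consecutive cycles contribute (a gap in observation
    breaks the chain).  Returns a frame with columns ``arm``,
    ``from_state``, ``to_state``, ``count``.
    """
    rows = []
    for (pid, arm), grp in sequences.groupby(["patient_id", "arm"], sort=False):
        grp = grp.sort_values("cycle")
        cyc = grp["cycle"].to_numpy()
        st = grp["state"].to_numpy()
        consec = np.flatnonzero(np.diff(cyc) == 1)
        for i in consec:
            rows.append((arm, st[i], st[i + 1]))
    counted = pd.DataFrame(rows, columns=["arm", "from_state", "to_state"])
    if counted.empty:
        return pd.DataFrame(columns=["arm", "from_state", "to_state", "count"])
    return (
        counted.groupby(["arm", "from_state", "to_state"])
        .size()
        .rename("count")
        .reset_index()
    )


def estimate_transitions(
    sequences: pd.DataFrame,
    prior: tuple[float, float] = (1.0, 1.0),
) -> dict[str, dict[tuple[str, str], Optional[TransitionEstimate]]]:
    """Per-arm transition-probability estimates from discretized sequences.

    For each allowed transition, ``point = events / at-risk cycles`` and
    the Beta parameters are ``events + prior[0]`` / ``non-events +
    prior[1]``.  The default uniform Beta(1,1) prior keeps alpha and beta
    strictly positive so every estimate is usable in PSA; pass ``(0, 0)``
    for raw counts.  A transition whose from-state was never at risk is
    returned as ``None``.
    """
    counts = count_transitions(sequences)
    backward = counts[
        (counts["from_state"] == "progressive")
        & (counts["to_state"] == "progression_free")
    ]
    if len(backward) and backward["count"].sum() > 0:
        raise ValidationError(
            "records contain backward transitions progressive->progression_free, "
            "which the three-state model excludes"
        )
    out: dict[str, dict[tuple[str, str], Optional[TransitionEstimate]]] = {}
    for arm in sorted(sequences["arm"].unique()):
        sub = counts[counts["arm"] == arm]
        at_risk = {
            s: int(sub[sub["from_state"] == s]["count"].sum()) for s in ALIVE_STATES
        }
        for state, n in at_risk.items():
            if 0 < n < MIN_RECORDS_PER_STATE:
                warnings.warn(
                    f"arm '{arm}': only {n} at-risk cycles in state '{state}' "
                    f"(minimum-sample guidance is {MIN_RECORDS_PER_STATE})",
                    stacklevel=2,
                )
        arm_est: dict[tuple[str, str], Optional[TransitionEstimate]] = {}
        for frm, to in TRANSITIONS:
            n = at_risk[frm]
            if n == 0:
                arm_est[(frm, to)] = None
                continue
            ev = int(
                sub[(sub["from_state"] == frm) & (sub["to_state"] == to)]["count"].sum()
            )
            arm_est[(frm, to)] = TransitionEstimate(
                point=ev / n,
                alpha=ev + prior[0],
                beta=(n - ev) + prior[1],
                events=ev,
                at_risk=n,
            )
        out[arm] = arm_est
    return out


def estimates_to_matrix(
    estimates: dict[tuple[str, str], Optional[TransitionEstimate]],
    policy: str = "proportional",
) -> TransitionMatrix:
    """Assemble estimated transition probabilities into a valid matrix."""
    missing = [k for k, v in estimates.items() if v is None]
    if missing:
        raise ValidationError(
            f"transitions {missing} could not be estimated (no at-risk cycles); "
            "collect more records or supply external values"
        )
    raw = {f"{frm}_to_{to}": est.point for (frm, to), est in estimates.items()}
    return build_matrix(raw, policy=policy)


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------


def survival_months(
    records: pd.DataFrame, arm: Optional[str] = None
) -> pd.DataFrame:
    """Per-patient time-to-death (months) with an event indicator.

    Death time is the recorded death month; patients without a death row
    are censored at their last observation.
    """
    df = _validate_records(records)
    if arm is not None:
        df = df[df["arm"] == arm]
    rows = []
    for pid, grp in df.groupby("patient_id", sort=False):
        death = grp[grp["state"] == "death"]
        if len(death):
            rows.append((pid, float(death["obs_month"].iloc[0]), 1))
        else:
            rows.append((pid, float(grp["obs_month"].max()), 0))
    return pd.DataFrame(rows, columns=["patient_id", "duration_months", "event"])


def km_median(
    durations: np.ndarray | pd.Series, events: np.ndarray | pd.Series
) -> Optional[float]:
    """Kaplan-Meier median survival: earliest time with S(t) <= 0.5.

    Returns ``None`` ("not reached") when the product-limit curve never
    crosses 0.5, including the all-censored case.
    """
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=int)
    if durations.size == 0:
        raise ValidationError("no survival data supplied")
    if events.sum() == 0:
        return None
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    med = kmf.median_survival_time_
    return None if np.isinf(med) else float(med)


# ---------------------------------------------------------------------------
# Costs and utilities
# ---------------------------------------------------------------------------

_COST_COLUMNS = {
    "direct_medical": "direct_medical_idr",
    "direct_nonmedical": "direct_nonmedical_idr",
    "indirect": "indirect_idr",
}


def _mean_se(values: np.ndarray, n_patients: int) -> dict[str, Optional[float]]:
    mean = float(np.mean(values))
    if n_patients < 2 or values.size < 2:
        return {"mean": mean, "se": None}
    return {"mean": mean, "se": float(np.std(values, ddof=1) / math.sqrt(values.size))}


def summarize_costs_utilities(
    records: pd.DataFrame, arm: str, state: str
) -> dict[str, dict[str, Optional[float]]]:
    """Mean and standard error of each per-cycle cost component and utility.

    Means are taken over contributing observation rows (per-visit billing
    amounts and interview utilities); the SE is the standard error of that
    mean.  With fewer than two contributing patients the SE is reported as
    ``None`` (unavailable) rather than zero.
    """
    if state not in ALIVE_STATES:
        raise ValidationError(f"costs/utilities are summarized for alive states, not '{state}'")
    df = _validate_records(records)
    sub = df[(df["arm"] == arm) & (df["state"] == state)]
    if sub.empty:
        raise ValidationError(f"no records for arm '{arm}' in state '{state}'")
    if len(sub) < MIN_RECORDS_PER_STATE:
        warnings.warn(
            f"arm '{arm}', state '{state}': {len(sub)} records, below the "
            f"minimum-sample guidance of {MIN_RECORDS_PER_STATE}",
            stacklevel=2,
        )
    out: dict[str, dict[str, Optional[float]]] = {}
    for name, col in _COST_COLUMNS.items():
        vals = sub[col].dropna().to_numpy(dtype=float)
        if vals.size == 0:
            raise ValidationError(f"no '{col}' values for arm '{arm}', state '{state}'")
        n_pat = sub.loc[sub[col].notna(), "patient_id"].nunique()
        out[name] = _mean_se(vals, n_pat)
    util = sub["eq5d_index"].dropna()
    if len(util):
        out["utility"] = _mean_se(
            util.to_numpy(dtype=float), sub.loc[util.index, "patient_id"].nunique()
        )
    else:
        out["utility"] = {"mean": None, "se": None}
    return out


def config_fragment(
    records: pd.DataFrame,
    cycle_months: float = 2.0,
    prior: tuple[float, float] = (1.0, 1.0),
) -> dict:
    """Full model-config fragment estimated from records.

    Returns a nested dict with ``transition_probabilities`` (real-world
    blocks), ``costs_idr`` and ``utilities`` keys matching the model
    configuration schema, ready to merge over a base configuration.
    """
    seqs = discretize(records, cycle_months)
    est = estimate_transitions(seqs, prior)
    block_names = {"chemo": "chemo_real_world", "chemo_bev": "chemo_bev_real_world"}
    tp: dict[str, dict] = {}
    for arm, block in block_names.items():
        if arm not in est:
            continue
        tp[block] = {}
        for (frm, to), e in est[arm].items():
            if e is None:
                raise ValidationError(
                    f"arm '{arm}': transition {frm}->{to} has no at-risk cycles"
                )
            tp[block][f"{frm}_to_{to}"] = {
                "value": e.point,
                "alpha": e.alpha,
                "beta": e.beta,
            }
    costs: dict[str, dict] = {}
    utils: dict[str, dict] = {}
    for arm in sorted(records["arm"].unique()):
        costs[arm] = {}
        utils[arm] = {}
        for state in ALIVE_STATES:
            summary = summarize_costs_utilities(records, arm, state)
            costs[arm][state] = {
                comp: {
                    "mean": summary[comp]["mean"],
                    "se": summary[comp]["se"] or 0.0,
                }
                for comp in _COST_COLUMNS
            }
            if summary["utility"]["mean"] is not None:
                utils[arm][state] = {
                    "mean": summary["utility"]["mean"],
                    "se": summary["utility"]["se"] or 0.0,
                }
    return {"transition_probabilities": tp, "costs_idr": costs, "utilities": utils}
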