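"""Probabilistic sensitivity analysis (PSA).

Every uncertain input is given a sampling distribution, all parameters are
drawn jointly and independently, the full deterministic pipeline is
re-evaluated per draw, and the results are summarized on the
cost-effectiveness plane and as a cost-effectiveness acceptability curve
(CEAC): the fraction of draws with positive net monetary benefit at each
willingness-to-pay value.

Family assignment (the source table prints only standard errors and, for
some transitions, beta parameters):

* transition probabilities with printed alpha/beta -> Beta with those
  parameters as printed (kept verbatim even where they are inconsistent
  with the point estimate); other transitions are fixed;
* utilities -> Beta by method of moments;
* costs -> Gamma by method of moments (components whose SE equals the
  mean become Gamma with shape 1, i.e. exponential — genuinely
  high-uncertainty inputs);
* risk ratios -> log-normal by method of moments.

After each draw, every transition row is re-assembled so drawn entries
keep their sampled values and undrawn entries are rescaled proportionally
into the remaining probability mass; a draw whose rows cannot form a valid
matrix is rejected and counted.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import Arm, DataSource, ModelConfig, PerspectiveLabel, TransitionBlock
from .markov import DEATH, PD, PF, RiskRatioPair, TransitionMatrix, ValidationError, apply_risk_ratios, build_matrix
from .valuation import StateValues, evaluate_scenario

_PF_ROW = (
    "progression_free_to_progression_free",
    "progression_free_to_progressive",
    "progression_free_to_death",
)
_PD_ROW = ("progressive_to_progressive", "progressive_to_death")


@dataclass(frozen=True)
class DistributionSpec:
    """One parameter's sampling distribution.

    ``family`` is one of ``beta``, ``gamma``, ``lognormal``, ``fixed``;
    ``params`` holds the family's native parameters (``alpha``/``beta``,
    ``shape``/``scale``, ``mu``/``sigma``, or ``value``).
    """

    family: str
    params: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "params", dict(self.params))
        if self.family not in ("beta", "gamma", "lognormal", "fixed"):
            raise ValidationError(f"unknown distribution family '{self.family}'")

    def mean(self) -> float:
        p = self.params
        if self.family == "fixed":
            return p["value"]
        if self.family == "beta":
            return p["alpha"] / (p["alpha"] + p["beta"])
        if self.family == "gamma":
            return p["shape"] * p["scale"]
        return math.exp(p["mu"] + p["sigma"] ** 2 / 2.0)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        p = self.params
        if self.family == "fixed":
            return np.full(n, p["value"])
        if self.family == "beta":
            return rng.beta(p["alpha"], p["beta"], size=n)
        if self.family == "gamma":
            return rng.gamma(p["shape"], p["scale"], size=n)
        return rng.lognormal(p["mu"], p["sigma"], size=n)


def fit_moments(family: str, mean: float, se: float) -> DistributionSpec:
    """Method-of-moments fit of a distribution to a mean and standard error.

    Beta: alpha = m*nu, beta = (1-m)*nu with nu = m(1-m)/s^2 - 1, feasible
    only when s^2 < m(1-m).  Gamma: shape = (m/s)^2, scale = s^2/m.
    Log-normal: sigma^2 = ln(1 + s^2/m^2), mu = ln(m) - sigma^2/2.
    A zero SE yields a fixed (degenerate) spec.
    """
    if se < 0:
        raise ValidationError("standard error must be non-negative")
    if se == 0:
        return DistributionSpec("fixed", {"value": mean})
    var = se * se
    if family == "beta":
        if not 0.0 < mean < 1.0:
            raise ValidationError(f"beta mean {mean} outside (0, 1)")
        if var >= mean * (1.0 - mean):
            raise ValidationError(
                f"infeasible beta moments (se^2 = {var:.4g} >= m(1-m) = "
                f"{mean * (1 - mean):.4g}); use a 'fixed' spec instead"
            )
        nu = mean * (1.0 - mean) / var - 1.0
        return DistributionSpec("beta", {"alpha": mean * nu, "beta": (1.0 - mean) * nu})
    if family == "gamma":
        if mean <= 0:
            raise ValidationError("gamma mean must be positive")
        return DistributionSpec("gamma", {"shape": (mean / se) ** 2, "scale": var / mean})
    if family == "lognormal":
        if mean <= 0:
            raise ValidationError("lognormal mean must be positive")
        sigma2 = math.log1p(var / mean**2)
        return DistributionSpec(
            "lognormal", {"mu": math.log(mean) - sigma2 / 2.0, "sigma": math.sqrt(sigma2)}
        )
    if family == "fixed":
        return DistributionSpec("fixed", {"value": mean})
    raise ValidationError(f"unknown distribution family '{family}'")


def _beta_sd(alpha: float, beta: float) -> float:
    s = alpha + beta
    return math.sqrt(alpha * beta / (s * s * (s + 1.0)))


def _tp_block_specs(
    prefix: str, block: TransitionBlock, se_scale: float
) -> dict[str, DistributionSpec]:
    specs: dict[str, DistributionSpec] = {}
    for name, entry in block:
        key = f"{prefix}.{name}"
        if entry.alpha is None:
            specs[key] = DistributionSpec("fixed", {"value": entry.value})
        elif se_scale == 1.0:
            specs[key] = DistributionSpec(
                "beta", {"alpha": entry.alpha, "beta": entry.beta}
            )
        else:
            # re-centre on the base-case value with the implied beta SD
            # scaled, so uncertainty can be shrunk toward the deterministic
            # model in convergence checks
            sd = _beta_sd(entry.alpha, entry.beta) * se_scale
            specs[key] = fit_moments("beta", entry.value, sd)
    return specs


def build_specs(
    config: ModelConfig,
    data_source: Optional[DataSource] = None,
    se_scale: float = 1.0,
) -> dict[str, DistributionSpec]:
    """Distribution specs for every uncertain parameter of a scenario.

    Parameter names are dotted paths: ``tp.<block>.<transition>``,
    ``rr.<endpoint>``, ``cost.<arm>.<state>.<component>``,
    ``util.<arm>.<state>``.  ``se_scale`` multiplies every standard error
    (and re-centres printed-alpha/beta transitions on their point
    estimates), which is useful for shrinking-uncertainty diagnostics;
    the default 1.0 keeps printed beta parameters verbatim.
    """
    ds: DataSource = data_source or config.scenario.data_source
    specs: dict[str, DistributionSpec] = {}
    tp = config.transition_probabilities
    if ds == "secondary":
        specs.update(_tp_block_specs("tp.chemo_secondary", tp.chemo_secondary, se_scale))
        for endpoint in ("progression_free_survival", "overall_survival"):
            entry = getattr(config.risk_ratios, endpoint)
            specs[f"rr.{endpoint}"] = fit_moments(
                "lognormal", entry.value, entry.se * se_scale
            )
    else:
        specs.update(_tp_block_specs("tp.chemo_real_world", tp.chemo_real_world, se_scale))
        specs.update(
            _tp_block_specs("tp.chemo_bev_real_world", tp.chemo_bev_real_world, se_scale)
        )
    for arm in ("chemo", "chemo_bev"):
        costs = getattr(config.costs_idr, arm)
        utils = getattr(config.utilities, arm)
        for state in ("progression_free", "progressive"):
            sc = getattr(costs, state)
            for comp in ("direct_medical", "direct_nonmedical", "indirect"):
                entry = getattr(sc, comp)
                specs[f"cost.{arm}.{state}.{comp}"] = fit_moments(
                    "gamma", entry.mean, entry.se * se_scale
                )
            u = getattr(utils, state)
            specs[f"util.{arm}.{state}"] = fit_moments("beta", u.mean, u.se * se_scale)
    return specs


def spec_digest(specs: Mapping[str, DistributionSpec]) -> str:
    """Stable SHA-256 digest of a spec set, for run provenance."""
    blob = json.dumps(
        {k: [v.family, dict(sorted(v.params.items()))] for k, v in sorted(specs.items())},
        sort_keys=True,
    )
    return hashlib.sha256(blob.encode()).hexdigest()


def sample_draws(
    specs: Mapping[str, DistributionSpec], n: int, seed: int
) -> pd.DataFrame:
    """``n`` independent joint draws of all parameters, one column each.

    Parameters are sampled independently (no correlation structure is
    assumed) in sorted name order from a single seeded generator, so the
    whole table — and therefore any individual draw — is reproducible from
    ``(specs, n, seed)``.
    """
    if n < 1:
        raise ValidationError("number of draws must be at least 1")
    rng = np.random.default_rng(seed)
    cols = {name: specs[name].sample(rng, n) for name in sorted(specs)}
    out = pd.DataFrame(cols)
    out.insert(0, "draw_id", np.arange(n))
    return out


# ---------------------------------------------------------------------------
# Draw -> model inputs
# ---------------------------------------------------------------------------


def _materialize_rows(
    block: TransitionBlock, drawn: Mapping[str, float]
) -> dict[str, float]:
    """Assemble raw rows from a draw, preserving sampled entries.

    Entries present in ``drawn`` keep their sampled values; the remaining
    entries of each row are rescaled proportionally into the residual mass
    ``1 - sum(drawn)``.  Raises if the drawn entries of a row already
    exceed 1 (the caller rejects such draws).
    """
    base = {name: entry.value for name, entry in block}
    out: dict[str, float] = {}
    for row in (_PF_ROW, _PD_ROW):
        drawn_names = [t for t in row if t in drawn]
        free_names = [t for t in row if t not in drawn]
        drawn_sum = sum(drawn[t] for t in drawn_names)
        if drawn_sum > 1.0:
            raise ValidationError(f"drawn probabilities in a row sum to {drawn_sum:.4g} > 1")
        for t in drawn_names:
            out[t] = drawn[t]
        if free_names:
            free_sum = sum(base[t] for t in free_names)
            residual = 1.0 - drawn_sum
            if free_sum <= 0:
                # no mass to apportion: give the whole residual to the first
                # free entry (degenerate but valid)
                for t in free_names:
                    out[t] = 0.0
                out[free_names[0]] = residual
            else:
                for t in free_names:
                    out[t] = base[t] * residual / free_sum
        elif not math.isclose(drawn_sum, 1.0):
            for t in drawn_names:
                out[t] = drawn[t] / drawn_sum
    return out


def _draw_matrices(
    config: ModelConfig,
    ds: DataSource,
    draw: Mapping[str, float],
    sampled: frozenset[str],
) -> dict[Arm, TransitionMatrix]:
    tp = config.transition_probabilities
    mode = config.settings.risk_ratio_mode
    policy = config.settings.normalization_policy

    def _block(prefix: str, block: TransitionBlock) -> TransitionMatrix:
        drawn = {
            name: draw[f"{prefix}.{name}"]
            for name, _ in block
            if f"{prefix}.{name}" in sampled
        }
        if not drawn:
            # no uncertainty on this block: reproduce the base-case matrix
            return build_matrix({n: e.value for n, e in block}, policy=policy)
        return build_matrix(_materialize_rows(block, drawn), policy="proportional")

    if ds == "real_world":
        return {
            "chemo": _block("tp.chemo_real_world", tp.chemo_real_world),
            "chemo_bev": _block("tp.chemo_bev_real_world", tp.chemo_bev_real_world),
        }
    chemo = _block("tp.chemo_secondary", tp.chemo_secondary)
    rr = RiskRatioPair(
        rr_pfs=draw["rr.progression_free_survival"], rr_os=draw["rr.overall_survival"]
    )
    return {"chemo": chemo, "chemo_bev": apply_risk_ratios(chemo, rr, mode=mode)}


def _draw_values(draw: Mapping[str, float]) -> dict[Arm, dict[str, StateValues]]:
    out: dict[Arm, dict[str, StateValues]] = {}
    for arm in ("chemo", "chemo_bev"):
        out[arm] = {
            state: StateValues(
                direct_medical=draw[f"cost.{arm}.{state}.direct_medical"],
                direct_nonmedical=draw[f"cost.{arm}.{state}.direct_nonmedical"],
                indirect=draw[f"cost.{arm}.{state}.indirect"],
                utility=min(draw[f"util.{arm}.{state}"], 1.0),
            )
            for state in ("progression_free", "progressive")
        }
    return out


def default_wtp_grid() -> np.ndarray:
    """0 to 1,000 million IDR in 10-million steps."""
    return np.arange(0.0, 1_000_000_001.0, 10_000_000.0)


@dataclass(frozen=True)
class PSAResult:
    """CE plane, CEAC and provenance for one PSA run."""

    ce_plane: pd.DataFrame  # draw_id, delta_cost_idr, delta_qaly
    ceac: pd.DataFrame  # wtp_idr, probability_cost_effective
    seed: int
    n: int
    rejected_draws: int
    spec_digest: str
    horizon_cycles: int

    def metadata(self) -> dict:
        return {
            "seed": self.seed,
            "n": self.n,
            "rejected_draws": self.rejected_draws,
            "spec_digest": self.spec_digest,
            "horizon_cycles": self.horizon_cycles,
        }


def ceac_from_ce_plane(
    ce_plane: pd.DataFrame, wtp_grid: Sequence[float]
) -> pd.DataFrame:
    """Acceptability curve: P(NMB > 0) across the willingness-to-pay grid."""
    wtp = np.asarray(wtp_grid, dtype=float)
    if wtp.size == 0:
        raise ValidationError("WTP grid must be non-empty")
    dq = ce_plane["delta_qaly"].to_numpy()
    dc = ce_plane["delta_cost_idr"].to_numpy()
    nmb = wtp[:, None] * dq[None, :] - dc[None, :]
    return pd.DataFrame(
        {"wtp_idr": wtp, "probability_cost_effective": (nmb > 0).mean(axis=1)}
    )


def run_psa(
    config: ModelConfig,
    n: int = 1000,
    seed: int = 0,
    wtp_grid: Optional[Sequence[float]] = None,
    data_source: Optional[DataSource] = None,
    perspective: Optional[PerspectiveLabel] = None,
    specs: Optional[Mapping[str, DistributionSpec]] = None,
) -> PSAResult:
    """Sample parameters, re-run the model per draw, and summarize.

    Each draw is evaluated through the same scenario pipeline as the
    deterministic base case, over the base case's lifetime horizon.  Draws
    whose transition rows cannot form a valid matrix are rejected and
    counted (this cannot happen with the default family assignment, whose
    supports respect the constraints).
    """
    ds: DataSource = data_source or config.scenario.data_source
    pl: PerspectiveLabel = perspective or config.scenario.perspective
    if specs is None:
        specs = build_specs(config, ds)
    base = evaluate_scenario(config, ds, pl)
    sampled = frozenset(k for k, v in specs.items() if v.family != "fixed")
    draws = sample_draws(specs, n, seed)
    rows = []
    rejected = 0
    for rec in draws.to_dict("records"):
        try:
            mats = _draw_matrices(config, ds, rec, sampled)
            vals = _draw_values(rec)
        except (ValidationError, ValueError):
            rejected += 1
            continue
        res = evaluate_scenario(
            config, ds, pl, matrices=mats, values=vals,
            horizon_cycles=base.horizon_cycles,
        )
        rows.append(
            {
                "draw_id": int(rec["draw_id"]),
                "delta_cost_idr": res.comparison.delta_cost_idr,
                "delta_qaly": res.comparison.delta_qaly,
            }
        )
    if not rows:
        raise ValidationError("every PSA draw was rejected; check the spec set")
    ce_plane = pd.DataFrame(rows)
    grid = default_wtp_grid() if wtp_grid is None else np.asarray(wtp_grid, float)
    ceac = ceac_from_ce_plane(ce_plane, grid)
    return PSAResult(
        ce_plane=ce_plane,
        ceac=ceac,
        seed=seed,
        n=n,
        rejected_draws=rejected,
        spec_digest=spec_digest(specs),
        horizon_cycles=base.horizon_cycles,
    )
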