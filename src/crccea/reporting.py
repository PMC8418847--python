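"""Scenario orchestration and result tables.

A *scenario* is a data source (secondary systematic-review inputs or
real-world estimates) combined with a costing perspective (healthcare or
societal).  This module runs scenarios deterministically or as a PSA,
writes plain CSV/JSON result files with full provenance (config digest,
seed, horizon), and formats the comparative cost-utility table in the
shape of the study's results table: per data source, cost (USD), QALYs
and the ICER of adding bevacizumab.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .config import DataSource, ModelConfig, PerspectiveLabel
from .psa import PSAResult, run_psa
from .valuation import ScenarioResult, evaluate_scenario

ARM_LABELS = {
    "chemo": "FOLFOX/FOLFIRI/XELOX",
    "chemo_bev": "FOLFOX/FOLFIRI/XELOX + Bevacizumab",
}


def summary_frame(result: ScenarioResult) -> pd.DataFrame:
    """Per-arm discounted totals as a tidy frame."""
    rows = []
    for arm in ("chemo", "chemo_bev"):
        s = result.summaries[arm]
        rows.append(
            {
                "arm": arm,
                "treatment": ARM_LABELS[arm],
                "scenario": result.data_source,
                "perspective": result.perspective,
                "cost_idr": s.total_cost_idr,
                "cost_usd": s.total_cost_usd,
                "qaly": s.total_qaly,
                "life_years_undiscounted": s.life_years_undiscounted,
            }
        )
    return pd.DataFrame(rows)


def comparison_frame(result: ScenarioResult) -> pd.DataFrame:
    """Incremental economics as a one-row frame."""
    c = result.comparison
    return pd.DataFrame(
        [
            {
                "scenario": result.data_source,
                "perspective": result.perspective,
                "delta_cost_idr": c.delta_cost_idr,
                "delta_cost_usd": c.delta_cost_usd,
                "delta_qaly": c.delta_qaly,
                "icer_idr_per_qaly": c.icer_idr_per_qaly,
                "icer_usd_per_qaly": c.icer_usd_per_qaly,
                "dominance": c.dominance,
                "wtp_idr_per_qaly": c.wtp_idr_per_qaly,
                "nmb_idr": c.nmb_idr,
                "cost_effective_at_threshold": c.cost_effective,
            }
        ]
    )


def run_scenario(
    config: ModelConfig,
    mode: str = "deterministic",
    seed: int = 0,
    out_dir: Optional[str | Path] = None,
    iterations: int = 1000,
    wtp_grid: Optional[Sequence[float]] = None,
    data_source: Optional[DataSource] = None,
    perspective: Optional[PerspectiveLabel] = None,
) -> tuple[ScenarioResult, Optional[PSAResult]]:
    """Run one scenario and optionally write its result files.

    ``mode`` is ``deterministic`` or ``psa`` (the PSA always includes the
    deterministic base case).  When ``out_dir`` is given, writes per-arm
    trace CSVs, a per-arm summary CSV, the incremental-comparison CSV, the
    PSA CE-plane/CEAC CSVs in psa mode, and a ``run_metadata.json`` with
    the config digest and seed so any file can be regenerated
    bit-identically.
    """
    if mode not in ("deterministic", "psa", "det"):
        raise ValueError(f"unknown mode '{mode}'")
    det = evaluate_scenario(config, data_source, perspective)
    psa_result: Optional[PSAResult] = None
    if mode == "psa":
        psa_result = run_psa(
            config,
            n=iterations,
            seed=seed,
            wtp_grid=wtp_grid,
            data_source=data_source,
            perspective=perspective,
        )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for arm, trace in det.traces.items():
            trace.to_frame().to_csv(out / f"trace_{arm}.csv", index=False)
        summary_frame(det).to_csv(out / "summary.csv", index=False)
        comparison_frame(det).to_csv(out / "comparison.csv", index=False)
        meta = {
            "config_digest": config.digest(),
            "seed": seed,
            "mode": mode,
            "data_source": det.data_source,
            "perspective": det.perspective,
            "horizon_cycles": det.horizon_cycles,
        }
        if psa_result is not None:
            psa_result.ce_plane.to_csv(out / "psa_ce_plane.csv", index=False)
            psa_result.ceac.to_csv(out / "psa_ceac.csv", index=False)
            meta.update(psa_result.metadata())
        (out / "run_metadata.json").write_text(json.dumps(meta, indent=2))
    return det, psa_result


def table2(
    config: ModelConfig,
    perspective: PerspectiveLabel = "societal",
    data_sources: Sequence[DataSource] = ("secondary", "real_world"),
) -> pd.DataFrame:
    """Cost-utility table across data sources, one row per treatment.

    Columns: treatment, data_source, cost_usd, qaly, icer_usd_per_qaly
    (the ICER appears on the reference row of each block, mirroring the
    published layout; dominance labels replace it when no trade-off
    exists).
    """
    rows = []
    for ds in data_sources:
        res = evaluate_scenario(config, ds, perspective)
        c = res.comparison
        icer_cell = (
            c.icer_usd_per_qaly if c.icer_usd_per_qaly is not None else c.dominance
        )
        for arm in ("chemo", "chemo_bev"):
            s = res.summaries[arm]
            rows.append(
                {
                    "treatment": ARM_LABELS[arm],
                    "data_source": ds,
                    "perspective": perspective,
                    "cost_usd": s.total_cost_usd,
                    "qaly": s.total_qaly,
                    "icer_per_qaly_usd": icer_cell if arm == "chemo" else "",
                }
            )
    return pd.DataFrame(rows)


def format_table(df: pd.DataFrame) -> str:
    """Fixed-width text rendering of a result table."""
    return df.to_string(index=False, float_format=lambda x: f"{x:,.2f}")
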