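"""End-to-end orchestration: simulate -> fit -> growth -> stats -> report.

Each stage is an importable function over plain tables so the numbered
analysis drivers, the CLI and the tests all share one code path.  A single
pipeline seed fans out to per-stage, per-tumor child seeds through
``numpy.random.SeedSequence`` spawn keys, so any stage can be reproduced in
isolation without replaying the whole run.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (
    CohortDesign,
    generate_parameter_maps,
    simulate_dce,
    simulate_growth,
    simulate_hypoxic_fraction,
)
from .config import PipelineConfig
from .growth import (
    TumorGrowthRecord,
    caliper_frame_to_records,
    growth_trend_comparison,
    records_to_caliper_frame,
    relative_volume,
    tgd_v3,
    time_to_threshold,
)
from .kinetics import fit_roi, summarize_roi
from .stats import build_correlation_table, group_ttest, summarize_cohort

__all__ = [
    "derive_seed",
    "fit_cohort_endpoints",
    "growth_analysis",
    "cohort_statistics",
    "run_pipeline",
    "render_report_markdown",
]

logger = logging.getLogger("brixflow")

# stage codes for child-seed derivation
_SEED_DCE = 10
_SEED_INJECTION = 11
_SEED_GROWTH = 12
_SEED_HYPOXIA = 13


def derive_seed(seed: int, *key: int) -> int:
    """Deterministic child seed (< 2**31) for a stage/tumor key."""
    ss = np.random.SeedSequence(seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


def fit_cohort_endpoints(
    design: CohortDesign,
    *,
    bounds: Optional[Sequence[tuple[float, float]]] = None,
    tol: float = 1e-8,
    max_nfev: int = 500,
    r2_min: float = 0.5,
    kep_qc_threshold: float = 0.25,
    injection_jitter_s: Optional[tuple[float, float]] = (2.0, 6.0),
) -> pd.DataFrame:
    """Simulate and fit the whole imaging cohort, one row per tumor.

    For every tumor the pre- and post-treatment series are generated,
    fitted voxel-wise and summarized over usable voxels; the per-tumor
    hypoxic fraction is drawn from the coupling to the true A change.
    """
    fit_kwargs = dict(tol=tol, max_nfev=max_nfev, r2_min=r2_min,
                      kep_qc_threshold=kep_qc_threshold)
    if bounds is not None:
        fit_kwargs["bounds"] = tuple(bounds)

    rows = []
    exclusion_counts: dict[str, int] = {}
    for gi, spec in enumerate(design.groups):
        for ti in range(spec.n_tumors):
            actual = None
            if injection_jitter_s is not None:
                rng = np.random.default_rng(
                    derive_seed(design.seed, _SEED_INJECTION, gi, ti)
                )
                actual = float(rng.uniform(*injection_jitter_s))
            row: dict = {"group": spec.name, "tumor_id": f"{spec.name}-{ti:02d}"}
            for si, session in enumerate(("pre", "post")):
                truth = generate_parameter_maps(design, gi, ti, session)
                series = simulate_dce(
                    truth,
                    design,
                    derive_seed(design.seed, _SEED_DCE, gi, ti, si),
                    actual_injection_duration_s=actual,
                )
                pmap = fit_roi(series, **fit_kwargs)
                for reason in pmap.reason[pmap.excluded]:
                    exclusion_counts[reason] = exclusion_counts.get(reason, 0) + 1
                if not pmap.evaluable:
                    logger.warning("tumor %s %s: no usable voxels", row["tumor_id"], session)
                    continue
                summ = summarize_roi(pmap)
                suffix = "pre" if session == "pre" else "post"
                row[f"A_{suffix}"] = summ.mean_A
                row[f"kel_{suffix}"] = summ.mean_k_el
                row[f"kep_{suffix}"] = summ.mean_k_ep if summ.mean_k_ep is not None else np.nan
                row[f"n_voxels_{suffix}"] = summ.n_voxels
                row[f"kep_reliable_{suffix}"] = summ.kep_reliable
            true_delta_a = spec.a_effect - 1.0
            row["hypoxic_fraction_pct"] = 100.0 * simulate_hypoxic_fraction(
                true_delta_a, design, derive_seed(design.seed, _SEED_HYPOXIA, gi, ti)
            )
            rows.append(row)
    frame = pd.DataFrame(rows)
    frame.attrs["exclusion_counts"] = exclusion_counts
    return frame


def growth_analysis(
    records: Sequence[TumorGrowthRecord],
    *,
    control_group: str = "Control",
    threshold: float = 3.0,
    convention: str = "length_squared",
    extra_comparisons: Sequence[tuple[str, str]] = (),
) -> dict:
    """Growth endpoints, TGD per treated arm, and trend comparisons."""
    by_group: dict[str, list[TumorGrowthRecord]] = {}
    for rec in records:
        by_group.setdefault(rec.group, []).append(rec)
    if control_group not in by_group:
        raise ValueError(f"control group {control_group!r} not found")

    endpoint_rows = []
    for rec in records:
        rv = relative_volume(rec, convention)
        t3, cens = time_to_threshold(rv, rec.days, threshold)
        day8_idx = int(np.argmin(np.abs(rec.days - 8)))
        endpoint_rows.append(
            {
                "tumor_id": rec.tumor_id,
                "group": rec.group,
                "time_to_3x_days": t3,
                "censored": cens,
                "delta_volume_pct": 100.0 * (rv[day8_idx] - 1.0),
                "volume_day0_mm3": rec.volumes(convention)[0],
            }
        )
    endpoints = pd.DataFrame(endpoint_rows)

    tgd_rows = []
    for name, recs in by_group.items():
        if name == control_group:
            continue
        ep = tgd_v3(recs, by_group[control_group], threshold=threshold, convention=convention)
        tgd_rows.append(
            {
                "group": name,
                "tgd_days": ep.tgd_days,
                "lower_bound": ep.lower_bound,
                "treated_mean_days": ep.treated_mean_days,
                "control_mean_days": ep.control_mean_days,
                "n_treated_censored": ep.n_treated_censored,
            }
        )
    tgd_table = pd.DataFrame(tgd_rows)

    comparisons = [(name, control_group) for name in by_group if name != control_group]
    comparisons += [c for c in extra_comparisons if c[0] in by_group and c[1] in by_group]
    trend_rows = []
    for a, b in comparisons:
        try:
            tc = growth_trend_comparison(by_group[a], by_group[b], convention=convention)
        except ValueError as err:
            logger.warning("trend comparison %s vs %s skipped: %s", a, b, err)
            continue
        trend_rows.append(
            {
                "group_a": a,
                "group_b": b,
                "linear_t": tc.linear_t,
                "linear_p": tc.linear_p,
                "quadratic_t": tc.quadratic_t,
                "quadratic_p": tc.quadratic_p,
            }
        )
    return {
        "endpoints": endpoints,
        "tgd": tgd_table,
        "trends": pd.DataFrame(trend_rows),
    }


def _holm(pvals: pd.Series) -> pd.Series:
    order = np.argsort(pvals.to_numpy())
    m = len(pvals)
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * pvals.iloc[idx])
        adjusted[idx] = min(1.0, running)
    return pd.Series(adjusted, index=pvals.index)


def cohort_statistics(
    endpoints: pd.DataFrame,
    *,
    control_group: str = "Control",
    paired_within_group: bool = True,
    holm_correction: bool = False,
) -> dict:
    """Group summaries, within/between-group t-tests and correlation tables."""
    summary, group_means = summarize_cohort(endpoints)
    correlations = build_correlation_table(group_means)

    test_rows = []
    for group, sub in endpoints.groupby("group", sort=False):
        for param in ("A", "kel"):
            pre = sub[f"{param}_pre"].dropna()
            post = sub[f"{param}_post"].dropna()
            if paired_within_group:
                both = sub[[f"{param}_pre", f"{param}_post"]].dropna()
                pre, post = both[f"{param}_pre"], both[f"{param}_post"]
            if len(pre) < 2 or len(post) < 2:
                continue
            res = group_ttest(post, pre, paired=paired_within_group)
            test_rows.append(
                {"test": f"{param}_post_vs_pre", "group": group,
                 "t": res.t, "p": res.p, "n": len(pre), "paired": res.paired}
            )
    src = endpoints.copy()
    for param in ("A", "kel"):
        if f"{param}_pre" in src.columns and f"{param}_post" in src.columns:
            src[f"delta_{param}_pct"] = (
                100.0 * (src[f"{param}_post"] - src[f"{param}_pre"]) / src[f"{param}_pre"]
            )
    has_control = (src["group"] == control_group).any()
    for group in src["group"].unique():
        if group == control_group or not has_control:
            continue
        for col in ("delta_A_pct", "delta_kel_pct", "hypoxic_fraction_pct"):
            if col not in src.columns:
                continue
            a = src.loc[src["group"] == group, col].dropna()
            b = src.loc[src["group"] == control_group, col].dropna()
            if len(a) < 2 or len(b) < 2:
                continue
            res = group_ttest(a, b, paired=False)
            test_rows.append(
                {"test": f"{col}_vs_control", "group": group,
                 "t": res.t, "p": res.p, "n": len(a) + len(b), "paired": False}
            )
    tests = pd.DataFrame(test_rows)
    if holm_correction and not tests.empty:
        tests["p_holm"] = tests.groupby("test")["p"].transform(_holm)
    return {
        "summary": summary,
        "group_means": group_means,
        "correlations": correlations,
        "tests": tests,
    }


def run_pipeline(config: PipelineConfig, out_dir: Optional[Path] = None) -> dict:
    """Execute the full pipeline; optionally write all tables under out_dir.

    Deterministic given the config: identical configs produce bit-identical
    CSV outputs.
    """
    logger.info("brixflow %s, seed %d", __version__, config.seed)
    design = config.simulation.to_design(config.seed)

    logger.info("stage simulate+fit: %d groups", len(design.groups))
    try:
        endpoints = fit_cohort_endpoints(
            design,
            bounds=config.fitting.bounds,
            tol=config.fitting.tol,
            max_nfev=config.fitting.max_nfev,
            r2_min=config.fitting.r2_min,
            kep_qc_threshold=config.fitting.kep_qc_threshold,
            injection_jitter_s=config.simulation.injection_jitter_s,
        )
    except Exception as err:
        raise RuntimeError(f"[stage: simulate+fit] {err}") from err

    logger.info("stage growth")
    try:
        records = simulate_growth(design, derive_seed(config.seed, _SEED_GROWTH))
        growth = growth_analysis(
            records,
            control_group=config.growth.control_group,
            threshold=config.growth.threshold_fold,
            convention=config.growth.volume_convention,
            extra_comparisons=(
                ("RT", "Hypoxic RT"),
                ("RT", "PL-DXR"),
                ("Hypoxic RT", "PL-DXR + hypoxic RT"),
            ),
        )
    except Exception as err:
        raise RuntimeError(f"[stage: growth] {err}") from err

    logger.info("stage stats")
    try:
        merged = endpoints.merge(
            growth["endpoints"][["tumor_id", "delta_volume_pct", "time_to_3x_days", "censored"]],
            on="tumor_id",
            how="left",
        )
        stats_out = cohort_statistics(
            merged,
            control_group=config.growth.control_group,
            paired_within_group=config.stats.paired_within_group,
            holm_correction=config.stats.holm_correction,
        )
    except Exception as err:
        raise RuntimeError(f"[stage: stats] {err}") from err

    report = {
        "version": __version__,
        "seed": config.seed,
        "config": config.model_dump(mode="json"),
        "n_tumors": int(len(endpoints)),
        "exclusion_counts": endpoints.attrs.get("exclusion_counts", {}),
        "endpoints": merged,
        "caliper": records_to_caliper_frame(records),
        "growth_endpoints": growth["endpoints"],
        "tgd": growth["tgd"],
        "trends": growth["trends"],
        "summary": stats_out["summary"],
        "group_means": stats_out["group_means"],
        "correlations": stats_out["correlations"],
        "tests": stats_out["tests"],
    }

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name in (
            "endpoints", "caliper", "growth_endpoints", "tgd", "trends",
            "summary", "group_means", "correlations", "tests",
        ):
            report[name].to_csv(out_dir / f"{name}.csv", index=False)
        meta = {k: report[k] for k in ("version", "seed", "config", "n_tumors", "exclusion_counts")}
        meta["correlations"] = report["correlations"].to_dict(orient="records")
        meta["tgd"] = report["tgd"].to_dict(orient="records")
        (out_dir / "report.json").write_text(json.dumps(meta, indent=2))
        (out_dir / "report.md").write_text(render_report_markdown(report))
    return report


def render_report_markdown(report: dict) -> str:
    """Human-readable summary of a pipeline run."""
    lines = [
        "# brixflow cohort report",
        "",
        f"- version: {report['version']}",
        f"- seed: {report['seed']}",
        f"- tumors analyzed: {report['n_tumors']}",
        f"- voxel exclusions: {report['exclusion_counts'] or 'none'}",
        "",
        "## Group means",
        "",
        report["group_means"].round(3).to_string(index=False),
        "",
        "## Tumor growth delay (vs control)",
        "",
        report["tgd"].round(2).to_string(index=False)
        if not report["tgd"].empty
        else "(no treated groups)",
        "",
        "## Trend comparisons",
        "",
        report["trends"].round(4).to_string(index=False)
        if not report["trends"].empty
        else "(none)",
        "",
        "## Correlations across group means",
        "",
        report["correlations"].round(3).to_string(index=False)
        if not report["correlations"].empty
        else "(none)",
        "",
    ]
    return "\n".join(lines)
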