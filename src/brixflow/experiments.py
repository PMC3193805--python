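"""Validation experiments for the pipeline on its own synthetic test bed.

Each function recomputes one quality metric from scratch — forward-model
correctness, optimizer/oracle equivalence, voxel-parameter recovery,
statistical calibration, and reproduction of the study-level effect
directions — and returns plain numbers.  They back both the acceptance test
suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .cohort import (
    CohortDesign,
    GroupSpec,
    default_design,
    generate_parameter_maps,
    simulate_dce,
    simulate_growth,
)
from .growth import (
    TumorGrowthRecord,
    growth_trend_comparison,
    relative_volume,
    tgd_v3,
    time_to_threshold,
)
from .kinetics import RSICurve, fit_roi, fit_voxel, grid_search_fit
from .model import brix_peak_time, brix_rsi
from .pipeline import derive_seed, fit_cohort_endpoints
from .stats import REFERENCE_GROUP_ENDPOINTS, group_ttest, pearson

__all__ = [
    "reference_means_correlation",
    "peak_time_accuracy",
    "diagonal_continuity",
    "oracle_equivalence",
    "parameter_recovery",
    "ttest_type_i_error",
    "trend_type_i_error",
    "effect_direction_agreement",
    "growth_endpoint_examples",
]


def reference_means_correlation():
    """Pearson r between group-mean hypoxic fractions and A-parameter changes."""
    return pearson(
        REFERENCE_GROUP_ENDPOINTS["hypoxic_fraction_pct"],
        REFERENCE_GROUP_ENDPOINTS["delta_A_pct"],
    )


def peak_time_accuracy(seed: int, n_draws: int = 100) -> float:
    """Max |analytic peak time - dense-grid argmax| in minutes over random draws.

    The argmax is located without using the analytic formula: a coarse 1 ms
    scan of the first 30 minutes followed by a 1e-7-minute refinement around
    the coarse maximum.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    coarse_t = np.arange(1e-3, 30.0, 1e-3)
    for _ in range(n_draws):
        k_ep = rng.uniform(0.1, 10.0)
        k_el = rng.uniform(0.02, 2.0)
        if abs(k_ep - k_el) < 1e-6:
            continue
        t0 = coarse_t[np.argmax(brix_rsi(coarse_t, 1.0, k_ep, k_el))]
        fine_t = np.linspace(max(t0 - 2e-3, 1e-9), t0 + 2e-3, 40001)
        dense = fine_t[np.argmax(brix_rsi(fine_t, 1.0, k_ep, k_el))]
        worst = max(worst, abs(dense - brix_peak_time(k_ep, k_el)))
    return worst


def diagonal_continuity(seed: int, n_draws: int = 20) -> float:
    """Max relative gap between the curve just off k_ep == k_el and on it."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0.05, 20.0, 200)
    worst = 0.0
    for _ in range(n_draws):
        k = rng.uniform(0.05, 10.0)
        on = brix_rsi(t, 1.0, k, k)
        off = brix_rsi(t, 1.0, k, k * (1 + 1e-9))
        worst = max(worst, float(np.max(np.abs(off - on) / np.abs(on))))
    return worst


def oracle_equivalence(seed: int, n_curves: int = 50, n_grid: int = 40) -> dict:
    """Main fitter vs exhaustive grid search + Nelder-Mead on noiseless curves.

    Returns the worst objective-value gap and worst parameter relative
    difference across random noiseless voxel curves on the default grid.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(1, 101) * 0.2
    max_obj_gap = 0.0
    max_param_rel = 0.0
    for _ in range(n_curves):
        A = rng.uniform(0.3, 3.0)
        k_ep = rng.uniform(0.5, 8.0)
        k_el = rng.uniform(0.05, 1.0)
        curve = RSICurve(times=t, rsi=brix_rsi(t, A, k_ep, k_el))
        main = fit_voxel(curve)
        oracle = grid_search_fit(curve, n_grid=n_grid)
        max_obj_gap = max(
            max_obj_gap, abs(main.residual_norm**2 - oracle.residual_norm**2)
        )
        for p in ("A", "k_ep", "k_el"):
            m, o = getattr(main, p), getattr(oracle, p)
            max_param_rel = max(max_param_rel, abs(m - o) / max(abs(o), 1e-12))
    return {"max_objective_gap": max_obj_gap, "max_param_rel_diff": max_param_rel}


def _single_tumor_design(seed: int, noise_sd: float) -> CohortDesign:
    return dataclasses.replace(
        default_design(seed=seed),
        groups=(GroupSpec("G", 1),),
        noise_sd=noise_sd,
    )


def parameter_recovery(seed: int, noise_sd: float = 0.05) -> dict:
    """Voxel-parameter recovery on the default ~400-voxel ROI.

    Median relative errors of A and k_el at the given noise level, plus the
    worst-voxel relative error of all three parameters at zero noise.
    """
    out = {}
    for label, sd in (("noisy", noise_sd), ("noiseless", 0.0)):
        design = _single_tumor_design(seed, sd)
        truth = generate_parameter_maps(design, 0, 0, "pre")
        series = simulate_dce(truth, design, derive_seed(seed, 1))
        pmap = fit_roi(series)
        usable = pmap.usable
        rel = {
            p: np.abs(getattr(pmap, m)[usable] - getattr(truth, p)[usable])
            / getattr(truth, p)[usable]
            for p, m in (("A", "A"), ("k_ep", "k_ep"), ("k_el", "k_el"))
        }
        if label == "noisy":
            out["median_rel_err_A_pct"] = 100.0 * float(np.median(rel["A"]))
            out["median_rel_err_kel_pct"] = 100.0 * float(np.median(rel["k_el"]))
            out["n_voxels"] = int(usable.sum())
            out["n_excluded"] = int(pmap.excluded.sum())
        else:
            out["noiseless_max_rel_err"] = float(max(np.max(r) for r in rel.values()))
    return out


def ttest_type_i_error(seed: int, n_reps: int = 1000, n: int = 9) -> float:
    """Rejection rate of the two-sample t-test on null normal samples."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        rejections += group_ttest(a, b, paired=False).p < 0.05
    return rejections / n_reps


def trend_type_i_error(seed: int, n_reps: int = 1000, n: int = 9) -> float:
    """Rejection rate of the quadratic trend comparison on identical growth laws."""
    base = CohortDesign(
        groups=(
            GroupSpec("a", n, growth_modifier=1.0),
            GroupSpec("b", n, growth_modifier=1.0),
        ),
        seed=0,
    )
    rejections = 0
    for rep in range(n_reps):
        records = simulate_growth(base, derive_seed(seed, 2, rep))
        a = [r for r in records if r.group == "a"]
        b = [r for r in records if r.group == "b"]
        rejections += growth_trend_comparison(a, b).quadratic_p < 0.05
    return rejections / n_reps


# expected direction of each arm's group-mean change, (delta A sign, delta k_el sign)
EXPECTED_EFFECT_SIGNS = {
    "Control": (-1, +1),
    "PL-DXR": (-1, +1),
    "PL-DXR + hypoxic RT": (+1, +1),
    "Hypoxic RT": (+1, -1),
    "RT": (+1, -1),
}


def effect_direction_agreement(
    seed: int,
    n_seeds: int = 50,
    n_tumors: int = 3,
    grid_size: int = 16,
    roi_semi_axes: tuple[float, float] = (5.6, 4.5),
) -> float:
    """Fraction of simulated cohorts whose fitted group-mean changes in A and
    k_el all have the study's signs.

    Each cohort uses the default effect multipliers and acquisition at 5 %
    noise; the endpoint estimates come from the full simulate-and-fit path,
    not from the ground truth.
    """
    design0 = default_design(seed=0, grid_size=grid_size, roi_semi_axes=roi_semi_axes)
    groups = tuple(
        dataclasses.replace(g, n_tumors=n_tumors) for g in design0.groups
    )
    hits = 0
    for s in range(n_seeds):
        design = dataclasses.replace(design0, groups=groups, seed=derive_seed(seed, 3, s))
        endpoints = fit_cohort_endpoints(design)
        endpoints["delta_A_pct"] = 100 * (endpoints["A_post"] - endpoints["A_pre"]) / endpoints["A_pre"]
        endpoints["delta_kel_pct"] = 100 * (endpoints["kel_post"] - endpoints["kel_pre"]) / endpoints["kel_pre"]
        means = endpoints.groupby("group")[["delta_A_pct", "delta_kel_pct"]].mean()
        ok = all(
            np.sign(means.loc[g, "delta_A_pct"]) == sa
            and np.sign(means.loc[g, "delta_kel_pct"]) == sk
            for g, (sa, sk) in EXPECTED_EFFECT_SIGNS.items()
        )
        hits += ok
    return hits / n_seeds


def growth_endpoint_examples() -> dict:
    """Hand-checkable growth endpoints computed through the public API.

    A piecewise-linear relative-volume series (1, 2, 4) at days (0, 4, 8)
    crosses 3-fold at day 6; a treated arm fully censored at day 29 against
    a control arm crossing at day 10 yields a lower-bound delay of 19 days.
    """
    t3, censored = time_to_threshold(np.array([1.0, 2.0, 4.0]), np.array([0.0, 4.0, 8.0]))

    days = np.array([0.0, 4.0, 8.0, 12.0, 16.0, 20.0, 24.0, 28.0, 29.0])
    flat = TumorGrowthRecord("t", "treated", days, np.full(len(days), 6.0), np.full(len(days), 4.0))
    ctrl_days = np.array([0.0, 10.0, 29.0])
    ctrl_len = np.array([5.0, 5.0 * 3 ** (1 / 3), 5.0 * 6 ** (1 / 3)])
    ctrl = TumorGrowthRecord("c", "control", ctrl_days, ctrl_len, 0.8 * ctrl_len)
    ep = tgd_v3([flat, flat], [ctrl, ctrl])
    return {
        "interpolated_time_to_3x_days": t3,
        "interpolated_censored": censored,
        "tgd_lower_bound_days": ep.tgd_days,
        "tgd_is_lower_bound": ep.lower_bound,
        "control_mean_days": ep.control_mean_days,
    }
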