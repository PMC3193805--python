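"""Voxel-wise pharmacokinetic analysis of a DCE-MRI series.

Stages: relative signal intensity (RSI) normalization against the
pre-contrast baseline, alignment of the post-contrast time axis across
tumors with different actual injection durations, bounded nonlinear
least-squares fitting of the Brix model per voxel, quality-based voxel
exclusion, a reliability check for the exchange-rate parameter ``k_ep``
(poorly determined when the enhancement upslope is under-sampled), and
ROI-level summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .model import brix_peak_time, brix_rsi

__all__ = [
    "DCESeries",
    "RSICurve",
    "RSIStack",
    "BrixFit",
    "ParametricMap",
    "ROISummary",
    "DEFAULT_BOUNDS",
    "DEFAULT_STARTS",
    "compute_rsi",
    "correct_time_axis",
    "fit_voxel",
    "grid_search_fit",
    "fit_roi",
    "qc_kep",
    "summarize_roi",
]

#: fit bounds (lower, upper) for (A, k_ep [1/min], k_el [1/min])
DEFAULT_BOUNDS: tuple[tuple[float, float], ...] = ((0.0, 50.0), (0.0, 30.0), (0.0, 5.0))
#: default start point plus two fallback multi-start points
DEFAULT_STARTS: tuple[tuple[float, float, float], ...] = (
    (1.0, 1.0, 0.1),
    (0.5, 5.0, 0.05),
    (3.0, 0.5, 0.5),
)

# voxel exclusion reason codes
REASON_BASELINE = "non_positive_baseline"
REASON_FIT_FAILED = "fit_failed"
REASON_BOUND = "bound_saturated"
REASON_LOW_R2 = "low_r2"


@dataclass
class DCESeries:
    """One tumor's dynamic series on a single slice.

    ``signal`` has shape (rows, cols, frames); ``frame_times`` are minutes
    relative to contrast injection, with the ``n_baseline_frames``
    pre-contrast frames at times <= 0 and all post-contrast frames at
    times > 0.  Injection durations are in seconds.
    """

    signal: np.ndarray
    frame_times: np.ndarray
    n_baseline_frames: int
    nominal_injection_duration: float
    actual_injection_duration: float
    roi_mask: np.ndarray

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.roi_mask = np.asarray(self.roi_mask, dtype=bool)
        if self.signal.ndim != 3:
            raise ValueError("signal must be (rows, cols, frames)")
        if self.frame_times.shape != (self.signal.shape[2],):
            raise ValueError("frame_times length must match frame axis")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValueError("frame_times must be strictly increasing")
        if not 1 <= self.n_baseline_frames < len(self.frame_times):
            raise ValueError("need >= 1 baseline frame and >= 1 post frame")
        if np.any(self.frame_times[: self.n_baseline_frames] > 0):
            raise ValueError("baseline frames must have times <= 0")
        if np.any(self.frame_times[self.n_baseline_frames :] <= 0):
            raise ValueError("post-contrast frames must have times > 0")
        if np.any(self.signal < 0):
            raise ValueError("signal must be non-negative")
        if self.roi_mask.shape != self.signal.shape[:2]:
            raise ValueError("roi_mask must match the spatial grid")
        if self.actual_injection_duration <= 0:
            raise ValueError("actual_injection_duration must be positive")


@dataclass
class RSICurve:
    """Relative enhancement of one voxel over the post-contrast frames."""

    times: np.ndarray
    rsi: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.rsi = np.asarray(self.rsi, dtype=float)
        if self.times.shape != self.rsi.shape:
            raise ValueError("times and rsi must have equal length")
        if np.any(self.times <= 0):
            raise ValueError("RSI curves are defined on post-contrast times > 0")


@dataclass
class RSIStack:
    """Per-voxel RSI over a grid: ``rsi`` is (rows, cols, n_post)."""

    rsi: np.ndarray
    times: np.ndarray
    valid_baseline: np.ndarray  # False where the baseline mean was <= 0

    def curve(self, row: int, col: int) -> RSICurve:
        return RSICurve(times=self.times, rsi=self.rsi[row, col])


@dataclass
class BrixFit:
    """Fitted Brix parameters for one voxel with diagnostics."""

    A: float
    k_ep: float
    k_el: float
    residual_norm: float
    r_squared: float
    converged: bool
    at_bound: tuple[bool, bool, bool]


@dataclass
class ROISummary:
    mean_A: float
    sem_A: float
    mean_k_el: float
    sem_k_el: float
    mean_k_ep: Optional[float]
    sem_k_ep: Optional[float]
    n_voxels: int
    kep_reliable: bool


@dataclass
class ParametricMap:
    """Spatial maps of fitted parameters over an ROI with exclusion mask."""

    A: np.ndarray
    k_ep: np.ndarray
    k_el: np.ndarray
    r_squared: np.ndarray
    roi_mask: np.ndarray
    excluded: np.ndarray
    reason: np.ndarray  # string codes, "" where not excluded
    at_bound: np.ndarray  # (rows, cols, 3) upper-bound saturation flags
    post_times: np.ndarray  # corrected post-contrast frame times, minutes
    kep_reliable: bool = True
    evaluable: bool = True

    @property
    def usable(self) -> np.ndarray:
        return self.roi_mask & ~self.excluded

    def to_dataframe(self) -> pd.DataFrame:
        rows, cols = np.nonzero(self.roi_mask)
        return pd.DataFrame(
            {
                "voxel_row": rows,
                "voxel_col": cols,
                "A": self.A[rows, cols],
                "k_ep": self.k_ep[rows, cols],
                "k_el": self.k_el[rows, cols],
                "r2": self.r_squared[rows, cols],
                "excluded": self.excluded[rows, cols],
                "reason": self.reason[rows, cols],
            }
        )


def compute_rsi(series: DCESeries) -> RSIStack:
    """Normalize the series to relative signal intensity per voxel.

    RSI(t) = (SI(t) - SI(0)) / SI(0) with SI(0) the mean over the
    pre-contrast baseline frames.  Voxels whose baseline mean is not
    strictly positive are flagged non-evaluable rather than raising.
    """
    nb = series.n_baseline_frames
    baseline = series.signal[:, :, :nb].mean(axis=2)
    valid = baseline > 0
    safe = np.where(valid, baseline, 1.0)
    post = series.signal[:, :, nb:]
    rsi = post / safe[:, :, None] - 1.0
    rsi[~valid] = np.nan
    return RSIStack(rsi=rsi, times=series.frame_times[nb:].copy(), valid_baseline=valid)


def correct_time_axis(series: DCESeries) -> DCESeries:
    """Align the post-contrast time axis on the common bolus midpoint.

    Post-contrast frame times are shifted by half the deviation of the
    actual from the nominal injection duration, ``(actual - nominal)/2``
    seconds converted to minutes; baseline frames are unchanged.  The
    returned series has ``actual == nominal`` so the correction is
    idempotent.
    """
    shift_min = (series.actual_injection_duration - series.nominal_injection_duration) / 2.0 / 60.0
    times = series.frame_times.copy()
    times[series.n_baseline_frames :] += shift_min
    return replace(
        series,
        frame_times=times,
        actual_injection_duration=series.nominal_injection_duration,
    )


def _residuals(p: np.ndarray, t: np.ndarray, y: np.ndarray) -> np.ndarray:
    A, k_ep, k_el = p
    return brix_rsi(t, A, k_ep, k_el) - y


def _jacobian(p: np.ndarray, t: np.ndarray, y: np.ndarray) -> np.ndarray:
    A, k_ep, k_el = p
    E1 = np.exp(-k_ep * t)
    E2 = np.exp(-k_el * t)
    scale = max(k_ep, k_el, 1e-30)
    if abs(k_el - k_ep) <= 1e-9 * scale:
        # degenerate closed form A*k_ep*t*exp(-k_ep*t)
        dA = k_ep * t * E1
        dkep = A * t * E1 * (1.0 - k_ep * t)
        dkel = -0.5 * A * k_ep * t**2 * E1
    else:
        denom = k_el - k_ep
        C = k_ep / denom
        D = E1 - E2
        dA = C * D
        dkep = A * (k_el / denom**2 * D - C * t * E1)
        dkel = A * (-k_ep / denom**2 * D + C * t * E2)
    return np.column_stack([dA, dkep, dkel])


def _r_squared(y: np.ndarray, residual: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return float("nan")
    return 1.0 - float(np.sum(residual**2)) / ss_tot


def _canonicalize(p: np.ndarray) -> np.ndarray:
    """Map to the k_ep >= k_el branch of the model's symmetric parameter pair.

    (A, k_ep, k_el) and (A*k_ep/k_el, k_el, k_ep) generate identical curves;
    the convention here is fast exchange, slow elimination.
    """
    A, k_ep, k_el = p
    if k_el > k_ep and k_el > 0:
        return np.array([A * k_ep / k_el, k_el, k_ep])
    return np.asarray(p, dtype=float)


def _at_bound(p: np.ndarray, bounds: Sequence[tuple[float, float]]) -> tuple[bool, bool, bool]:
    flags = []
    for value, (lo, hi) in zip(p, bounds):
        flags.append(bool(value >= hi - 1e-6 * (hi - lo)))
    return tuple(flags)


def fit_voxel(
    curve: RSICurve,
    init: Optional[Sequence[float]] = None,
    *,
    bounds: Sequence[tuple[float, float]] = DEFAULT_BOUNDS,
    starts: Sequence[Sequence[float]] = DEFAULT_STARTS,
    tol: float = 1e-8,
    max_nfev: int = 500,
) -> BrixFit:
    """Fit the Brix model to one voxel's RSI curve by bounded least squares.

    A Trust Region Reflective least-squares solve (analytic Jacobian) is run
    from ``init`` (default (1, 1, 0.1)); on failure or a poor fit the
    remaining multi-start points are tried and the lowest-cost solution kept.
    The result is canonicalized to ``k_ep >= k_el``.
    """
    t = curve.times
    y = curve.rsi
    if len(t) < 10:
        raise ValueError("need at least 10 post-contrast points")
    if np.any(~np.isfinite(y)):
        raise ValueError("RSI curve contains non-finite values")

    if np.max(np.abs(y)) == 0.0:
        # no enhancement: amplitude zero, r^2 undefined
        return BrixFit(0.0, 0.0, 0.0, 0.0, float("nan"), True, (False, False, False))

    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    start_list = [np.asarray(init, dtype=float)] if init is not None else []
    start_list += [np.asarray(s, dtype=float) for s in starts]

    best = None
    for k, x0 in enumerate(start_list):
        x0 = np.clip(x0, lo + 1e-12, hi)
        try:
            res = least_squares(
                _residuals,
                x0,
                jac=_jacobian,
                bounds=(lo, hi),
                args=(t, y),
                ftol=tol,
                xtol=tol,
                gtol=tol,
                max_nfev=max_nfev,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
        # accept the first start when it converged to a decent fit
        if k == 0 and res.success and _r_squared(y, res.fun) >= 0.5:
            break

    if best is None:
        return BrixFit(
            float("nan"), float("nan"), float("nan"), float("nan"), float("nan"),
            False, (False, False, False),
        )

    # mirror-branch escape: the (k_ep, k_el) exchange symmetry combined with
    # the asymmetric rate bounds can strand the solver with a rate saturated;
    # restart once from the mirrored parameter point and keep the better fit
    A_b, kep_b, kel_b = best.x
    if kel_b > 0 and (
        kel_b >= hi[2] * (1 - 1e-6) or kep_b >= hi[1] * (1 - 1e-6)
    ):
        mirror = np.clip(
            [A_b * kep_b / kel_b, kel_b, kep_b], lo + 1e-12, hi
        )
        try:
            res = least_squares(
                _residuals, mirror, jac=_jacobian, bounds=(lo, hi), args=(t, y),
                ftol=tol, xtol=tol, gtol=tol, max_nfev=max_nfev,
            )
            if res.cost < best.cost:
                best = res
        except Exception:
            pass

    p = _canonicalize(best.x)
    residual = _residuals(p, t, y)
    return BrixFit(
        A=float(p[0]),
        k_ep=float(p[1]),
        k_el=float(p[2]),
        residual_norm=float(np.linalg.norm(residual)),
        r_squared=_r_squared(y, residual),
        converged=bool(best.success),
        at_bound=_at_bound(p, bounds),
    )


def grid_search_fit(
    curve: RSICurve,
    *,
    bounds: Sequence[tuple[float, float]] = DEFAULT_BOUNDS,
    n_grid: int = 40,
    refine: bool = True,
) -> BrixFit:
    """Exhaustive coarse grid search over (A, k_ep, k_el) with local refinement.

    Serves as an independent global-optimization route for cross-checking
    :func:`fit_voxel`: the objective is evaluated on an ``n_grid``^3 lattice
    spanning the bounds and the best lattice point is polished with
    Nelder-Mead (a derivative-free method, unlike the main fitter).
    """
    t = curve.times
    y = curve.rsi
    grids = []
    for lo, hi in bounds:
        # geometric spacing: these are positive scale parameters, and a linear
        # lattice would waste almost all nodes far from typical magnitudes;
        # the lattice stays strictly positive, refinement can reach 0
        grids.append(np.geomspace(max(lo, hi * 1e-4), hi, n_grid))
    Ag, kepg, kelg = np.meshgrid(*grids, indexing="ij", sparse=True)

    # vectorized objective over the lattice
    kep_t = kepg[..., None] * t
    kel_t = kelg[..., None] * t
    denom = kelg - kepg
    denom = np.where(np.abs(denom) < 1e-12, 1e-12, denom)
    shape = (kepg[..., None] / denom[..., None]) * (np.exp(-kep_t) - np.exp(-kel_t))
    pred = Ag[..., None] * shape
    sse = np.sum((pred - y) ** 2, axis=-1)

    # the model is symmetric under (k_ep, k_el) exchange, but the asymmetric
    # rate bounds can strand a local refinement on the wrong branch; start one
    # refinement from the best lattice point of each branch and keep the best
    kep_grid = grids[1][:, None]
    kel_grid = grids[2][None, :]
    fast_exchange = np.broadcast_to(
        (kep_grid >= kel_grid)[None, :, :], sse.shape
    )
    starts = []
    for mask in (fast_exchange, ~fast_exchange):
        masked = np.where(mask, sse, np.inf)
        if np.isfinite(masked.min()):
            idx = np.unravel_index(np.argmin(masked), sse.shape)
            starts.append(np.array([grids[0][idx[0]], grids[1][idx[1]], grids[2][idx[2]]]))

    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def objective(p):
        if np.any(p < lo) or np.any(p > hi):
            return np.inf
        return float(np.sum(_residuals(p, t, y) ** 2))

    best_p, best_obj = None, np.inf
    for p0 in starts:
        if refine:
            from scipy.optimize import minimize

            res = minimize(
                objective,
                p0,
                method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 5000, "maxfev": 10000},
            )
            candidate = res.x
        else:
            candidate = p0
        obj = objective(candidate)
        if obj < best_obj:
            best_p, best_obj = candidate, obj

    p = _canonicalize(best_p)
    residual = _residuals(p, t, y)
    return BrixFit(
        A=float(p[0]),
        k_ep=float(p[1]),
        k_el=float(p[2]),
        residual_norm=float(np.linalg.norm(residual)),
        r_squared=_r_squared(y, residual),
        converged=True,
        at_bound=_at_bound(p, bounds),
    )


def fit_roi(
    series: DCESeries,
    *,
    bounds: Sequence[tuple[float, float]] = DEFAULT_BOUNDS,
    starts: Sequence[Sequence[float]] = DEFAULT_STARTS,
    tol: float = 1e-8,
    max_nfev: int = 500,
    r2_min: float = 0.5,
    kep_qc_threshold: float = 0.25,
) -> ParametricMap:
    """Fit every in-ROI voxel and assemble parametric maps with exclusions.

    Voxels are excluded for a non-positive baseline, fit failure, r^2 below
    ``r2_min`` (or undefined), or amplitude/elimination-rate saturation at
    the upper fit bound.  A saturated ``k_ep`` does not exclude the voxel;
    it feeds the ROI-level k_ep reliability check instead.
    """
    if series.roi_mask.sum() == 0:
        raise ValueError("ROI mask is empty")

    corrected = correct_time_axis(series)
    stack = compute_rsi(corrected)
    shape = series.roi_mask.shape
    nan_map = np.full(shape, np.nan)
    pmap = ParametricMap(
        A=nan_map.copy(),
        k_ep=nan_map.copy(),
        k_el=nan_map.copy(),
        r_squared=nan_map.copy(),
        roi_mask=series.roi_mask.copy(),
        excluded=np.zeros(shape, dtype=bool),
        reason=np.full(shape, "", dtype=object),
        at_bound=np.zeros(shape + (3,), dtype=bool),
        post_times=stack.times,
    )

    for row, col in zip(*np.nonzero(series.roi_mask)):
        if not stack.valid_baseline[row, col]:
            pmap.excluded[row, col] = True
            pmap.reason[row, col] = REASON_BASELINE
            continue
        fit = fit_voxel(
            stack.curve(row, col),
            bounds=bounds, starts=starts, tol=tol, max_nfev=max_nfev,
        )
        pmap.A[row, col] = fit.A
        pmap.k_ep[row, col] = fit.k_ep
        pmap.k_el[row, col] = fit.k_el
        pmap.r_squared[row, col] = fit.r_squared
        pmap.at_bound[row, col] = fit.at_bound
        if not fit.converged:
            pmap.excluded[row, col] = True
            pmap.reason[row, col] = REASON_FIT_FAILED
        elif not np.isfinite(fit.r_squared) or fit.r_squared < r2_min:
            pmap.excluded[row, col] = True
            pmap.reason[row, col] = REASON_LOW_R2
        elif fit.at_bound[0] or fit.at_bound[2]:
            pmap.excluded[row, col] = True
            pmap.reason[row, col] = REASON_BOUND

    pmap.evaluable = bool(pmap.usable.sum() > 0)
    pmap.kep_reliable = qc_kep(pmap, corrected, threshold=kep_qc_threshold)
    return pmap


def qc_kep(
    pmap: ParametricMap,
    series: Optional[DCESeries] = None,
    *,
    threshold: float = 0.25,
    min_pre_peak_samples: int = 3,
) -> bool:
    """Decide whether ROI-level k_ep summaries are reliable.

    A usable voxel counts against k_ep when its fitted k_ep saturated the
    upper bound or when fewer than ``min_pre_peak_samples`` post-contrast
    frames fall before the fitted peak time t* = ln(k_ep/k_el)/(k_ep - k_el)
    (the upslope is then effectively unsampled).  k_ep is unreliable when
    the flagged fraction exceeds ``threshold``.
    """
    times = pmap.post_times if series is None else series.frame_times[series.n_baseline_frames :]
    usable = pmap.usable
    n_usable = int(usable.sum())
    if n_usable == 0:
        return False
    flagged = 0
    for row, col in zip(*np.nonzero(usable)):
        k_ep = pmap.k_ep[row, col]
        k_el = pmap.k_el[row, col]
        if pmap.at_bound[row, col, 1]:
            flagged += 1
            continue
        if not (k_ep > 0 and k_el > 0):
            flagged += 1
            continue
        t_star = brix_peak_time(k_ep, k_el)
        if int(np.sum(times < t_star)) < min_pre_peak_samples:
            flagged += 1
    return (flagged / n_usable) <= threshold


def summarize_roi(pmap: ParametricMap) -> ROISummary:
    """Mean and SEM of A and k_el (and k_ep when reliable) over usable voxels."""
    usable = pmap.usable
    n = int(usable.sum())
    if n == 0:
        raise ValueError("no usable voxels in ROI")

    def _mean_sem(values: np.ndarray) -> tuple[float, float]:
        v = values[usable]
        sem = float(np.std(v, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        return float(np.mean(v)), sem

    mean_A, sem_A = _mean_sem(pmap.A)
    mean_kel, sem_kel = _mean_sem(pmap.k_el)
    if pmap.kep_reliable:
        mean_kep, sem_kep = _mean_sem(pmap.k_ep)
    else:
        mean_kep = sem_kep = None
    return ROISummary(
        mean_A=mean_A,
        sem_A=sem_A,
        mean_k_el=mean_kel,
        sem_k_el=sem_kel,
        mean_k_ep=mean_kep,
        sem_k_ep=sem_kep,
        n_voxels=n,
        kep_reliable=pmap.kep_reliable,
    )
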