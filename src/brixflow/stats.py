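"""Group-level treatment-response statistics.

Aggregates per-tumor imaging, growth and hypoxia endpoints into group
summaries (mean, SEM, n), computes pre-to-post relative changes in percent,
and runs the study-style inference: two-sided Student's t-tests (paired
within group across sessions, unpaired between groups) and Pearson
correlations across group means, including the five cross-endpoint pairings
relating hypoxic fraction and tumor-volume change to the kinetic-parameter
changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TTestResult",
    "CorrelationResult",
    "relative_change",
    "group_ttest",
    "pearson",
    "build_correlation_table",
    "summarize_cohort",
    "REFERENCE_GROUP_ENDPOINTS",
]

#: Group-level endpoint summary the synthetic cohort is calibrated to emulate:
#: day-8 hypoxic fractions and day-0 -> day-8 relative changes of the Brix
#: A and k_el parameters, in percent, for the five treatment arms.
REFERENCE_GROUP_ENDPOINTS = pd.DataFrame(
    {
        "group": ["Control", "PL-DXR", "PL-DXR + hypoxic RT", "Hypoxic RT", "RT"],
        "hypoxic_fraction_pct": [23.0, 21.0, 14.0, 15.0, 11.0],
        "delta_A_pct": [-18.0, -26.0, 4.0, 20.0, 29.0],
        "delta_kel_pct": [45.0, 85.0, 47.0, -27.0, -27.0],
    }
)


def relative_change(pre: float, post: float) -> float:
    """Relative change in percent, 100 * (post - pre) / pre."""
    if pre == 0:
        raise ValueError("pre value must be non-zero")
    return 100.0 * (post - pre) / pre


@dataclass
class TTestResult:
    t: float
    p: float
    df: float
    paired: bool
    degenerate: bool = False


def group_ttest(
    sample_a: Sequence[float], sample_b: Sequence[float], paired: bool = False
) -> TTestResult:
    """Two-sided Student's t-test between two samples.

    The paired variant serves within-group pre/post comparisons on the same
    tumors; the unpaired (pooled-variance) variant serves between-group
    comparisons.  Zero-variance inputs yield ``p = NaN`` with a degenerate
    flag instead of raising.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per sample")
    if paired and len(a) != len(b):
        raise ValueError("paired test requires equal sample sizes")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if paired:
            res = sps.ttest_rel(a, b)
            df = len(a) - 1
        else:
            res = sps.ttest_ind(a, b, equal_var=True)
            df = len(a) + len(b) - 2
    t, p = float(res.statistic), float(res.pvalue)
    degenerate = not np.isfinite(t)
    return TTestResult(t=t, p=p, df=float(df), paired=paired, degenerate=degenerate)


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson product-moment correlation with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 pairs")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in input")
    res = sps.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=len(x))


#: the cross-endpoint pairings computed across group means
CORRELATION_PAIRINGS = (
    ("hypoxic_fraction_pct", "delta_A_pct"),
    ("hypoxic_fraction_pct", "delta_kel_pct"),
    ("hypoxic_fraction_pct", "delta_volume_pct"),
    ("delta_volume_pct", "delta_A_pct"),
    ("delta_volume_pct", "delta_kel_pct"),
)


def build_correlation_table(group_means: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlations between group-mean endpoints.

    ``group_means`` has one row per group with (a subset of) the columns
    named in :data:`CORRELATION_PAIRINGS`.  Each pairing is computed over
    the groups with both endpoints present; a pairing with fewer than 3
    complete pairs (or a missing column) is skipped with a warning.
    """
    rows = []
    for x_col, y_col in CORRELATION_PAIRINGS:
        if x_col not in group_means.columns or y_col not in group_means.columns:
            warnings.warn(f"skipping {x_col} vs {y_col}: column missing")
            continue
        sub = group_means[[x_col, y_col]].dropna()
        if len(sub) < 3:
            warnings.warn(f"skipping {x_col} vs {y_col}: fewer than 3 complete pairs")
            continue
        res = pearson(sub[x_col], sub[y_col])
        rows.append({"x": x_col, "y": y_col, "r": res.r, "p": res.p, "n": res.n})
    return pd.DataFrame(rows, columns=["x", "y", "r", "p", "n"])


def _sem(v: np.ndarray) -> float:
    return float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0


def summarize_cohort(endpoints: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group summary statistics from a per-tumor endpoint table.

    ``endpoints`` needs columns ``group`` plus any of: ``A_pre``, ``A_post``,
    ``kel_pre``, ``kel_post``, ``hypoxic_fraction_pct``, ``delta_volume_pct``.
    Returns ``(summary, group_means)``: a long table of per-group mean / SEM /
    n per endpoint, and a wide table of group means ready for
    :func:`build_correlation_table`.  Group relative changes are the mean of
    per-tumor relative changes (primary) with the change of group means
    exported alongside.
    """
    if "group" not in endpoints.columns:
        raise ValueError("endpoints must have a 'group' column")
    df = endpoints.copy()
    for param, pre_col, post_col in (("A", "A_pre", "A_post"), ("kel", "kel_pre", "kel_post")):
        if pre_col in df.columns and post_col in df.columns:
            df[f"delta_{param}_pct"] = 100.0 * (df[post_col] - df[pre_col]) / df[pre_col]

    value_cols = [
        c
        for c in (
            "A_pre", "A_post", "kel_pre", "kel_post",
            "delta_A_pct", "delta_kel_pct",
            "hypoxic_fraction_pct", "delta_volume_pct",
        )
        if c in df.columns
    ]
    long_rows = []
    wide_rows = []
    for group, sub in df.groupby("group", sort=False):
        wide = {"group": group}
        for col in value_cols:
            v = sub[col].dropna().to_numpy()
            if len(v) == 0:
                wide[col] = np.nan
                continue
            long_rows.append(
                {"group": group, "endpoint": col,
                 "mean": float(np.mean(v)), "sem": _sem(v), "n": len(v)}
            )
            wide[col] = float(np.mean(v))
        # change of group means, secondary definition of the group change
        for param, pre_col, post_col in (("A", "A_pre", "A_post"), ("kel", "kel_pre", "kel_post")):
            if pre_col in sub.columns and post_col in sub.columns:
                pre_m = sub[pre_col].dropna().mean()
                post_m = sub[post_col].dropna().mean()
                if pre_m and np.isfinite(pre_m):
                    long_rows.append(
                        {"group": group, "endpoint": f"delta_{param}_of_means_pct",
                         "mean": relative_change(pre_m, post_m), "sem": np.nan,
                         "n": int(sub[pre_col].notna().sum())}
                    )
        wide_rows.append(wide)
    return pd.DataFrame(long_rows), pd.DataFrame(wide_rows)
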