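"""Drug-sensitivity biomarker discovery on a PDX panel.

Screens features whose pretreatment expression associates with post-treatment
percent change in tumor volume.  PDXs are split by the sign of the activity
(tumor shrank vs. grew); with at least ``min_group_size`` PDXs on each side an
unpaired two-sample t-test of expression between the two groups is used,
otherwise a per-feature correlation of expression with the continuous
activity.  p-values are Benjamini-Hochberg adjusted; selection is at
FDR < ``fdr``, falling back to the nominal type-I level when the FDR screen
comes up empty (the small-panel regime).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dataio import DrugActivityTable, ExpressionMatrix

__all__ = [
    "split_by_activity",
    "choose_method",
    "t_test_per_feature",
    "correlation_per_feature",
    "benjamini_hochberg",
    "discover_biomarkers",
]

BIOMARKER_COLUMNS = [
    "feature_id",
    "method",
    "statistic",
    "p_value",
    "q_value",
    "direction",
    "selected",
    "alpha_mode",
    "degenerate",
]


def split_by_activity(activity: DrugActivityTable):
    """Partition PDX ids into (shrunken, grown) by the sign of activity.

    Shrinkage must be strict: activity exactly 0 counts as "grown"
    (non-responding).
    """
    if len(activity) == 0:
        raise ValueError("activity table is empty")
    shrunken = [s for s, a in zip(activity.sample_ids, activity.activity) if a < 0]
    grown = [s for s, a in zip(activity.sample_ids, activity.activity) if a >= 0]
    return shrunken, grown


def choose_method(shrunken_n: int, grown_n: int, activity_variance=None,
                  min_group_size: int = 2) -> str:
    """Pick the discovery test from the group sizes.

    Returns ``"t_test"`` when both groups have at least ``min_group_size``
    PDXs, else ``"correlation"``.  ``activity_variance`` is accepted for
    interface completeness but does not enter the rule (see docs/methods.md).
    """
    if shrunken_n < 0 or grown_n < 0:
        raise ValueError("group sizes must be nonnegative")
    if shrunken_n + grown_n < 4:
        raise ValueError(
            f"only {shrunken_n + grown_n} PDXs in total; at least 4 are needed "
            "for any discovery test"
        )
    if min(shrunken_n, grown_n) < min_group_size:
        return "correlation"
    return "t_test"


def t_test_per_feature(expr: ExpressionMatrix, shrunken_ids, grown_ids,
                       equal_var: bool = True):
    """Two-sided unpaired t-test per feature, grown vs. shrunken PDXs.

    The statistic is oriented as ``grown - shrunken``: positive means the
    feature is higher in resistant (grown) tumors.  Pooled-variance
    Student's t by default; Welch with ``equal_var=False``.

    Returns ``(statistic, p_value, degenerate)`` arrays.  Features with zero
    variance in both groups get statistic 0, p 1 when the group means tie,
    or p 0 when they are perfectly separated; both cases are flagged.
    """
    if len(shrunken_ids) < 2 or len(grown_ids) < 2:
        raise ValueError("each activity group needs at least 2 PDXs for a t-test")
    a = expr.subset_samples(grown_ids).values
    b = expr.subset_samples(shrunken_ids).values
    zero_var = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = zero_var | ~np.isfinite(t)
    equal_means = zero_var & (a.mean(axis=1) == b.mean(axis=1))
    separated = zero_var & ~equal_means
    t[equal_means] = 0.0
    p[equal_means] = 1.0
    t[separated] = np.sign(a.mean(axis=1) - b.mean(axis=1))[separated] * np.inf
    p[separated] = 0.0
    nan = ~np.isfinite(p)
    t[nan] = 0.0
    p[nan] = 1.0
    return t, p, degenerate


def _pearson_with_p(x: np.ndarray, y: np.ndarray):
    """Row-wise Pearson correlation of ``x`` (features x samples) with ``y``,
    with the two-sided t-approximation p-value."""
    n = x.shape[1]
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    sx = np.sqrt((xc ** 2).sum(axis=1))
    sy = np.sqrt((yc ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ yc) / (sx * sy)
    r = np.clip(r, -1.0, 1.0)
    degenerate = (sx == 0) | (sy == 0) | ~np.isfinite(r)
    r = np.where(degenerate, 0.0, r)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isfinite(t), p, 0.0)  # |r| == 1 -> p = 0
    p = np.where(degenerate, 1.0, p)
    return r, p, degenerate


def correlation_per_feature(expr: ExpressionMatrix, activity: DrugActivityTable,
                            flavor: str = "spearman"):
    """Per-feature correlation of expression with continuous drug activity.

    ``flavor`` is ``"pearson"`` or ``"spearman"`` (average ranks, two-sided
    t-approximation p-value).  Positive statistic means higher expression
    tracks tumor growth.  Returns ``(statistic, p_value, degenerate)``.
    """
    if flavor not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation flavor {flavor!r}")
    act = activity.reindex(expr.sample_ids)
    n = expr.n_samples
    if n < 4:
        raise ValueError("correlation discovery needs at least 4 PDXs")
    y = act.activity
    if y.var() == 0:
        raise ValueError("drug activity is constant; correlation is undefined")
    x = expr.values
    if flavor == "spearman":
        x = stats.rankdata(x, axis=1)
        y = stats.rankdata(y)
    return _pearson_with_p(np.asarray(x, dtype=float), np.asarray(y, dtype=float))


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted q-values (monotone in the p-ranking)."""
    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def discover_biomarkers(expr: ExpressionMatrix, activity: DrugActivityTable,
                        method: str = "auto", fdr: float = 0.05,
                        nominal_alpha: float = 0.05, nominal_fallback: bool = True,
                        min_group_size: int = 2, equal_var: bool = True,
                        correlation_flavor: str = "spearman",
                        selection: str = "fdr") -> pd.DataFrame:
    """Screen initial drug-sensitivity biomarkers.

    Runs the configured (or automatically chosen) per-feature test, adjusts
    p-values with Benjamini-Hochberg, and selects features at
    ``q < fdr``.  If nothing survives the FDR screen and ``nominal_fallback``
    is on, selection is redone at the nominal level ``p < nominal_alpha`` and
    the table's ``alpha_mode`` records ``"nominal"``.

    ``selection="nominal"`` skips the FDR screen and selects at the nominal
    level directly — the operative small-panel regime, where the FDR screen
    of a panel of a dozen PDXs is either empty or traps a handful of
    features too few to carry the downstream co-expression analysis.

    Returns a DataFrame with one row per input feature, in input order, with
    columns ``feature_id, method, statistic, p_value, q_value, direction,
    selected, alpha_mode, degenerate``.
    """
    if selection not in ("fdr", "nominal"):
        raise ValueError(f"unknown selection mode {selection!r}")
    act = activity.reindex(expr.sample_ids)
    shrunken, grown = split_by_activity(act)

    if method == "auto":
        method = choose_method(len(shrunken), len(grown), act.activity.var(),
                               min_group_size=min_group_size)
    if method == "correlation":
        method = correlation_flavor
    if method == "t_test":
        stat, p, degenerate = t_test_per_feature(expr, shrunken, grown,
                                                 equal_var=equal_var)
    elif method in ("pearson", "spearman"):
        stat, p, degenerate = correlation_per_feature(expr, act, flavor=method)
    else:
        raise ValueError(f"unknown discovery method {method!r}")

    q = benjamini_hochberg(p)
    if selection == "nominal":
        selected = p < nominal_alpha
        alpha_mode = "nominal"
    else:
        selected = q < fdr
        alpha_mode = "fdr"
        if not selected.any() and nominal_fallback:
            selected = p < nominal_alpha
            alpha_mode = "nominal"

    table = pd.DataFrame(
        {
            "feature_id": expr.feature_ids,
            "method": method,
            "statistic": stat,
            "p_value": p,
            "q_value": q,
            "direction": np.sign(stat).astype(int),
            "selected": selected,
            "alpha_mode": alpha_mode,
            "degenerate": degenerate,
        },
        columns=BIOMARKER_COLUMNS,
    )
    table.attrs["n_shrunken"] = len(shrunken)
    table.attrs["n_grown"] = len(grown)
    return table
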