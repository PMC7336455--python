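"""Concordant co-expression analysis (CCEA).

Xenograft passage reshapes a tumor's transcriptional program, so a gene that
predicts drug activity in PDX models is only trusted for patients when its
co-expression neighborhood is preserved in patient tumors.  For each
candidate biomarker ``g`` among ``n`` candidates, two length-(n-1) vectors
are formed: the correlations of ``g`` with every other candidate in the PDX
panel (a column of ``U``) and the same correlations in a pretreatment
patient cohort (a column of ``V``).  The concordance co-expression
coefficient (CCEC) of ``g`` is Lin's concordance correlation coefficient
between the two vectors,

    c(g) = 2 * sum_k (U_kg - Ubar)(V_kg - Vbar)
           / [ sum_k (U_kg - Ubar)^2 + sum_k (V_kg - Vbar)^2
               + (n-1) * (Ubar - Vbar)^2 ],

with sums over k != g and Ubar, Vbar the off-diagonal means.  c(g) is 1 only
when the two co-expression neighborhoods agree exactly, and it penalizes
both scatter and location shift.  Biomarkers with a significantly positive
CCEC (BH-adjusted), optionally above an absolute floor ``min_ccec``, are the
concordantly co-expressed (CCE) biomarkers passed on to model training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import ExpressionMatrix, align_features
from .discovery import benjamini_hochberg

__all__ = [
    "CorrelationMatrixPair",
    "pairwise_correlations",
    "ccec",
    "ccec_all",
    "ccec_pvalue",
    "run_ccea",
]

CCEA_COLUMNS = ["feature_id", "ccec", "p_value", "q_value", "selected", "degenerate"]


@dataclass
class CorrelationMatrixPair:
    """Matched pairwise-correlation matrices of the same features in the
    PDX panel (``U``) and the patient cohort (``V``)."""

    feature_ids: list
    U: np.ndarray
    V: np.ndarray
    correlation_flavor: str = "pearson"

    def __post_init__(self):
        n = len(self.feature_ids)
        for name, m in (("U", self.U), ("V", self.V)):
            m = np.asarray(m, dtype=float)
            if m.shape != (n, n):
                raise ValueError(f"{name} must be {n}x{n}")
            if not np.allclose(m, m.T, atol=1e-10):
                raise ValueError(f"{name} must be symmetric")
            if np.any(np.abs(m) > 1 + 1e-10):
                raise ValueError(f"{name} entries must lie in [-1, 1]")
        self.U = np.asarray(self.U, dtype=float)
        self.V = np.asarray(self.V, dtype=float)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)


def pairwise_correlations(expr: ExpressionMatrix, features=None,
                          flavor: str = "pearson"):
    """n x n matrix of pairwise feature correlations across samples.

    Symmetric with unit diagonal.  Constant features get zero rows/columns
    (unit diagonal kept) and are reported in the returned ``degenerate``
    boolean mask — they can never be selected downstream.

    Returns ``(matrix, degenerate)``.
    """
    if features is not None:
        expr = expr.subset_features(features)
    if expr.n_samples < 3:
        raise ValueError("pairwise correlations need at least 3 samples")
    if expr.n_features < 2:
        raise ValueError("pairwise correlations need at least 2 features")
    x = expr.values
    if flavor == "spearman":
        x = stats.rankdata(x, axis=1)
    elif flavor != "pearson":
        raise ValueError(f"unknown correlation flavor {flavor!r}")
    degenerate = x.std(axis=1) == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.corrcoef(x)
    m = np.asarray(m, dtype=float)
    m[degenerate, :] = 0.0
    m[:, degenerate] = 0.0
    np.fill_diagonal(m, 1.0)
    m = np.clip((m + m.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(m, 1.0)
    return m, degenerate


def _ccc_sums(u: np.ndarray, v: np.ndarray):
    """Raw sums for Lin's CCC between two equal-length vectors."""
    m = len(u)
    ubar = u.mean()
    vbar = v.mean()
    du = u - ubar
    dv = v - vbar
    num = 2.0 * float(du @ dv)
    den = float(du @ du) + float(dv @ dv) + m * (ubar - vbar) ** 2
    return num, den


def ccec(pair_or_U, V=None, g=None):
    """Concordance co-expression coefficient of feature ``g``.

    Accepts either ``ccec(pair, g)`` with a :class:`CorrelationMatrixPair`,
    or two raw correlation matrices ``ccec(U, V, g)``.  Equals Lin's
    concordance correlation coefficient between the off-diagonal
    correlation vectors ``U[., g]`` and ``V[., g]``.  Both vectors constant
    with equal means is degenerate and returns 0.
    """
    if isinstance(pair_or_U, CorrelationMatrixPair):
        if g is None:
            g = V
        U, V = pair_or_U.U, pair_or_U.V
    else:
        U = np.asarray(pair_or_U, dtype=float)
        V = np.asarray(V, dtype=float)
    if g is None:
        raise ValueError("feature index g is required")
    n = U.shape[0]
    if n < 3:
        raise ValueError("CCEC needs at least 3 features (2 off-diagonal partners)")
    mask = np.arange(n) != g
    num, den = _ccc_sums(U[mask, g], V[mask, g])
    if den == 0.0:
        return 0.0
    return num / den


def ccec_all(U: np.ndarray, V: np.ndarray):
    """CCEC for every feature; returns ``(ccec, degenerate)`` arrays."""
    U = np.asarray(U, dtype=float)
    V = np.asarray(V, dtype=float)
    n = U.shape[0]
    if n < 3:
        raise ValueError("CCEC needs at least 3 features")
    out = np.empty(n)
    degenerate = np.zeros(n, dtype=bool)
    mask = ~np.eye(n, dtype=bool)
    for g in range(n):
        num, den = _ccc_sums(U[mask[:, g], g], V[mask[:, g], g])
        if den == 0.0:
            out[g] = 0.0
            degenerate[g] = True
        else:
            out[g] = num / den
    return out, degenerate


def ccec_pvalue(c, m: int):
    """Two-sided p-value for H0: CCEC = 0.

    Fisher-type test on the inverse-hyperbolic-tangent transform:
    ``Z = atanh(c)`` with standard error ``1 / sqrt(m - 2)`` under the null,
    where ``m`` is the number of paired off-diagonal entries (n - 1).
    ``|c| = 1`` returns p = 0.
    """
    c = np.asarray(c, dtype=float)
    if m < 3:
        raise ValueError("p-value needs at least 3 paired entries")
    boundary = np.abs(c) >= 1.0
    safe = np.where(boundary, 0.0, c)
    z = np.arctanh(safe) * np.sqrt(m - 2)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(boundary, 0.0, p)
    if p.ndim == 0:
        return float(p)
    return p


def _permutation_pvalues(U, V, observed, n_perm, rng):
    """Feature-label permutation null: permute the feature labels of V
    (rows and columns jointly) and recompute every CCEC."""
    n = U.shape[0]
    exceed = np.ones(n)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Vp = V[np.ix_(perm, perm)]
        cp, _ = ccec_all(U, Vp)
        exceed += np.abs(cp) >= np.abs(observed)
    return exceed / (n_perm + 1)


def run_ccea(pdx_expr: ExpressionMatrix, patient_expr: ExpressionMatrix,
             biomarkers: pd.DataFrame, min_ccec: float = 0.0, fdr: float = 0.05,
             correlation_flavor: str = "pearson", p_method: str = "atanh",
             n_permutations: int = 500, random_state=None) -> pd.DataFrame:
    """Compute CCEC for every selected biomarker and flag CCE biomarkers.

    ``biomarkers`` is a discovery table (see
    :func:`pdxgem.discovery.discover_biomarkers`); only its ``selected``
    rows enter the analysis.  Selection requires BH-adjusted
    ``q < fdr`` and ``ccec > min_ccec`` (the significance-only default is
    ``min_ccec = 0``; a stricter absolute floor such as 0.3 trims the
    signature further).

    Returns a DataFrame with columns ``feature_id, ccec, p_value, q_value,
    selected, degenerate``; the correlation matrices and cohort sizes ride
    along in ``.attrs``.
    """
    candidates = biomarkers.loc[biomarkers["selected"], "feature_id"].tolist()
    pdx_sub = pdx_expr.subset_features(
        [f for f in pdx_expr.feature_ids if f in set(candidates)]
    )
    pdx_sub, pat_sub = align_features(pdx_sub, patient_expr)
    if pdx_sub.n_features < 3:
        raise ValueError(
            f"only {pdx_sub.n_features} selected biomarker(s) shared across "
            "cohorts; CCEA needs at least 3"
        )

    U, degU = pairwise_correlations(pdx_sub, flavor=correlation_flavor)
    V, degV = pairwise_correlations(pat_sub, flavor=correlation_flavor)
    c, deg_c = ccec_all(U, V)
    degenerate = degU | degV | deg_c
    m = pdx_sub.n_features - 1

    if p_method == "atanh":
        p = ccec_pvalue(np.where(degenerate, 0.0, c), m)
    elif p_method == "permutation":
        rng = np.random.default_rng(random_state)
        p = _permutation_pvalues(U, V, c, n_permutations, rng)
    else:
        raise ValueError(f"unknown p_method {p_method!r}")
    p = np.where(degenerate, 1.0, p)
    c = np.where(degenerate, 0.0, c)

    q = benjamini_hochberg(p)
    selected = (q < fdr) & (c > min_ccec) & ~degenerate

    table = pd.DataFrame(
        {
            "feature_id": pdx_sub.feature_ids,
            "ccec": c,
            "p_value": p,
            "q_value": q,
            "selected": selected,
            "degenerate": degenerate,
        },
        columns=CCEA_COLUMNS,
    )
    table.attrs.update(
        n_features=pdx_sub.n_features,
        pdx_n=pdx_sub.n_samples,
        patient_n=pat_sub.n_samples,
        correlation_flavor=correlation_flavor,
        matrices=CorrelationMatrixPair(pdx_sub.feature_ids, U, V,
                                       correlation_flavor),
        n_selected=int(selected.sum()),
        ccec_min=float(c.min()),
        ccec_max=float(c.max()),
        ccec_median=float(np.median(c)),
    )
    return table
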