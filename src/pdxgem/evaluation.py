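"""Validation of model scores against independent cohort outcomes.

Scores live on the percent tumor-volume-change scale, so a LOW score means
predicted shrinkage, i.e. predicted response.  Every operation here takes
``responder_low`` explicitly (default True) rather than inferring the
orientation from the data.

Binary endpoints (e.g. pathological complete response vs residual disease)
get a two-sample t-test on the scores and a rank-based ROC AUC with an
optional stratified-bootstrap confidence interval.  Survival endpoints get
Kaplan-Meier medians per score stratum, the log-rank test and a Tarone-style
trend test across ordered strata (the log-rank score test with stratum
scores 1..k).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .dataio import OutcomeTable
from .gem import PredictionScores

__all__ = [
    "compare_score_groups",
    "auc",
    "auc_bootstrap_ci",
    "stratify_scores",
    "survival_compare",
    "trend_logrank",
    "cox_regression",
    "validate",
]

MEDIAN_LABELS = ["low", "high"]
TERTILE_LABELS = ["low", "intermediate", "high"]


def _as_scores(scores) -> pd.Series:
    if isinstance(scores, PredictionScores):
        return scores.to_series()
    return pd.Series(np.asarray(scores, dtype=float))


def _binary(outcome: OutcomeTable) -> np.ndarray:
    if outcome.outcome_kind != "binary_response":
        raise ValueError("a binary response outcome is required")
    return outcome.response


def compare_score_groups(scores, outcome: OutcomeTable, equal_var: bool = True):
    """Two-sided two-sample t-test of scores between responders (1) and
    non-responders (0).  Returns ``(t_statistic, p_value)`` with the
    statistic oriented as non-responders minus responders."""
    y = _binary(outcome)
    s = _as_scores(scores).to_numpy()
    resp, nonresp = s[y == 1], s[y == 0]
    if len(resp) < 2 or len(nonresp) < 2:
        raise ValueError("both response groups need at least 2 patients")
    t, p = stats.ttest_ind(nonresp, resp, equal_var=equal_var)
    return float(t), float(p)


def auc(scores, outcome: OutcomeTable, responder_low: bool = True) -> float:
    """Rank-based ROC AUC of scores discriminating responders.

    The Mann-Whitney form U / (n1 * n2) with half-credit for ties.  With
    ``responder_low=True`` it is the probability that a responder's score is
    below a non-responder's.
    """
    y = _binary(outcome)
    s = _as_scores(scores).to_numpy()
    n_resp = int((y == 1).sum())
    n_non = int((y == 0).sum())
    if n_resp == 0 or n_non == 0:
        raise ValueError("both response classes must be present")
    ranks = stats.rankdata(s)
    # P(score_nonresponder > score_responder) + 0.5 * P(tie)
    u = ranks[y == 0].sum() - n_non * (n_non + 1) / 2.0
    value = u / (n_resp * n_non)
    return float(value if responder_low else 1.0 - value)


def auc_bootstrap_ci(scores, outcome: OutcomeTable, responder_low: bool = True,
                     n_boot: int = 2000, level: float = 0.95, random_state=None):
    """Stratified-bootstrap percentile CI for the AUC.

    Resamples within each response class, ``n_boot`` replicates, seeded.
    Returns ``(auc, lower, upper)``.
    """
    y = _binary(outcome)
    s = _as_scores(scores).to_numpy()
    rng = np.random.default_rng(random_state)
    idx_r = np.flatnonzero(y == 1)
    idx_n = np.flatnonzero(y == 0)
    point = auc(s, outcome, responder_low=responder_low)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        take = np.concatenate(
            [rng.choice(idx_r, idx_r.size), rng.choice(idx_n, idx_n.size)]
        )
        yb = y[take]
        ob = OutcomeTable([str(i) for i in range(take.size)], "binary_response",
                          response=yb)
        boots[b] = auc(s[take], ob, responder_low=responder_low)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    return point, float(lo), float(hi)


def stratify_scores(scores, mode: str = "median_split") -> pd.Series:
    """Assign each sample a score stratum.

    ``median_split``: ``low`` for scores <= median (ties at the median go
    low), ``high`` above.  ``tertiles``: ``low``/``intermediate``/``high``
    split at the empirical 1/3 and 2/3 quantiles, with boundary ties going
    to the lower stratum.  All-identical scores cannot be stratified.
    """
    s = _as_scores(scores)
    if s.nunique() < 2:
        raise ValueError("all scores identical; no stratification possible")
    x = s.to_numpy()
    if mode == "median_split":
        if len(s) < 2:
            raise ValueError("median split needs at least 2 samples")
        med = np.median(x)
        labels = np.where(x <= med, "low", "high")
        categories = MEDIAN_LABELS
    elif mode == "tertiles":
        if len(s) < 3:
            raise ValueError("tertile split needs at least 3 samples")
        q1, q2 = np.quantile(x, [1.0 / 3.0, 2.0 / 3.0])
        labels = np.where(x <= q1, "low", np.where(x <= q2, "intermediate", "high"))
        categories = TERTILE_LABELS
    else:
        raise ValueError(f"unknown stratification mode {mode!r}")
    out = pd.Series(pd.Categorical(labels, categories=categories, ordered=True),
                    index=s.index, name="stratum")
    if out.nunique() < 2:
        raise ValueError("scores too tied to form more than one stratum")
    return out


def trend_logrank(time, event, group_scores):
    """Log-rank trend (Tarone) test across ordered groups.

    ``group_scores`` are numeric scores (1..k for ordered strata).  At each
    distinct event time the observed-minus-expected deaths per group and
    their hypergeometric covariance are accumulated;
    ``Z = s'(O - E) / sqrt(s' V s)``.  Returns ``(z, p)`` two-sided.
    With two groups this reduces to the ordinary log-rank test.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group_scores = np.asarray(group_scores, dtype=float)
    groups = np.unique(group_scores)
    k = groups.size
    if k < 2:
        raise ValueError("trend test needs at least 2 groups")
    if event.sum() == 0:
        raise ValueError("no events observed")
    U = np.zeros(k)
    V = np.zeros((k, k))
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = at_risk.sum()
        d = ((time == t) & (event == 1)).sum()
        if n < 2:
            continue
        n_g = np.array([(at_risk & (group_scores == g)).sum() for g in groups],
                       dtype=float)
        d_g = np.array(
            [((time == t) & (event == 1) & (group_scores == g)).sum() for g in groups],
            dtype=float,
        )
        e_g = d * n_g / n
        U += d_g - e_g
        frac = n_g / n
        V += d * (n - d) / (n - 1) * (np.diag(frac) - np.outer(frac, frac))
    num = float(groups @ U)
    var = float(groups @ V @ groups)
    if var <= 0:
        return 0.0, 1.0
    z = num / np.sqrt(var)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def survival_compare(strata, outcome: OutcomeTable):
    """Compare survival across score strata.

    Returns a dict with the Kaplan-Meier median survival per stratum, the
    log-rank p-value across strata, the trend-test p-value over the ordered
    strata, and the per-stratum KM curve coordinates for plotting.
    """
    if outcome.outcome_kind != "survival":
        raise ValueError("a survival outcome is required")
    strata = pd.Series(strata)
    if strata.nunique() < 2:
        raise ValueError("at least 2 strata are required")
    time, event = outcome.time, outcome.event
    if event.sum() == 0:
        raise ValueError("no events observed")

    if isinstance(strata.dtype, pd.CategoricalDtype):
        levels = [c for c in strata.cat.categories if (strata == c).any()]
    else:
        levels = sorted(strata.unique())
    order = {lab: i + 1 for i, lab in enumerate(levels)}
    codes = strata.map(order).to_numpy(dtype=float)

    medians, curves = {}, {}
    for lab in levels:
        mask = (strata == lab).to_numpy()
        if event[mask].sum() == 0:
            raise ValueError(f"stratum {lab!r} has no events")
        km = KaplanMeierFitter()
        km.fit(time[mask], event[mask], label=str(lab))
        medians[str(lab)] = float(km.median_survival_time_)
        sf = km.survival_function_
        curves[str(lab)] = {
            "time": [float(v) for v in sf.index],
            "survival": [float(v) for v in sf.iloc[:, 0]],
        }

    lr = multivariate_logrank_test(time, codes, event)
    z, trend_p = trend_logrank(time, event, codes)
    return {
        "strata": [str(lab) for lab in levels],
        "median_survival": medians,
        "logrank_statistic": float(lr.test_statistic),
        "logrank_p": float(lr.p_value),
        "trend_z": z,
        "trend_p": trend_p,
        "km_curves": curves,
    }


def cox_regression(scores, outcome: OutcomeTable, covariates: pd.DataFrame | None = None):
    """Thin pass-through to a proportional-hazards fit of survival on the
    raw continuous score (plus optional covariates).

    Returns the fitted ``lifelines.CoxPHFitter``; the score's hazard ratio
    is ``exp(coef)`` for the ``"pdxgem_score"`` column.
    """
    from lifelines import CoxPHFitter

    if outcome.outcome_kind != "survival":
        raise ValueError("a survival outcome is required")
    df = pd.DataFrame({
        "time": outcome.time,
        "event": outcome.event,
        "pdxgem_score": _as_scores(scores).to_numpy(),
    })
    if covariates is not None:
        df = pd.concat([df, covariates.reset_index(drop=True)], axis=1)
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")
    return cph


def validate(scores, outcome: OutcomeTable, cohort_label: str = "",
             responder_low: bool = True, strata_mode: str = "median_split",
             n_boot: int = 2000, random_state=None) -> dict:
    """Full validation report for one cohort (binary or survival outcome)."""
    s = _as_scores(scores)
    if isinstance(scores, PredictionScores):
        outcome = outcome.reindex(scores.sample_ids)
    report: dict = {
        "cohort_label": cohort_label,
        "outcome_kind": outcome.outcome_kind,
        "n": len(outcome),
        "responder_low": responder_low,
    }
    if outcome.outcome_kind == "binary_response":
        t, p = compare_score_groups(s, outcome)
        point, lo, hi = auc_bootstrap_ci(
            s, outcome, responder_low=responder_low, n_boot=n_boot,
            random_state=random_state,
        )
        y = outcome.response
        report.update(
            t_statistic=t,
            t_test_p=p,
            auc=point,
            auc_ci=[lo, hi],
            group_means={
                "responder": float(s.to_numpy()[y == 1].mean()),
                "non_responder": float(s.to_numpy()[y == 0].mean()),
            },
        )
    else:
        strata = stratify_scores(s, mode=strata_mode)
        report["strata_definition"] = strata_mode
        report["survival_tests"] = survival_compare(strata, outcome)
    return report
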