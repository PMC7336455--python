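"""Multi-gene random-forest drug-response model (the GEM).

Training standardizes each CCE biomarker gene-wise across the PDX panel,
fits a regression random forest of drug activity (percent tumor-volume
change) on the standardized expression, drops features whose variable
importance is not positive, and refits on the survivors.  The fitted model
scores new cohorts on the activity scale: a low score predicts tumor
shrinkage, i.e. response.

Variable importance is the out-of-bag permutation importance (the mean
increase in out-of-bag MSE when a feature's values are permuted), matching
the behavior of the classical randomForest regression importance; impurity
and in-sample permutation importances are available as alternatives.

Prediction-time cohorts are standardized gene-wise *within the cohort*:
per-gene z-scoring is the only transfer rule that is invariant to platform
location/scale shifts between the PDX arrays and a clinical cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

from .dataio import DrugActivityTable, ExpressionMatrix

__all__ = [
    "GemModel",
    "PredictionScores",
    "standardize_features",
    "train_gem",
    "predict_scores",
    "save_model",
    "load_model",
]

SERIALIZATION_VERSION = 1

#: Maximum fraction of model features a cohort may be missing at scoring time.
MAX_MISSING_MODEL_FEATURES = 0.2


@dataclass
class PredictionScores:
    """Per-sample model scores, on the percent tumor-volume-change scale."""

    sample_ids: list
    score: np.ndarray

    def __post_init__(self):
        self.score = np.asarray(self.score, dtype=float)
        if self.score.shape != (len(self.sample_ids),):
            raise ValueError("one score per sample is required")
        if not np.all(np.isfinite(self.score)):
            raise ValueError("scores must be finite")

    def to_series(self) -> pd.Series:
        return pd.Series(self.score, index=self.sample_ids, name="pdxgem_score")


@dataclass
class GemModel:
    """A trained drug-response predictor.

    ``feature_ids`` are the final features (all with positive importance),
    ``forest`` the refit random forest, ``importances`` the OOB permutation
    importances from the refit, and ``training_r`` / ``training_r_oob`` the
    Pearson correlations between observed activity and the in-sample refit
    predictions / the out-of-bag predictions.
    """

    feature_ids: list
    forest: RandomForestRegressor
    importances: pd.Series
    training_r: float
    training_r_oob: float
    n_trees: int
    random_state: int | None
    importance_kind: str
    standardization: str = "per-cohort gene-wise z-score"
    drug_label: str = ""
    initial_importances: pd.Series | None = None

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)


def standardize_features(expr: ExpressionMatrix, on_constant: str = "drop"):
    """Gene-wise z-scoring: each feature row to mean 0, sd 1 (divisor n-1).

    Constant features are dropped with a warning (``on_constant="drop"``) or
    set to all-zero rows (``on_constant="zero"``, used at prediction time).
    """
    if expr.n_samples < 2:
        raise ValueError("standardization needs at least 2 samples")
    x = expr.values
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    constant = sd[:, 0] == 0
    if constant.any():
        names = [f for f, c in zip(expr.feature_ids, constant) if c]
        if on_constant == "drop":
            warnings.warn(
                f"dropped {len(names)} constant feature(s) during "
                f"standardization: {names[:10]}",
                UserWarning,
                stacklevel=2,
            )
        elif on_constant == "zero":
            warnings.warn(
                f"{len(names)} constant feature(s) set to zero after "
                f"standardization: {names[:10]}",
                UserWarning,
                stacklevel=2,
            )
        else:
            raise ValueError(f"unknown on_constant policy {on_constant!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (x - mean) / sd
    if on_constant == "drop":
        keep = ~constant
        return ExpressionMatrix(z[keep], list(np.array(expr.feature_ids)[keep]),
                                expr.sample_ids, expr.meta)
    z[constant, :] = 0.0
    return ExpressionMatrix(z, expr.feature_ids, expr.sample_ids, expr.meta)


# ---------------------------------------------------------------------------
# out-of-bag machinery
# ---------------------------------------------------------------------------

def _bootstrap_indices(tree, n_samples: int) -> np.ndarray:
    """Reproduce the bootstrap sample indices sklearn drew for one tree.

    sklearn seeds each tree with an integer and draws
    ``RandomState(seed).randint(0, n, n)``; regenerating from the stored
    seed recovers the in-bag multiset exactly (cross-checked in the test
    suite against the forest's own ``oob_prediction_``).
    """
    return np.random.RandomState(tree.random_state).randint(0, n_samples, n_samples)


def _oob_masks(forest: RandomForestRegressor, n_samples: int) -> np.ndarray:
    masks = np.ones((len(forest.estimators_), n_samples), dtype=bool)
    for t, tree in enumerate(forest.estimators_):
        masks[t, _bootstrap_indices(tree, n_samples)] = False
    return masks


def oob_predictions(forest: RandomForestRegressor, X: np.ndarray) -> np.ndarray:
    """Per-sample mean prediction over the trees that did not see the sample.

    Samples that are in-bag for every tree get the full-forest prediction
    (with 500 trees this has probability ~(1 - e^{-1})^500 ~ 0).
    """
    n = X.shape[0]
    masks = _oob_masks(forest, n)
    total = np.zeros(n)
    count = np.zeros(n)
    for t, tree in enumerate(forest.estimators_):
        oob = masks[t]
        if oob.any():
            total[oob] += tree.predict(X[oob])
            count[oob] += 1
    never = count == 0
    if never.any():
        total[never] = forest.predict(X[never])
        count[never] = 1.0
    return total / count


def _oob_permutation_importance(forest: RandomForestRegressor, X: np.ndarray,
                                y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Mean over trees of (permuted OOB MSE - OOB MSE), per feature.

    The randomForest "%IncMSE" analogue, reported unscaled.
    """
    n, p = X.shape
    masks = _oob_masks(forest, n)
    importances = np.zeros(p)
    n_used = 0
    for t, tree in enumerate(forest.estimators_):
        oob = np.flatnonzero(masks[t])
        if oob.size < 2:
            continue
        n_used += 1
        Xo = X[oob]
        base_err = np.mean((tree.predict(Xo) - y[oob]) ** 2)
        # one stacked predict per tree: p permuted copies of the OOB block
        stacked = np.repeat(Xo[None, :, :], p, axis=0)
        for j in range(p):
            stacked[j, :, j] = Xo[rng.permutation(oob.size), j]
        pred = tree.predict(stacked.reshape(p * oob.size, p))
        pred = pred.reshape(p, oob.size)
        perm_err = np.mean((pred - y[oob]) ** 2, axis=1)
        importances += perm_err - base_err
    if n_used == 0:
        raise RuntimeError("no tree had out-of-bag samples")
    return importances / n_used


def _fit_forest(X: np.ndarray, y: np.ndarray, n_trees: int, random_state) -> RandomForestRegressor:
    p = X.shape[1]
    forest = RandomForestRegressor(
        n_estimators=n_trees,
        max_features=max(1, p // 3),
        min_samples_leaf=5,
        bootstrap=True,
        random_state=random_state,
        n_jobs=1,
    )
    forest.fit(X, y)
    return forest


def _importances(forest, X, y, kind: str, seed) -> np.ndarray:
    rng = np.random.default_rng(seed)
    if kind == "oob_permutation":
        return _oob_permutation_importance(forest, X, y, rng)
    if kind == "impurity":
        return forest.feature_importances_
    if kind == "permutation":
        res = permutation_importance(
            forest, X, y, n_repeats=10,
            random_state=np.random.RandomState(np.random.SeedSequence(seed).generate_state(1)[0] % (2 ** 31)),
        )
        return res.importances_mean
    raise ValueError(f"unknown importance kind {kind!r}")


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def train_gem(pdx_expr: ExpressionMatrix, activity: DrugActivityTable,
              cce_features, n_trees: int = 500, random_state: int | None = 0,
              importance: str = "oob_permutation", drug_label: str = "") -> GemModel:
    """Train the drug-response forest on the CCE biomarkers.

    Standardizes gene-wise, fits the forest, drops features with importance
    <= 0, refits on the survivors, and records the training correlations.
    Deterministic given the data and ``random_state``.
    """
    cce_features = list(cce_features)
    if len(cce_features) < 2:
        raise ValueError("model training needs at least 2 CCE biomarkers")
    if pdx_expr.n_samples < 4:
        raise ValueError("model training needs at least 4 PDX samples")
    act = activity.reindex(pdx_expr.sample_ids)
    z = standardize_features(pdx_expr.subset_features(cce_features))
    X = z.values.T
    y = act.activity

    forest0 = _fit_forest(X, y, n_trees, random_state)
    imp0 = _importances(forest0, X, y, importance, random_state)
    initial = pd.Series(imp0, index=z.feature_ids, name="importance")
    keep = imp0 > 0
    if not keep.any():
        raise ValueError(
            "no feature had positive variable importance; consider a larger "
            "PDX panel or skipping the importance filter"
        )
    survivors = [f for f, k in zip(z.feature_ids, keep) if k]

    Xs = X[:, keep]
    forest = _fit_forest(Xs, y, n_trees, random_state)
    imp = _importances(forest, Xs, y, importance, random_state)
    pred_in = forest.predict(Xs)
    pred_oob = oob_predictions(forest, Xs)

    return GemModel(
        feature_ids=survivors,
        forest=forest,
        importances=pd.Series(imp, index=survivors, name="importance"),
        training_r=_pearson(pred_in, y),
        training_r_oob=_pearson(pred_oob, y),
        n_trees=n_trees,
        random_state=random_state,
        importance_kind=importance,
        drug_label=drug_label,
        initial_importances=initial,
    )


def predict_scores(model: GemModel, cohort_expr: ExpressionMatrix) -> PredictionScores:
    """Score a cohort with a trained model.

    The cohort is standardized gene-wise within itself, restricted and
    ordered to the model's features, and passed through the forest.  Model
    features absent from the cohort (or constant within it) are imputed at
    the standardized value 0 (the cohort mean), with a warning; more than
    20% missing features is an error.
    """
    if cohort_expr.n_samples < 3:
        raise ValueError("scoring needs at least 3 cohort samples to standardize")
    present = [f for f in model.feature_ids if f in cohort_expr._feature_index]
    overlap = len(present) / model.n_features
    missing = [f for f in model.feature_ids if f not in cohort_expr._feature_index]
    if overlap < 1.0 - MAX_MISSING_MODEL_FEATURES:
        raise ValueError(
            f"cohort contains only {overlap:.1%} of the model's "
            f"{model.n_features} features (>= "
            f"{1.0 - MAX_MISSING_MODEL_FEATURES:.0%} required)"
        )
    if missing:
        warnings.warn(
            f"{len(missing)} model feature(s) absent from the cohort, imputed "
            f"at the cohort mean: {missing[:10]}",
            UserWarning,
            stacklevel=2,
        )
    z = standardize_features(cohort_expr.subset_features(present), on_constant="zero")
    frame = z.to_frame().reindex(model.feature_ids, fill_value=0.0)
    X = frame.to_numpy().T
    return PredictionScores(cohort_expr.sample_ids, model.forest.predict(X))


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def save_model(model: GemModel, path) -> None:
    """Serialize a trained model (joblib container, versioned)."""
    joblib.dump({"format": "pdxgem-model", "version": SERIALIZATION_VERSION,
                 "model": model}, path)


def load_model(path) -> GemModel:
    payload = joblib.load(path)
    if not isinstance(payload, dict) or payload.get("format") != "pdxgem-model":
        raise ValueError(f"{path} is not a serialized model")
    if payload.get("version") != SERIALIZATION_VERSION:
        raise ValueError(f"unsupported model version {payload.get('version')!r}")
    return payload["model"]
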