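"""Top-level estimator: discovery -> CCEA -> forest, with an sklearn face.

:class:`PDXGem` wires the pipeline stages into a single
``fit(X, y, reference=...)`` / ``predict(X)`` estimator so the model
composes with scikit-learn tooling (``get_params``/``set_params``, cloning,
model selection).  ``X`` follows the sklearn convention of samples x
features (an :class:`~pdxgem.dataio.ExpressionMatrix` is also accepted and
transposed internally); ``y`` is the percent tumor-volume change of each
PDX.  ``reference`` is the pretreatment patient cohort used by the
concordant co-expression screen and is required unless ``skip_ccea``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from . import ccea, discovery, gem
from .dataio import DrugActivityTable, ExpressionMatrix

__all__ = ["PDXGem"]


def _as_expression(X, feature_ids=None, prefix="S") -> ExpressionMatrix:
    """Coerce samples x features input to a features x samples matrix."""
    if isinstance(X, ExpressionMatrix):
        return X
    if isinstance(X, pd.DataFrame):
        values = X.to_numpy(dtype=float).T
        features = [str(c) for c in X.columns]
        samples = [str(i) for i in X.index]
    else:
        values = np.asarray(X, dtype=float).T
        n_feat, n_samp = values.shape
        if feature_ids is None:
            feature_ids = [f"X{j}" for j in range(n_feat)]
        features = list(feature_ids)
        samples = [f"{prefix}{i}" for i in range(n_samp)]
    return ExpressionMatrix(values, features, samples)


class PDXGem(BaseEstimator, RegressorMixin):
    """Drug-response predictor trained on a PDX panel.

    Parameters
    ----------
    discovery_method : {"auto", "t_test", "pearson", "spearman"}
        Per-feature association test for the biomarker screen; "auto" picks
        the t-test when both activity groups have at least
        ``min_group_size`` PDXs, else the correlation test.
    min_group_size : int
        Smallest per-group size allowed for the t-test branch.
    discovery_fdr, nominal_fallback : float, bool
        FDR level of the screen and whether to fall back to the nominal
        0.05 level when nothing passes.
    correlation_flavor : {"spearman", "pearson"}
        Flavor used by the correlation discovery branch.
    ccea_flavor : {"pearson", "spearman"}
        Correlation flavor inside the co-expression matrices.
    ccea_fdr, min_ccec : float
        CCE selection: BH q < ``ccea_fdr`` and CCEC > ``min_ccec``.
    skip_ccea : bool
        Train directly on all discovered biomarkers (no patient reference
        needed) — the ablation mode.
    n_trees : int
        Forest size.
    importance : {"oob_permutation", "impurity", "permutation"}
        Variable-importance flavor used for the positive-importance filter.
    random_state : int or None
        Seed for the forest and importance permutations.

    Attributes
    ----------
    biomarkers_ : DataFrame
        Discovery table (one row per input feature).
    ccea_ : DataFrame or None
        CCEA table over the discovered biomarkers (None when skipped).
    gem_ : GemModel
        The trained forest bundle.
    feature_ids_ : list of str
        Final model features (positive importance).
    stage_counts_ : dict
        Feature counts through discovered -> CCE -> positive-importance.
    training_r_, training_r_oob_ : float
        In-sample and out-of-bag correlation of predictions with activity.
    """

    def __init__(self, *, discovery_method="auto", min_group_size=2,
                 discovery_fdr=0.05, nominal_fallback=True,
                 discovery_selection="fdr",
                 correlation_flavor="spearman", equal_var=True,
                 ccea_flavor="pearson", ccea_fdr=0.05, min_ccec=0.0,
                 skip_ccea=False, n_trees=500, importance="oob_permutation",
                 random_state=None):
        self.discovery_method = discovery_method
        self.min_group_size = min_group_size
        self.discovery_fdr = discovery_fdr
        self.nominal_fallback = nominal_fallback
        self.discovery_selection = discovery_selection
        self.correlation_flavor = correlation_flavor
        self.equal_var = equal_var
        self.ccea_flavor = ccea_flavor
        self.ccea_fdr = ccea_fdr
        self.min_ccec = min_ccec
        self.skip_ccea = skip_ccea
        self.n_trees = n_trees
        self.importance = importance
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, X, y, reference=None, feature_ids=None, drug_label=""):
        """Run discovery, CCEA and forest training.

        ``X``: PDX expression, samples x features (array/DataFrame) or an
        ``ExpressionMatrix``; ``y``: percent tumor-volume change per PDX;
        ``reference``: pretreatment patient cohort on the same feature
        space (required unless ``skip_ccea=True``).
        """
        expr = _as_expression(X, feature_ids, prefix="PDX")
        if isinstance(y, DrugActivityTable):
            activity = y.reindex(expr.sample_ids)
        else:
            activity = DrugActivityTable(expr.sample_ids,
                                         np.asarray(y, dtype=float))

        self.biomarkers_ = discovery.discover_biomarkers(
            expr, activity,
            method=self.discovery_method,
            fdr=self.discovery_fdr,
            nominal_fallback=self.nominal_fallback,
            min_group_size=self.min_group_size,
            equal_var=self.equal_var,
            correlation_flavor=self.correlation_flavor,
            selection=self.discovery_selection,
        )
        discovered = self.biomarkers_.loc[self.biomarkers_["selected"],
                                          "feature_id"].tolist()
        if len(discovered) < 2:
            raise ValueError(
                f"only {len(discovered)} biomarker(s) discovered; cannot train"
            )

        if self.skip_ccea:
            self.ccea_ = None
            cce_features = discovered
        else:
            if reference is None:
                raise ValueError(
                    "a patient reference cohort is required unless skip_ccea=True"
                )
            ref = _as_expression(reference, feature_ids, prefix="REF")
            self.ccea_ = ccea.run_ccea(
                expr, ref, self.biomarkers_,
                min_ccec=self.min_ccec, fdr=self.ccea_fdr,
                correlation_flavor=self.ccea_flavor,
            )
            cce_features = self.ccea_.loc[self.ccea_["selected"],
                                          "feature_id"].tolist()
            if len(cce_features) < 2:
                raise ValueError(
                    f"only {len(cce_features)} CCE biomarker(s) selected; "
                    "cannot train (consider skip_ccea=True or a larger panel)"
                )

        self.gem_ = gem.train_gem(
            expr, activity, cce_features,
            n_trees=self.n_trees, random_state=self.random_state,
            importance=self.importance, drug_label=drug_label,
        )
        self.feature_ids_ = list(self.gem_.feature_ids)
        self.importances_ = self.gem_.importances
        self.training_r_ = self.gem_.training_r
        self.training_r_oob_ = self.gem_.training_r_oob
        self.stage_counts_ = {
            "discovered": len(discovered),
            "cce_selected": len(cce_features),
            "positive_importance": len(self.feature_ids_),
        }
        self.n_features_in_ = expr.n_features
        return self

    def predict(self, X) -> np.ndarray:
        """Score a cohort (samples x features); returns one score per sample
        on the percent tumor-volume-change scale (low = predicted response)."""
        if not hasattr(self, "gem_"):
            raise RuntimeError("this PDXGem instance is not fitted yet")
        expr = _as_expression(X, prefix="S")
        return gem.predict_scores(self.gem_, expr).score

    def predict_scores(self, X) -> gem.PredictionScores:
        """Like :meth:`predict` but keeps the sample identifiers."""
        if not hasattr(self, "gem_"):
            raise RuntimeError("this PDXGem instance is not fitted yet")
        return gem.predict_scores(self.gem_, _as_expression(X, prefix="S"))
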