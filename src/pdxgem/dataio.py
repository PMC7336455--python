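"""Containers and readers for expression matrices, drug-activity and outcome tables.

The common currency of the pipeline is a genes-by-samples matrix of
log-scale expression values (:class:`ExpressionMatrix`).  Drug activity is
the percent change in xenograft tumor volume after treatment
(:class:`DrugActivityTable`); clinical validation cohorts carry either a
binary response label or a survival outcome (:class:`OutcomeTable`).

Expression values are assumed to be already normalized (processed array or
log-scale intensity matrices); no cross-sample renormalization is ever
applied here.  Feature matching between datasets is by exact identifier
string — cross-platform probeset/gene mapping is the caller's job.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "DrugActivityTable",
    "OutcomeTable",
    "ParseError",
    "read_expression",
    "write_expression",
    "read_activity",
    "write_activity",
    "read_outcome",
    "write_outcome",
    "align_features",
    "percent_tumor_volume_change",
]

#: Cell tokens treated as missing on load.
NA_TOKENS = {"", "NA", "N/A", "NaN", "nan", "null", "NULL", "."}

#: Features with more than this fraction of missing cells are dropped.
MAX_MISSING_FRACTION = 0.2


class ParseError(ValueError):
    """Raised when an input file violates its declared format."""


class ExpressionMatrix:
    """A features x samples matrix of continuous (log-scale) expression values.

    Parameters
    ----------
    values : array-like of shape (n_features, n_samples)
        Finite expression values.
    feature_ids : sequence of str
        Unique probeset or gene-symbol identifiers, one per row.
    sample_ids : sequence of str
        Unique sample identifiers, one per column.
    meta : dict, optional
        Free-form key -> string annotations.
    """

    def __init__(self, values, feature_ids, sample_ids, meta=None):
        values = np.asarray(values, dtype=float)
        feature_ids = [str(f) for f in feature_ids]
        sample_ids = [str(s) for s in sample_ids]
        if values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if values.shape != (len(feature_ids), len(sample_ids)):
            raise ValueError(
                f"shape {values.shape} does not match "
                f"{len(feature_ids)} features x {len(sample_ids)} samples"
            )
        if len(set(feature_ids)) != len(feature_ids):
            raise ValueError("duplicate feature identifiers")
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample identifiers")
        if not np.all(np.isfinite(values)):
            raise ValueError("expression values must be finite after load")
        self.values = values
        self.feature_ids = feature_ids
        self.sample_ids = sample_ids
        self.meta = dict(meta or {})
        self._feature_index = {f: i for i, f in enumerate(feature_ids)}

    # -- basic protocol -------------------------------------------------
    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ExpressionMatrix({self.n_features} features x "
            f"{self.n_samples} samples)"
        )

    # -- conversion -----------------------------------------------------
    @classmethod
    def from_frame(cls, frame: pd.DataFrame, meta=None) -> "ExpressionMatrix":
        """Build from a features-x-samples DataFrame (index = feature ids)."""
        return cls(frame.to_numpy(dtype=float), list(frame.index), list(frame.columns), meta)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)

    # -- subsetting -----------------------------------------------------
    def subset_features(self, features) -> "ExpressionMatrix":
        """Restrict to ``features`` in the given order."""
        try:
            rows = [self._feature_index[f] for f in features]
        except KeyError as exc:
            raise KeyError(f"feature {exc.args[0]!r} not in matrix") from None
        return ExpressionMatrix(
            self.values[rows, :], list(features), self.sample_ids, self.meta
        )

    def subset_samples(self, samples) -> "ExpressionMatrix":
        index = {s: j for j, s in enumerate(self.sample_ids)}
        try:
            cols = [index[s] for s in samples]
        except KeyError as exc:
            raise KeyError(f"sample {exc.args[0]!r} not in matrix") from None
        return ExpressionMatrix(
            self.values[:, cols], self.feature_ids, list(samples), self.meta
        )

    def feature_values(self, feature: str) -> np.ndarray:
        return self.values[self._feature_index[feature], :]


@dataclass
class DrugActivityTable:
    """Per-PDX drug activity: percent change in tumor volume after treatment.

    Negative activity means the tumor shrank (the PDX is drug-sensitive);
    zero or positive activity means it grew (resistant).
    """

    sample_ids: list
    activity: np.ndarray

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.activity = np.asarray(self.activity, dtype=float)
        if self.activity.ndim != 1 or len(self.activity) != len(self.sample_ids):
            raise ValueError("one activity value per sample id is required")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers in activity table")
        if not np.all(np.isfinite(self.activity)):
            raise ValueError("activity values must be finite")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def to_series(self) -> pd.Series:
        return pd.Series(self.activity, index=self.sample_ids, name="activity_pct")

    def reindex(self, sample_ids) -> "DrugActivityTable":
        """Reorder/subset to ``sample_ids`` (all must be present)."""
        s = self.to_series()
        missing = [x for x in sample_ids if x not in s.index]
        if missing:
            raise KeyError(f"samples missing from activity table: {missing}")
        return DrugActivityTable(list(sample_ids), s.loc[list(sample_ids)].to_numpy())

    @classmethod
    def from_volumes(cls, sample_ids, pre_volume, post_volume) -> "DrugActivityTable":
        return cls(sample_ids, percent_tumor_volume_change(pre_volume, post_volume))


@dataclass
class OutcomeTable:
    """Clinical outcome of a validation cohort.

    ``outcome_kind`` is ``"binary_response"`` (``response``: 1 = responder,
    e.g. pathological complete response) or ``"survival"`` (``time`` in
    months, ``event``: 1 = event observed).
    """

    sample_ids: list
    outcome_kind: str
    response: np.ndarray | None = None
    time: np.ndarray | None = None
    event: np.ndarray | None = None

    def __post_init__(self):
        self.sample_ids = [str(s) for s in self.sample_ids]
        n = len(self.sample_ids)
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample identifiers in outcome table")
        if self.outcome_kind == "binary_response":
            if self.response is None or self.time is not None or self.event is not None:
                raise ValueError("binary_response outcome requires exactly `response`")
            self.response = np.asarray(self.response, dtype=int)
            if self.response.shape != (n,) or not np.isin(self.response, (0, 1)).all():
                raise ValueError("response must be a 0/1 vector, one per sample")
        elif self.outcome_kind == "survival":
            if self.time is None or self.event is None or self.response is not None:
                raise ValueError("survival outcome requires exactly `time` and `event`")
            self.time = np.asarray(self.time, dtype=float)
            self.event = np.asarray(self.event, dtype=int)
            if self.time.shape != (n,) or np.any(self.time < 0) or not np.all(np.isfinite(self.time)):
                raise ValueError("time must be finite and nonnegative, one per sample")
            if self.event.shape != (n,) or not np.isin(self.event, (0, 1)).all():
                raise ValueError("event must be a 0/1 vector, one per sample")
        else:
            raise ValueError(f"unknown outcome_kind {self.outcome_kind!r}")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def reindex(self, sample_ids) -> "OutcomeTable":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [x for x in sample_ids if x not in index]
        if missing:
            raise KeyError(f"samples missing from outcome table: {missing}")
        rows = [index[s] for s in sample_ids]
        if self.outcome_kind == "binary_response":
            return OutcomeTable(list(sample_ids), "binary_response", response=self.response[rows])
        return OutcomeTable(
            list(sample_ids), "survival", time=self.time[rows], event=self.event[rows]
        )


# ---------------------------------------------------------------------------
# scalar helpers
# ---------------------------------------------------------------------------

def percent_tumor_volume_change(pre_volume, post_volume):
    """Percent change in tumor volume, ``100 * (post - pre) / pre``.

    Negative iff the tumor shrank under treatment.  Accepts scalars or
    arrays; ``pre_volume`` must be strictly positive and ``post_volume``
    nonnegative.
    """
    pre = np.asarray(pre_volume, dtype=float)
    post = np.asarray(post_volume, dtype=float)
    if np.any(pre <= 0):
        raise ValueError("pre-treatment volume must be strictly positive")
    if np.any(post < 0):
        raise ValueError("post-treatment volume must be nonnegative")
    out = 100.0 * (post - pre) / pre
    if out.ndim == 0:
        return float(out)
    return out


def align_features(a: ExpressionMatrix, b: ExpressionMatrix):
    """Restrict two matrices to their shared features, rows in identical order.

    The intersection is ordered by the first matrix's feature list; sample
    sets are untouched.  Raises ``ValueError`` on an empty intersection.
    """
    common = [f for f in a.feature_ids if f in b._feature_index]
    if not common:
        raise ValueError("the two matrices share no feature identifiers")
    return a.subset_features(common), b.subset_features(common)


# ---------------------------------------------------------------------------
# expression matrix i/o
# ---------------------------------------------------------------------------

def read_expression(path, dialect: str = "matrix_tsv") -> ExpressionMatrix:
    """Read a tab-delimited expression matrix.

    ``matrix_tsv``: row 1 is ``feature_id<TAB>sample1<TAB>...``, one feature
    per row.  ``series_matrix_like`` is the same but lines beginning with
    ``"!"`` (GEO series-matrix metadata) are ignored.

    Missing cells (``NA`` and friends) are imputed with the feature's mean
    across samples when at most 20% of the feature's cells are missing;
    features above that are dropped with a warning.  Duplicate feature ids
    are collapsed to the duplicate row with the highest mean expression
    (the common probeset-collapse convention), with a warning.
    """
    if dialect not in ("matrix_tsv", "series_matrix_like"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = text.splitlines()
    if dialect == "series_matrix_like":
        lines = [ln for ln in lines if not ln.startswith("!")]
    lines = [ln for ln in lines if ln.strip() != ""]
    if not lines:
        raise ParseError(f"{path}: no matrix block found")

    header = lines[0].split("\t")
    sample_ids = [c.strip() for c in header[1:]]
    if not sample_ids:
        raise ParseError(f"{path}: malformed header (no sample columns)")
    if len(set(sample_ids)) != len(sample_ids):
        dupes = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise ParseError(f"{path}: duplicate sample ids {dupes}")

    raw = pd.read_csv(
        io.StringIO("\n".join(lines)),
        sep="\t",
        index_col=0,
        dtype=str,
        keep_default_na=False,
    )
    raw.columns = sample_ids

    cleaned = raw.apply(lambda col: col.str.strip())
    na_mask = cleaned.isin(NA_TOKENS).to_numpy()
    # numpy's parser round-trips %.17g exactly (pd.to_numeric does not)
    arr = cleaned.to_numpy(dtype=object)
    arr[na_mask] = "nan"
    try:
        values = arr.astype(np.float64)
    except ValueError:
        for (i, j), cell in np.ndenumerate(arr):
            try:
                float(cell)
            except ValueError:
                raise ParseError(
                    f"{path}: non-numeric value {cleaned.iat[i, j]!r} at "
                    f"feature {raw.index[i]!r}, sample {sample_ids[j]!r}"
                ) from None
        raise  # pragma: no cover - unreachable
    numeric = pd.DataFrame(values, index=raw.index, columns=raw.columns)

    # missing-value policy
    frac_missing = numeric.isna().mean(axis=1)
    too_missing = frac_missing > MAX_MISSING_FRACTION
    if too_missing.any():
        dropped = list(numeric.index[too_missing])
        warnings.warn(
            f"dropped {len(dropped)} feature(s) with >{MAX_MISSING_FRACTION:.0%} "
            f"missing values: {dropped[:10]}",
            UserWarning,
            stacklevel=2,
        )
        numeric = numeric.loc[~too_missing]
    if numeric.isna().to_numpy().any():
        row_means = numeric.mean(axis=1)
        numeric = numeric.apply(lambda col: col.fillna(row_means))

    # duplicate-feature policy: keep the row with the highest mean expression
    index = numeric.index.astype(str)
    if index.duplicated().any():
        dupes = sorted(set(index[index.duplicated()]))
        warnings.warn(
            f"collapsed duplicate feature id(s) {dupes[:10]} by keeping the "
            "row with highest mean expression",
            UserWarning,
            stacklevel=2,
        )
        numeric.index = index
        means = numeric.mean(axis=1)
        order = np.argsort(-means.to_numpy(), kind="stable")
        best = numeric.iloc[order]
        best = best[~best.index.duplicated(keep="first")]
        # restore original file order of the surviving rows
        first_pos = {f: i for i, f in reversed(list(enumerate(index)))}
        numeric = best.loc[sorted(best.index, key=first_pos.__getitem__)]

    if numeric.shape[0] == 0:
        raise ParseError(f"{path}: no features left after missing-value handling")
    return ExpressionMatrix.from_frame(numeric.astype(float))


def write_expression(matrix: ExpressionMatrix, path) -> None:
    """Write ``matrix_tsv`` at full stored precision (round-trips exactly)."""
    frame = matrix.to_frame()
    frame.index.name = "feature_id"
    frame.to_csv(path, sep="\t", float_format="%.17g")


# ---------------------------------------------------------------------------
# activity / outcome i/o
# ---------------------------------------------------------------------------

def read_activity(path) -> DrugActivityTable:
    """Read an activity CSV: ``sample_id`` plus either ``activity_pct`` or
    ``pre_volume`` and ``post_volume`` columns."""
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: activity table needs a sample_id column")
    ids = df["sample_id"].astype(str).tolist()
    if "activity_pct" in df.columns:
        return DrugActivityTable(ids, df["activity_pct"].to_numpy(dtype=float))
    if {"pre_volume", "post_volume"} <= set(df.columns):
        return DrugActivityTable.from_volumes(
            ids,
            df["pre_volume"].to_numpy(dtype=float),
            df["post_volume"].to_numpy(dtype=float),
        )
    raise ParseError(
        f"{path}: expected activity_pct or pre_volume+post_volume columns"
    )


def write_activity(table: DrugActivityTable, path) -> None:
    pd.DataFrame(
        {"sample_id": table.sample_ids, "activity_pct": table.activity}
    ).to_csv(path, index=False, float_format="%.17g")


def read_outcome(path) -> OutcomeTable:
    """Read an outcome CSV: ``sample_id`` plus ``response`` or ``time,event``."""
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ParseError(f"{path}: outcome table needs a sample_id column")
    ids = df["sample_id"].astype(str).tolist()
    if "response" in df.columns:
        return OutcomeTable(ids, "binary_response", response=df["response"].to_numpy())
    if {"time", "event"} <= set(df.columns):
        return OutcomeTable(
            ids,
            "survival",
            time=df["time"].to_numpy(dtype=float),
            event=df["event"].to_numpy(),
        )
    raise ParseError(f"{path}: expected response or time+event columns")


def write_outcome(table: OutcomeTable, path) -> None:
    if table.outcome_kind == "binary_response":
        df = pd.DataFrame({"sample_id": table.sample_ids, "response": table.response})
    else:
        df = pd.DataFrame(
            {"sample_id": table.sample_ids, "time": table.time, "event": table.event}
        )
    df.to_csv(path, index=False, float_format="%.17g")
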