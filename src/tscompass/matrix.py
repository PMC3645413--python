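"""The series x operations feature matrix: assembly, special-value
handling, filtering and outlier-robust normalization.

Cells where an operation returned a special value are masked and carry a
reason code; they never hold a numeric value.  The normalized view maps
each column through an outlier-robust sigmoid centred on the column median
with width 1.35 IQR (1.349 IQR equals one sd for a normal distribution),
then rescales the column to [0, 1]; the transform is invariant under
positive affine maps of a column and bounded against arbitrarily large
outliers.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .catalogue.base import Operation, evaluate
from .io import Collection, TimeSeries
from .values import SpecialValue, is_special

logger = logging.getLogger(__name__)

__all__ = [
    "DataMatrix",
    "compute_matrix",
    "filter_special",
    "robust_sigmoid_normalize",
    "RobustSigmoidScaler",
    "FeatureExtractor",
]


@dataclass
class DataMatrix:
    """Series x operations outputs with a special-value mask.

    raw holds NaN at masked cells (the mask is authoritative); reasons
    holds the special-value reason string at masked cells, '' elsewhere.
    """

    raw: np.ndarray
    mask: np.ndarray
    reasons: np.ndarray
    row_ids: list
    col_ids: list
    normalized: np.ndarray | None = None
    row_labels: list | None = None
    row_targets: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        n, p = self.raw.shape
        if self.mask.shape != (n, p) or np.asarray(self.reasons).shape != (n, p):
            raise ValueError("raw/mask/reasons shapes disagree")
        if len(self.row_ids) != n or len(self.col_ids) != p:
            raise ValueError("id lists do not match matrix shape")
        if self.normalized is not None:
            norm = np.asarray(self.normalized, dtype=float)
            ok = norm[~self.mask]
            if ok.size and (np.nanmin(ok) < -1e-9 or np.nanmax(ok) > 1 + 1e-9):
                raise ValueError("normalized values outside [0, 1]")

    @property
    def shape(self):
        return self.raw.shape

    def special_fraction(self, axis: str = "operations") -> np.ndarray:
        ax = 0 if axis == "operations" else 1
        return self.mask.mean(axis=ax)

    def select_columns(self, col_ids: Sequence[str]) -> "DataMatrix":
        idx = [self.col_ids.index(c) for c in col_ids]
        return replace(
            self,
            raw=self.raw[:, idx],
            mask=self.mask[:, idx],
            reasons=self.reasons[:, idx],
            col_ids=[self.col_ids[i] for i in idx],
            normalized=None if self.normalized is None else self.normalized[:, idx],
        )

    def select_rows(self, idx: Sequence[int]) -> "DataMatrix":
        idx = list(idx)
        return replace(
            self,
            raw=self.raw[idx],
            mask=self.mask[idx],
            reasons=self.reasons[idx],
            row_ids=[self.row_ids[i] for i in idx],
            normalized=None if self.normalized is None else self.normalized[idx],
            row_labels=None if self.row_labels is None
            else [self.row_labels[i] for i in idx],
            row_targets=None if self.row_targets is None
            else self.row_targets[idx],
        )

    # -- persistence ----------------------------------------------------

    def to_hdf5(self, path, registry_hash: str = "") -> None:
        import h5py

        with h5py.File(path, "w") as f:
            kw = {"track_times": False}  # byte-stable output files
            f.create_dataset("raw", data=self.raw, **kw)
            f.create_dataset("mask", data=self.mask, **kw)
            f.create_dataset(
                "reasons",
                data=np.char.encode(self.reasons.astype(str), "utf-8"),
                **kw,
            )
            if self.normalized is not None:
                f.create_dataset("normalized", data=self.normalized, **kw)
            f.attrs["row_ids"] = [s.encode() for s in self.row_ids]
            f.attrs["col_ids"] = [s.encode() for s in self.col_ids]
            f.attrs["registry_hash"] = registry_hash
            if self.row_labels is not None:
                f.attrs["row_labels"] = [
                    ("" if v is None else v).encode() for v in self.row_labels
                ]
            if self.row_targets is not None:
                f.create_dataset("row_targets", data=self.row_targets, **kw)

    @classmethod
    def from_hdf5(cls, path) -> "DataMatrix":
        import h5py

        def _s(v):
            return v.decode() if isinstance(v, bytes) else str(v)

        with h5py.File(path, "r") as f:
            reasons = np.char.decode(f["reasons"][...].astype("S64"), "utf-8")
            labels = None
            if "row_labels" in f.attrs:
                labels = [_s(v) or None for v in f.attrs["row_labels"]]
            return cls(
                raw=f["raw"][...],
                mask=f["mask"][...],
                reasons=reasons.astype(object),
                row_ids=[_s(v) for v in f.attrs["row_ids"]],
                col_ids=[_s(v) for v in f.attrs["col_ids"]],
                normalized=f["normalized"][...] if "normalized" in f else None,
                row_labels=labels,
                row_targets=f["row_targets"][...] if "row_targets" in f else None,
            )

    def to_csv_triple(self, directory) -> None:
        """Interoperable export: values.csv, mask.csv, ids.json."""
        import pandas as pd

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.raw, index=self.row_ids, columns=self.col_ids).to_csv(
            directory / "values.csv"
        )
        pd.DataFrame(
            self.mask.astype(int), index=self.row_ids, columns=self.col_ids
        ).to_csv(directory / "mask.csv")
        (directory / "ids.json").write_text(
            json.dumps(
                {"row_ids": self.row_ids, "col_ids": self.col_ids},
                indent=1,
            )
        )


def compute_matrix(collection: Collection, ops: Sequence[Operation],
                   workers: int = 1) -> DataMatrix:
    """Evaluate every operation on every series.

    Special values become masked cells with their reason recorded.  The
    result is assembled in (series, operation) order and is independent of
    ``workers``; parallelism uses threads over rows.
    """
    ops = list(ops)
    members = list(collection)
    if not members or not ops:
        raise ValueError("compute_matrix needs non-empty inputs")
    n, p = len(members), len(ops)
    raw = np.full((n, p), np.nan)
    mask = np.zeros((n, p), dtype=bool)
    reasons = np.full((n, p), "", dtype=object)

    def row(i: int) -> None:
        ts = members[i]
        for j, op in enumerate(ops):
            out = evaluate(op, ts)
            if is_special(out):
                mask[i, j] = True
                reasons[i, j] = out.reason
            else:
                raw[i, j] = out
        logger.info("computed %d/%d: %s", i + 1, n, ts.id)

    if workers > 1:
        from concurrent.futures import ThreadPoolExecutor

        with ThreadPoolExecutor(max_workers=workers) as pool:
            list(pool.map(row, range(n)))
    else:
        for i in range(n):
            row(i)

    labels = [ts.class_label for ts in members]
    targets = np.array(
        [np.nan if ts.target is None else ts.target for ts in members]
    )
    return DataMatrix(
        raw=raw, mask=mask, reasons=reasons,
        row_ids=[ts.id for ts in members], col_ids=[op.id for op in ops],
        row_labels=labels if any(l is not None for l in labels) else None,
        row_targets=targets if not np.all(np.isnan(targets)) else None,
    )


def filter_special(m: DataMatrix, max_frac: float = 0.20,
                   axis: str = "operations"):
    """Drop columns (or rows) whose special-value fraction is not strictly
    below ``max_frac`` (only entries with less than the threshold fraction
    of special values are kept).  Returns (matrix, report); the report
    lists (id, fraction, dominant reason) for each dropped entry.
    """
    if not 0 <= max_frac <= 1:
        raise ValueError("max_frac must be in [0, 1]")
    frac = m.special_fraction(axis)
    keep = frac < max_frac
    if not keep.any():
        raise ValueError(
            f"special-value filter at {max_frac} removed every "
            f"{axis[:-1]}; raise the threshold"
        )
    report = []
    ids = m.col_ids if axis == "operations" else m.row_ids
    for i in np.nonzero(~keep)[0]:
        cell_reasons = (
            m.reasons[:, i][m.mask[:, i]]
            if axis == "operations"
            else m.reasons[i][m.mask[i]]
        )
        vals, counts = np.unique(cell_reasons.astype(str), return_counts=True)
        dominant = str(vals[np.argmax(counts)]) if vals.size else ""
        report.append(
            {"id": ids[i], "fraction": float(frac[i]), "reason": dominant}
        )
    if axis == "operations":
        out = m.select_columns([c for c, k in zip(m.col_ids, keep) if k])
    else:
        out = m.select_rows(list(np.nonzero(keep)[0]))
    if report:
        logger.info("filter_special dropped %d %s", len(report), axis)
    return out, report


class RobustSigmoidScaler(TransformerMixin, BaseEstimator):
    """Outlier-robust sigmoidal column scaler (NaN-aware).

    Each column x is mapped through 1 / (1 + exp(-(x - med) / (1.35 iqr)))
    and then linearly rescaled so the observed (fitted) values span [0, 1].
    Columns with zero IQR fall back to rank scaling (all-equal columns map
    to 0.5); fallbacks are recorded in ``fallback_columns_``.

    NaN entries are ignored during fit and propagated by transform.
    """

    def __init__(self, width: float = 1.35):
        self.width = width

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D array")
        n, p = X.shape
        self.medians_ = np.full(p, np.nan)
        self.iqrs_ = np.full(p, np.nan)
        self.post_min_ = np.full(p, np.nan)
        self.post_max_ = np.full(p, np.nan)
        self.fallback_columns_ = []
        self._rank_values_ = {}
        for j in range(p):
            col = X[:, j]
            ok = col[~np.isnan(col)]
            if ok.size == 0:
                continue
            med = np.median(ok)
            q75, q25 = np.percentile(ok, [75, 25])
            iqr = q75 - q25
            self.medians_[j] = med
            self.iqrs_[j] = iqr
            if iqr == 0:
                self.fallback_columns_.append(j)
                self._rank_values_[j] = np.unique(ok)
                logger.info(
                    "robust sigmoid: column %d has zero IQR, rank fallback", j
                )
                continue
            y_ok = 1.0 / (1.0 + np.exp(-(ok - med) / (self.width * iqr)))
            self.post_min_[j] = y_ok.min()
            self.post_max_[j] = y_ok.max()
        self.n_features_in_ = p
        return self

    def transform(self, X):
        check_is_fitted(self, "medians_")
        X = np.asarray(X, dtype=float)
        out = np.full_like(X, np.nan)
        for j in range(X.shape[1]):
            col = X[:, j]
            ok = ~np.isnan(col)
            if not ok.any() or np.isnan(self.medians_[j]):
                continue
            if j in self._rank_values_:
                uniq = self._rank_values_[j]
                if uniq.size == 1:
                    out[ok, j] = 0.5
                else:
                    pos = np.searchsorted(uniq, col[ok])
                    out[ok, j] = pos / (uniq.size - 1)
                continue
            y = 1.0 / (
                1.0 + np.exp(-(col[ok] - self.medians_[j])
                             / (self.width * self.iqrs_[j]))
            )
            lo, hi = self.post_min_[j], self.post_max_[j]
            if hi > lo:
                y = (y - lo) / (hi - lo)
            else:
                y = np.full_like(y, 0.5)
            out[ok, j] = np.clip(y, 0.0, 1.0)
        return out


def robust_sigmoid_normalize(m: DataMatrix) -> DataMatrix:
    """Populate the matrix's normalized view with the robust sigmoid
    column transform.  The mask is conserved exactly."""
    X = np.where(m.mask, np.nan, m.raw)
    scaler = RobustSigmoidScaler()
    norm = scaler.fit(X).transform(X)
    return replace(m, normalized=norm)


class FeatureExtractor(TransformerMixin, BaseEstimator):
    """sklearn-style transformer from lists of time series to the feature
    matrix (NaN marks special-valued cells).

    Parameters
    ----------
    ops : sequence of Operation, optional
        Defaults to the full default registry at fit time.
    normalize : bool
        Apply the robust sigmoid transform (fitted on the fit data).
    """

    def __init__(self, ops=None, normalize: bool = False):
        self.ops = ops
        self.normalize = normalize

    def _matrix(self, X) -> DataMatrix:
        members = [
            ts if isinstance(ts, TimeSeries)
            else TimeSeries(id=f"series_{i}", values=np.asarray(ts, dtype=float))
            for i, ts in enumerate(X)
        ]
        return compute_matrix(Collection(members), self.ops_)

    def fit(self, X, y=None):
        from .catalogue.base import default_registry

        self.ops_ = list(self.ops) if self.ops is not None else list(default_registry())
        if self.normalize:
            m = self._matrix(X)
            self.scaler_ = RobustSigmoidScaler().fit(
                np.where(m.mask, np.nan, m.raw)
            )
        return self

    def transform(self, X):
        check_is_fitted(self, "ops_")
        m = self._matrix(X)
        raw = np.where(m.mask, np.nan, m.raw)
        if self.normalize:
            return self.scaler_.transform(raw)
        return raw

    def get_feature_names_out(self, input_features=None):
        check_is_fitted(self, "ops_")
        return np.array([op.id for op in self.ops_])
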