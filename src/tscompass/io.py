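"""Data model for univariate time series and collections, plus text readers/writers.

A :class:`TimeSeries` is a uniformly sampled, finite, real-valued sequence
with an identifier and optional metadata (keywords, a class label for
classification tasks, a continuous target for regression tasks).  A
:class:`Collection` is an ordered, id-unique list of series, normally built
from a TSV manifest.

Series are stored raw: normalisation (z-scoring) happens inside the
operations that need it, never globally, so that distribution-type features
(mean, spread, ...) see the original values.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

from .values import SpecialValue

__all__ = [
    "TimeSeries",
    "Collection",
    "FormatError",
    "read_timeseries_file",
    "write_timeseries",
    "read_manifest",
    "write_manifest",
    "zscore",
]


class FormatError(ValueError):
    """Raised when an on-disk series file or manifest violates the format."""


@dataclass(frozen=True)
class TimeSeries:
    """One univariate, uniformly sampled time series.

    Parameters
    ----------
    id : str
        Identifier, unique within a collection.
    values : numpy.ndarray
        Finite real values in time order.  NaN/Inf are rejected.
    keywords : frozenset of str
        Free-form tags.
    class_label : str, optional
        Categorical label for classification tasks.
    target : float, optional
        Continuous response for regression tasks.
    source : str
        Free-text provenance (file path, generator spec, ...).
    """

    id: str
    values: np.ndarray
    keywords: frozenset = frozenset()
    class_label: str | None = None
    target: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("values must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"series {self.id!r} contains non-finite values")
        arr = np.ascontiguousarray(arr)
        arr.setflags(write=False)
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "keywords", frozenset(self.keywords))

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def length(self) -> int:
        return len(self)

    def with_values(self, values: Sequence[float]) -> "TimeSeries":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass
class Collection:
    """An ordered collection of time series with unique ids.

    Iteration order is the construction (manifest) order and is stable
    across runs.
    """

    members: list = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [ts.id for ts in self.members]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate series ids: {sorted(dupes)}")

    def __iter__(self) -> Iterator[TimeSeries]:
        return iter(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __getitem__(self, key):
        if isinstance(key, str):
            for ts in self.members:
                if ts.id == key:
                    return ts
            raise KeyError(key)
        return self.members[key]

    @property
    def ids(self) -> list:
        return [ts.id for ts in self.members]

    @property
    def label_set(self) -> set:
        return {ts.class_label for ts in self.members if ts.class_label is not None}

    @property
    def has_targets(self) -> bool:
        return all(ts.target is not None for ts in self.members) and len(self.members) > 0

    @property
    def labels(self) -> list:
        return [ts.class_label for ts in self.members]

    @property
    def targets(self) -> np.ndarray:
        return np.array(
            [np.nan if ts.target is None else ts.target for ts in self.members]
        )


_TOKEN_SPLIT = re.compile(r"[,\s]+")


def read_timeseries_file(path) -> TimeSeries:
    """Read a series from a text file: one float per line, or a single
    comma/whitespace-delimited row.  Lines starting with ``#`` are comments.

    The series id defaults to the file stem.  Empty files and non-numeric,
    NaN or Inf tokens raise :class:`FormatError` naming the line.
    """
    path = Path(path)
    values: list = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            for tok in _TOKEN_SPLIT.split(stripped):
                if not tok:
                    continue
                try:
                    v = float(tok)
                except ValueError:
                    raise FormatError(
                        f"{path}: non-numeric token {tok!r} at line {lineno}"
                    ) from None
                if not math.isfinite(v):
                    raise FormatError(
                        f"{path}: non-finite value {tok!r} at line {lineno}"
                    )
                values.append(v)
    if not values:
        raise FormatError(f"{path}: no numeric data")
    return TimeSeries(id=path.stem, values=np.array(values), source=str(path))


def write_timeseries(path, ts: TimeSeries) -> None:
    """Write one float per line using repr-faithful formatting, so that a
    read/write round trip reproduces the values bit-exactly."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        for v in ts.values:
            fh.write(f"{float(v)!r}\n")


def read_manifest(path) -> Collection:
    """Read a TSV manifest into a :class:`Collection`.

    Required columns: ``id``, ``path``.  Optional: ``class_label``,
    ``target``, ``keywords`` (comma-joined).  Relative paths are resolved
    against the manifest's directory.  Duplicate ids and missing files are
    errors (all missing paths are listed at once).
    """
    import pandas as pd

    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("id", "path"):
        if col not in df.columns:
            raise FormatError(f"{path}: manifest missing required column {col!r}")
    ids = df["id"].tolist()
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise FormatError(f"{path}: duplicate ids in manifest: {dupes}")

    base = path.parent
    resolved = [base / p if not Path(p).is_absolute() else Path(p) for p in df["path"]]
    missing = [str(p) for p in resolved if not p.exists()]
    if missing:
        raise FormatError(f"{path}: missing series files: {missing}")

    members = []
    for row, fpath in zip(df.itertuples(index=False), resolved):
        ts = read_timeseries_file(fpath)
        kw = getattr(row, "keywords", "")
        label = getattr(row, "class_label", "") or None
        target_s = getattr(row, "target", "")
        target = float(target_s) if target_s != "" else None
        members.append(
            replace(
                ts,
                id=row.id,
                keywords=frozenset(k for k in kw.split(",") if k),
                class_label=label,
                target=target,
            )
        )
    return Collection(members)


def write_manifest(path, collection: Collection, series_dir=None) -> None:
    """Write a collection as series files plus a TSV manifest."""
    path = Path(path)
    series_dir = Path(series_dir) if series_dir is not None else path.parent
    series_dir.mkdir(parents=True, exist_ok=True)
    rows = ["id\tpath\tclass_label\ttarget\tkeywords"]
    for ts in collection:
        fname = f"{ts.id}.txt"
        write_timeseries(series_dir / fname, ts)
        rel = (series_dir / fname).relative_to(path.parent)
        label = ts.class_label or ""
        target = "" if ts.target is None else repr(float(ts.target))
        kw = ",".join(sorted(ts.keywords))
        rows.append(f"{ts.id}\t{rel}\t{label}\t{target}\t{kw}")
    path.write_text("\n".join(rows) + "\n", encoding="utf-8")


def zscore(ts: TimeSeries):
    """Return a z-scored copy (mean 0, sample sd 1), or a
    :class:`SpecialValue` with reason ``constant_input`` for a constant
    series (never an exception: constancy is a data property)."""
    x = ts.values
    if x.size < 2:
        return SpecialValue("too_short")
    if np.ptp(x) == 0:  # exact-range test: sd underflows on constants
        return SpecialValue("constant_input")
    sd = x.std(ddof=1)
    return ts.with_values((x - x.mean()) / sd)
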