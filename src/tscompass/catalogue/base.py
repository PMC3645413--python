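"""Operation registry: named series-to-scalar features and their evaluation.

An :class:`Operation` wraps a pure function mapping a 1-D float array to a
single real number (or a :class:`~tscompass.values.SpecialValue`).  The
registry assigns each a unique id, a family, a parameter record and a
``scale_sensitive`` flag.  Operations flagged scale-insensitive are invariant
under positive affine transforms of the input (they z-score internally or are
invariant by construction); the flag is honest and checked by the test
suite over the whole registry.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Callable, Iterator

import numpy as np

from ..io import TimeSeries
from ..values import SpecialValue, is_special

FAMILIES = (
    "distribution",
    "correlation",
    "spectral",
    "stationarity",
    "information",
    "scaling",
    "model_fit",
    "symbolic",
    "novel",
)


@dataclass(frozen=True)
class Operation:
    """A registered feature: a pure series -> scalar function with metadata."""

    id: str
    name: str
    family: str
    func: Callable[[np.ndarray], object] = field(repr=False)
    params: dict = field(default_factory=dict)
    scale_sensitive: bool = False

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")

    def __call__(self, x: np.ndarray):
        return self.func(np.asarray(x, dtype=float))


def evaluate(op: Operation, ts):
    """Evaluate an operation on a series, mapping every data-dependent
    failure to a :class:`SpecialValue`.

    Returns a finite float or a SpecialValue; never raises for properties of
    the data (exceptions inside the operation become reason ``error``).
    Passing an unknown object for ``op`` is a programming error and raises.
    """
    x = ts.values if isinstance(ts, TimeSeries) else np.asarray(ts, dtype=float)
    try:
        out = op(x)
    except Exception as exc:  # data-dependent failure, not a crash
        return SpecialValue("error", f"{type(exc).__name__}: {exc}")
    if is_special(out):
        return out
    try:
        val = float(out)
    except (TypeError, ValueError):
        return SpecialValue("error", f"non-scalar output {out!r}")
    if math.isnan(val):
        return SpecialValue("nan")
    if math.isinf(val):
        return SpecialValue("inf")
    return val


class Registry:
    """Ordered, id-unique collection of operations."""

    def __init__(self, ops=()):
        self._ops: dict = {}
        for op in ops:
            self.register(op)

    def register(self, op: Operation) -> Operation:
        if op.id in self._ops:
            raise ValueError(f"duplicate operation id {op.id!r}")
        self._ops[op.id] = op
        return op

    def __iter__(self) -> Iterator[Operation]:
        return iter(self._ops.values())

    def __len__(self) -> int:
        return len(self._ops)

    def __contains__(self, op_id: str) -> bool:
        return op_id in self._ops

    def __getitem__(self, op_id: str) -> Operation:
        return self._ops[op_id]

    @property
    def ids(self) -> list:
        return list(self._ops)

    @property
    def families(self) -> set:
        return {op.family for op in self}

    def filter(self, families=None, ids=None) -> "Registry":
        ops = [
            op
            for op in self
            if (families is None or op.family in families)
            and (ids is None or op.id in ids)
        ]
        return Registry(ops)

    def to_json(self) -> str:
        """Export the registry as a reproducibility manifest."""
        records = [
            {
                "id": op.id,
                "name": op.name,
                "family": op.family,
                "params": op.params,
                "scale_sensitive": op.scale_sensitive,
            }
            for op in self
        ]
        return json.dumps(records, indent=1, sort_keys=True)

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]


def default_registry() -> Registry:
    """Build the default operation library: >=60 conceptually distinct
    operations spanning all nine families (parameter-swept instances are
    registered separately)."""
    from . import (  # local import to avoid cycles
        correlation,
        distribution,
        information,
        modelfit,
        novel,
        scaling,
        spectral,
        stationarity,
        symbolic,
    )

    reg = Registry()
    for mod in (
        distribution,
        correlation,
        spectral,
        stationarity,
        information,
        scaling,
        modelfit,
        symbolic,
        novel,
    ):
        for op in mod.make_operations():
            reg.register(op)
    return reg
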