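"""Special values: the non-real outputs an operation may return.

An operation either returns a finite real number or a :class:`SpecialValue`
carrying a reason code.  Special values are treated as missing cells of the
feature matrix downstream; they are never silently coerced to a number.
"""

from __future__ import annotations

from dataclasses import dataclass

REASONS = frozenset(
    {"nan", "inf", "error", "inapplicable", "constant_input", "too_short"}
)


@dataclass(frozen=True)
class SpecialValue:
    """A non-real operation output.

    reason is one of: ``nan``, ``inf``, ``error`` (a caught data-dependent
    exception), ``inapplicable`` (the quantity is undefined for this input),
    ``constant_input``, ``too_short``.
    """

    reason: str
    detail: str = ""

    def __post_init__(self) -> None:
        if self.reason not in REASONS:
            raise ValueError(f"unknown special-value reason {self.reason!r}")

    def __bool__(self) -> bool:  # pragma: no cover - guard against misuse
        raise TypeError("SpecialValue has no truth value; check isinstance instead")

    def __float__(self):
        raise TypeError(f"SpecialValue({self.reason!r}) cannot be coerced to float")


def is_special(x) -> bool:
    return isinstance(x, SpecialValue)
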