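"""Symbolic features: word statistics of tercile-coded increments.

Successive differences of the series are mapped onto a three-letter
alphabet by their empirical terciles (lowest third -> A, middle -> B,
top -> C), so each letter is a priori equally likely; word probabilities
are counted over overlapping windows.
"""

from __future__ import annotations

import numpy as np

from ..values import SpecialValue
from .base import Operation
from .information import _rank_bins

_LETTERS = "ABC"


def symbolize_increments(x: np.ndarray):
    """Tercile-code the increments of x.  Returns the letter string, or
    None for degenerate terciles (a tie straddling a bin boundary, e.g.
    constant increments)."""
    d = np.diff(np.asarray(x, dtype=float))
    idx = _rank_bins(d, 3)
    if idx is None:
        return None
    return "".join(_LETTERS[i] for i in idx)


def symbolic_word_prob(x: np.ndarray, word: str):
    """Probability of ``word`` among overlapping windows of the tercile
    letter string of the series increments."""
    x = np.asarray(x, dtype=float)
    if x.size < 20:
        return SpecialValue("too_short")
    if any(c not in _LETTERS for c in word) or not word:
        raise ValueError(f"word must be a non-empty string over {_LETTERS}")
    s = symbolize_increments(x)
    if s is None:
        return SpecialValue("inapplicable", "degenerate terciles")
    nwin = len(s) - len(word) + 1
    if nwin < 1:
        return SpecialValue("too_short")
    count = sum(1 for i in range(nwin) if s[i:i + len(word)] == word)
    return float(count / nwin)


def make_operations():
    return [
        Operation(f"word_{a}{b}", f"P(word '{a}{b}') of tercile increments",
                  "symbolic",
                  lambda x, w=a + b: symbolic_word_prob(x, w),
                  {"word": a + b})
        for a in _LETTERS
        for b in _LETTERS
    ]
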