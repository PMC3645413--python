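"""Sliding-window stationarity measures.

StatAv(w) is the sd of non-overlapping window means divided by the overall
sd: near 1/sqrt(w) for iid data and larger for drifting series.  The
companion measures compare window sds and the range of window means.
"""

from __future__ import annotations

import numpy as np

from ..values import SpecialValue
from .base import Operation


def _windows(x: np.ndarray, w: int):
    nw = x.size // w
    return x[: nw * w].reshape(nw, w)


def statav(x: np.ndarray, w: int):
    """sd of non-overlapping window means over sd of the series."""
    x = np.asarray(x, dtype=float)
    if x.size < 2 * w:
        return SpecialValue("too_short")
    if np.ptp(x) == 0:
        return SpecialValue("constant_input")
    sd = x.std(ddof=1)
    means = _windows(x, w).mean(axis=1)
    return float(means.std(ddof=1) / sd)


def sliding_sd_ratio(x: np.ndarray, w: int = 100):
    """Max over min of non-overlapping window sds (local volatility spread)."""
    x = np.asarray(x, dtype=float)
    if x.size < 2 * w:
        return SpecialValue("too_short")
    wins = _windows(x, w)
    if np.any(np.ptp(wins, axis=1) == 0):
        return SpecialValue("inapplicable", "constant window")
    sds = wins.std(axis=1, ddof=1)
    if np.min(sds) == 0:
        return SpecialValue("inapplicable", "constant window")
    return float(np.max(sds) / np.min(sds))


def sliding_mean_range(x: np.ndarray, w: int = 100):
    """Range of non-overlapping window means, in units of the series sd."""
    x = np.asarray(x, dtype=float)
    if x.size < 2 * w:
        return SpecialValue("too_short")
    if np.ptp(x) == 0:
        return SpecialValue("constant_input")
    sd = x.std(ddof=1)
    means = _windows(x, w).mean(axis=1)
    return float((np.max(means) - np.min(means)) / sd)


def make_operations():
    ops = [
        Operation(f"statav_{w}", f"StatAv, window {w}", "stationarity",
                  lambda x, w=w: statav(x, w), {"w": w})
        for w in (25, 50, 100)
    ]
    ops.append(Operation("sliding_sd_ratio_100", "window sd max/min ratio",
                         "stationarity", sliding_sd_ratio, {"w": 100}))
    ops.append(Operation("sliding_mean_range_100",
                         "window mean range over sd", "stationarity",
                         sliding_mean_range, {"w": 100}))
    return ops
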