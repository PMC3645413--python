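"""Self-affine scaling estimators: detrended fluctuation analysis and a
discrete-wavelet-transform energy slope.

For a series with power-law spectrum S(f) ~ f^-alpha the DFA exponent of
the series is (alpha + 1) / 2: white noise gives 0.5, a Brownian path 1.5.
"""

from __future__ import annotations

import numpy as np
import pywt

from ..values import SpecialValue
from .base import Operation


def dfa_profile(x: np.ndarray, n_scales: int = 20):
    """DFA fluctuation function.  Returns (scales, F) where F(n) is the rms
    residual of least-squares linear detrends over non-overlapping windows
    of size n, applied to the cumulative profile of the mean-removed series.
    Window sizes are log-spaced from 10 to N/4.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    y = np.cumsum(x - x.mean())
    sizes = np.unique(
        np.round(np.exp(np.linspace(np.log(10), np.log(n // 4), n_scales)))
    ).astype(int)
    t_full = np.arange(n, dtype=float)
    fs = []
    for w in sizes:
        nw = n // w
        seg = y[: nw * w].reshape(nw, w)
        t = t_full[:w]
        tc = t - t.mean()
        denom = float(np.dot(tc, tc))
        slope = seg @ tc / denom
        resid = seg - seg.mean(axis=1, keepdims=True) - slope[:, None] * tc
        fs.append(np.sqrt(np.mean(resid**2)))
    return sizes, np.array(fs)


def dfa_exponent(x: np.ndarray):
    """Slope of ln F(n) vs ln n (the DFA scaling exponent)."""
    x = np.asarray(x, dtype=float)
    if x.size < 200:
        return SpecialValue("too_short")
    if np.ptp(x) == 0:
        return SpecialValue("constant_input")
    sizes, fs = dfa_profile(x)
    good = fs > 0
    if good.sum() < 5:
        return SpecialValue("inapplicable", "degenerate fluctuation function")
    return float(np.polyfit(np.log(sizes[good]), np.log(fs[good]), 1)[0])


def wavelet_scaling(x: np.ndarray, wavelet: str = "db4", levels: int = 4):
    """Slope of log2 mean detail-coefficient energy across the levels of a
    discrete wavelet transform; a wavelet-domain alternative to DFA."""
    x = np.array(x, dtype=float)  # pywt needs a writable buffer
    if x.size < 2 ** (levels + 2):
        return SpecialValue("too_short")
    if np.ptp(x) == 0:
        return SpecialValue("constant_input")
    coeffs = pywt.wavedec(x, wavelet, level=levels)
    # coeffs[1:] are details from coarsest (level `levels`) to finest (1)
    energies = [np.mean(c**2) for c in coeffs[1:]]
    lev = np.arange(levels, 0, -1, dtype=float)
    e = np.array(energies)
    if np.any(e <= 0):
        return SpecialValue("inapplicable", "zero detail energy")
    return float(np.polyfit(lev, np.log2(e), 1)[0])


def make_operations():
    return [
        Operation("dfa_exponent", "DFA scaling exponent", "scaling",
                  dfa_exponent),
        Operation("wavelet_scaling", "wavelet detail-energy slope (db4)",
                  "scaling", wavelet_scaling,
                  {"wavelet": "db4", "levels": 4}),
    ]
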