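"""Linear autocorrelation features.

The sample autocorrelation uses the biased (1/N) normalization, which keeps
|rho| <= 1 and the autocorrelation function positive semi-definite.
"""

from __future__ import annotations

import numpy as np

from ..values import SpecialValue
from .base import Operation


def autocorr(x: np.ndarray, lag: int):
    """Biased-normalization sample autocorrelation at a single lag:
    sum (x_t - xbar)(x_{t+lag} - xbar) / sum (x_t - xbar)^2."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if not 0 <= lag < n:
        return SpecialValue("too_short", f"need N > lag = {lag}")
    if np.ptp(x) == 0:
        return SpecialValue("constant_input")
    xc = x - x.mean()
    denom = float(np.dot(xc, xc))
    if denom == 0:
        return SpecialValue("constant_input")
    if lag == 0:
        return 1.0
    return float(np.dot(xc[:-lag], xc[lag:]) / denom)


def acf_fft(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Full autocorrelation function up to max_lag via FFT (same biased
    normalization as :func:`autocorr`)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    xc = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n - 1)))
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conj(f), nfft)[: max_lag + 1]
    return acov / acov[0]


def first_zero_ac(x: np.ndarray):
    """First lag at which the autocorrelation falls to or below zero."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 3:
        return SpecialValue("too_short")
    if np.ptp(x) == 0:
        return SpecialValue("constant_input")
    rho = acf_fft(x, n // 2)
    hits = np.nonzero(rho[1:] <= 0)[0]
    if hits.size == 0:
        return SpecialValue("inapplicable", "no zero crossing within N/2")
    return float(hits[0] + 1)


def ac_decay_time(x: np.ndarray):
    """First lag at which the autocorrelation drops below 1/e."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 3:
        return SpecialValue("too_short")
    if np.ptp(x) == 0:
        return SpecialValue("constant_input")
    rho = acf_fft(x, n // 2)
    hits = np.nonzero(rho[1:] < 1 / np.e)[0]
    if hits.size == 0:
        return SpecialValue("inapplicable", "no 1/e crossing within N/2")
    return float(hits[0] + 1)


def make_operations():
    ops = [
        Operation(f"ac_{lag}", f"autocorrelation, lag {lag}", "correlation",
                  lambda x, lag=lag: autocorr(x, lag), {"lag": lag})
        for lag in range(1, 41)
    ]
    ops.append(Operation("first_zero_ac", "first zero-crossing lag of ACF",
                         "correlation", first_zero_ac))
    ops.append(Operation("ac_decay_time", "ACF 1/e decay time",
                         "correlation", ac_decay_time))
    return ops
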