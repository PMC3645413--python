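"""Power-spectrum features: centroid, peak, band powers, log-log slope.

All operations work on the raw periodogram of the mean-removed series with
the DC term excluded, which makes them invariant to positive affine
transforms of the input.
"""

from __future__ import annotations

import numpy as np

from ..values import SpecialValue
from .base import Operation


def periodogram(x: np.ndarray):
    """One-sided periodogram (DC excluded).  Returns (freqs, power) with
    frequencies in cycles per sample, f_k = k/N for k = 1..N//2."""
    x = np.asarray(x, dtype=float)
    n = x.size
    xc = x - x.mean()
    p = np.abs(np.fft.rfft(xc)) ** 2 / n
    f = np.arange(p.size) / n
    return f[1:], p[1:]


def _checked(x, min_n=16):
    x = np.asarray(x, dtype=float)
    if x.size < min_n:
        return None, SpecialValue("too_short")
    if np.ptp(x) == 0:
        return None, SpecialValue("constant_input")
    return x, None


def spectral_centroid(x):
    x, err = _checked(x)
    if err:
        return err
    f, p = periodogram(x)
    return float(np.sum(f * p) / np.sum(p))


def peak_frequency(x):
    """Frequency of the largest periodogram ordinate (ties: lowest)."""
    x, err = _checked(x)
    if err:
        return err
    f, p = periodogram(x)
    return float(f[int(np.argmax(p))])


def band_power_fraction(x, band: str):
    """Fraction of total (non-DC) power in the lowest or highest quarter of
    the frequency axis."""
    x, err = _checked(x)
    if err:
        return err
    f, p = periodogram(x)
    nyq = f[-1]
    sel = f < nyq / 4 if band == "low" else f >= 3 * nyq / 4
    return float(np.sum(p[sel]) / np.sum(p))


def spectral_slope(x):
    """Least-squares slope of log S(f) vs log f over the central frequency
    decade (DC and the top 10% of frequencies excluded): an estimate of
    -alpha for a power-law spectrum S(f) ~ f^-alpha.

    The log-periodogram ordinates are S(f) times iid noise, so the additive
    log-noise offset is constant across frequencies and the slope estimate
    is unbiased without smoothing.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 256:
        return SpecialValue("too_short")
    if np.ptp(x) == 0:
        return SpecialValue("constant_input")
    f, p = periodogram(x)
    keep = int(0.9 * f.size)
    f, p = f[:keep], p[:keep]
    pos = p > 0
    f, p = f[pos], p[pos]
    lo, hi = np.log(f[0]), np.log(f[-1])
    centre = 0.5 * (lo + hi)
    half = 0.5 * np.log(10)
    sel = (np.log(f) >= centre - half) & (np.log(f) <= centre + half)
    if sel.sum() < 10:
        return SpecialValue("inapplicable", "too few frequencies in decade")
    slope = np.polyfit(np.log(f[sel]), np.log(p[sel]), 1)[0]
    return float(slope)


def make_operations():
    return [
        Operation("spectral_centroid", "spectral centroid", "spectral",
                  spectral_centroid),
        Operation("peak_frequency", "peak frequency", "spectral",
                  peak_frequency),
        Operation("power_low_frac", "power fraction, lowest quarter band",
                  "spectral", lambda x: band_power_fraction(x, "low"),
                  {"band": "low"}),
        Operation("power_high_frac", "power fraction, highest quarter band",
                  "spectral", lambda x: band_power_fraction(x, "high"),
                  {"band": "high"}),
        Operation("spectral_slope", "log-log spectral slope", "spectral",
                  spectral_slope),
    ]
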