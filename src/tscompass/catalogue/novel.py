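"""Operations probing time-series structure through perturbation and
simulation: the outlier-adjusted autocorrelation ratio and summaries of an
inertial particle attracted to the signal.

The inertial particle is a damped unit mass pulled toward the series by a
linear spring: v_{t+1} = gamma v_t + kappa (x_t - p_t),
p_{t+1} = p_t + v_{t+1}, started at p_0 = x_0 with v_0 = 0.  How well the
particle tracks the signal (residual spread, residual autocorrelation,
typical speed) summarizes the smoothness and predictability of the input.
"""

from __future__ import annotations

import math

import numpy as np

from ..values import SpecialValue
from .base import Operation
from .correlation import autocorr


def outlier_adjusted_ac3(x: np.ndarray, frac: float = 0.10):
    """Ratio of the lag-3 autocorrelation before and after removing the
    ceil(frac * N) points furthest from the mean (survivors concatenated in
    time order)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 20:
        return SpecialValue("too_short")
    num = autocorr(x, 3)
    if isinstance(num, SpecialValue):
        return num
    k = math.ceil(frac * n)
    dev = np.abs(x - x.mean())
    # stable argsort: ties removed by latest time index, deterministically
    drop = np.argsort(dev, kind="stable")[n - k:]
    keep = np.ones(n, dtype=bool)
    keep[drop] = False
    den = autocorr(x[keep], 3)
    if isinstance(den, SpecialValue) or abs(den) < 1e-10:
        return SpecialValue("inapplicable", "denominator undefined or ~0")
    return float(num / den)


def inertial_particle(x: np.ndarray, stiffness: float = 0.1,
                      damping: float = 0.9):
    """Simulate the particle.  Returns (positions, velocities)."""
    if not (0 < damping < 1) or stiffness <= 0:
        raise ValueError("require 0 < damping < 1 and stiffness > 0")
    x = np.asarray(x, dtype=float)
    n = x.size
    p = np.empty(n)
    v = np.empty(n)
    pt, vt = x[0], 0.0
    for t in range(n):
        p[t] = pt
        v[t] = vt
        vt = damping * vt + stiffness * (x[t] - pt)
        pt = pt + vt
    return p, v


def inertial_particle_stat(x: np.ndarray, stiffness: float = 0.1,
                           damping: float = 0.9, which: str = "resid_sd"):
    """One summary of the particle simulation after an N/10 burn-in:
    ``resid_sd`` (sd of x_t - p_t), ``resid_ac1`` (lag-1 autocorrelation of
    the residuals) or ``mean_abs_v`` (mean particle speed)."""
    x = np.asarray(x, dtype=float)
    if x.size < 20:
        return SpecialValue("too_short")
    p, v = inertial_particle(x, stiffness, damping)
    burn = x.size // 10
    resid = x[burn:] - p[burn:]
    if which == "resid_sd":
        return float(resid.std(ddof=1))
    if which == "resid_ac1":
        return autocorr(resid, 1)
    if which == "mean_abs_v":
        return float(np.mean(np.abs(v[burn:])))
    raise ValueError(f"unknown summary {which!r}")


def make_operations():
    ops = [
        Operation("outlier_adjusted_ac3",
                  "lag-3 AC ratio before/after 10% outlier removal",
                  "novel", outlier_adjusted_ac3, {"frac": 0.10}),
    ]
    sensitive = {"resid_sd": True, "resid_ac1": False, "mean_abs_v": True}
    for which, sens in sensitive.items():
        ops.append(
            Operation(f"inertial_{which}", f"inertial particle {which}",
                      "novel",
                      lambda x, w=which: inertial_particle_stat(x, which=w),
                      {"stiffness": 0.1, "damping": 0.9, "which": which},
                      scale_sensitive=sens)
        )
    return ops
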