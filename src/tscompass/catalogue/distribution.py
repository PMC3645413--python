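"""Distribution-of-values features: location, spread, shape, outliers.

Location and spread operations see the raw series (they are deliberately
scale-sensitive); shape and outlier-fraction measures are affine-invariant.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from ..values import SpecialValue
from .base import Operation


def _require_spread(func):
    def wrapped(x):
        x = np.asarray(x, dtype=float)
        if x.size < 3:
            return SpecialValue("too_short")
        if np.ptp(x) == 0:
            return SpecialValue("constant_input")
        return func(x)

    return wrapped


@_require_spread
def ks_normfit(x):
    """Kolmogorov-Smirnov distance between the empirical distribution and a
    normal fitted by sample mean and sd: a simple Gaussianity statistic."""
    return float(stats.kstest(x, "norm", args=(x.mean(), x.std(ddof=1))).statistic)


def outlier_fraction(x, k: float):
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        return SpecialValue("too_short")
    if np.ptp(x) == 0:
        return SpecialValue("constant_input")
    sd = x.std(ddof=1)
    return float(np.mean(np.abs(x - x.mean()) > k * sd))


def make_operations():
    ops = [
        Operation("mean", "mean", "distribution",
                  lambda x: float(np.mean(x)), scale_sensitive=True),
        Operation("median", "median", "distribution",
                  lambda x: float(np.median(x)), scale_sensitive=True),
        Operation("sd", "sample standard deviation", "distribution",
                  lambda x: float(np.std(x, ddof=1)) if x.size > 1
                  else SpecialValue("too_short"),
                  scale_sensitive=True),
        Operation("iqr", "interquartile range", "distribution",
                  lambda x: float(stats.iqr(x)), scale_sensitive=True),
        Operation("skewness", "skewness", "distribution",
                  _require_spread(lambda x: float(stats.skew(x)))),
        Operation("kurtosis", "excess kurtosis", "distribution",
                  _require_spread(lambda x: float(stats.kurtosis(x)))),
        Operation("ks_normfit", "KS distance to fitted normal",
                  "distribution", ks_normfit),
    ]
    for k in (2, 3, 5):
        ops.append(
            Operation(f"outlier_frac_{k}", f"fraction beyond {k} sd",
                      "distribution",
                      lambda x, k=k: outlier_fraction(x, k), {"k": k})
        )
    return ops
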