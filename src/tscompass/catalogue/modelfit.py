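"""Simple model-based features: AR(3) fit, variance-ratio statistic, local
mean forecaster residuals, Gaussian-process length scale on segments.
"""

from __future__ import annotations

import numpy as np

from ..values import SpecialValue
from .base import Operation
from .correlation import autocorr


def _ar3_fit(x: np.ndarray):
    """OLS fit of an AR(3) model to the z-scored series.  Returns
    (coefficients, residual variance) or a SpecialValue."""
    x = np.asarray(x, dtype=float)
    if x.size < 50:
        return SpecialValue("too_short")
    if np.ptp(x) == 0:
        return SpecialValue("constant_input")
    z = (x - x.mean()) / x.std(ddof=1)
    y = z[3:]
    design = np.column_stack([z[2:-1], z[1:-2], z[:-3]])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return coef, float(resid.var(ddof=3))


def ar3_coeff(x: np.ndarray):
    """Lag-1 coefficient of an AR(3) model fitted by OLS to the z-scored
    series.  Tracks long-range structure surprisingly well: it correlates
    linearly with the scaling exponent of self-affine series."""
    out = _ar3_fit(x)
    if isinstance(out, SpecialValue):
        return out
    return float(out[0][0])


def ar3_resid_var(x: np.ndarray):
    """Residual variance of the AR(3) OLS fit on the z-scored series
    (1 minus the variance explained by three lags)."""
    out = _ar3_fit(x)
    if isinstance(out, SpecialValue):
        return out
    return out[1]


def variance_ratio(x: np.ndarray, q: int = 2, standardized: bool = False):
    """Variance ratio VR(q) = Var(x_t - x_{t-q}) / (q Var(x_t - x_{t-1}))
    with unbiased variance estimates; near 1 for a random walk, 1/q for
    iid levels.  With standardized=True, returns the homoscedastic
    standardized statistic sqrt(n) (VR - 1) / sqrt(2(2q-1)(q-1)/(3q)).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 10 * q:
        return SpecialValue("too_short")
    d1 = np.diff(x)
    if np.ptp(d1) == 0:
        return SpecialValue("constant_input")
    vd = d1.var(ddof=1)
    dq = x[q:] - x[:-q]
    vr = float(dq.var(ddof=1) / (q * vd))
    if not standardized:
        return vr
    n = d1.size
    se = np.sqrt(2 * (2 * q - 1) * (q - 1) / (3 * q * n))
    return float((vr - 1) / se)


def mean_forecaster_resid_ac(x: np.ndarray, w: int = 3):
    """Lag-1 autocorrelation of the residuals of a trailing-window local
    mean forecaster: e_t = x_t - mean(x_{t-w}..x_{t-1})."""
    x = np.asarray(x, dtype=float)
    if x.size < w + 10:
        return SpecialValue("too_short")
    csum = np.concatenate([[0.0], np.cumsum(x)])
    trailing = (csum[w:-1] - csum[:-w - 1]) / w  # mean of x[t-w..t-1], t=w..N-1
    resid = x[w:] - trailing
    if np.ptp(x) == 0 or np.ptp(resid) == 0:
        return SpecialValue("inapplicable", "constant residuals")
    return autocorr(resid, 1)


_GP_EIG_CACHE: dict = {}


def _gp_grid(seg: int, n_ell: int = 30):
    """Cached eigendecompositions of the squared-exponential kernel matrix
    for a log-spaced length-scale grid on [0.1, seg] samples."""
    key = (seg, n_ell)
    if key not in _GP_EIG_CACHE:
        t = np.arange(seg, dtype=float)
        d2 = (t[:, None] - t[None, :]) ** 2
        ells = np.exp(np.linspace(np.log(0.1), np.log(seg), n_ell))
        eigvals, eigvecs = [], []
        for ell in ells:
            k = np.exp(-0.5 * d2 / ell**2)
            w, q = np.linalg.eigh(k)
            eigvals.append(np.clip(w, 0.0, None))
            eigvecs.append(q)
        _GP_EIG_CACHE[key] = (ells, np.array(eigvals), np.array(eigvecs))
    return _GP_EIG_CACHE[key]


def gp_lengthscale(x: np.ndarray, seg: int = 50):
    """Mean log length scale of squared-exponential Gaussian-process fits
    on non-overlapping segments.

    Each segment is z-scored and the exact GP log marginal likelihood is
    maximized over a fixed grid: 30 log-spaced length scales on [0.1, seg]
    and 12 log-spaced noise-to-signal ratios, with the overall signal
    variance profiled analytically.  Grid search keeps the operation a
    deterministic feature rather than a model fit.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4 * seg:
        return SpecialValue("too_short")
    ells, eigvals, eigvecs = _gp_grid(seg)
    etas = np.exp(np.linspace(np.log(1e-3), np.log(1e2), 12))
    logs = []
    nseg = x.size // seg
    for s in range(nseg):
        y = x[s * seg:(s + 1) * seg]
        if np.ptp(y) == 0:
            continue  # constant segment: skipped
        y = (y - y.mean()) / y.std(ddof=1)
        lmls = np.full(ells.size, -np.inf)
        for li in range(ells.size):
            z2 = (eigvecs[li].T @ y) ** 2
            for eta in etas:
                lam = eigvals[li] + eta
                shat = np.sum(z2 / lam) / seg
                lml = -0.5 * seg * np.log(shat) - 0.5 * np.sum(np.log(lam))
                lmls[li] = max(lmls[li], lml)
        # sub-sample length scales give numerically tied likelihoods;
        # prefer the smallest length scale within a rounding tolerance
        pick = int(np.nonzero(lmls >= lmls.max() - 1e-8)[0][0])
        logs.append(np.log(ells[pick]))
    if not logs:
        return SpecialValue("inapplicable", "all segments constant")
    return float(np.mean(logs))


def make_operations():
    ops = [
        Operation("ar3_coeff", "AR(3) lag-1 coefficient", "model_fit",
                  ar3_coeff, {"order": 3}),
        Operation("ar3_resid_var", "AR(3) residual variance", "model_fit",
                  ar3_resid_var, {"order": 3}),
        Operation("variance_ratio_2", "variance ratio VR(2)", "model_fit",
                  lambda x: variance_ratio(x, 2), {"q": 2}),
        Operation("variance_ratio_4", "variance ratio VR(4)", "model_fit",
                  lambda x: variance_ratio(x, 4), {"q": 4}),
        Operation("gp_lengthscale_50",
                  "mean log GP squared-exponential length scale",
                  "model_fit", gp_lengthscale, {"seg": 50}),
    ]
    for w in (3, 5, 10):
        ops.append(
            Operation(f"mf_resid_ac_{w}",
                      f"mean-forecaster residual AC, window {w}",
                      "model_fit",
                      lambda x, w=w: mean_forecaster_resid_ac(x, w),
                      {"w": w})
        )
    return ops
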