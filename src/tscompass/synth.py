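"""Synthetic time-series generators: iterative maps, a stochastic switching
map, Euler-Maruyama SDE paths (including geometric Brownian motion),
coloured noise, noisy periodic signals and self-affine series with a known
spectral exponent alpha.

Every generator is a pure function of its arguments including the seed:
the same call always returns a bit-identical series.  Self-affine series
target a power-law spectrum S(f) ~ f^-alpha; the corresponding
fractional-Brownian-motion Hurst exponent is H = (alpha - 1) / 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import TimeSeries

__all__ = [
    "GenerationError",
    "GeneratorSpec",
    "iterate_map",
    "stochastic_sine_map",
    "sde_euler",
    "fourier_filter",
    "midpoint_displacement",
    "noise_series",
    "generate",
    "GENERATORS",
]


class GenerationError(RuntimeError):
    """Raised when a generator's orbit escapes or parameters are invalid."""


@dataclass(frozen=True)
class GeneratorSpec:
    """A reproducible recipe: generator name, parameters, length, seed."""

    name: str
    params: dict = field(default_factory=dict)
    length: int = 1000
    seed: int = 0
    transient: int = 0
    id: str | None = None
    class_label: str | None = None
    target: float | None = None


_MAPS = {
    # name: (update, invariant interval, default x0)
    "logistic": (lambda a, x: a * x * (1 - x), (0.0, 1.0), 0.3),
    "sine": (lambda a, x: a * math.sin(math.pi * x), (0.0, 1.0), 0.3),
    "cubic": (lambda a, x: a * x * (1 - x * x), (-1.0, 1.0), 0.3),
    "asym_logistic": (lambda a, x: a * x * (1 - x) ** 2, (0.0, 1.0), 0.3),
}


def iterate_map(name: str, A: float, n: int, x0: float | None = None,
                transient: int = 0, seed: int = 0) -> TimeSeries:
    """Iterate a one-dimensional map for ``n`` samples after discarding
    ``transient`` steps.

    Maps: logistic x -> A x (1 - x); sine x -> A sin(pi x);
    cubic x -> A x (1 - x^2); asym_logistic x -> A x (1 - x)^2.
    When x0 is omitted it is drawn (seeded) from the map's interval.
    Orbit escape raises :class:`GenerationError` naming the step.
    """
    if name not in _MAPS:
        raise GenerationError(f"unknown map {name!r}")
    update, (lo, hi), _ = _MAPS[name]
    if x0 is None:
        rng = np.random.default_rng(seed)
        x0 = float(lo + (hi - lo) * (0.25 + 0.5 * rng.random()))
    x = float(x0)
    out = np.empty(n)
    for step in range(transient + n):
        x = update(A, x)
        if not math.isfinite(x) or abs(x) > 1e8:
            raise GenerationError(f"{name} map orbit escaped at step {step}")
        if step >= transient:
            out[step - transient] = x
    return TimeSeries(
        id=f"{name}_A{A:g}_s{seed}", values=out,
        keywords=frozenset({"map", name}),
        source=f"iterate_map({name}, A={A}, x0={x0}, n={n}, transient={transient})",
    )


def stochastic_sine_map(A: float = 2.2, p: float = 0.01, amp: float = 2.0,
                        n: int = 1000, x0: float = 1.0,
                        transient: int = 0, seed: int = 0) -> TimeSeries:
    """x_{t+1} = A sin(x_t) + eta_t with eta ~ Uniform(-amp, amp) applied
    with probability p per step.  At the default A = 2.2 the deterministic
    map has two symmetric attracting sets; sufficiently large noise kicks
    the orbit between their basins, producing noisy switching dynamics."""
    rng = np.random.default_rng(seed)
    x = float(x0)
    out = np.empty(n)
    for step in range(transient + n):
        x = A * math.sin(x)
        if rng.random() < p:
            x += rng.uniform(-amp, amp)
        if step >= transient:
            out[step - transient] = x
    return TimeSeries(
        id=f"ssm_A{A:g}_p{p:g}_s{seed}", values=out,
        keywords=frozenset({"map", "stochastic", "switching"}),
        source=f"stochastic_sine_map(A={A}, p={p}, amp={amp}, n={n})",
    )


def sde_euler(kind: str = "gbm", a: float = 0.05, b: float = 0.2,
              c: float = 0.0, d: float = 0.0, x0: float = 1.0,
              dt: float = 1e-3, n: int = 1000, seed: int = 0) -> TimeSeries:
    """Euler-Maruyama path of an SDE, length n + 1 including x0.

    gbm:    dX = a X dt + b X dW  (geometric Brownian motion)
    affine: dX = (a + c X) dt + (b + d X) dW

    A GBM path started above zero is clipped at a machine-epsilon floor if
    the discretization undershoots; the clip count is recorded in the
    series' provenance string.  A non-finite state raises
    :class:`GenerationError`.
    """
    if kind not in ("gbm", "affine"):
        raise GenerationError(f"unknown SDE kind {kind!r}")
    if dt <= 0:
        raise GenerationError("dt must be positive")
    rng = np.random.default_rng(seed)
    dw = rng.normal(0.0, math.sqrt(dt), size=n)
    out = np.empty(n + 1)
    out[0] = x = float(x0)
    clips = 0
    floor = np.finfo(float).tiny
    for t in range(n):
        if kind == "gbm":
            x = x + a * x * dt + b * x * dw[t]
            if x0 > 0 and x < floor:
                x = floor
                clips += 1
        else:
            x = x + (a + c * x) * dt + (b + d * x) * dw[t]
        if not math.isfinite(x):
            raise GenerationError(f"SDE state non-finite at step {t}")
        out[t + 1] = x
    return TimeSeries(
        id=f"{kind}_a{a:g}_b{b:g}_s{seed}", values=out,
        keywords=frozenset({"sde", kind}),
        source=f"sde_euler({kind}, a={a}, b={b}, c={c}, d={d}, "
               f"x0={x0}, dt={dt}, n={n}, clips={clips})",
    )


def fourier_filter(alpha: float, n: int, seed: int = 0) -> TimeSeries:
    """Self-affine series with spectrum S(f) ~ f^-alpha by Fourier
    filtering: seeded white noise is transformed, each non-DC amplitude is
    scaled by f^{-alpha/2} (DC set to zero), and the inverse transform is
    z-scored."""
    if n < 256:
        raise GenerationError("fourier_filter needs n >= 256")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(n)
    spec = np.fft.rfft(noise)
    f = np.arange(spec.size) / n
    spec[0] = 0.0
    spec[1:] = spec[1:] * f[1:] ** (-alpha / 2)
    x = np.fft.irfft(spec, n)
    x = (x - x.mean()) / x.std(ddof=1)
    return TimeSeries(
        id=f"ff_a{alpha:g}_s{seed}", values=x,
        keywords=frozenset({"selfaffine", "fourier"}),
        target=alpha,
        source=f"fourier_filter(alpha={alpha}, n={n})",
    )


def midpoint_displacement(alpha: float, n: int, seed: int = 0) -> TimeSeries:
    """Approximate fractional-Brownian-motion path with Hurst exponent
    H = (alpha - 1)/2 by classic recursive random midpoint displacement
    (variance scaled by 2^{-2H} per level).  Requires alpha in (1, 3)."""
    if not 1 < alpha < 3:
        raise GenerationError("midpoint displacement needs alpha in (1, 3)")
    h = (alpha - 1) / 2
    levels = max(1, math.ceil(math.log2(max(n - 1, 1))))
    size = 2**levels + 1
    rng = np.random.default_rng(seed)
    x = np.zeros(size)
    x[-1] = rng.standard_normal()
    scale = math.sqrt(1 - 2 ** (2 * h - 2))
    step = size - 1
    for level in range(levels):
        half = step // 2
        idx = np.arange(half, size, step)
        sd = scale * 2 ** (-(level + 1) * h)
        x[idx] = 0.5 * (x[idx - half] + x[idx + half]) + sd * rng.standard_normal(idx.size)
        step = half
    return TimeSeries(
        id=f"mpd_a{alpha:g}_s{seed}", values=x[:n],
        keywords=frozenset({"selfaffine", "midpoint"}),
        target=alpha,
        source=f"midpoint_displacement(alpha={alpha}, n={n})",
    )


def noise_series(kind: str = "white_gaussian", n: int = 1000, seed: int = 0,
                 phi: float = 0.8, sigma: float = 1.0,
                 freq: float = 0.05, amplitude: float = 1.0,
                 noise_sd: float = 0.2) -> TimeSeries:
    """Noise models: iid Gaussian noise, a stationary AR(1) process
    (initialized from its stationary distribution) and a noisy sinusoid
    (amplitude * sin(2 pi freq t) + Gaussian noise)."""
    rng = np.random.default_rng(seed)
    if kind == "white_gaussian":
        x = rng.normal(0.0, sigma, n)
    elif kind == "ar1":
        if not -1 < phi < 1:
            raise GenerationError("AR(1) requires |phi| < 1")
        eps = rng.normal(0.0, sigma, n)
        x = np.empty(n)
        x[0] = rng.normal(0.0, sigma / math.sqrt(1 - phi**2))
        for t in range(1, n):
            x[t] = phi * x[t - 1] + eps[t]
    elif kind == "noisy_sine":
        t = np.arange(n)
        x = amplitude * np.sin(2 * np.pi * freq * t)
        if noise_sd > 0:
            x = x + rng.normal(0.0, noise_sd, n)
        else:  # keep exact periodicity bit-stable
            x = x.copy()
    else:
        raise GenerationError(f"unknown noise kind {kind!r}")
    return TimeSeries(
        id=f"{kind}_s{seed}", values=x,
        keywords=frozenset({"noise", kind}),
        source=f"noise_series({kind}, n={n}, seed={seed})",
    )


GENERATORS = {
    "iterate_map": iterate_map,
    "stochastic_sine_map": stochastic_sine_map,
    "sde_euler": sde_euler,
    "fourier_filter": fourier_filter,
    "midpoint_displacement": midpoint_displacement,
    "noise_series": noise_series,
}


def generate(spec: GeneratorSpec) -> TimeSeries:
    """Run a :class:`GeneratorSpec`, applying id/label/target overrides."""
    if spec.name not in GENERATORS:
        raise GenerationError(f"unknown generator {spec.name!r}")
    func = GENERATORS[spec.name]
    kwargs = dict(spec.params)
    if spec.name in ("iterate_map", "stochastic_sine_map"):
        kwargs.setdefault("transient", spec.transient)
    if spec.name == "sde_euler":
        # sde paths have length n + 1 including x0
        ts = func(n=spec.length - 1, seed=spec.seed, **kwargs)
    else:
        ts = func(n=spec.length, seed=spec.seed, **kwargs)
    from dataclasses import replace

    overrides = {}
    if spec.id is not None:
        overrides["id"] = spec.id
    if spec.class_label is not None:
        overrides["class_label"] = spec.class_label
    if spec.target is not None:
        overrides["target"] = spec.target
    return replace(ts, **overrides) if overrides else ts
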