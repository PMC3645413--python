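"""Canonical synthetic benchmark collections.

These fix the study conditions used throughout the test-suite and the
reproduction script: a two-class discrimination task (white noise vs noisy
sinusoid), a self-affine regression task (spectral exponent recovery), and
a mixed collection of qualitatively different dynamics for redundancy /
reduced-set analysis.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .io import Collection
from . import synth

__all__ = [
    "classification_benchmark",
    "selfaffine_benchmark",
    "mixed_benchmark",
]


def classification_benchmark(n_per_class: int = 50, n: int = 1000,
                             seed: int = 0) -> Collection:
    """White Gaussian noise vs a noisy sinusoid (amplitude 1, frequency
    0.05 cycles/sample, noise sd 0.5), ``n_per_class`` series each."""
    members = []
    for i in range(n_per_class):
        ts = synth.noise_series("white_gaussian", n=n, seed=seed + i)
        members.append(replace(ts, id=f"noise_{i}", class_label="noise"))
        ts = synth.noise_series("noisy_sine", n=n, seed=seed + 10000 + i,
                                freq=0.05, amplitude=1.0, noise_sd=0.5)
        members.append(replace(ts, id=f"sine_{i}", class_label="sine"))
    return Collection(members)


def selfaffine_benchmark(n_series: int = 40, n: int = 5000,
                         seed: int = 0) -> Collection:
    """Fourier-filtered self-affine series with scaling exponents alpha
    drawn uniformly on [-1, 3]; the true alpha is attached as the
    regression target."""
    rng = np.random.default_rng(seed)
    alphas = rng.uniform(-1.0, 3.0, n_series)
    members = [
        replace(synth.fourier_filter(float(a), n, seed=seed + 100 + i),
                id=f"sa_{i}")
        for i, a in enumerate(alphas)
    ]
    return Collection(members)


def mixed_benchmark(per_kind: int = 8, n: int = 1000,
                    seed: int = 0) -> Collection:
    """A diverse collection spanning qualitatively different dynamics:
    white noise, AR(1), noisy sinusoids, chaotic logistic-map orbits,
    geometric Brownian motion and self-affine series."""
    members = []
    for i in range(per_kind):
        members.append(replace(
            synth.noise_series("white_gaussian", n=n, seed=seed + i),
            id=f"wn_{i}", class_label="noise"))
        members.append(replace(
            synth.noise_series("ar1", n=n, seed=seed + 100 + i, phi=0.8),
            id=f"ar1_{i}", class_label="ar1"))
        members.append(replace(
            synth.noise_series("noisy_sine", n=n, seed=seed + 200 + i,
                               freq=0.02 + 0.01 * i, noise_sd=0.3),
            id=f"ns_{i}", class_label="sine"))
        members.append(replace(
            synth.iterate_map("logistic", 3.6 + 0.05 * i, n,
                              transient=100, seed=seed + 300 + i),
            id=f"log_{i}", class_label="map"))
        members.append(replace(
            synth.sde_euler("gbm", a=0.05, b=0.2, dt=1e-3, n=n - 1,
                            seed=seed + 400 + i),
            id=f"gbm_{i}", class_label="sde"))
        members.append(replace(
            synth.fourier_filter(0.5 + 0.25 * i, n, seed=seed + 500 + i),
            id=f"sa_{i}", class_label="selfaffine", target=None))
    return Collection(members)
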