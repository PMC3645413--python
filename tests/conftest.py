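"""Shared fixtures: the default registry and the synthetic benchmark
matrices (computed once per session; all inputs are generated in-process)."""

import numpy as np
import pytest

import tscompass as tc
from tscompass.benchmarks import (
    classification_benchmark,
    mixed_benchmark,
    selfaffine_benchmark,
)


@pytest.fixture(scope="session")
def registry():
    return tc.default_registry()


def _prepared(collection, registry):
    m = tc.compute_matrix(collection, list(registry))
    m, _ = tc.filter_special(m)
    return tc.robust_sigmoid_normalize(m)


@pytest.fixture(scope="session")
def cls_matrix(registry):
    """Feature matrix of the two-class benchmark: 50 white-noise vs 50
    noisy-sine series of 1000 samples."""
    return _prepared(classification_benchmark(seed=0), registry)


@pytest.fixture(scope="session")
def sa_matrix(registry):
    """Feature matrix of the self-affine regression benchmark: 40
    Fourier-filtered series (5000 samples, alpha uniform on [-1, 3])."""
    return _prepared(selfaffine_benchmark(seed=0), registry)


@pytest.fixture(scope="session")
def mixed_matrix(registry):
    """Feature matrix of the mixed-dynamics benchmark (48 series spanning
    noise, AR(1), sinusoids, chaotic maps, SDE paths, self-affine)."""
    return _prepared(mixed_benchmark(seed=0), registry)


def make_matrix(X, mask=None, col_ids=None, row_ids=None, **kw):
    """Small helper to wrap a plain array as a DataMatrix."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if mask is None:
        mask = np.zeros((n, p), dtype=bool)
    return tc.DataMatrix(
        raw=X,
        mask=np.asarray(mask, dtype=bool),
        reasons=np.where(mask, "error", "").astype(object),
        row_ids=row_ids or [f"r{i}" for i in range(n)],
        col_ids=col_ids or [f"c{j}" for j in range(p)],
        **kw,
    )


@pytest.fixture
def matrix_factory():
    return make_matrix
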