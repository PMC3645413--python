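"""Information-theoretic and entropy features.

Approximate entropy ApEn(m, r) and sample entropy SampEn(m, r) follow the
standard template-matching definitions: templates are m-length delay
vectors, matches are counted under the Chebyshev (max-coordinate) distance
at tolerance r times the sample standard deviation.  ApEn includes
self-matches; SampEn excludes them.  Lempel-Ziv complexity counts LZ76
phrases of the median-binarized sequence.  Auto-mutual information uses a
plug-in estimate with equiprobable (rank) binning.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from ..values import SpecialValue
from .base import Operation

__all__ = [
    "apen",
    "sampen",
    "lempel_ziv",
    "auto_mutual_info",
    "pnn_x",
    "make_operations",
]


def _embed(x: np.ndarray, m: int) -> np.ndarray:
    """Delay-embedding matrix: rows x[i:i+m], i = 0..N-m."""
    n = x.size - m + 1
    return np.lib.stride_tricks.sliding_window_view(x, m)[:n]


def apen(x: np.ndarray, m: int = 2, r: float = 0.2):
    """Approximate entropy ApEn(m, r), r as a fraction of the sample sd.

    ApEn = Phi^m - Phi^{m+1} with Phi^m the mean log fraction of templates
    within Chebyshev tolerance (self-matches included).
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < m + 2:
        return SpecialValue("too_short")
    if np.ptp(x) == 0:
        return SpecialValue("constant_input")
    tol = r * x.std(ddof=1)

    def phi(mm: int) -> float:
        templ = _embed(x, mm)
        tree = cKDTree(templ)
        counts = tree.query_ball_point(templ, tol, p=np.inf, return_length=True)
        return float(np.mean(np.log(counts / templ.shape[0])))

    return phi(m) - phi(m + 1)


def sampen(x: np.ndarray, m: int = 2, r: float = 0.2):
    """Sample entropy SampEn(m, r) = -ln(A/B), self-matches excluded.

    B counts m-template pairs within tolerance, A counts (m+1)-template
    pairs; both use the N-m templates that have an (m+1)-length extension,
    the standard convention.  A = 0 or B = 0 is signalled as inapplicable
    (the statistic is undefined), a constant series as constant_input.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < m + 2:
        return SpecialValue("too_short")
    if np.ptp(x) == 0:
        return SpecialValue("constant_input")
    tol = r * x.std(ddof=1)

    def pairs(mm: int) -> int:
        templ = _embed(x, mm)[: n - m]  # same template count at both lengths
        tree = cKDTree(templ)
        total = tree.count_neighbors(tree, tol, p=np.inf)
        return int(total - templ.shape[0]) // 2

    b = pairs(m)
    a = pairs(m + 1)
    if a == 0 or b == 0:
        return SpecialValue("inapplicable", "no template matches")
    return float(-np.log(a / b))


def _lz76_phrases(bits: np.ndarray) -> int:
    """LZ76 exhaustive-history phrase count of a 0/1 sequence.

    Each phrase is the longest prefix of the remaining sequence that occurs
    in the part of the string seen so far, extended by one symbol.
    """
    s = bytes(bits.astype(np.uint8))
    n = len(s)
    phrases = 0
    i = 0
    while i < n:
        ell = 1
        # grow while the candidate (minus its final, novel symbol) is
        # reproducible from the history
        while i + ell <= n and s[i : i + ell] in s[: i + ell - 1]:
            ell += 1
        phrases += 1
        i += ell
    return phrases


def lempel_ziv(x: np.ndarray):
    """Normalized LZ76 complexity of the median-binarized series:
    phrase count divided by N / log2(N) (which tends to 1 for an
    incompressible binary sequence)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        return SpecialValue("too_short")
    bits = (x > np.median(x)).astype(np.uint8)
    c = _lz76_phrases(bits)
    return float(c * np.log2(n) / n)


def _rank_bins(v: np.ndarray, bins: int):
    """Equiprobable binning by rank.  Returns bin indices, or None when a
    tie straddles a bin boundary (degenerate binning)."""
    n = v.size
    order = np.argsort(v, kind="stable")
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(n)
    idx = ranks * bins // n
    s = v[order]
    for b in range(1, bins):
        cut = b * n // bins
        if cut >= 1 and s[cut - 1] == s[cut]:
            return None
    return idx


def auto_mutual_info(x: np.ndarray, lag: int = 1, bins: int = 10):
    """Plug-in auto-mutual information (nats) between x_t and x_{t+lag}
    with equiprobable binning of each margin.  lag 0 returns the marginal
    entropy of the binned variable (ln(bins) for an exactly even split)."""
    x = np.asarray(x, dtype=float)
    n = x.size - lag
    if n < 4 * bins:
        return SpecialValue("too_short")
    u = x[: x.size - lag] if lag > 0 else x
    v = x[lag:] if lag > 0 else x
    bu = _rank_bins(u, bins)
    bv = _rank_bins(v, bins)
    if bu is None or bv is None:
        return SpecialValue("inapplicable", "degenerate binning")
    if lag == 0:
        p = np.bincount(bu, minlength=bins) / n
        p = p[p > 0]
        return float(-np.sum(p * np.log(p)))
    joint = np.bincount(bu * bins + bv, minlength=bins * bins).reshape(bins, bins)
    pij = joint / n
    pi = pij.sum(axis=1, keepdims=True)
    pj = pij.sum(axis=0, keepdims=True)
    nz = pij > 0
    return float(np.sum(pij[nz] * np.log(pij[nz] / (pi @ pj)[nz])))


def pnn_x(x: np.ndarray, threshold: float = 50.0):
    """pNNx: fraction of successive differences exceeding ``threshold`` in
    absolute value.  For interbeat (RR) interval series in milliseconds this
    is the classic heart-rate-variability statistic."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        return SpecialValue("too_short")
    d = np.abs(np.diff(x))
    return float(np.mean(d > threshold))


def make_operations():
    ops = [
        Operation("apen_2_0.2", "ApEn(2,0.2)", "information",
                  lambda x: apen(x, 2, 0.2), {"m": 2, "r": 0.2}),
        Operation("sampen_2_0.2", "SampEn(2,0.2)", "information",
                  lambda x: sampen(x, 2, 0.2), {"m": 2, "r": 0.2}),
        Operation("sampen_3_0.05", "SampEn(3,0.05)", "information",
                  lambda x: sampen(x, 3, 0.05), {"m": 3, "r": 0.05}),
        Operation("lempel_ziv", "normalized Lempel-Ziv complexity",
                  "information", lempel_ziv),
    ]
    for lag in range(1, 6):
        ops.append(
            Operation(f"ami_{lag}", f"auto-mutual information, lag {lag}",
                      "information",
                      lambda x, lag=lag: auto_mutual_info(x, lag, 10),
                      {"lag": lag, "bins": 10})
        )
    for thr in (20.0, 50.0):
        ops.append(
            Operation(f"pnn_{int(thr)}", f"pNN{int(thr)}", "information",
                      lambda x, thr=thr: pnn_x(x, thr),
                      {"threshold_ms": thr}, scale_sensitive=True)
        )
    return ops
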