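"""Unsupervised organization of series and operations by empirical
behaviour: mask-aware distances, PAM k-medoids, complete-linkage
clustering, reduced operation sets scored by residual variance, nearest-
neighbour networks and PCA projection.

Time series are compared by Euclidean distance between their normalized
feature vectors (rescaled for shared unmasked coverage); operations are
compared by 1 - |r| (linear) or 1 - NMI (nonlinear) over their outputs
across a dataset.  A reduced operation set keeps the k-medoids
representatives; its quality is the residual variance 1 - R^2, where R
correlates the pairwise series distances in the reduced space with those
in the full space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr
from sklearn.base import BaseEstimator, ClusterMixin

from .matrix import DataMatrix
from .values import SpecialValue

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "Clustering",
    "ReducedSet",
    "ts_distance",
    "op_distance_corr",
    "op_distance_nmi",
    "KMedoids",
    "kmedoids",
    "linkage_cluster",
    "residual_variance",
    "build_reduced_set",
    "neighbour_network",
    "pca_project",
]


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with ids.  NaN marks pairs for which
    the metric was undefined (insufficient shared coverage)."""

    values: np.ndarray
    ids: list
    metric: str
    unreliable: np.ndarray | None = None  # pairs with < 50% shared columns
    signed_r: np.ndarray | None = None  # for correlation metric display

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(self.ids) != v.shape[0]:
            raise ValueError("ids do not match matrix size")
        finite = np.isfinite(v)
        both = finite & finite.T
        if not np.allclose(v[both], v.T[both], atol=1e-12):
            raise ValueError("distance matrix not symmetric")
        v = np.where(both, (v + v.T) / 2, v)  # exact symmetry
        if np.any(np.diagonal(v) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(v[finite] < 0):
            raise ValueError("distances must be non-negative")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        if np.any(~np.isfinite(self.values)):
            raise ValueError("matrix contains undefined pairs")
        return squareform(self.values, checks=False)

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(path)


@dataclass
class Clustering:
    assignment: dict
    method: str
    k: int
    medoids: list | None = None

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "method": self.method,
                "k": self.k,
                "medoids": self.medoids,
                "assignment": self.assignment,
            },
            indent=1,
            sort_keys=True,
        )


@dataclass
class ReducedSet:
    member_ids: list
    residual_variance: float
    k: int

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "k": self.k,
                "member_ids": self.member_ids,
                "residual_variance": self.residual_variance,
            },
            indent=1,
            sort_keys=True,
        )


# -- distances ---------------------------------------------------------


def ts_distance(m: DataMatrix) -> DistanceMatrix:
    """Mask-aware Euclidean distance between normalized series rows:
    d(i,j) = sqrt((P / |S|) sum_{c in S} (a_c - b_c)^2) over the columns S
    unmasked in both rows, rescaled by the total column count P so that
    pairs with different coverage remain comparable.  Pairs sharing fewer
    than half the columns are flagged unreliable (distance still given)."""
    if m.normalized is None:
        raise ValueError("ts_distance needs the normalized view")
    X = np.where(m.mask, np.nan, m.normalized)
    n, p = X.shape
    d = np.zeros((n, n))
    unreliable = np.zeros((n, n), dtype=bool)
    for i in range(n):
        diff = X[i] - X[i:]
        shared = ~np.isnan(diff)
        cnt = shared.sum(axis=1)
        ss = np.nansum(diff**2, axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.sqrt(p * ss / cnt)
        vals[cnt == 0] = np.nan
        d[i, i:] = d[i:, i] = vals
        flag = cnt < 0.5 * p
        unreliable[i, i:] = unreliable[i:, i] = flag
        d[i, i] = 0.0
    if unreliable.any():
        logger.info("ts_distance: %d unreliable pairs", int(unreliable.sum()) // 2)
    return DistanceMatrix(d, list(m.row_ids), "euclidean_masked",
                          unreliable=unreliable)


def op_distance_corr(m: DataMatrix, min_shared: int = 5) -> DistanceMatrix:
    """Correlation distance between operation columns: d = 1 - |r| over
    shared unmasked rows of the normalized outputs (sign-blind, since
    redundancy cares about predictability, not direction).  The signed r
    matrix is kept for display.  Pairs with fewer than ``min_shared``
    shared rows or zero variance are undefined (NaN)."""
    if m.normalized is None:
        raise ValueError("op_distance_corr needs the normalized view")
    X = np.where(m.mask, np.nan, m.normalized)
    p = X.shape[1]
    r = np.full((p, p), np.nan)
    for a in range(p):
        r[a, a] = 1.0
        for b in range(a + 1, p):
            ok = ~np.isnan(X[:, a]) & ~np.isnan(X[:, b])
            if ok.sum() < min_shared:
                continue
            u, v = X[ok, a], X[ok, b]
            if u.std() == 0 or v.std() == 0:
                continue
            r[a, b] = r[b, a] = np.corrcoef(u, v)[0, 1]
    d = 1.0 - np.abs(r)
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, None)
    return DistanceMatrix(d, list(m.col_ids), "one_minus_abs_corr",
                          signed_r=r)


def _nmi(u: np.ndarray, v: np.ndarray, bins: int):
    from .catalogue.information import _rank_bins

    bu = _rank_bins(u, bins)
    bv = _rank_bins(v, bins)
    if bu is None or bv is None:
        return None
    n = u.size
    joint = np.bincount(bu * bins + bv, minlength=bins * bins).reshape(bins, bins)
    pij = joint / n
    pi = pij.sum(axis=1)
    pj = pij.sum(axis=0)
    nz = pij > 0
    mi = float(np.sum(pij[nz] * np.log(pij[nz] / np.outer(pi, pj)[nz])))
    hu = -np.sum(pi[pi > 0] * np.log(pi[pi > 0]))
    hv = -np.sum(pj[pj > 0] * np.log(pj[pj > 0]))
    if hu <= 0 or hv <= 0:
        return None
    return mi / np.sqrt(hu * hv)


def op_distance_nmi(m: DataMatrix, bins: int = 10) -> DistanceMatrix:
    """Normalized-mutual-information distance between operation columns:
    d = 1 - MI(u, v)/sqrt(H(u) H(v)) with equiprobable binning over shared
    rows; captures nonlinear redundancy that correlation misses."""
    if m.normalized is None:
        raise ValueError("op_distance_nmi needs the normalized view")
    X = np.where(m.mask, np.nan, m.normalized)
    p = X.shape[1]
    d = np.full((p, p), np.nan)
    for a in range(p):
        d[a, a] = 0.0
        for b in range(a + 1, p):
            ok = ~np.isnan(X[:, a]) & ~np.isnan(X[:, b])
            if ok.sum() < 4 * bins:
                continue
            nmi = _nmi(X[ok, a], X[ok, b], bins)
            if nmi is None:
                continue
            d[a, b] = d[b, a] = max(0.0, 1.0 - nmi)
    return DistanceMatrix(d, list(m.col_ids), "one_minus_nmi")


# -- clustering --------------------------------------------------------


class KMedoids(ClusterMixin, BaseEstimator):
    """PAM k-medoids on a precomputed distance matrix.

    fit(X) expects a square distance matrix.  The BUILD initialization is
    always tried; the remaining ``restarts - 1`` starts are seeded random
    medoid subsets.  Each start runs steepest-descent SWAP to convergence;
    the lowest-cost solution wins.  Deterministic given ``random_state``.

    Attributes: ``medoid_indices_``, ``labels_``, ``inertia_``.
    """

    def __init__(self, n_clusters: int = 2, restarts: int = 20,
                 random_state: int = 0):
        self.n_clusters = n_clusters
        self.restarts = restarts
        self.random_state = random_state

    @staticmethod
    def _cost(d: np.ndarray, medoids: np.ndarray) -> float:
        return float(d[:, medoids].min(axis=1).sum())

    @staticmethod
    def _build(d: np.ndarray, k: int) -> np.ndarray:
        n = d.shape[0]
        medoids = [int(np.argmin(d.sum(axis=0)))]
        while len(medoids) < k:
            cur = d[:, medoids].min(axis=1)
            gains = np.maximum(cur[None, :] - d, 0).sum(axis=1)
            gains[medoids] = -np.inf
            medoids.append(int(np.argmax(gains)))
        return np.array(sorted(medoids))

    def _swap(self, d: np.ndarray, medoids: np.ndarray) -> np.ndarray:
        """Steepest-descent SWAP with vectorized swap deltas based on each
        point's nearest and second-nearest medoid distances."""
        n = d.shape[0]
        medoids = medoids.copy()
        k = medoids.size
        while True:
            dm = d[:, medoids]  # (n, k)
            order = np.argsort(dm, axis=1)
            near = order[:, 0]
            d1 = dm[np.arange(n), near]
            d2 = dm[np.arange(n), order[:, 1]] if k > 1 else np.full(n, np.inf)
            in_set = np.zeros(n, dtype=bool)
            in_set[medoids] = True
            cands = np.nonzero(~in_set)[0]
            if cands.size == 0:
                break
            best = (-1e-15, None, None)
            dh = d[cands]  # (n_cand, n)
            for mi in range(k):
                alt = np.where(near == mi, d2, d1)
                deltas = np.minimum(dh, alt[None, :]).sum(axis=1) - d1.sum()
                j = int(np.argmin(deltas))
                if deltas[j] < best[0]:
                    best = (float(deltas[j]), mi, int(cands[j]))
            if best[1] is None:
                break
            medoids[best[1]] = best[2]
        return np.array(sorted(medoids))

    def fit(self, X, y=None):
        d = np.asarray(X, dtype=float)
        n = d.shape[0]
        k = self.n_clusters
        if not 1 <= k <= n:
            raise ValueError(f"n_clusters must be in [1, {n}]")
        if np.any(~np.isfinite(d)):
            raise ValueError("distance matrix contains undefined entries")
        rng = np.random.default_rng(self.random_state)
        starts = [self._build(d, k)]
        for _ in range(max(0, self.restarts - 1)):
            starts.append(np.sort(rng.choice(n, size=k, replace=False)))
        best_medoids, best_cost = None, np.inf
        for s in starts:
            med = self._swap(d, s)
            c = self._cost(d, med)
            if c < best_cost - 1e-15:
                best_medoids, best_cost = med, c
        self.medoid_indices_ = best_medoids
        self.labels_ = np.argmin(d[:, best_medoids], axis=1)
        self.labels_[best_medoids] = np.arange(k)  # medoid belongs to itself
        self.inertia_ = best_cost
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def kmedoids(d: DistanceMatrix, k: int, seed: int = 0,
             restarts: int = 20) -> Clustering:
    """PAM k-medoids over a :class:`DistanceMatrix` (best of ``restarts``
    seeded starts by total distance-to-medoid cost)."""
    est = KMedoids(n_clusters=k, restarts=restarts, random_state=seed)
    est.fit(d.values)
    return Clustering(
        assignment={i: int(l) for i, l in zip(d.ids, est.labels_)},
        medoids=[d.ids[i] for i in est.medoid_indices_],
        method="pam_kmedoids",
        k=k,
    )


def linkage_cluster(d: DistanceMatrix, k: int | None = None,
                    threshold: float | None = None) -> Clustering:
    """Agglomerative complete-linkage clustering, cut either into k
    clusters or at a merge-height threshold."""
    if (k is None) == (threshold is None):
        raise ValueError("give exactly one of k / threshold")
    z = linkage(d.condensed(), method="complete")
    if k is not None:
        flat = fcluster(z, t=k, criterion="maxclust")
    else:
        flat = fcluster(z, t=threshold, criterion="distance")
    return Clustering(
        assignment={i: int(c) - 1 for i, c in zip(d.ids, flat)},
        method="complete_linkage",
        k=int(flat.max()),
    )


def residual_variance(full: DistanceMatrix, reduced: DistanceMatrix):
    """1 - R^2, R being the linear correlation between the upper-triangle
    distance vectors of the two matrices; 0 means the reduced space
    preserves the full geometry exactly."""
    if full.ids != reduced.ids:
        raise ValueError("distance matrices must share ids and order")
    n = full.n
    if n < 3:
        raise ValueError("need at least 3 points")
    iu = np.triu_indices(n, k=1)
    a, b = full.values[iu], reduced.values[iu]
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < 3 or a.std() == 0 or b.std() == 0:
        return SpecialValue("inapplicable", "zero variance in distances")
    r = pearsonr(a, b).statistic
    return float(min(1.0, max(0.0, 1.0 - r * r)))


def build_reduced_set(m: DataMatrix, k: int, metric: str = "corr",
                      seed: int = 0) -> ReducedSet:
    """k-medoids reduced operation set with its residual variance.

    Operation distances (corr or nmi) are clustered with PAM; the medoid
    operations form the reduced set.  Columns whose distance to some other
    column is undefined are excluded from the clustering (logged).
    """
    dist = op_distance_corr(m) if metric == "corr" else op_distance_nmi(m)
    # greedily drop the columns responsible for undefined pairs (typically
    # near-constant operations with no variance to correlate)
    good = np.ones(len(dist.ids), dtype=bool)
    bad = ~np.isfinite(dist.values)
    while True:
        counts = (bad & good[None, :] & good[:, None]).sum(axis=1)
        counts[~good] = 0
        if counts.max() == 0:
            break
        worst = np.nonzero(counts == counts.max())[0]
        drop = min(worst, key=lambda i: dist.ids[i])
        good[drop] = False
    if not good.all():
        logger.info("build_reduced_set: excluding %d columns with undefined "
                    "pairs", int((~good).sum()))
    ids = [i for i, g in zip(dist.ids, good) if g]
    if k > len(ids):
        raise ValueError(f"k={k} exceeds {len(ids)} usable operations")
    sub = DistanceMatrix(dist.values[np.ix_(good, good)], ids, dist.metric)
    clust = kmedoids(sub, k, seed=seed)
    members = sorted(clust.medoids)
    full_d = ts_distance(m)
    red_d = ts_distance(m.select_columns(members))
    rv = residual_variance(full_d, red_d)
    if isinstance(rv, SpecialValue):
        rv = float("nan")
    return ReducedSet(member_ids=members, residual_variance=rv, k=k)


def neighbour_network(d: DistanceMatrix, target: str, k_neighbours: int,
                      link_threshold: float, node_attrs: dict | None = None):
    """Nearest-neighbour network around a target: the target plus its k
    nearest ids (ties broken lexicographically), with edges for every
    intra-node pair at distance strictly below ``link_threshold``.
    Returns a ``networkx.Graph`` with a ``target`` graph attribute."""
    import networkx as nx

    if target not in d.ids:
        raise KeyError(f"unknown target id {target!r}")
    ti = d.ids.index(target)
    dist = d.values[ti]
    order = sorted(
        (i for i in range(d.n) if i != ti),
        key=lambda i: (dist[i], d.ids[i]),
    )
    nodes = [ti] + order[:k_neighbours]
    g = nx.Graph(target=target, metric=d.metric)
    for i in nodes:
        attrs = (node_attrs or {}).get(d.ids[i], {})
        g.add_node(d.ids[i], **attrs)
    for ai in range(len(nodes)):
        for bi in range(ai + 1, len(nodes)):
            i, j = nodes[ai], nodes[bi]
            if np.isfinite(d.values[i, j]) and d.values[i, j] < link_threshold:
                g.add_edge(d.ids[i], d.ids[j], distance=float(d.values[i, j]))
    return g


@dataclass
class Projection:
    scores: np.ndarray
    explained_variance_ratio: np.ndarray
    loadings: np.ndarray
    row_ids: list
    filled_fraction: float


def pca_project(m: DataMatrix, dims: int = 2) -> Projection:
    """Project series onto the first principal components of the normalized
    feature matrix.  Masked cells are filled with their column's unmasked
    mean (the filled fraction is reported); each component's sign is fixed
    by making its largest-magnitude loading positive."""
    from sklearn.decomposition import PCA

    if m.normalized is None:
        raise ValueError("pca_project needs the normalized view")
    if len(m.row_ids) < dims:
        raise ValueError("need at least `dims` series")
    X = np.where(m.mask, np.nan, m.normalized)
    col_mean = np.nanmean(X, axis=0)
    keep = ~np.isnan(col_mean)
    X = X[:, keep]
    filled = np.isnan(X)
    X = np.where(filled, np.broadcast_to(col_mean[keep], X.shape), X)
    pca = PCA(n_components=dims, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_
    for c in range(dims):
        top = np.argmax(np.abs(loadings[c]))
        if loadings[c, top] < 0:
            loadings[c] = -loadings[c]
            scores[:, c] = -scores[:, c]
    frac = float(filled.mean())
    if frac:
        logger.info("pca_project: mean-filled %.1f%% of cells", 100 * frac)
    return Projection(
        scores=scores,
        explained_variance_ratio=pca.explained_variance_ratio_,
        loadings=loadings,
        row_ids=list(m.row_ids),
        filled_fraction=frac,
    )
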