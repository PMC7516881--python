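"""Diagonal Gaussian mixture simplification by Fisher-Rao hierarchical clustering.

A diagonal Gaussian mixture model (DGMM) f = sum_i w_i N(mu_i, diag(s_i^2))
is simplified into a mixture g of l < m components by agglomerative
clustering of the components under the diagonal-submanifold Fisher-Rao
distance (single / complete / average linkage), replacing each cluster by a
single Gaussian:

* the Fisher-Rao centroid — per-coordinate hyperbolic (Galperin) centroid
  of the member (mu, sigma) pairs, or
* the Bregman left-sided centroid — per-coordinate moment matching, the
  KL-optimal single-Gaussian approximation of the cluster sub-mixture.

Quality is measured by the Kullback-Leibler divergence KL(f || g), estimated
by Monte Carlo since no closed form exists for mixtures; ``learn_components``
picks the smallest l whose simplification meets a prescribed KL budget.
``classify_points`` implements maximum-(unweighted)-density component
assignment, the rule used for pixel classification in image segmentation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .core import Gaussian
from .submanifolds import dist_diagonal
from .univariate import UnivariateNormal, WeightedUnivariate, galperin_centroid

__all__ = [
    "DGMM",
    "MergeTree",
    "KLEstimate",
    "dgmm_logpdf",
    "dgmm_sample",
    "kl_monte_carlo",
    "fr_centroid",
    "bregman_left_centroid",
    "linkage_distance",
    "agglomerate",
    "simplify",
    "learn_components",
    "classify_points",
    "fit_dgmm",
]

Linkage = Literal["single", "complete", "average"]
Centroid = Literal["fisher-rao", "bregman"]

_VAR_FLOOR = 1e-6


def _diag_stds(theta: Gaussian) -> np.ndarray:
    off = theta.sigma - np.diag(np.diag(theta.sigma))
    if off.size and np.abs(off).max() > 1e-9 * max(np.linalg.norm(theta.sigma), 1.0):
        raise ValueError("DGMM components must have diagonal covariance")
    return np.sqrt(np.diag(theta.sigma))


@dataclass(frozen=True)
class DGMM:
    """Weighted mixture of diagonal-covariance Gaussians (weights sum to 1)."""

    weights: np.ndarray
    components: tuple[Gaussian, ...]

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        comps = tuple(self.components)
        if len(comps) < 1 or w.shape != (len(comps),):
            raise ValueError("weights and components disagree or mixture is empty")
        if w.min() < 0 or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be nonnegative and sum to 1")
        dims = {c.dim for c in comps}
        if len(dims) != 1:
            raise ValueError("all components must share one dimension")
        for c in comps:
            _diag_stds(c)  # raises on non-diagonal covariance
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "components", comps)

    @property
    def m(self) -> int:
        return len(self.components)

    @property
    def dim(self) -> int:
        return self.components[0].dim


def _component_logpdfs(f: DGMM, X: np.ndarray) -> np.ndarray:
    """(npoints, m) matrix of per-component diagonal-normal log densities."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out = np.empty((X.shape[0], f.m))
    for j, c in enumerate(f.components):
        var = np.diag(c.sigma)
        z = (X - c.mu) ** 2 / var
        out[:, j] = -0.5 * (
            z.sum(axis=1) + np.log(2.0 * math.pi) * f.dim + np.log(var).sum()
        )
    return out


def dgmm_logpdf(f: DGMM, x) -> float | np.ndarray:
    """log f(x) via log-sum-exp over components; vectorized over rows of x."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    lp = _component_logpdfs(f, x)
    with np.errstate(divide="ignore"):
        logw = np.log(f.weights)
    a = lp + logw
    amax = a.max(axis=1, keepdims=True)
    out = amax[:, 0] + np.log(np.exp(a - amax).sum(axis=1))
    return float(out[0]) if single else out


def dgmm_sample(f: DGMM, n: int, seed: int) -> np.ndarray:
    """Draw n points: choose components by weight, then diagonal-normal draws."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    idx = rng.choice(f.m, size=n, p=f.weights)
    X = np.empty((n, f.dim))
    for j in range(f.m):
        mask = idx == j
        k = int(mask.sum())
        if k:
            c = f.components[j]
            X[mask] = c.mu + rng.standard_normal((k, f.dim)) * np.sqrt(np.diag(c.sigma))
    return X


@dataclass(frozen=True)
class KLEstimate:
    value: float
    std_error: float
    n: int


def kl_monte_carlo(f: DGMM, g: DGMM, n: int = 5000, seed: int = 0) -> KLEstimate:
    """Monte-Carlo estimate of KL(f || g): mean of log f - log g under x ~ f."""
    if f.dim != g.dim:
        raise ValueError("dimension mismatch")
    X = dgmm_sample(f, n, seed)
    diffs = dgmm_logpdf(f, X) - dgmm_logpdf(g, X)
    se = float(diffs.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return KLEstimate(float(diffs.mean()), se, n)


def _cluster_as_weighted(cluster: Sequence[tuple[float, Gaussian]]):
    if len(cluster) == 0:
        raise ValueError("empty cluster")
    if sum(w for w, _ in cluster) <= 0:
        raise ValueError("cluster total weight must be positive")
    return cluster


def fr_centroid(cluster: Sequence[tuple[float, Gaussian]]) -> Gaussian:
    """Per-coordinate hyperbolic (Galperin) centroid of weighted diagonal Gaussians."""
    cluster = _cluster_as_weighted(cluster)
    n = cluster[0][1].dim
    mus, vars_ = np.empty(n), np.empty(n)
    for j in range(n):
        pts = [
            WeightedUnivariate(w, UnivariateNormal(c.mu[j], math.sqrt(c.sigma[j, j])))
            for w, c in cluster
        ]
        cj = galperin_centroid(pts)
        mus[j], vars_[j] = cj.mu, cj.sigma**2
    return Gaussian(mus, np.diag(vars_))


def bregman_left_centroid(cluster: Sequence[tuple[float, Gaussian]]) -> Gaussian:
    """Moment-matching centroid: the KL-optimal single-Gaussian merge.

    mu_c = sum w~_i mu_i,  var_c = sum w~_i (var_i + mu_i^2) - mu_c^2,
    with weights normalized within the cluster.
    """
    cluster = _cluster_as_weighted(cluster)
    wts = np.array([w for w, _ in cluster])
    wts = wts / wts.sum()
    mus = np.stack([c.mu for _, c in cluster])
    vars_ = np.stack([np.diag(c.sigma) for _, c in cluster])
    mu_c = wts @ mus
    var_c = wts @ (vars_ + mus**2) - mu_c**2
    return Gaussian(mu_c, np.diag(np.maximum(var_c, _VAR_FLOOR)))


def linkage_distance(
    A: Sequence[Gaussian], B: Sequence[Gaussian], kind: Linkage = "complete"
) -> float:
    """Single/complete/average linkage over pairwise diagonal-manifold distances."""
    if len(A) == 0 or len(B) == 0:
        raise ValueError("clusters must be nonempty")
    d = [dist_diagonal(a, b) for a in A for b in B]
    if kind == "single":
        return min(d)
    if kind == "complete":
        return max(d)
    if kind == "average":
        return float(np.mean(d))
    raise ValueError(f"unknown linkage {kind!r}")


@dataclass(frozen=True)
class MergeTree:
    """Record of agglomerative merges; supports cutting at any level l.

    Cluster ids: 0..m-1 are the leaves, m+k is the cluster created by the
    k-th merge.  ``merges`` holds (id_i, id_j, linkage_distance) triples in
    merge order.
    """

    leaf_count: int
    merges: tuple[tuple[int, int, float], ...]

    def partition(self, l: int) -> list[list[int]]:
        """Leaf-index clusters after cutting the tree at l clusters."""
        if not 1 <= l <= self.leaf_count:
            raise ValueError(f"l must be in [1, {self.leaf_count}]")
        members = {i: [i] for i in range(self.leaf_count)}
        next_id = self.leaf_count
        for i, j, _ in self.merges[: self.leaf_count - l]:
            members[next_id] = members.pop(i) + members.pop(j)
            next_id += 1
        return [sorted(v) for v in sorted(members.values())]


def agglomerate(f: DGMM, kind: Linkage = "complete") -> MergeTree:
    """Greedy agglomerative clustering of mixture components (naive O(m^3)).

    At each step the globally closest pair of clusters is merged; ties are
    broken toward the lexicographically smallest (i, j) id pair.
    """
    clusters: dict[int, list[int]] = {i: [i] for i in range(f.m)}
    next_id = f.m
    merges: list[tuple[int, int, float]] = []
    while len(clusters) > 1:
        best = None
        ids = sorted(clusters)
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                i, j = ids[ai], ids[bi]
                d = linkage_distance(
                    [f.components[k] for k in clusters[i]],
                    [f.components[k] for k in clusters[j]],
                    kind,
                )
                if best is None or d < best[0] - 1e-15:
                    best = (d, i, j)
        d, i, j = best
        clusters[next_id] = clusters.pop(i) + clusters.pop(j)
        merges.append((i, j, d))
        next_id += 1
    return MergeTree(f.m, tuple(merges))


def simplify(
    f: DGMM,
    l: int,
    kind: Linkage = "complete",
    centroid: Centroid = "bregman",
    tree: MergeTree | None = None,
) -> DGMM:
    """Cut the merge tree at l clusters and replace each by its centroid.

    The replacement weight is the sum of member weights, so the output
    weights again sum to 1.  ``l = m`` returns the input mixture (possibly
    reordered).  A precomputed ``tree`` may be passed to amortize scans
    over several levels.
    """
    if not 1 <= l <= f.m:
        raise ValueError(f"l must be in [1, {f.m}]")
    if tree is None:
        tree = agglomerate(f, kind)
    merge_fn = fr_centroid if centroid == "fisher-rao" else bregman_left_centroid
    weights, comps = [], []
    for members in tree.partition(l):
        cluster = [(float(f.weights[k]), f.components[k]) for k in members]
        weights.append(sum(w for w, _ in cluster))
        comps.append(merge_fn(cluster) if len(cluster) > 1 else cluster[0][1])
    return DGMM(np.array(weights), tuple(comps))


def learn_components(
    f: DGMM,
    tau: float,
    kind: Linkage = "complete",
    centroid: Centroid = "bregman",
    n_mc: int = 5000,
    seed: int = 0,
) -> tuple[int, DGMM]:
    """Smallest l with KL(f || simplify(f, l)) <= tau, scanning l = 1..m.

    KL is not guaranteed monotone in l, hence the explicit upward scan.
    Returns (m, f) when no strict simplification qualifies.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    tree = agglomerate(f, kind)
    for l in range(1, f.m):
        g = simplify(f, l, kind, centroid, tree=tree)
        if kl_monte_carlo(f, g, n_mc, seed).value <= tau:
            return l, g
    return f.m, f


def classify_points(f: DGMM, points) -> np.ndarray:
    """Assign each point to the component with the highest unweighted density.

    Mixture weights are deliberately ignored (maximum-likelihood component
    rule); ties go to the lowest component index.
    """
    lp = _component_logpdfs(f, np.atleast_2d(np.asarray(points, dtype=float)))
    return np.argmax(lp, axis=1)


def fit_dgmm(points, m: int, seed: int = 0) -> DGMM:
    """Fit a diagonal-covariance mixture to points by EM (k-means++ init)."""
    from sklearn.mixture import GaussianMixture

    X = np.atleast_2d(np.asarray(points, dtype=float))
    if X.shape[0] < m:
        raise ValueError(f"need at least {m} points to fit {m} components")
    gm = GaussianMixture(
        n_components=m,
        covariance_type="diag",
        reg_covar=_VAR_FLOOR,
        random_state=int(seed) % (2**32),
        n_init=3,
    ).fit(X)
    comps = tuple(
        Gaussian(gm.means_[j], np.diag(np.maximum(gm.covariances_[j], _VAR_FLOOR)))
        for j in range(m)
    )
    w = gm.weights_ / gm.weights_.sum()
    return DGMM(w, comps)
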