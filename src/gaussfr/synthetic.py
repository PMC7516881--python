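"""Seeded generators for the test families used throughout the package.

Every generator is a pure function of its integer seed (no global RNG
state), and each family satisfies its defining structural constraint
exactly: mirrored pairs are mirror-conjugate to machine precision, the
rotated-eigenvalue family always has spectrum {lambda1, lambda2}, planted
mixtures record their ground-truth partition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import Gaussian
from .mixtures import DGMM

__all__ = [
    "random_spd",
    "random_gaussian",
    "make_eq33_pair",
    "make_mirrored_pair",
    "make_planted_dgmm",
    "make_synthetic_image",
    "PlantedDGMM",
]


def random_spd(n: int, seed: int, condition_range: tuple[float, float] = (0.2, 5.0)) -> np.ndarray:
    """Random SPD matrix Q diag(lam) Q' with log-uniform eigenvalues in the range."""
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = condition_range
    if not 0 < lo <= hi:
        raise ValueError("condition range must be positive and ordered")
    rng = np.random.default_rng(seed)
    lam = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n))
    Q, _ = np.linalg.qr(rng.standard_normal((n, n)))
    S = (Q * lam) @ Q.T
    return 0.5 * (S + S.T)


def random_gaussian(n: int, seed: int, mean_scale: float = 1.0) -> Gaussian:
    """Random Gaussian with standard-normal mean (scaled) and random SPD covariance."""
    rng = np.random.default_rng(seed)
    return Gaussian(
        mean_scale * rng.standard_normal(n), random_spd(n, seed + 10_000_019)
    )


def make_eq33_pair(
    lambda1: float = 2.0,
    lambda2: float = 0.5,
    mu_offset: float = 1.0,
    alpha: float = 0.0,
) -> tuple[Gaussian, Gaussian]:
    """The rotated-eigenvalue bound-comparison family.

    Returns theta0 = (0, I2) and theta_hat = ((mu, 0), R(alpha) diag(l1, l2)
    R(alpha)'), the two-parameter family every bivariate pair reduces to by
    whitening.
    """
    if lambda1 <= 0 or lambda2 <= 0:
        raise ValueError("eigenvalues must be positive")
    c, s = math.cos(alpha), math.sin(alpha)
    R = np.array([[c, s], [-s, c]])
    sigma = R @ np.diag([lambda1, lambda2]) @ R.T
    return Gaussian([0.0, 0.0], np.eye(2)), Gaussian([mu_offset, 0.0], sigma)


def make_mirrored_pair(
    n: int, seed: int, separation: float = 2.0
) -> tuple[Gaussian, Gaussian]:
    """Random mirrored pair: means +-(separation/2) e1, Sigma2 = M1 Sigma1 M1."""
    if n < 2:
        raise ValueError("mirrored pairs need n >= 2")
    S1 = random_spd(n, seed)
    M = np.eye(n)
    M[0, 0] = -1.0
    S2 = M @ S1 @ M
    mu = np.zeros(n)
    mu[0] = separation / 2.0
    return Gaussian(-mu, S1), Gaussian(mu, S2)


@dataclass(frozen=True)
class PlantedDGMM:
    """A mixture of near-duplicate component groups with known partition."""

    mixture: DGMM
    partition: tuple[tuple[int, ...], ...]


def make_planted_dgmm(
    n: int,
    groups: int,
    per_group: int,
    seed: int,
    group_separation: float = 12.0,
    within_jitter: float = 0.15,
) -> PlantedDGMM:
    """Planted mixture: ``groups`` clusters of ``per_group`` near-duplicates.

    Group centers sit ``group_separation`` apart (per coordinate step on a
    simplex-like grid); members of a group jitter around the center by
    ``within_jitter`` in mean and by +-20% in log standard deviation, so the
    between/within Fisher-Rao distance ratio is large and complete-linkage
    clustering recovers the planted partition.
    """
    if groups < 1 or per_group < 1:
        raise ValueError("groups and per_group must be >= 1")
    rng = np.random.default_rng(seed)
    # deterministic well-separated centers: scaled unit directions
    centers = np.zeros((groups, n))
    for g in range(groups):
        direction = np.zeros(n)
        direction[g % n] = 1.0
        centers[g] = (1 + g // n) * group_separation * direction

    comps, partition, k = [], [], 0
    for g in range(groups):
        ids = []
        for _ in range(per_group):
            mu = centers[g] + within_jitter * rng.standard_normal(n)
            stds = np.exp(rng.uniform(-0.2, 0.2, size=n))
            comps.append(Gaussian(mu, np.diag(stds**2)))
            ids.append(k)
            k += 1
        partition.append(tuple(ids))
    m = groups * per_group
    raw = rng.uniform(0.5, 1.5, size=m)
    return PlantedDGMM(DGMM(raw / raw.sum(), tuple(comps)), tuple(partition))


def make_synthetic_image(
    width: int, height: int, dgmm: DGMM, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Sample an RGB image pixel-wise from a 3-dimensional mixture.

    Returns (image, labels): image is (height, width, 3) uint8 with values
    clipped to [0, 255]; labels is the (height, width) array of the true
    component index each pixel was drawn from.
    """
    if dgmm.dim != 3:
        raise ValueError("image synthesis needs a 3-dimensional (RGB) mixture")
    npix = width * height
    rng = np.random.default_rng(seed)
    idx = rng.choice(dgmm.m, size=npix, p=dgmm.weights)
    X = np.empty((npix, 3))
    for j in range(dgmm.m):
        mask = idx == j
        kk = int(mask.sum())
        if kk:
            c = dgmm.components[j]
            X[mask] = c.mu + rng.standard_normal((kk, 3)) * np.sqrt(np.diag(c.sigma))
    img = np.clip(np.rint(X), 0, 255).astype(np.uint8).reshape(height, width, 3)
    return img, idx.reshape(height, width)
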