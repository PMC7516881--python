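"""Univariate normal geometry: hyperbolic distance, geodesics, centroids.

The space of univariate normals N(mu, sigma^2), parametrized by the upper
half-plane {(mu, sigma) : sigma > 0}, carries the Fisher metric
ds^2 = (dmu^2 + 2 dsigma^2) / sigma^2.  After rescaling u = mu / sqrt(2) it
becomes sqrt(2) times the standard Poincare half-plane, so the distance is

    d((mu1, s1), (mu2, s2))
        = sqrt(2) * acosh(1 + ((u1 - u2)^2 + (s1 - s2)^2) / (2 s1 s2)).

The half-plane is mapped onto the upper sheet of the Minkowski hyperboloid
z^2 - x^2 - y^2 = 1, where weighted centroids are plain linear averages
followed by projection back onto the sheet (Galperin's construction).  This
centroid is the primitive used for merging mixture components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "UnivariateNormal",
    "HyperboloidPoint",
    "WeightedUnivariate",
    "uv_fisher_rao",
    "uv_fisher_rao_logform",
    "uv_geodesic",
    "to_hyperboloid",
    "from_hyperboloid",
    "galperin_centroid",
]

_SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class UnivariateNormal:
    mu: float
    sigma: float

    def __post_init__(self):
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        object.__setattr__(self, "mu", float(self.mu))
        object.__setattr__(self, "sigma", float(self.sigma))


@dataclass(frozen=True)
class HyperboloidPoint:
    """Point on the upper sheet z^2 - x^2 - y^2 = 1, z > 0."""

    x: float
    y: float
    z: float

    def __post_init__(self):
        x, y, z = float(self.x), float(self.y), float(self.z)
        if z <= 0:
            raise ValueError("hyperboloid point must have z > 0")
        norm = z * z - x * x - y * y
        if abs(norm - 1.0) > 1e-9 * max(z * z, 1.0):
            raise ValueError(f"not on the unit hyperboloid: z^2-x^2-y^2 = {norm}")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "z", z)

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass(frozen=True)
class WeightedUnivariate:
    weight: float
    point: UnivariateNormal

    def __post_init__(self):
        if self.weight < 0:
            raise ValueError("weight must be nonnegative")
        object.__setattr__(self, "weight", float(self.weight))


def uv_fisher_rao(p: UnivariateNormal, q: UnivariateNormal) -> float:
    """Fisher-Rao distance between two univariate normals (acosh form)."""
    u1, u2 = p.mu / _SQRT2, q.mu / _SQRT2
    arg = 1.0 + ((u1 - u2) ** 2 + (p.sigma - q.sigma) ** 2) / (2.0 * p.sigma * q.sigma)
    # clamp guards round-off just below 1 for near-identical points
    return _SQRT2 * math.acosh(max(arg, 1.0))


def uv_fisher_rao_logform(p: UnivariateNormal, q: UnivariateNormal) -> float:
    """Equivalent quotient-log form of the distance (cross-check implementation).

    sqrt(2) * log( (|P1 - P2m| + |P1 - P2|) / (|P1 - P2m| - |P1 - P2|) )
    with P_i = (mu_i/sqrt(2), sigma_i) and P2m the sigma-reflection of P2.
    """
    u1, u2 = p.mu / _SQRT2, q.mu / _SQRT2
    dplus = math.hypot(u1 - u2, p.sigma + q.sigma)
    dminus = math.hypot(u1 - u2, p.sigma - q.sigma)
    if dplus == dminus:  # identical points
        return 0.0
    return _SQRT2 * math.log((dplus + dminus) / (dplus - dminus))


def to_hyperboloid(p: UnivariateNormal) -> HyperboloidPoint:
    """Map (mu, sigma) to the Minkowski hyperboloid via the half-plane chart.

    With (u, v) = (mu/sqrt(2), sigma):
        x = (u^2 + v^2 - 1) / (2 v),  y = u / v,  z = (u^2 + v^2 + 1) / (2 v).
    The Minkowski form then reproduces the distance:
    d = sqrt(2) * acosh(z1 z2 - x1 x2 - y1 y2).
    """
    u, v = p.mu / _SQRT2, p.sigma
    r2 = u * u + v * v
    return HyperboloidPoint((r2 - 1.0) / (2.0 * v), u / v, (r2 + 1.0) / (2.0 * v))


def from_hyperboloid(h: HyperboloidPoint) -> UnivariateNormal:
    """Inverse chart: v = 1/(z-x), u = y/(z-x)."""
    d = h.z - h.x
    if d <= 0:
        raise ValueError("point not in the image of the upper half-plane chart")
    return UnivariateNormal(_SQRT2 * h.y / d, 1.0 / d)


def _minkowski(a: np.ndarray, b: np.ndarray) -> float:
    """Minkowski pairing z1 z2 - x1 x2 - y1 y2 for (x, y, z) triples."""
    return float(a[2] * b[2] - a[0] * b[0] - a[1] * b[1])


def uv_geodesic(p: UnivariateNormal, q: UnivariateNormal, t: float) -> UnivariateNormal:
    """Constant-speed geodesic on [0, 1] from p to q.

    Evaluated on the hyperboloid: gamma(t) = cosh(t*d_h) p + sinh(t*d_h) w,
    with w the unit tangent toward q, then mapped back to (mu, sigma).
    """
    hp, hq = to_hyperboloid(p).as_array(), to_hyperboloid(q).as_array()
    c = max(_minkowski(hp, hq), 1.0)
    dh = math.acosh(c)  # hyperbolic (unscaled) distance
    if dh < 1e-15:
        return p
    w = (hq - c * hp) / math.sinh(dh)
    g = math.cosh(t * dh) * hp + math.sinh(t * dh) * w
    return from_hyperboloid(HyperboloidPoint(*g))


def galperin_centroid(points: Sequence[WeightedUnivariate]) -> UnivariateNormal:
    """Weighted hyperbolic centroid by Minkowski averaging.

    Maps each (mu_i, sigma_i) to the hyperboloid, forms c' = sum_i u_i q_i,
    normalizes c = c' / sqrt(z'^2 - x'^2 - y'^2) back onto the sheet, and
    maps back to (mu, sigma).
    """
    if len(points) == 0:
        raise ValueError("centroid of an empty set is undefined")
    total = sum(wp.weight for wp in points)
    if total <= 0:
        raise ValueError("at least one weight must be strictly positive")
    acc = np.zeros(3)
    for wp in points:
        acc += wp.weight * to_hyperboloid(wp.point).as_array()
    norm2 = _minkowski(acc, acc)
    if norm2 <= 0:
        raise ValueError("weighted Minkowski sum is not timelike")
    c = acc / math.sqrt(norm2)
    return from_hyperboloid(HyperboloidPoint(*c))
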