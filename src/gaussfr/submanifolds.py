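"""Closed-form Fisher-Rao distances and geodesics on special submanifolds.

Four submanifolds of the Gaussian manifold admit explicit distances:

* fixed covariance (Mahalanobis distance; not totally geodesic),
* fixed mean (affine-invariant SPD distance; totally geodesic),
* diagonal covariance (product of univariate half-planes; not totally geodesic),
* diagonal covariance with mean along e1 (totally geodesic).

Because the last submanifold is totally geodesic, a Householder rotation of
the mean difference onto e1 followed by a UDU' factorization of the rotated
covariance gives an exact closed form for the full-manifold distance between
any two Gaussians sharing one covariance matrix (``dist_common_sigma``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .core import Gaussian, _check_spd, spd_function
from .univariate import UnivariateNormal, uv_fisher_rao, uv_geodesic

__all__ = [
    "UDUFactorization",
    "mahalanobis_restricted",
    "geodesic_const_sigma",
    "dist_common_mean",
    "geodesic_common_mean",
    "dist_diagonal",
    "dist_diag_eigenmean",
    "udu_decompose",
    "dist_common_sigma",
    "householder_to_e1",
]

SIGMA_EQ_TOL = 1e-9  # relative Frobenius tolerance for "same covariance"


def _require_same_dim(theta1: Gaussian, theta2: Gaussian):
    if theta1.dim != theta2.dim:
        raise ValueError("Gaussians have different dimensions")


def _require_same_sigma(theta1: Gaussian, theta2: Gaussian):
    scale = max(np.linalg.norm(theta1.sigma), 1.0)
    if np.linalg.norm(theta1.sigma - theta2.sigma) > SIGMA_EQ_TOL * scale:
        raise ValueError(
            "covariances differ; use fisher_rao() for the general distance"
        )


def mahalanobis_restricted(theta1: Gaussian, theta2: Gaussian) -> float:
    """Distance inside the fixed-covariance submanifold (Mahalanobis).

    sqrt((mu1-mu2)' Sigma0^{-1} (mu1-mu2)).  Being the distance of a
    non-totally-geodesic submanifold this always upper-bounds the
    full-manifold distance of the same pair.
    """
    _require_same_dim(theta1, theta2)
    _require_same_sigma(theta1, theta2)
    d = theta1.mu - theta2.mu
    return float(math.sqrt(d @ np.linalg.solve(theta1.sigma, d)))


def geodesic_const_sigma(theta1: Gaussian, theta2: Gaussian, t: float) -> Gaussian:
    """Geodesic of the fixed-covariance submanifold: linear mean interpolation."""
    _require_same_dim(theta1, theta2)
    _require_same_sigma(theta1, theta2)
    return Gaussian((1.0 - t) * theta1.mu + t * theta2.mu, theta1.sigma)


def _log_eigs_whitened(sigma1: np.ndarray, sigma2: np.ndarray) -> np.ndarray:
    """log eigenvalues of Sigma1^{-1/2} Sigma2 Sigma1^{-1/2} (generalized eigprob)."""
    w = scipy.linalg.eigvalsh(sigma2, sigma1)
    return np.log(w)


def dist_common_mean(theta1: Gaussian, theta2: Gaussian) -> float:
    """Exact Fisher-Rao distance for equal means: sqrt(1/2 sum log^2 lambda_i).

    lambda_i are the eigenvalues of Sigma1^{-1/2} Sigma2 Sigma1^{-1/2}; the
    fixed-mean submanifold is totally geodesic so this is the distance in the
    full manifold.
    """
    _require_same_dim(theta1, theta2)
    if not np.allclose(theta1.mu, theta2.mu, atol=1e-9, rtol=1e-9):
        raise ValueError("means differ; this closed form needs equal means")
    logw = _log_eigs_whitened(theta1.sigma, theta2.sigma)
    return float(math.sqrt(0.5 * np.sum(logw**2)))


def geodesic_common_mean(theta1: Gaussian, theta2: Gaussian, t: float) -> Gaussian:
    """Equal-mean geodesic: Sigma(t) = S1^{1/2} exp(t log(S1^{-1/2} S2 S1^{-1/2})) S1^{1/2}."""
    _require_same_dim(theta1, theta2)
    if not np.allclose(theta1.mu, theta2.mu, atol=1e-9, rtol=1e-9):
        raise ValueError("means differ; this closed form needs equal means")
    R = spd_function(theta1.sigma, "sqrt")
    Rinv = spd_function(theta1.sigma, "inv_sqrt")
    A = Rinv @ theta2.sigma @ Rinv
    At = spd_function(spd_function(0.5 * (A + A.T), "log") * t, "exp")
    return Gaussian(theta1.mu, R @ At @ R)


def _require_diagonal(theta: Gaussian):
    off = theta.sigma - np.diag(np.diag(theta.sigma))
    if np.abs(off).max() > 1e-9 * max(np.linalg.norm(theta.sigma), 1.0):
        raise ValueError("covariance is not diagonal")


def dist_diagonal(theta1: Gaussian, theta2: Gaussian) -> float:
    """Product-metric distance for diagonal covariances (per-coordinate univariate).

    This submanifold is not totally geodesic, so the value upper-bounds the
    full-manifold distance.
    """
    _require_same_dim(theta1, theta2)
    _require_diagonal(theta1)
    _require_diagonal(theta2)
    s1 = np.sqrt(np.diag(theta1.sigma))
    s2 = np.sqrt(np.diag(theta2.sigma))
    total = 0.0
    for m1, a, m2, b in zip(theta1.mu, s1, theta2.mu, s2):
        total += uv_fisher_rao(UnivariateNormal(m1, a), UnivariateNormal(m2, b)) ** 2
    return math.sqrt(total)


def geodesic_diagonal(theta1: Gaussian, theta2: Gaussian, t: float) -> Gaussian:
    """Geodesic of the diagonal submanifold: per-coordinate univariate geodesics."""
    _require_same_dim(theta1, theta2)
    _require_diagonal(theta1)
    _require_diagonal(theta2)
    s1 = np.sqrt(np.diag(theta1.sigma))
    s2 = np.sqrt(np.diag(theta2.sigma))
    mus, vars_ = [], []
    for m1, a, m2, b in zip(theta1.mu, s1, theta2.mu, s2):
        g = uv_geodesic(UnivariateNormal(m1, a), UnivariateNormal(m2, b), t)
        mus.append(g.mu)
        vars_.append(g.sigma**2)
    return Gaussian(np.array(mus), np.diag(vars_))


def dist_diag_eigenmean(theta1: Gaussian, theta2: Gaussian) -> float:
    """Exact distance when covariances are diagonal and means lie on the e1 axis.

    d^2 = d*((mu11, s11), (mu21, s21))^2 + sum_{i>=2} d*((0, s1i), (0, s2i))^2.
    This submanifold is totally geodesic, so the value is exact in the full
    manifold.
    """
    _require_same_dim(theta1, theta2)
    _require_diagonal(theta1)
    _require_diagonal(theta2)
    for theta in (theta1, theta2):
        if theta.dim > 1 and np.abs(theta.mu[1:]).max() > 1e-9 * max(
            np.abs(theta.mu).max(), 1.0
        ):
            raise ValueError("means must be multiples of e1 on this submanifold")
    s1 = np.sqrt(np.diag(theta1.sigma))
    s2 = np.sqrt(np.diag(theta2.sigma))
    total = uv_fisher_rao(
        UnivariateNormal(theta1.mu[0], s1[0]), UnivariateNormal(theta2.mu[0], s2[0])
    ) ** 2
    for a, b in zip(s1[1:], s2[1:]):
        total += uv_fisher_rao(UnivariateNormal(0.0, a), UnivariateNormal(0.0, b)) ** 2
    return math.sqrt(total)


@dataclass(frozen=True)
class UDUFactorization:
    """S = U D U' with U unit-upper-triangular and D positive diagonal."""

    U: np.ndarray
    D: np.ndarray

    def reconstruct(self) -> np.ndarray:
        return self.U @ self.D @ self.U.T


def udu_decompose(S) -> UDUFactorization:
    """UDU' factorization of an SPD matrix via reversal-conjugated Cholesky.

    With J the index-reversal permutation, J S J = L L' (lower Cholesky);
    then J L J is upper triangular and S = U D U' with U = (J L J) scaled to
    a unit diagonal.  The unit-upper-triangular U satisfies U^{-1} e1 = e1,
    which is what keeps an e1-aligned mean on the axis.
    """
    S = _check_spd(np.asarray(S, dtype=float), name="S")
    n = S.shape[0]
    J = np.eye(n)[::-1]
    L = np.linalg.cholesky(J @ S @ J)
    W = J @ L @ J  # upper triangular, positive diagonal
    d = np.diag(W).copy()
    U = W @ np.diag(1.0 / d)
    return UDUFactorization(U, np.diag(d**2))


def householder_to_e1(v: np.ndarray) -> np.ndarray:
    """Orthogonal P with P v = |v| e1 (sign-stable Householder reflection)."""
    v = np.asarray(v, dtype=float)
    n = v.shape[0]
    nv = np.linalg.norm(v)
    if nv == 0:
        raise ValueError("cannot rotate the zero vector onto e1")
    u = v / nv
    e1 = np.zeros(n)
    e1[0] = 1.0
    s = 1.0 if u[0] >= 0 else -1.0
    # reflect through w = u + s*e1 (never ill-conditioned): maps u -> -s*e1,
    # then flip the first coordinate's sign when needed to land on +e1
    w = u + s * e1
    w = w / np.linalg.norm(w)
    H = np.eye(n) - 2.0 * np.outer(w, w)
    if s < 0:
        return H
    F = np.eye(n)
    F[0, 0] = -1.0
    return F @ H


def dist_common_sigma(theta1: Gaussian, theta2: Gaussian) -> float:
    """Exact full-manifold distance between Gaussians sharing one covariance.

    Rotate the mean difference onto e1 with an orthogonal P, factor
    P Sigma P' = U D U', and evaluate the e1-axis diagonal closed form
    between (0, D) and (|mu2 - mu1| e1, D).  Always <= the Mahalanobis
    distance of the same pair, strictly so off the diagonal case.
    """
    _require_same_dim(theta1, theta2)
    _require_same_sigma(theta1, theta2)
    dmu = theta2.mu - theta1.mu
    sep = float(np.linalg.norm(dmu))
    if sep == 0.0:
        return 0.0
    P = householder_to_e1(dmu)
    fact = udu_decompose(P @ theta1.sigma @ P.T)
    D = fact.D
    n = theta1.dim
    e1 = np.zeros(n)
    e1[0] = sep
    return dist_diag_eigenmean(Gaussian(np.zeros(n), D), Gaussian(e1, D))
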