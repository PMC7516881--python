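"""Lower and upper bounds for the Fisher-Rao distance between Gaussians.

No closed form is known for the distance between two arbitrary multivariate
normals; this module provides computable bounds that sandwich it:

* ``lower_bound`` — the Calvo-Oller bound, obtained by isometrically
  embedding each Gaussian as an (n+1) x (n+1) SPD matrix and measuring the
  affine-invariant SPD distance there.  It is itself a metric.
* ``ub1`` — whitens the pair, diagonalizes the second covariance and sums
  per-coordinate univariate distances in the eigenbasis (the diagonal
  submanifold upper-bounds the distance because it is not totally geodesic).
* ``ub3`` — a triangle-inequality bound through an intermediate Gaussian on
  the totally geodesic e1-axis diagonal submanifold, with the intermediate
  variance chosen analytically as sigma*^2 = (|mu3|^2 + 2) / 2 (the foot of
  the hyperbolic perpendicular from (0, 1) to the line mu = |mu3|).
* ``ub2`` — same decomposition, but with the full intermediate diagonal
  numerically optimized (so UB2 <= UB3 by construction).

``ub123`` assembles the envelope min(UB1, UB2, UB3) alongside the lower
bound.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
import scipy.optimize

from .core import Gaussian, canonicalize_pair
from .submanifolds import dist_common_mean, householder_to_e1
from .univariate import UnivariateNormal, uv_fisher_rao

__all__ = [
    "BoundReport",
    "embed_spd",
    "lower_bound",
    "ub1",
    "ub2",
    "ub3",
    "ub123",
]


@dataclass(frozen=True)
class BoundReport:
    """Lower bound and the three upper bounds with their envelope."""

    lb: float
    ub1: float
    ub2: float
    ub3: float

    @property
    def ub123(self) -> float:
        return min(self.ub1, self.ub2, self.ub3)


def embed_spd(theta: Gaussian) -> np.ndarray:
    """Embed a Gaussian as the (n+1)-order SPD block matrix [[S+mm', m],[m', 1]]."""
    n = theta.dim
    out = np.zeros((n + 1, n + 1))
    out[:n, :n] = theta.sigma + np.outer(theta.mu, theta.mu)
    out[:n, n] = theta.mu
    out[n, :n] = theta.mu
    out[n, n] = 1.0
    return out


def lower_bound(theta1: Gaussian, theta2: Gaussian) -> float:
    """Calvo-Oller lower bound: SPD affine-invariant distance of the embeddings."""
    if theta1.dim != theta2.dim:
        raise ValueError("dimension mismatch")
    S1, S2 = embed_spd(theta1), embed_spd(theta2)
    w = scipy.linalg.eigvalsh(S2, S1)
    return float(math.sqrt(0.5 * np.sum(np.log(w) ** 2)))


def _whiten(theta1: Gaussian, theta2: Gaussian):
    """Whitened data (mu3, Sigma3) of the canonical pair ((0, I), theta3)."""
    theta3, _ = canonicalize_pair(theta1, theta2)
    return theta3.mu, theta3.sigma


def ub1(theta1: Gaussian, theta2: Gaussian) -> float:
    """Upper bound through the diagonal submanifold in the whitened eigenbasis.

    A = Sigma1^{-1/2} Sigma2 Sigma1^{-1/2} = Q Lambda Q'; with the rotated
    mean mu = Q' Sigma1^{-1/2} (mu2 - mu1), each eigenvalue is paired with
    the mean coordinate of the same eigenvector:

        UB1 = sqrt( sum_i d*((0,1), (mu_i, sqrt(lambda_i)))^2 ).
    """
    mu3, Sigma3 = _whiten(theta1, theta2)
    lam, Q = np.linalg.eigh(Sigma3)
    mu = Q.T @ mu3
    total = 0.0
    for m, l in zip(mu, lam):
        total += uv_fisher_rao(UnivariateNormal(0.0, 1.0), UnivariateNormal(m, math.sqrt(l))) ** 2
    return math.sqrt(total)


def _axis_leg(m: float, stds: np.ndarray) -> float:
    """Distance from (0, I) to (m e1, diag(stds^2)) on the e1-axis submanifold."""
    total = uv_fisher_rao(UnivariateNormal(0.0, 1.0), UnivariateNormal(m, stds[0])) ** 2
    for s in stds[1:]:
        total += uv_fisher_rao(UnivariateNormal(0.0, 1.0), UnivariateNormal(0.0, s)) ** 2
    return math.sqrt(total)


def _mean_leg(D_diag: np.ndarray, P: np.ndarray, Sigma3: np.ndarray) -> float:
    """Fixed-mean distance between Sigma_bar = P^{-1} D P^{-t} and Sigma3."""
    Sigma_bar = P.T @ np.diag(D_diag) @ P
    w = scipy.linalg.eigvalsh(Sigma3, Sigma_bar)
    return math.sqrt(0.5 * float(np.sum(np.log(w) ** 2)))


def ub3(theta1: Gaussian, theta2: Gaussian) -> float:
    """Analytic triangle bound through the e1-axis diagonal submanifold.

    The intermediate Gaussian is (mu3, Sigma_bar) with
    Sigma_bar = P^{-1} diag(sigma*^2, 1, ..., 1) P^{-t} and
    sigma*^2 = (|mu3|^2 + 2)/2 minimizing the first leg analytically.
    """
    mu3, Sigma3 = _whiten(theta1, theta2)
    m = float(np.linalg.norm(mu3))
    if m == 0.0:
        return dist_common_mean(theta1, theta2)
    n = theta1.dim
    P = householder_to_e1(mu3)
    sstar = math.sqrt((m * m + 2.0) / 2.0)
    leg1 = uv_fisher_rao(UnivariateNormal(0.0, 1.0), UnivariateNormal(m, sstar))
    D = np.ones(n)
    D[0] = sstar * sstar
    return leg1 + _mean_leg(D, P, Sigma3)


def ub2(theta1: Gaussian, theta2: Gaussian) -> float:
    """Triangle bound with numerically optimized intermediate diagonal.

    Minimizes, over positive diagonals D (in log standard-deviation
    coordinates), the sum of the e1-axis leg from (0, I) to (|mu3| e1, D)
    and the fixed-mean leg from (mu3, P^{-1} D P^{-t}) to (mu3, Sigma3).
    Multistart from the UB3 solution and the identity; any returned value is
    a valid upper bound regardless of optimizer convergence.
    """
    mu3, Sigma3 = _whiten(theta1, theta2)
    m = float(np.linalg.norm(mu3))
    n = theta1.dim
    if m == 0.0:
        return dist_common_mean(theta1, theta2)
    P = householder_to_e1(mu3)

    def objective(logs):
        stds = np.exp(np.clip(logs, -20.0, 20.0))
        return _axis_leg(m, stds) + _mean_leg(stds**2, P, Sigma3)

    sstar = math.sqrt((m * m + 2.0) / 2.0)
    x_ub3 = np.zeros(n)
    x_ub3[0] = math.log(sstar)
    best = min(objective(x_ub3), objective(np.zeros(n)))
    for x0 in (x_ub3, np.zeros(n)):
        res = scipy.optimize.minimize(
            objective, x0, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
        )
        if not res.success and res.fun > best + 1e-9:
            warnings.warn("UB2 optimizer did not converge; value is still a bound")
        best = min(best, float(res.fun))
    return best


def ub123(theta1: Gaussian, theta2: Gaussian) -> BoundReport:
    """Assemble the lower bound and the three upper bounds with their envelope."""
    return BoundReport(
        lb=lower_bound(theta1, theta2),
        ub1=ub1(theta1, theta2),
        ub2=ub2(theta1, theta2),
        ub3=ub3(theta1, theta2),
    )
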