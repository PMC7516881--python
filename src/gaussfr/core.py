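"""Parameter types and SPD matrix calculus for the Gaussian manifold.

The statistical manifold is M = {N(mu, Sigma) : mu in R^n, Sigma SPD},
equipped with the Fisher information metric.  In the (mu, Sigma) chart the
metric at theta = (mu, Sigma) acting on tangent pairs (x1, B1), (x2, B2) is

    <v1, v2>_theta = x1' Sigma^{-1} x2 + (1/2) tr(Sigma^{-1} B1 Sigma^{-1} B2).

Affine maps psi_(c,Q): (mu, Sigma) -> (Q mu + c, Q Sigma Q') with Q invertible
are isometries of this metric; whitening by the first member of a pair
(``canonicalize_pair``) reduces every two-point problem to the base point
(0, I_n) versus a single transformed Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Gaussian",
    "TangentVector",
    "NaturalCoords",
    "AffineIsometry",
    "make_gaussian",
    "spd_function",
    "apply_isometry",
    "canonicalize_pair",
    "to_natural",
    "from_natural",
    "metric_inner",
]

# Symmetry / positivity tolerances used by all validating constructors.
SYM_TOL = 1e-9
EIG_TOL = 1e-12


def _as_vector(x) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.ndim != 1:
        v = v.reshape(-1)
    return v


def _check_symmetric(S: np.ndarray, tol: float = SYM_TOL, name: str = "matrix") -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError(f"{name} must be square, got shape {S.shape}")
    scale = max(np.abs(S).max(), 1.0)
    if np.abs(S - S.T).max() > tol * scale:
        raise ValueError(f"{name} is not symmetric within tolerance {tol}")
    return 0.5 * (S + S.T)


def _check_spd(S: np.ndarray, name: str = "matrix") -> np.ndarray:
    S = _check_symmetric(S, name=name)
    w = np.linalg.eigvalsh(S)
    scale = max(np.abs(w).max(), 1.0)
    if w.min() <= EIG_TOL * scale:
        raise ValueError(
            f"{name} is not positive definite: smallest eigenvalue {w.min():.6g}"
        )
    return S


@dataclass(frozen=True)
class Gaussian:
    """A point theta = (mu, Sigma) of the manifold of n-variate normals."""

    mu: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        mu = _as_vector(self.mu)
        sigma = _check_spd(np.asarray(self.sigma, dtype=float), name="sigma")
        if sigma.shape[0] != mu.shape[0]:
            raise ValueError(
                f"dimension mismatch: mu has length {mu.shape[0]}, "
                f"sigma is {sigma.shape[0]}x{sigma.shape[1]}"
            )
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)

    @property
    def dim(self) -> int:
        return self.mu.shape[0]

    def close_to(self, other: "Gaussian", tol: float = 1e-9) -> bool:
        return (
            self.dim == other.dim
            and np.allclose(self.mu, other.mu, atol=tol, rtol=tol)
            and np.allclose(self.sigma, other.sigma, atol=tol, rtol=tol)
        )


@dataclass(frozen=True)
class TangentVector:
    """Tangent data (x, B) at the base point (0, I_n): a vector and a symmetric matrix."""

    x: np.ndarray
    B: np.ndarray

    def __post_init__(self):
        x = _as_vector(self.x)
        B = _check_symmetric(np.asarray(self.B, dtype=float), name="B")
        if B.shape[0] != x.shape[0]:
            raise ValueError("x and B dimensions disagree")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "B", B)

    @property
    def dim(self) -> int:
        return self.x.shape[0]


@dataclass(frozen=True)
class NaturalCoords:
    """Natural coordinates (delta, Delta) = (Sigma^{-1} mu, Sigma^{-1})."""

    delta: np.ndarray
    Delta: np.ndarray

    def __post_init__(self):
        delta = _as_vector(self.delta)
        Delta = _check_spd(np.asarray(self.Delta, dtype=float), name="Delta")
        if Delta.shape[0] != delta.shape[0]:
            raise ValueError("delta and Delta dimensions disagree")
        object.__setattr__(self, "delta", delta)
        object.__setattr__(self, "Delta", Delta)


@dataclass(frozen=True)
class AffineIsometry:
    """The isometry psi_(c,Q): (mu, Sigma) -> (Q mu + c, Q Sigma Q')."""

    c: np.ndarray
    Q: np.ndarray

    def __post_init__(self):
        c = _as_vector(self.c)
        Q = np.asarray(self.Q, dtype=float)
        if Q.ndim != 2 or Q.shape[0] != Q.shape[1] or Q.shape[0] != c.shape[0]:
            raise ValueError("c and Q dimensions disagree")
        if not np.isfinite(np.linalg.cond(Q)) or np.linalg.cond(Q) > 1e12:
            raise ValueError("Q is singular or numerically rank-deficient")
        object.__setattr__(self, "c", c)
        object.__setattr__(self, "Q", Q)

    def compose(self, other: "AffineIsometry") -> "AffineIsometry":
        """Return the isometry equal to applying ``other`` first, then ``self``."""
        return AffineIsometry(self.Q @ other.c + self.c, self.Q @ other.Q)

    def inverse(self) -> "AffineIsometry":
        Qinv = np.linalg.inv(self.Q)
        return AffineIsometry(-Qinv @ self.c, Qinv)


def make_gaussian(mu, sigma) -> Gaussian:
    """Validate and build a Gaussian, symmetrizing sigma.

    Raises ``ValueError`` naming the smallest eigenvalue if sigma is not SPD,
    or describing the shape mismatch if dimensions disagree.
    """
    return Gaussian(mu, sigma)


_SPD_FUNCS = {
    "sqrt": np.sqrt,
    "inv_sqrt": lambda w: 1.0 / np.sqrt(w),
    "log": np.log,
    "exp": np.exp,
    "inv": lambda w: 1.0 / w,
}


def spd_function(S, f: str) -> np.ndarray:
    """Apply a scalar function spectrally to a symmetric (SPD for sqrt/log) matrix.

    Supported tags: ``sqrt``, ``inv_sqrt``, ``log``, ``exp``, ``inv``.
    """
    if f not in _SPD_FUNCS:
        raise ValueError(f"unknown matrix function tag {f!r}")
    if f == "exp":
        S = _check_symmetric(np.asarray(S, dtype=float), name="S")
    else:
        S = _check_spd(np.asarray(S, dtype=float), name="S")
    w, V = np.linalg.eigh(S)
    fw = _SPD_FUNCS[f](w)
    out = (V * fw) @ V.T
    return 0.5 * (out + out.T)


def apply_isometry(iso: AffineIsometry, theta: Gaussian) -> Gaussian:
    """Apply psi_(c,Q) to theta: (mu, Sigma) -> (Q mu + c, Q Sigma Q')."""
    Q = iso.Q
    return Gaussian(Q @ theta.mu + iso.c, Q @ theta.sigma @ Q.T)


def canonicalize_pair(theta1: Gaussian, theta2: Gaussian):
    """Whiten a pair by theta1, mapping it to ((0, I), theta3).

    Returns ``(theta3, iso)`` where ``iso`` is the isometry with
    Q = Sigma1^{-1/2}, c = -Q mu1, so that applying it to theta1 yields (0, I)
    and to theta2 yields theta3 = (Q (mu2 - mu1), Q Sigma2 Q).
    """
    if theta1.dim != theta2.dim:
        raise ValueError("dimension mismatch between the two Gaussians")
    Q = spd_function(theta1.sigma, "inv_sqrt")
    iso = AffineIsometry(-Q @ theta1.mu, Q)
    theta3 = apply_isometry(iso, theta2)
    return theta3, iso


def to_natural(theta: Gaussian) -> NaturalCoords:
    """Chart change (mu, Sigma) -> (delta, Delta) = (Sigma^{-1} mu, Sigma^{-1})."""
    Delta = spd_function(theta.sigma, "inv")
    return NaturalCoords(Delta @ theta.mu, Delta)


def from_natural(nc: NaturalCoords) -> Gaussian:
    """Inverse chart change (delta, Delta) -> (Delta^{-1} delta, Delta^{-1})."""
    sigma = spd_function(nc.Delta, "inv")
    return Gaussian(sigma @ nc.delta, sigma)


def metric_inner(theta: Gaussian, v1: TangentVector, v2: TangentVector) -> float:
    """Fisher metric inner product at theta in the (mu, Sigma) chart.

    <v1, v2> = x1' Sigma^{-1} x2 + (1/2) tr(Sigma^{-1} B1 Sigma^{-1} B2)
    """
    Sinv = spd_function(theta.sigma, "inv")
    return float(
        v1.x @ Sinv @ v2.x + 0.5 * np.trace(Sinv @ v1.B @ Sinv @ v2.B)
    )
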