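"""Explicit Gaussian geodesics, geodesic shooting, and mirrored-pair solver.

In natural coordinates (delta, Delta) = (Sigma^{-1} mu, Sigma^{-1}) the
geodesic through the base point (0, I_n) with initial tangent (x, B) — x a
vector, B symmetric — has the closed form

    delta(t) = -B (cosh(tG) - I) (G^-)^2 x + sinh(tG) G^- x
    Delta(t) =  I + (cosh(tG) - I)/2 + B (cosh(tG) - I)(G^-)^2 B / 2
                  - sinh(tG) G^- B / 2 - B sinh(tG) G^- / 2,

with G^2 = B^2 + 2 x x' (symmetric PSD) and G^- a generalized inverse of G.
All matrix kernels are evaluated spectrally with analytic limits at zero
eigenvalues, so no pseudoinverse is ever formed.  The geodesic has constant
speed sqrt(tr(B^2)/2 + |x|^2), which is therefore the Fisher-Rao distance
from (0, I) to the time-1 endpoint.

Two boundary-value solvers are built on this closed form:

* ``geodesic_shooting`` — whitens an arbitrary pair to ((0, I), theta3) and
  finds the tangent whose time-1 endpoint hits theta3 (a root-finding
  problem in the tangent entries);
* ``mirrored_solve`` — for mirrored pairs (means on the e1 axis, covariances
  conjugate under the reflection negating e1) exploits the known structure
  of the midpoint and tangent to reduce the problem to a square non-linear
  system of order n + n(n+1)/2, with the distance then given in closed form
  as 2 sqrt(sum b_l^2 + x^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .core import (
    AffineIsometry,
    Gaussian,
    NaturalCoords,
    TangentVector,
    apply_isometry,
    canonicalize_pair,
    from_natural,
    spd_function,
    to_natural,
)
from .submanifolds import (
    SIGMA_EQ_TOL,
    dist_common_mean,
    dist_common_sigma,
    dist_diag_eigenmean,
    householder_to_e1,
)

__all__ = [
    "ShootingResult",
    "MirroredSolution",
    "geodesic_natural",
    "tangent_speed",
    "geodesic_shooting",
    "is_mirrored",
    "mirrored_solve",
    "mirrored_geodesic",
    "fisher_rao",
]

# eigenvalues of G below this switch the scalar kernels to their series limits
_KERNEL_EPS = 1e-6


def _kernels(g: np.ndarray, t: float):
    """Scalar kernels cosh(tg)-1, (cosh(tg)-1)/g^2, sinh(tg)/g with g->0 limits."""
    g = np.asarray(g, dtype=float)
    tg = t * g
    ch = np.cosh(tg) - 1.0
    small = g < _KERNEL_EPS
    gs = np.where(small, 1.0, g)
    k1 = np.where(small, 0.5 * t * t + (t**4) * g * g / 24.0, ch / gs**2)
    k2 = np.where(small, t + (t**3) * g * g / 6.0, np.sinh(tg) / gs)
    return ch, k1, k2


def _geodesic_arrays(x: np.ndarray, B: np.ndarray, t: float):
    """Raw (delta, Delta) of the closed-form geodesic, without validation."""
    n = x.shape[0]
    G2 = B @ B + 2.0 * np.outer(x, x)
    w, V = np.linalg.eigh(0.5 * (G2 + G2.T))
    g = np.sqrt(np.clip(w, 0.0, None))
    ch, k1, k2 = _kernels(g, t)
    Kch = (V * ch) @ V.T
    K1 = (V * k1) @ V.T
    K2 = (V * k2) @ V.T
    delta = -B @ K1 @ x + K2 @ x
    Delta = (
        np.eye(n)
        + 0.5 * Kch
        + 0.5 * B @ K1 @ B
        - 0.5 * K2 @ B
        - 0.5 * B @ K2
    )
    return delta, 0.5 * (Delta + Delta.T)


def geodesic_natural(v: TangentVector, t: float) -> NaturalCoords:
    """Evaluate the closed-form geodesic from (0, I) with tangent v at time t."""
    delta, Delta = _geodesic_arrays(v.x, v.B, t)
    return NaturalCoords(delta, Delta)


def tangent_speed(v: TangentVector) -> float:
    """Speed (= length of the unit-time geodesic) sqrt(tr(B^2)/2 + |x|^2)."""
    return float(math.sqrt(0.5 * np.trace(v.B @ v.B) + v.x @ v.x))


# --- tangent packing helpers -------------------------------------------------

def _tri_indices(n: int):
    return np.triu_indices(n)


def _pack_tangent(x: np.ndarray, B: np.ndarray) -> np.ndarray:
    iu = _tri_indices(x.shape[0])
    return np.concatenate([x, B[iu]])


def _unpack_tangent(z: np.ndarray, n: int) -> TangentVector:
    x = z[:n]
    B = np.zeros((n, n))
    iu = _tri_indices(n)
    B[iu] = z[n:]
    B = B + B.T - np.diag(np.diag(B))
    return TangentVector(x, B)


@dataclass(frozen=True)
class ShootingResult:
    """Solution of the geodesic boundary-value problem by shooting."""

    tangent: TangentVector
    distance: float
    endpoint_error: float


def geodesic_shooting(
    theta1: Gaussian, theta2: Gaussian, tol: float = 1e-8
) -> ShootingResult:
    """Fisher-Rao distance by solving the boundary-value problem numerically.

    The pair is whitened to ((0, I), theta3); the solver then finds the
    tangent (x, B) whose closed-form time-1 endpoint matches theta3 in
    natural coordinates.  Among multistart solutions below ``tol`` endpoint
    error, the one of smallest speed (= distance) is returned.
    """
    if theta1.dim != theta2.dim:
        raise ValueError("dimension mismatch")
    n = theta1.dim
    theta3, _ = canonicalize_pair(theta1, theta2)
    target = to_natural(theta3)
    d_star, D_star = target.delta, target.Delta
    iu = _tri_indices(n)
    # sqrt(2) weight makes the residual 2-norm the Frobenius norm of the gap
    wts = np.where(iu[0] == iu[1], 1.0, math.sqrt(2.0))

    def residual(z):
        x = z[:n]
        Bm = np.zeros((n, n))
        Bm[iu] = z[n:]
        Bm = Bm + Bm.T - np.diag(np.diag(Bm))
        if 0.5 * np.trace(Bm @ Bm) + x @ x > 2500.0:  # speed > 50: off-scale
            return np.full(z.shape[0], 1e6)
        delta, Delta = _geodesic_arrays(x, Bm, 1.0)
        return np.concatenate([((Delta - D_star)[iu]) * wts, delta - d_star])

    B0 = -spd_function(D_star, "log")
    x0 = d_star.copy()
    starts = [
        _pack_tangent(x0, B0),
        _pack_tangent(0.5 * x0, 0.5 * B0),
        _pack_tangent(0.25 * x0, B0),
        np.zeros(n + n * (n + 1) // 2),
    ]
    best = None
    for z0 in starts:
        sol = scipy.optimize.least_squares(
            residual, z0, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14,
            max_nfev=2000,
        )
        err = float(np.linalg.norm(residual(sol.x)))
        v = _unpack_tangent(sol.x, n)
        cand = ShootingResult(v, tangent_speed(v), err)
        if err <= tol and (best is None or cand.distance < best.distance):
            if best is None or best.endpoint_error > tol or cand.distance < best.distance:
                best = cand
        elif best is None or (best.endpoint_error > tol and err < best.endpoint_error):
            best = cand
    if best is None or best.endpoint_error > tol:
        err = best.endpoint_error if best is not None else float("inf")
        raise RuntimeError(
            f"geodesic shooting failed to converge: best endpoint error {err:.3g}"
        )
    return best


# --- mirrored pairs ----------------------------------------------------------

def _mirror(n: int) -> np.ndarray:
    M = np.eye(n)
    M[0, 0] = -1.0
    return M


def _canonical_rotation(theta1: Gaussian, theta2: Gaussian):
    """Orthogonal P aligning mu2 - mu1 with e1, or None for equal means."""
    dmu = theta2.mu - theta1.mu
    if np.linalg.norm(dmu) == 0:
        return None
    return householder_to_e1(dmu)


def is_mirrored(theta1: Gaussian, theta2: Gaussian, tol: float = 1e-8) -> bool:
    """True iff the pair is mirrored in its canonical frame.

    After rotating the mean difference onto e1, both means must lie on the
    e1 axis and the covariances must satisfy Sigma2 = M1 Sigma1 M1 with M1
    the reflection negating e1 (first row/column off-diagonal entries
    negated, everything else equal).
    """
    if theta1.dim != theta2.dim:
        return False
    P = _canonical_rotation(theta1, theta2)
    if P is None:
        return False
    m1, m2 = P @ theta1.mu, P @ theta2.mu
    scale_mu = max(np.abs(m1).max(), np.abs(m2).max(), 1.0)
    n = theta1.dim
    if n > 1 and max(np.abs(m1[1:]).max(), np.abs(m2[1:]).max()) > tol * scale_mu:
        return False
    S1 = P @ theta1.sigma @ P.T
    S2 = P @ theta2.sigma @ P.T
    M = _mirror(n)
    scale_S = max(np.linalg.norm(S1), 1.0)
    return bool(np.linalg.norm(S2 - M @ S1 @ M) <= tol * scale_S)


@dataclass(frozen=True)
class MirroredSolution:
    """Solution of the mirrored-pair boundary system.

    ``x`` and ``b`` are the non-zero tangent entries (arrowhead structure),
    ``eta`` the free part of the midpoint mean, ``d11``/``Dmid`` the blocks
    of the diagonal-block midpoint covariance; the Fisher-Rao distance is
    2*sqrt(sum b_l^2 + x^2).
    """

    x: float
    b: np.ndarray
    eta: np.ndarray
    d11: float
    Dmid: np.ndarray
    distance: float
    residual: float
    # frame data needed to evaluate the geodesic
    P: np.ndarray
    mu_half: np.ndarray
    Sigma_half: np.ndarray
    tangent: TangentVector


def _arrowhead(x: float, b: np.ndarray) -> TangentVector:
    n = b.shape[0] + 1
    xv = np.zeros(n)
    xv[0] = x
    B = np.zeros((n, n))
    B[0, 1:] = b
    B[1:, 0] = b
    return TangentVector(xv, B)


class _MirroredSystem:
    """The square boundary system for a mirrored pair in its canonical frame."""

    def __init__(self, a1: Gaussian, a2: Gaussian):
        self.a1, self.a2 = a1, a2
        n = a1.dim
        self.n = n
        self.S2inv = spd_function(a2.sigma, "inv")
        self.mu_mid1 = 0.5 * (a1.mu[0] + a2.mu[0])
        self.iu_mid = np.triu_indices(n - 1)
        self.iu = np.triu_indices(n)

    def split(self, u):
        n, iu_mid = self.n, self.iu_mid
        x = u[0]
        b = u[1 : n]
        eta = u[n : 2 * n - 1]
        # log-parameters clipped to keep the midpoint covariance well scaled
        # while hybr explores
        p = float(np.clip(u[2 * n - 1], -12.0, 12.0))
        E = np.zeros((n - 1, n - 1))
        E[iu_mid] = np.clip(u[2 * n :], -12.0, 12.0)
        E = E + E.T - np.diag(np.diag(E))
        return x, b, eta, p, E

    def build(self, u):
        n = self.n
        x, b, eta, p, E = self.split(u)
        d11 = math.exp(p)
        L = np.zeros((n, n))
        L[0, 0] = d11
        if n > 1:
            we, Ve = np.linalg.eigh(0.5 * (E + E.T))
            Dmid = (Ve * np.exp(we)) @ Ve.T
            L[1:, 1:] = (Ve * np.exp(0.5 * we)) @ Ve.T
        else:
            Dmid = np.zeros((0, 0))
        mu_half = np.concatenate([[self.mu_mid1], eta])
        return x, b, eta, d11, Dmid, L, mu_half

    def residual(self, u):
        x, b, eta, d11, Dmid, L, mu_half = self.build(u)
        if float(np.sum(b**2)) + x**2 > 2500.0:  # speed > 50: off-scale
            return np.full(u.shape[0], 1e6)
        tv = _arrowhead(x, b)
        delta, Delta = _geodesic_arrays(tv.x, tv.B, 1.0)
        Rm = Delta - L @ self.S2inv @ L
        rv = delta - L @ self.S2inv @ (self.a2.mu - mu_half)
        return np.concatenate([Rm[self.iu], rv])

    def initial_guess(self):
        """Heuristic start: block-diagonal covariance average for the midpoint,
        matrix-log of the whitened endpoint for the tangent."""
        n = self.n
        S_avg = 0.5 * (self.a1.sigma + self.a2.sigma)
        p0 = 0.5 * math.log(S_avg[0, 0])
        E0 = (
            spd_function(S_avg[1:, 1:], "log")[self.iu_mid]
            if n > 1
            else np.zeros(0)
        )
        L0 = np.zeros((n, n))
        L0[0, 0] = math.exp(p0)
        if n > 1:
            L0[1:, 1:] = spd_function(S_avg[1:, 1:], "sqrt")
        Bg = -spd_function(L0 @ self.S2inv @ L0, "log")
        b0 = Bg[0, 1:]
        mu_mid = np.concatenate([[self.mu_mid1], np.zeros(n - 1)])
        x0 = float((L0 @ self.S2inv @ (self.a2.mu - mu_mid))[0])
        return self.pack(x0, b0, np.zeros(n - 1), p0, E0)

    def pack(self, x, b, eta, p, E_flat):
        return np.concatenate([[x], b, eta, [p], E_flat])

    def solve(self, starts, tol):
        """Run hybr from each start; return (best_u, best_res), preferring the
        shortest converged geodesic (the system can admit several branches)."""
        best_u, best_res = None, float("inf")
        best_dist = float("inf")
        for u0 in starts:
            sol = scipy.optimize.root(self.residual, u0, method="hybr", tol=1e-13)
            res = float(np.abs(self.residual(sol.x)).max())
            if res <= tol:
                xc, bc, *_ = self.split(sol.x)
                dist_c = 2.0 * math.sqrt(float(np.sum(bc**2)) + xc**2)
                if dist_c < best_dist - 1e-12:
                    best_u, best_res, best_dist = sol.x, res, dist_c
            elif not np.isfinite(best_dist) and res < best_res:
                best_u, best_res = sol.x, res
        return best_u, best_res


def mirrored_solve(
    theta1: Gaussian, theta2: Gaussian, tol: float = 1e-10
) -> MirroredSolution:
    """Solve the mirrored-pair boundary system and return the exact distance.

    Unknowns (x, b, eta, d11, Dmid) parametrize the geodesic midpoint
    theta_1/2 = ((mu1+mu2)/2, eta; blockdiag(d11^2, Dmid)) and the tangent
    there.  With L the SPD square root of Sigma_1/2 the time-1 endpoint in
    natural coordinates must satisfy

        Delta(1) = L Sigma2^{-1} L,
        delta(1) = L Sigma2^{-1} (mu2 - mu_1/2).

    d11 and Dmid live in log coordinates so the midpoint covariance stays
    SPD.  Direct multistart is tried first; for widely separated means the
    solver falls back to homotopy continuation in the mean separation,
    warm-starting each step from the previous solution.
    """
    if not is_mirrored(theta1, theta2):
        raise ValueError("pair is not mirrored (in its canonical frame)")
    n = theta1.dim
    P = _canonical_rotation(theta1, theta2)
    a1 = apply_isometry(AffineIsometry(np.zeros(n), P), theta1)
    a2 = apply_isometry(AffineIsometry(np.zeros(n), P), theta2)

    system = _MirroredSystem(a1, a2)
    rng = np.random.default_rng(0)
    u_heur = system.initial_guess()
    starts = [u_heur]
    starts += [
        system.pack(
            s * u_heur[0],
            s * u_heur[1:n],
            np.zeros(n - 1),
            u_heur[2 * n - 1],
            u_heur[2 * n :],
        )
        for s in (0.5, 0.75, 1.5, 0.25)
    ]
    starts += [u_heur + 0.2 * rng.standard_normal(u_heur.shape[0]) for _ in range(4)]
    best_u, best_res = system.solve(starts, tol)

    if best_res > tol:
        # homotopy in the mean separation: shrink the means toward zero,
        # solve the easy problem, then walk the separation back up
        u_prev = None
        for s in np.linspace(0.2, 1.0, 9):
            sys_s = _MirroredSystem(
                Gaussian(s * a1.mu, a1.sigma), Gaussian(s * a2.mu, a2.sigma)
            )
            step_starts = [sys_s.initial_guess()] if u_prev is None else [u_prev]
            u_s, res_s = sys_s.solve(step_starts, tol)
            if u_s is None or res_s > tol:
                # perturb and retry once before giving up on this path
                retry = [
                    (step_starts[0] + 0.1 * rng.standard_normal(step_starts[0].shape))
                    for _ in range(4)
                ]
                u_s, res_s = sys_s.solve(step_starts + retry, tol)
            if u_s is None or res_s > tol:
                break
            u_prev = u_s
        else:
            best_u, best_res = system.solve([u_prev], tol)

    if best_u is None or best_res > tol:
        raise RuntimeError(
            f"mirrored solver failed: best residual max-norm {best_res:.3g}"
        )
    x, b, eta, d11, Dmid, L, mu_half = system.build(best_u)
    Sigma_half = np.zeros((n, n))
    Sigma_half[0, 0] = d11**2
    if n > 1:
        Sigma_half[1:, 1:] = Dmid
    dist = 2.0 * math.sqrt(float(np.sum(b**2)) + x**2)
    return MirroredSolution(
        x=float(x),
        b=np.asarray(b, dtype=float),
        eta=np.asarray(eta, dtype=float),
        d11=float(d11),
        Dmid=Dmid,
        distance=dist,
        residual=best_res,
        P=P,
        mu_half=mu_half,
        Sigma_half=Sigma_half,
        tangent=_arrowhead(float(x), np.asarray(b, dtype=float)),
    )


def mirrored_geodesic(sol: MirroredSolution, theta1: Gaussian, t: float) -> Gaussian:
    """Evaluate the mirrored geodesic at t in [-1, 1] (gamma(-1/+1) = endpoints).

    The closed-form curve in natural coordinates is mapped back through the
    midpoint isometry and the canonical-frame rotation.  Values of t outside
    [-1, 1] extend the geodesic beyond the endpoints.
    """
    n = theta1.dim
    nc = geodesic_natural(sol.tangent, t)
    bar = from_natural(nc)
    L = np.zeros((n, n))
    L[0, 0] = sol.d11
    if n > 1:
        L[1:, 1:] = spd_function(sol.Dmid, "sqrt")
    # psi^{-1}: (mu, Sigma) -> (L mu + mu_half, L Sigma L)
    g = Gaussian(L @ bar.mu + sol.mu_half, L @ bar.sigma @ L.T)
    # undo the canonical rotation
    return apply_isometry(AffineIsometry(np.zeros(n), sol.P.T), g)


# --- dispatcher --------------------------------------------------------------

def _is_diag_eigenmean_pair(theta1: Gaussian, theta2: Gaussian) -> bool:
    for theta in (theta1, theta2):
        off = theta.sigma - np.diag(np.diag(theta.sigma))
        if np.abs(off).max() > 1e-9 * max(np.linalg.norm(theta.sigma), 1.0):
            return False
        if theta.dim > 1 and np.abs(theta.mu[1:]).max() > 1e-9 * max(
            np.abs(theta.mu).max(), 1.0
        ):
            return False
    return True


def fisher_rao(theta1: Gaussian, theta2: Gaussian) -> tuple[float, str]:
    """Fisher-Rao distance routed to the cheapest exact method available.

    Returns ``(distance, tag)`` with tag in {"identical", "common-mean",
    "common-sigma", "diag-eigenmean", "mirrored", "shooting"}.
    """
    if theta1.dim != theta2.dim:
        raise ValueError("dimension mismatch")
    if theta1.close_to(theta2):
        return 0.0, "identical"
    if np.allclose(theta1.mu, theta2.mu, atol=1e-9, rtol=1e-9):
        return dist_common_mean(theta1, theta2), "common-mean"
    scale = max(np.linalg.norm(theta1.sigma), 1.0)
    if np.linalg.norm(theta1.sigma - theta2.sigma) <= SIGMA_EQ_TOL * scale:
        return dist_common_sigma(theta1, theta2), "common-sigma"
    if _is_diag_eigenmean_pair(theta1, theta2):
        return dist_diag_eigenmean(theta1, theta2), "diag-eigenmean"
    if is_mirrored(theta1, theta2):
        return mirrored_solve(theta1, theta2).distance, "mirrored"
    return geodesic_shooting(theta1, theta2).distance, "shooting"
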