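"""Exponential families over a lattice base distribution.

For a base distribution rho on a truncated integer lattice, the cumulant
generating function (CGF) is

    psi(theta) = log sum_n rho_n exp(theta . n),

convex in the tilt coordinate theta (z_i = exp(theta_i)).  This module
computes psi and its derivative tensors by exact weighted summation over the
lattice (never sampling, never finite differences, which appear only as
cross-checks in the test-suite): the mean n(theta) = grad psi, the Fisher
metric g = Hess psi = tilted covariance, and the totally symmetric cubic
(Amari-Chentsov) tensor T = third cumulant tensor.  The Legendre transform
psi*(n) = sup_theta [theta.n - psi(theta)] is the large-deviation function;
it is computed by damped Newton iteration on the concave dual.

Conserved quantities of the underlying dynamics appear here as flat
directions of psi and zero eigenvalues of g; degenerate directions are
handled with a pseudo-inverse at eigenvalue threshold 1e-10 and reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .jump_process import LatticeDistribution

__all__ = [
    "TiltedPoint",
    "LegendrePair",
    "ConnectionData",
    "cgf_and_mean",
    "tilt",
    "legendre_ldf",
    "cubic_tensor",
    "psi_divergence",
    "pythagorean_sensitivity",
]

#: eigenvalue threshold below which a Fisher direction counts as degenerate
DEGENERATE_EIG_TOL = 1e-10


def _as_theta(theta, D: int) -> np.ndarray:
    th = np.atleast_1d(np.asarray(theta, dtype=float))
    if th.shape != (D,):
        raise ValueError(f"theta must have length {D}, got shape {th.shape}")
    if not np.all(np.isfinite(th)):
        raise ValueError("theta components must be finite")
    return th


def _tilted_log_weights(rho: LatticeDistribution, theta: np.ndarray):
    """(psi, normalised tilted log-probabilities) at theta."""
    logrho = np.full(rho.probs.shape, -np.inf)
    pos = rho.probs > 0
    logrho[pos] = np.log(rho.probs[pos])
    a = logrho + rho.states @ theta
    psi = logsumexp(a)
    return psi, a - psi


@dataclass
class TiltedPoint:
    """One point of the exponential family: tilt, CGF value, mean, Fisher metric."""

    theta: np.ndarray
    psi: float
    mean: np.ndarray
    fisher: np.ndarray

    def degenerate_directions(self) -> np.ndarray:
        """Orthonormal eigenvectors of g with eigenvalue below threshold."""
        w, v = np.linalg.eigh(self.fisher)
        return v[:, np.abs(w) < DEGENERATE_EIG_TOL * max(1.0, np.max(np.abs(w)))]

    def to_json(self) -> str:
        return json.dumps(
            {
                "theta": self.theta.tolist(),
                "psi": self.psi,
                "mean": self.mean.tolist(),
                "fisher": self.fisher.tolist(),
            }
        )


@dataclass
class LegendrePair:
    """Legendre-dual data at a mean value n: psi*(n), theta(n), inverse metric."""

    n: np.ndarray
    psi_star: float
    theta_of_n: np.ndarray
    inverse_metric: np.ndarray
    degenerate_subspace: np.ndarray  # columns span ker g at theta(n)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n": self.n.tolist(),
                "psi_star": self.psi_star,
                "theta_of_n": self.theta_of_n.tolist(),
                "inverse_metric": self.inverse_metric.tolist(),
                "degenerate_dimension": int(self.degenerate_subspace.shape[1]),
            }
        )


@dataclass
class ConnectionData:
    """Cubic tensor T_kij and the dually-flat connection pair in theta coordinates.

    In exponential coordinates the e-connection vanishes (Gamma^D = 0) and the
    m-connection coefficients equal the cubic tensor (Gamma^D* = T).
    """

    cubic: np.ndarray

    @property
    def gamma_flat(self) -> np.ndarray:
        return np.zeros_like(self.cubic)

    @property
    def gamma_dual(self) -> np.ndarray:
        return self.cubic


def cgf_and_mean(rho: LatticeDistribution, theta) -> TiltedPoint:
    """CGF value, tilted mean and Fisher metric by exact lattice summation."""
    th = _as_theta(theta, rho.truncation.D)
    psi, logw = _tilted_log_weights(rho, th)
    w = np.exp(logw)
    mean = w @ rho.states
    dev = rho.states - mean
    fisher = (dev * w[:, None]).T @ dev
    fisher = 0.5 * (fisher + fisher.T)
    return TiltedPoint(th, float(psi), mean, fisher)


def tilt(rho: LatticeDistribution, theta) -> LatticeDistribution:
    """Exponentially tilted distribution rho_n exp(theta.n - psi)."""
    th = _as_theta(theta, rho.truncation.D)
    _, logw = _tilted_log_weights(rho, th)
    return LatticeDistribution(rho.truncation, np.exp(logw), rho.leaked_mass)


def legendre_ldf(rho: LatticeDistribution, n, theta0=None, grad_tol: float = 1e-9,
                 max_iter: int = 200) -> LegendrePair:
    """Large-deviation function psi*(n) by damped Newton on the concave dual.

    ``n`` must lie strictly inside the componentwise range of the support of
    rho (and on the correct conserved shell if the family is degenerate);
    otherwise the gradient cannot be driven to zero and an ``unreachable
    mean`` error is raised.  Falls back to coordinatewise bracketed line
    search if Newton stalls.
    """
    D = rho.truncation.D
    n = np.atleast_1d(np.asarray(n, dtype=float))
    if n.shape != (D,):
        raise ValueError(f"n must have length {D}")
    support = rho.states[rho.probs > 0]
    lo, hi = support.min(axis=0), support.max(axis=0)
    fixed = lo == hi  # componentwise-degenerate support
    if np.any((n <= lo) & ~fixed) or np.any((n >= hi) & ~fixed) or np.any(n[fixed] != lo[fixed]):
        raise ValueError(
            f"unreachable mean: n={n} outside open support range ({lo}, {hi})"
        )

    theta = np.zeros(D) if theta0 is None else _as_theta(theta0, D)
    tp = cgf_and_mean(rho, theta)
    for _ in range(max_iter):
        grad = n - tp.mean  # gradient of the concave dual objective
        # project out exactly-degenerate directions (conserved shells):
        # along ker g the gradient is constant and must already vanish there
        w, v = np.linalg.eigh(tp.fisher)
        big = np.abs(w) > DEGENERATE_EIG_TOL * max(1.0, np.max(np.abs(w)))
        grad_dyn = v[:, big].T @ grad
        grad_deg = grad - v[:, big] @ grad_dyn
        if np.max(np.abs(grad_deg)) > 1e-6:
            raise ValueError(
                "unreachable mean: requested n violates a conserved quantity "
                f"of the base distribution (residual {np.max(np.abs(grad_deg)):.2e})"
            )
        if np.max(np.abs(grad)) < grad_tol or (big.any() and np.max(np.abs(grad_dyn)) < grad_tol):
            break
        step = v[:, big] @ (grad_dyn / w[big])
        # damped Newton: halve until the dual objective does not decrease
        obj = theta @ n - tp.psi
        lam = 1.0
        for _ in range(60):
            cand = theta + lam * step
            tp_c = cgf_and_mean(rho, cand)
            if cand @ n - tp_c.psi >= obj - 1e-15:
                theta, tp = cand, tp_c
                break
            lam *= 0.5
        else:  # pragma: no cover - coordinatewise fallback
            theta, tp = _coordinate_search(rho, n, theta)
    else:
        raise RuntimeError("Legendre maximisation did not converge")

    w, v = np.linalg.eigh(tp.fisher)
    big = np.abs(w) > DEGENERATE_EIG_TOL * max(1.0, np.max(np.abs(w)))
    inv = (v[:, big] / w[big]) @ v[:, big].T  # pseudo-inverse on the dynamical subspace
    return LegendrePair(
        n=n,
        psi_star=float(theta @ n - tp.psi),
        theta_of_n=theta,
        inverse_metric=inv,
        degenerate_subspace=v[:, ~big],
    )


def _coordinate_search(rho, n, theta):  # pragma: no cover - rarely taken
    from scipy.optimize import minimize_scalar

    for i in range(len(theta)):
        def neg_dual(x, i=i):
            th = theta.copy()
            th[i] = x
            return -(th @ n - cgf_and_mean(rho, th).psi)

        res = minimize_scalar(neg_dual, bracket=(theta[i] - 1.0, theta[i] + 1.0))
        theta[i] = res.x
    return theta, cgf_and_mean(rho, theta)


def cubic_tensor(rho: LatticeDistribution, theta) -> ConnectionData:
    """Amari-Chentsov tensor T_kij = third central moments of the tilted law."""
    th = _as_theta(theta, rho.truncation.D)
    _, logw = _tilted_log_weights(rho, th)
    w = np.exp(logw)
    mean = w @ rho.states
    dev = rho.states - mean
    T = np.einsum("s,sk,si,sj->kij", w, dev, dev, dev)
    # symmetrise representation noise
    T = (T + T.transpose(0, 2, 1) + T.transpose(1, 0, 2)
         + T.transpose(1, 2, 0) + T.transpose(2, 0, 1) + T.transpose(2, 1, 0)) / 6.0
    return ConnectionData(T)


def psi_divergence(rho: LatticeDistribution, theta, eta_point) -> float:
    """Bregman divergence of psi between the theta-tilt and the eta-tilt.

    D_psi(theta : eta) = psi(theta) - psi(eta) - n(eta) . (theta - eta),
    which equals KL(rho_eta || rho_theta) of the two tilted distributions.
    """
    D = rho.truncation.D
    th = _as_theta(theta, D)
    et = _as_theta(eta_point, D)
    tp_th = cgf_and_mean(rho, th)
    tp_et = cgf_and_mean(rho, et)
    return float(tp_th.psi - tp_et.psi - tp_et.mean @ (th - et))


def pythagorean_sensitivity(rho_family, n0, theta, step: float = 1e-4) -> np.ndarray:
    """Sensitivity matrix dn_i(theta, n0)/dn0_j of a base-distribution family.

    ``rho_family(n0) -> LatticeDistribution`` indexes the family (Poisson or
    binomial constructors).  Central finite differences in n0; this equals
    the mixed Fisher inner product < d/d theta_i , d/d n0_j >.
    """
    n0 = np.atleast_1d(np.asarray(n0, dtype=float))
    D = len(n0)
    out = np.empty((D, D))
    for j in range(D):
        e = np.zeros(D)
        e[j] = step
        mp = cgf_and_mean(rho_family(n0 + e), theta).mean
        mm = cgf_and_mean(rho_family(n0 - e), theta).mean
        out[:, j] = (mp - mm) / (2 * step)
    return out
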