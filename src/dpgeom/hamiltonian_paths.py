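"""Stationary-path (WKB / eikonal) dynamics of jump-process generating functions.

The generator of a mass-action jump process, acting on moment generating
functions, becomes at leading exponential order a classical Hamiltonian on
phase space, the *Liouville function*

    L(phi+, phi) = sum_r k_r (prod_i phi+_i^{y_ri} - prod_i phi+_i^{ybar_ri})
                   * prod_i phi_i^{y_ri}

in coherent-state coordinates, or equivalently in number-potential
coordinates (phi+ = e^theta, phi = e^-theta n)

    L(theta, n) = sum_r k_r (1 - e^{theta.(ybar_r - y_r)}) prod_i n_i^{y_ri}.

Stationary trajectories of the generating-function action solve

    dtheta_i/dt = dL/dn_i,     dn_i/dt = -dL/dtheta_i,

with the final tilt phi+_T = z imposed by the generating-function argument
and the initial mean n_0 = grad psi_0(theta_0) supplied by the initial CGF;
the two conditions are closed by shooting on theta_0.  Along solutions L is
conserved, phase-space volume is conserved (Liouville's theorem), the
evolved large-deviation function satisfies the Hamilton-Jacobi equation
d psi*/dt = L(d psi*/dn, n), and the inner product of dual tangent fields
(final-tilt variations transported backward, base-distribution variations
forward) is an invariant of motion.

All derivatives of L are exact: the Liouville function of a mass-action
model is polynomial in coherent-state fields, and is differentiated
symbolically (sympy) once per model, then compiled to numpy callables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import sympy as sp
from scipy.integrate import cumulative_simpson, solve_ivp

from .jump_process import JumpProcessSpec

__all__ = [
    "LiouvilleFunction",
    "PhaseTrajectory",
    "TangentFields",
    "AdjointCoordinates",
    "InitialCGF",
    "build_liouville",
    "stationary_path_ode",
    "solve_bvp",
    "hamilton_jacobi_residual",
    "propagate_tangents",
    "liouville_volume_check",
    "adjoint_transform",
    "mean_field_steady_state",
    "poisson_initial",
    "multinomial_initial",
    "lagrangian_dual",
    "phase_divergence",
    "monodromy_matrix",
    "wigner_split_invariance",
]

_IVP_OPTS = dict(method="DOP853", rtol=1e-10, atol=1e-12)


# ---------------------------------------------------------------------------
# Liouville function


class LiouvilleFunction:
    """Phase-space Hamiltonian of a mass-action jump process, both charts.

    Exposes compiled callables (all accepting length-D arrays):

    ==================  =====================================================
    ``np_value(th,n)``   L in number-potential coordinates
    ``np_dth, np_dn``    exact gradients
    ``np_dthdn`` etc.    exact Hessian blocks (d2 L / dtheta_i dn_j, ...)
    ``cs_value(pd,p)``   L in coherent-state coordinates (phi+, phi)
    ``cs_dpd, cs_dp``    coherent-state gradients
    ==================  =====================================================
    """

    def __init__(self, spec: JumpProcessSpec):
        self.spec = spec
        D = spec.D
        self.D = D
        th = sp.symbols(f"th0:{D}", real=True)
        n = sp.symbols(f"n0:{D}", positive=True)
        pd = sp.symbols(f"pd0:{D}", positive=True)
        p = sp.symbols(f"p0:{D}", positive=True)

        L_cs = sp.Integer(0)
        for r in spec.reactions:
            mon_y = sp.prod([pd[i] ** r.reactants[i] for i in range(D)])
            mon_ybar = sp.prod([pd[i] ** r.products[i] for i in range(D)])
            mon_phi = sp.prod([p[i] ** r.reactants[i] for i in range(D)])
            L_cs += r.rate * (mon_y - mon_ybar) * mon_phi
        subs = {pd[i]: sp.exp(th[i]) for i in range(D)}
        subs.update({p[i]: sp.exp(-th[i]) * n[i] for i in range(D)})
        L_np = sp.expand(L_cs.subs(subs))

        self._sym = dict(th=th, n=n, pd=pd, p=p, L_cs=L_cs, L_np=L_np)

        def lam(expr, args):
            return sp.lambdify(args, expr, modules="numpy")

        grad = lambda e, v: sp.Matrix([sp.diff(e, x) for x in v])
        hess = lambda e, v, w: sp.Matrix(
            [[sp.diff(e, x, y) for y in w] for x in v]
        )

        a_np = (th, n)
        self.np_value = lam(L_np, a_np)
        self.np_dth = lam(grad(L_np, th), a_np)
        self.np_dn = lam(grad(L_np, n), a_np)
        self.np_dthdn = lam(hess(L_np, th, n), a_np)   # [i,j] = d2L/dth_i dn_j
        self.np_dthdth = lam(hess(L_np, th, th), a_np)
        self.np_dndn = lam(hess(L_np, n, n), a_np)

        a_cs = (pd, p)
        self.cs_value = lam(L_cs, a_cs)
        self.cs_dpd = lam(grad(L_cs, pd), a_cs)
        self.cs_dp = lam(grad(L_cs, p), a_cs)
        self.cs_dpddp = lam(hess(L_cs, pd, p), a_cs)
        self.cs_dpdpd = lam(hess(L_cs, p, pd), a_cs)

        self._eta_cache: dict[tuple, dict] = {}

    # -- number-potential chart -------------------------------------------
    def value(self, theta, n) -> float:
        return float(self.np_value(np.asarray(theta, float), np.asarray(n, float)))

    def velocity(self, theta, n):
        """Hamiltonian vector field (dtheta/dt, dn/dt) in the (theta, n) chart."""
        theta = np.asarray(theta, float)
        n = np.asarray(n, float)
        return (
            np.asarray(self.np_dn(theta, n), float).ravel(),
            -np.asarray(self.np_dth(theta, n), float).ravel(),
        )

    def velocity_cs(self, phi_dag, phi):
        """Hamiltonian vector field (dphi+/dt, dphi/dt) in coherent-state coordinates."""
        pd = np.asarray(phi_dag, float)
        p = np.asarray(phi, float)
        return (
            np.asarray(self.cs_dp(pd, p), float).ravel(),
            -np.asarray(self.cs_dpd(pd, p), float).ravel(),
        )

    # -- adjoint (eta) chart ----------------------------------------------
    def eta_chart(self, nss):
        """Compiled derivatives of the descaled Liouville function L~(n, eta).

        Coordinates are eta_i = log(phi_i / nss_i); for a time-independent
        generator L~ equals L pointwise under theta = log(n/nss) - eta.
        """
        key = tuple(np.asarray(nss, float))
        if key not in self._eta_cache:
            D = self.D
            n = self._sym["n"]
            eta = sp.symbols(f"eta0:{D}", real=True)
            subs = {
                self._sym["th"][i]: sp.log(n[i] / sp.Float(key[i], 30)) - eta[i]
                for i in range(D)
            }
            L_eta = sp.simplify(self._sym["L_np"].subs(subs))
            args = (n, eta)
            grad = lambda e, v: sp.Matrix([sp.diff(e, x) for x in v])
            self._eta_cache[key] = dict(
                value=sp.lambdify(args, L_eta, modules="numpy"),
                dn=sp.lambdify(args, grad(L_eta, n), modules="numpy"),
                deta=sp.lambdify(args, grad(L_eta, eta), modules="numpy"),
                detadn=sp.lambdify(
                    args,
                    sp.Matrix([[sp.diff(L_eta, e_, n_) for n_ in n] for e_ in eta]),
                    modules="numpy",
                ),
            )
        return self._eta_cache[key]


def build_liouville(spec: JumpProcessSpec, check_seed: int = 0) -> LiouvilleFunction:
    """Build L from a model spec and verify probability conservation
    L(phi+ = 1, phi) = 0 on random phi."""
    L = LiouvilleFunction(spec)
    rng = np.random.default_rng(check_seed)
    ones = np.ones(L.D)
    for _ in range(5):
        phi = rng.uniform(0.1, 5.0, size=L.D)
        val = float(L.cs_value(ones, phi))
        if abs(val) > 1e-10 * (1 + np.abs(phi).max()):
            raise AssertionError(f"L(1, phi) = {val} != 0: conservation violated")
    return L


def stationary_path_ode(L: LiouvilleFunction, state, chart: str = "number-potential"):
    """Hamiltonian phase velocity at ``state = (q, p)`` in the requested chart.

    ``chart`` is ``"number-potential"`` (state = (theta, n)) or
    ``"coherent"`` (state = (phi+, phi)).
    """
    q, p = state
    if chart in ("number-potential", "np"):
        return L.velocity(q, p)
    if chart in ("coherent", "cs"):
        return L.velocity_cs(q, p)
    raise ValueError(f"unknown chart {chart!r}")


def phase_divergence(L: LiouvilleFunction, phi_dag, phi) -> float:
    """Divergence of the coherent-state Hamiltonian field; identically 0."""
    pd = np.asarray(phi_dag, float)
    p = np.asarray(phi, float)
    a = np.asarray(L.cs_dpddp(pd, p), float)   # d2L/dpd_i dp_j -> d(dphi+_i/dt)/dpd...
    b = np.asarray(L.cs_dpdpd(pd, p), float)
    # d(dphi+_i/dt)/dphi+_i = d2L/dp_i dpd_i ; d(dphi_i/dt)/dphi_i = -d2L/dpd_i dp_i
    return float(np.trace(a) - np.trace(b.T))


# ---------------------------------------------------------------------------
# initial CGFs


class InitialCGF:
    """Initial-time cumulant generating function psi_0(theta) with gradient."""

    def __init__(self, fn, grad=None, name: str = "custom"):
        self._fn = fn
        self._grad = grad
        self.name = name

    def __call__(self, theta) -> float:
        return float(self._fn(np.asarray(theta, float)))

    def grad(self, theta, h: float = 1e-6) -> np.ndarray:
        theta = np.asarray(theta, float)
        if self._grad is not None:
            return np.asarray(self._grad(theta), float)
        out = np.empty_like(theta)
        for i in range(len(theta)):
            e = np.zeros_like(theta)
            e[i] = h
            out[i] = (self._fn(theta + e) - self._fn(theta - e)) / (2 * h)
        return out

    def hessian(self, theta, h: float = 1e-5) -> np.ndarray:
        theta = np.asarray(theta, float)
        D = len(theta)
        out = np.empty((D, D))
        for j in range(D):
            e = np.zeros(D)
            e[j] = h
            out[:, j] = (self.grad(theta + e) - self.grad(theta - e)) / (2 * h)
        return 0.5 * (out + out.T)


def poisson_initial(means) -> InitialCGF:
    m = np.atleast_1d(np.asarray(means, float))
    return InitialCGF(
        lambda th: float(m @ (np.exp(th) - 1.0)),
        grad=lambda th: m * np.exp(th),
        name=f"poisson({m.tolist()})",
    )


def multinomial_initial(N: int, nu) -> InitialCGF:
    """CGF of a multinomial/binomial with N trials and cell fractions nu."""
    nu = np.atleast_1d(np.asarray(nu, float))
    if abs(nu.sum() - 1.0) > 1e-12:
        raise ValueError("cell fractions must sum to 1")

    def fn(th):
        return float(N * np.log(nu @ np.exp(th)))

    def grad(th):
        w = nu * np.exp(th)
        return N * w / w.sum()

    return InitialCGF(fn, grad=grad, name=f"multinomial(N={N})")


def mean_field_steady_state(L: LiouvilleFunction, n_guess, t_relax: float = 200.0):
    """Deterministic steady state: relax the mass-action ODE dn/dt = -dL/dtheta|_0.

    Relaxation (rather than root finding) automatically stays on the
    conserved-quantity shell selected by ``n_guess``.
    """
    zero = np.zeros(L.D)

    def rhs(t, n):
        return L.velocity(zero, n)[1]

    sol = solve_ivp(rhs, [0, t_relax], np.asarray(n_guess, float), **_IVP_OPTS)
    nss = sol.y[:, -1]
    if np.max(np.abs(rhs(0.0, nss))) > 1e-8 * (1 + np.abs(nss).max()):
        raise RuntimeError("mean-field ODE did not relax to a steady state")
    return nss


# ---------------------------------------------------------------------------
# trajectories


@dataclass
class PhaseTrajectory:
    """A solved stationary path with diagnostics.

    ``psi_running[k]`` is the stationary-point CGF value accumulated along
    the path up to ``t[k]`` (psi_t(theta_t) = psi_0 + int (theta' n - L));
    ``action`` is the Doi-Peliti action S = int(-theta' n + L), so
    psi_T = psi_0(theta_0) - S.
    """

    t: np.ndarray
    theta: np.ndarray           # (n_t, D)
    n: np.ndarray               # (n_t, D)
    action: float
    psi_running: np.ndarray
    L_values: np.ndarray
    diagnostics: dict = field(default_factory=dict)
    liouville: LiouvilleFunction = None
    psi0: InitialCGF = None
    _sol: object = field(default=None, repr=False)

    @property
    def phi_dag(self) -> np.ndarray:
        return np.exp(self.theta)

    @property
    def phi(self) -> np.ndarray:
        return np.exp(-self.theta) * self.n

    def interp(self, t: float):
        """(theta, n) at arbitrary time from the dense ODE solution."""
        y = self._sol.sol(t)
        D = self.theta.shape[1]
        return y[:D], y[D : 2 * D]

    def to_csv(self, path) -> None:
        import pandas as pd

        D = self.theta.shape[1]
        cols = {"t": self.t}
        for i in range(D):
            cols[f"theta_{i+1}"] = self.theta[:, i]
        for i in range(D):
            cols[f"n_{i+1}"] = self.n[:, i]
        for i in range(D):
            cols[f"phi_dag_{i+1}"] = self.phi_dag[:, i]
        for i in range(D):
            cols[f"phi_{i+1}"] = self.phi[:, i]
        cols["L_value"] = self.L_values
        pd.DataFrame(cols).to_csv(path, index=False)


def _integrate(L: LiouvilleFunction, theta0, n0, T, t_eval=None, quadratures=False):
    D = L.D

    if quadratures:
        def rhs(t, y):
            th, n = y[:D], y[D : 2 * D]
            dth, dn = L.velocity(th, n)
            lval = L.value(th, n)
            dpsi = dth @ n - lval
            return np.concatenate([dth, dn, [-dpsi], [dpsi]])

        y0 = np.concatenate([theta0, n0, [0.0], [0.0]])
    else:
        def rhs(t, y):
            dth, dn = L.velocity(y[:D], y[D:])
            return np.concatenate([dth, dn])

        y0 = np.concatenate([theta0, n0])
    return solve_ivp(rhs, [0, T], y0, t_eval=t_eval, dense_output=True, **_IVP_OPTS)


def solve_bvp(
    L: LiouvilleFunction,
    psi0: InitialCGF,
    z,
    T: float,
    n_steps: int = 400,
    theta0_guess=None,
    max_newton: int = 40,
) -> PhaseTrajectory:
    """Two-point boundary problem by single shooting with Newton on theta_0.

    Boundary data: final tilt phi+_T = z (theta_T = log z) and initial mean
    n_0 = grad psi_0(theta_0).  The Newton iteration drives
    ||theta_T(theta_0) - log z||_inf below 1e-10 (so ||phi+_T - z|| well
    below 1e-8); bounded restarts from damped guesses, then a hard error
    with the residual.
    """
    if T <= 0:
        raise ValueError("horizon T must be positive")
    D = L.D
    z = np.atleast_1d(np.asarray(z, float))
    log_z = np.log(z)

    def shoot(theta0):
        n0 = psi0.grad(theta0)
        sol = _integrate(L, theta0, n0, T)
        return sol.y[:D, -1] - log_z, sol

    guesses = [log_z * np.exp(-T), log_z, np.zeros(D), 0.5 * log_z]
    if theta0_guess is not None:
        guesses.insert(0, np.asarray(theta0_guess, float))

    theta0 = None
    for g in guesses:
        th = g.copy()
        try:
            res, _ = shoot(th)
        except Exception:
            continue
        ok = True
        for _ in range(max_newton):
            if np.max(np.abs(res)) < 1e-10:
                break
            # finite-difference Jacobian of the shooting map
            J = np.empty((D, D))
            h = 1e-7
            for j in range(D):
                e = np.zeros(D)
                e[j] = h
                rp, _ = shoot(th + e)
                J[:, j] = (rp - res) / h
            try:
                step = np.linalg.solve(J, -res)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(J, -res, rcond=None)[0]
            lam, improved = 1.0, False
            for _ in range(25):
                cand = th + lam * step
                try:
                    rc, _ = shoot(cand)
                except Exception:
                    lam *= 0.5
                    continue
                if np.max(np.abs(rc)) < np.max(np.abs(res)):
                    th, res, improved = cand, rc, True
                    break
                lam *= 0.5
            if not improved:
                ok = False
                break
        if ok and np.max(np.abs(res)) < 1e-10:
            theta0 = th
            break
    if theta0 is None:
        raise RuntimeError(
            f"shooting Newton failed: final residual {np.max(np.abs(res)):.3e} "
            "(theta_T - log z); try a better theta0_guess or a shorter horizon"
        )

    n0 = psi0.grad(theta0)
    t_eval = np.linspace(0.0, T, n_steps + 1)
    sol = _integrate(L, theta0, n0, T, t_eval=t_eval, quadratures=True)
    theta = sol.y[:D].T
    n = sol.y[D : 2 * D].T
    S = float(sol.y[2 * D, -1])
    psi_run = psi0(theta0) + sol.y[2 * D + 1]
    Lv = np.array([L.value(theta[k], n[k]) for k in range(len(t_eval))])
    diag = {
        "bvp_residual": float(np.max(np.abs(sol.y[:D, -1] - log_z))),
        "L_drift": float(np.max(np.abs(Lv - Lv[0]))),
        "hj_first_relation": None,
        "symplectic_residual": None,
    }
    return PhaseTrajectory(
        t=t_eval,
        theta=theta,
        n=n,
        action=S,
        psi_running=psi_run,
        L_values=Lv,
        diagnostics=diag,
        liouville=L,
        psi0=psi0,
        _sol=sol,
    )


def wigner_split_invariance(traj: PhaseTrajectory) -> float:
    """Time-invariance of the split stationary-point CGF (phase-space density).

    Splitting the stationary path at any interior time t and composing the
    accumulated CGF psi_t(theta_t) with the remaining action integral must
    reproduce psi_T independently of t; returns the maximum deviation.  The
    remaining integral is recomputed by Simpson quadrature of theta' n - L on
    the output grid, an independent route from the ODE quadrature.
    """
    L = traj.liouville
    integrand = np.array(
        [
            L.np_dn(traj.theta[k], traj.n[k]).ravel() @ traj.n[k] - traj.L_values[k]
            for k in range(len(traj.t))
        ],
        dtype=float,
    )
    cum = cumulative_simpson(integrand, x=traj.t, initial=0.0)
    tail = cum[-1] - cum  # integral from t to T
    psi_T = traj.psi_running[-1]
    return float(np.max(np.abs(traj.psi_running + tail - psi_T)))


def _theta_of_ndot(L: LiouvilleFunction, ndot, n, theta_guess, tol=1e-12):
    """Invert ndot = -dL/dtheta(theta, n) for theta by Newton iteration."""
    th = np.asarray(theta_guess, float).copy()
    for _ in range(80):
        F = -np.asarray(L.np_dth(th, n), float).ravel() - ndot
        if np.max(np.abs(F)) < tol:
            return th
        J = -np.asarray(L.np_dthdth(th, n), float)
        th = th + np.linalg.lstsq(J, -F, rcond=None)[0]
    raise RuntimeError("velocity-to-tilt inversion did not converge")


def lagrangian_dual(traj: PhaseTrajectory, directions=None, h: float = 1e-5,
                    sample_every: int = 50) -> dict:
    """Lagrange-Hamilton duality along the path.

    The Lagrangian Lagr(ndot, n) = [theta . ndot + L(theta, n)] at
    theta(ndot, n) is evaluated by Newton inversion of the velocity map
    ndot = -dL/dtheta.  Checks: the inversion recovers the trajectory tilt;
    dLagr/dndot = theta and dLagr/dn|_ndot = dL/dn|_theta, both by central
    finite differences of Lagr in the supplied velocity ``directions``
    (default: coordinate directions; conserved models must pass on-shell
    directions since off-shell velocities are unreachable).
    """
    L = traj.liouville
    D = L.D
    dirs = np.eye(D) if directions is None else np.atleast_2d(np.asarray(directions, float))
    invert_gap, grad_gap, force_gap = 0.0, 0.0, 0.0
    for k in range(0, len(traj.t), sample_every):
        th, n = traj.theta[k], traj.n[k]
        ndot = -np.asarray(L.np_dth(th, n), float).ravel()

        def lagr(v, n_):
            t_ = _theta_of_ndot(L, v, n_, th)
            return t_ @ v + L.value(t_, n_), t_

        _, th_back = lagr(ndot, n)
        invert_gap = max(invert_gap, float(np.max(np.abs(th_back - th))))
        dLdn = np.asarray(L.np_dn(th, n), float).ravel()
        for d in dirs:
            lp, _ = lagr(ndot + h * d, n)
            lm, _ = lagr(ndot - h * d, n)
            grad_gap = max(grad_gap, abs((lp - lm) / (2 * h) - th @ d))
            lp, _ = lagr(ndot, n + h * d)
            lm, _ = lagr(ndot, n - h * d)
            force_gap = max(force_gap, abs((lp - lm) / (2 * h) - dLdn @ d))
    return {"invert_gap": invert_gap, "grad_gap": grad_gap, "force_gap": force_gap}


# ---------------------------------------------------------------------------
# Hamilton-Jacobi diagnostics


def hamilton_jacobi_residual(
    traj: PhaseTrajectory,
    ldf_evolver,
    times=None,
    dt: float = 1e-3,
    flat_directions=None,
) -> dict:
    """Residual of d psi*/dt = L(d psi*/dn, n) along the trajectory.

    ``ldf_evolver(t, n) -> (psi_star, theta)`` must return the
    large-deviation function of the independently evolved distribution and
    its gradient at mean value n.  The time derivative is a central
    difference (step ``dt``), so the residual is second-order in dt.  Also
    reports the first Hamilton-Jacobi relation d psi*/dn = theta checked
    against the trajectory's own tilt; for models with conserved quantities
    theta is defined only up to the flat directions of the CGF, so columns
    of ``flat_directions`` are projected out of the comparison (L itself is
    flat along them and needs no gauge fixing).
    """
    L = traj.liouville
    T = traj.t[-1]
    if times is None:
        times = np.linspace(0.15 * T, 0.85 * T, 5)
    P = np.eye(L.D)
    if flat_directions is not None:
        F = np.atleast_2d(np.asarray(flat_directions, float))
        if F.shape[0] != L.D:
            F = F.T
        Q, _ = np.linalg.qr(F)
        P = P - Q @ Q.T
    res, theta_gap = [], []
    for t in times:
        th_t, n_t = traj.interp(t)
        _, theta_n = ldf_evolver(t, n_t)
        sp_, _ = ldf_evolver(t + dt, n_t)
        sm_, _ = ldf_evolver(t - dt, n_t)
        dpsidt = (sp_ - sm_) / (2 * dt)
        res.append(abs(dpsidt - L.value(theta_n, n_t)))
        theta_gap.append(np.max(np.abs(P @ (theta_n - th_t))))
    return {
        "max_residual": float(np.max(res)),
        "max_theta_gap": float(np.max(theta_gap)),
        "times": np.asarray(times),
    }


# ---------------------------------------------------------------------------
# tangent transport and Liouville volume


@dataclass
class TangentFields:
    """Dual tangent fields along a trajectory and their conserved pairing."""

    t: np.ndarray
    dtheta: np.ndarray          # (n_t, D): final-tilt variation, swept backward
    dn: np.ndarray              # (n_t, D): base-mean variation, swept forward
    deta: np.ndarray | None     # (n_t, D): base-coordinate variation (eta chart)
    inner: np.ndarray           # delta theta . delta n per time point

    @property
    def inner_drift(self) -> float:
        return float(np.max(np.abs(self.inner - self.inner[0])))


def propagate_tangents(
    traj: PhaseTrajectory,
    dtheta_T,
    deta_0=None,
    dn_0=None,
    nss=None,
) -> TangentFields:
    """Transport boundary variations along the linearised stationary-path flow.

    delta theta obeys (d/dt delta theta)^j = delta theta^i d2L/dtheta_i dn_j
    and is integrated backward from its final value; delta n obeys
    (d/dt delta n)_i = - delta n_j d2L/dn_j dtheta_i forward from its initial
    value.  Supply the initial base variation either directly as ``dn_0`` or
    as ``deta_0`` in the adjoint exponential coordinate, converted through
    the initial-family metric dn_0 = Hess psi_0(theta_0) . deta_0.  If
    ``nss`` is given, delta eta is additionally transported with the
    descaled generator L~ of the eta chart.
    """
    L = traj.liouville
    D = L.D
    dtheta_T = np.asarray(dtheta_T, float)
    if dn_0 is None:
        if deta_0 is None:
            raise ValueError("supply deta_0 or dn_0")
        g0 = traj.psi0.hessian(traj.theta[0])
        dn_0 = g0 @ np.asarray(deta_0, float)
    dn_0 = np.asarray(dn_0, float)

    def mixed(t):
        th, n = traj.interp(t)
        return np.asarray(L.np_dthdn(th, n), float)  # [i,j] = d2L/dth_i dn_j

    sol_th = solve_ivp(
        lambda t, v: v @ mixed(t),
        [traj.t[-1], 0.0],
        dtheta_T,
        t_eval=traj.t[::-1],
        **_IVP_OPTS,
    )
    dtheta = sol_th.y.T[::-1]

    sol_n = solve_ivp(
        lambda t, v: -mixed(t) @ v,
        [0.0, traj.t[-1]],
        dn_0,
        t_eval=traj.t,
        **_IVP_OPTS,
    )
    dn = sol_n.y.T

    deta = None
    if nss is not None and deta_0 is not None:
        chart = L.eta_chart(nss)

        def eta_of(t):
            th, n = traj.interp(t)
            return np.log(n / np.asarray(nss, float)) - th

        def rhs(t, v):
            th, n = traj.interp(t)
            m = np.asarray(chart["detadn"](n, eta_of(t)), float)
            return -(v @ m)

        sol_e = solve_ivp(rhs, [0.0, traj.t[-1]], np.asarray(deta_0, float),
                          t_eval=traj.t, **_IVP_OPTS)
        deta = sol_e.y.T

    inner = np.einsum("ki,ki->k", dtheta, dn)
    return TangentFields(traj.t.copy(), dtheta, dn, deta, inner)


def monodromy_matrix(traj: PhaseTrajectory) -> np.ndarray:
    """Linearisation of the time-T phase-space map, a 2D x 2D matrix in the
    ordering (theta, n), by integrating the variational equations."""
    L = traj.liouville
    D = L.D

    def rhs(t, y):
        th, n = traj.interp(t)
        A = np.asarray(L.np_dthdn(th, n), float)    # d2L/dth dn
        B = np.asarray(L.np_dndn(th, n), float)
        C = np.asarray(L.np_dthdth(th, n), float)
        M = y.reshape(2 * D, 2 * D)
        dth, dn = M[:D], M[D:]
        # columns of M are independent perturbation vectors
        ddth = A.T @ dth + B.T @ dn
        ddn = -C @ dth - A @ dn
        return np.vstack([ddth, ddn]).ravel()

    y0 = np.eye(2 * D).ravel()
    sol = solve_ivp(rhs, [0.0, traj.t[-1]], y0, **_IVP_OPTS)
    return sol.y[:, -1].reshape(2 * D, 2 * D)


def liouville_volume_check(traj: PhaseTrajectory, perturbation_basis) -> dict:
    """Liouville's theorem along a solved trajectory.

    (a) the phase-space divergence of the coherent-state Hamiltonian field
    vanishes at sampled trajectory points; (b) the monodromy matrix,
    restricted to the dynamical subspace spanned by ``perturbation_basis``
    (columns: theta-directions with nonzero Fisher eigenvalue; conserved
    directions are excluded), has determinant 1.
    """
    L = traj.liouville
    div = [
        abs(phase_divergence(L, traj.phi_dag[k], traj.phi[k]))
        for k in range(0, len(traj.t), max(1, len(traj.t) // 16))
    ]
    M = monodromy_matrix(traj)
    B = np.atleast_2d(np.asarray(perturbation_basis, float))
    if B.shape[0] != L.D:
        B = B.T
    D = L.D
    P = np.block([
        [B.T @ M[:D, :D] @ B, B.T @ M[:D, D:] @ B],
        [B.T @ M[D:, :D] @ B, B.T @ M[D:, D:] @ B],
    ])
    eigvals = np.linalg.eigvals(P)
    return {
        "max_divergence": float(np.max(div)),
        "restricted_monodromy": P,
        "restricted_det": float(np.real(np.linalg.det(P))),
        "eigenvalues": eigvals,
    }


# ---------------------------------------------------------------------------
# adjoint (descaled) coordinates


@dataclass
class AdjointCoordinates:
    """Baish-descaled fields and the adjoint exponential coordinate eta.

    varphi+_i = phi+_i nss_i, varphi_i = phi_i / nss_i, eta_i = log varphi_i;
    along any trajectory theta + eta = log(n / nss) componentwise.
    """

    t: np.ndarray
    varphi_dag: np.ndarray
    varphi: np.ndarray
    eta: np.ndarray
    L_tilde: np.ndarray
    max_L_mismatch: float
    max_eom_residual: float


def adjoint_transform(traj: PhaseTrajectory, nss, time_dependent: bool = False
                      ) -> AdjointCoordinates:
    """Descale a trajectory by the steady state nss and verify the eta chart.

    Checks that L~(n, eta) equals L(theta, n) pointwise (time-independent
    generators only) and that the transformed trajectory satisfies the
    eta-chart Hamiltonian equations dn/dt = +dL~/deta, deta/dt = -dL~/dn
    within 1e-6.
    """
    if time_dependent:
        raise NotImplementedError(
            "time-dependent generators are not supported: the d/dt log nss "
            "correction to L~ is excluded by design"
        )
    L = traj.liouville
    nss = np.asarray(nss, float)
    varphi_dag = traj.phi_dag * nss
    varphi = traj.phi / nss
    eta = np.log(varphi)
    chart = L.eta_chart(nss)
    Lt = np.array([float(chart["value"](traj.n[k], eta[k])) for k in range(len(traj.t))])
    mismatch = float(np.max(np.abs(Lt - traj.L_values)))

    # verify eta-chart equations of motion against time-derivatives of the path
    resid = 0.0
    for k in range(0, len(traj.t), max(1, len(traj.t) // 12)):
        t = traj.t[k]
        h = min(1e-5, traj.t[-1] / 1000)
        if t - h < 0 or t + h > traj.t[-1]:
            continue
        thp, npl = traj.interp(t + h)
        thm, nmn = traj.interp(t - h)
        ndot = (npl - nmn) / (2 * h)
        etadot = ((np.log(npl / nss) - thp) - (np.log(nmn / nss) - thm)) / (2 * h)
        pred_ndot = np.asarray(chart["deta"](traj.n[k], eta[k]), float).ravel()
        pred_etadot = -np.asarray(chart["dn"](traj.n[k], eta[k]), float).ravel()
        resid = max(
            resid,
            float(np.max(np.abs(ndot - pred_ndot))),
            float(np.max(np.abs(etadot - pred_etadot))),
        )
    return AdjointCoordinates(
        traj.t.copy(), varphi_dag, varphi, eta, Lt, mismatch, resid
    )
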