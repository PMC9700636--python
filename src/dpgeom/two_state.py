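"""Closed forms for N independent walkers hopping between two states.

The reaction a <-> b with rates k+ (a to b) and k- (b to a) acting on N
independent walkers preserves binomial occupation statistics exactly, so
every object of the large-deviation geometry — stationary paths, the
conserved phase-space density, the Fisher metric and its dual connections —
has an explicit formula.  Conventions:

* descaled time tau with dtau/dt = k+ + k-;
* steady-state fractions nu_ss_b = k+/(k+ + k-), nu_ss_a = 1 - nu_ss_b, and
  the offset coordinate nu_ss = (nu_ss_b - nu_ss_a)/2 in (-1/2, 1/2);
* base-distribution mean offset nu_bar (from the coherent-state fields phi),
  tilt offset nu_under (from phi+ referenced to the steady state), and the
  importance-distribution mean offset nu, all in (-1/2, 1/2);
* boundary data: nu_bar at tau = 0 and nu_under at tau = T.

The stationary-path flow is a pair of decoupled exponential laws

    nu_bar(tau) - nu_ss  = (nu_bar_0 - nu_ss)  e^{-tau}
    nu_under(tau) - nu_ss = (nu_under_T - nu_ss) e^{tau - T},

and all information quantities depend on the boundary data only through the
overlap parameter Lambda and the conserved density

    Lambda = (nu_bar_0 - nu_ss)(nu_under_T - nu_ss) / (1/4 - nu_ss^2),
    PhiHat0 = 1 / (1 + Lambda e^{-T}),      psi/N = -log PhiHat0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TwoStateParams",
    "TwoStateBoundary",
    "overlap_lambda",
    "phi0_and_invariant_cgf",
    "trajectories",
    "fisher_eigenvalue",
    "descaled_uv_and_volume",
    "coherent_hessian_defect",
    "covariant_derivatives",
    "uv_chart_jacobian",
    "uv_chart_monodromy",
    "uv_tangent_projection",
]

_ATANH = np.arctanh


@dataclass(frozen=True)
class TwoStateParams:
    """Rates and walker count, with the derived descaled steady state."""

    k_plus: float
    k_minus: float
    N: int = 1

    def __post_init__(self) -> None:
        if self.k_plus <= 0 or self.k_minus <= 0:
            raise ValueError("rates must be positive")
        if self.N < 1:
            raise ValueError("walker count must be >= 1")

    @property
    def nu_ss_b(self) -> float:
        return self.k_plus / (self.k_plus + self.k_minus)

    @property
    def nu_ss_a(self) -> float:
        return self.k_minus / (self.k_plus + self.k_minus)

    @property
    def nu_ss(self) -> float:
        return 0.5 * (self.nu_ss_b - self.nu_ss_a)

    @property
    def rate_sum(self) -> float:
        """dtau/dt: descaled time runs at the sum of the hop rates."""
        return self.k_plus + self.k_minus

    @property
    def theta_ss(self) -> float:
        """Tilt coordinate of the steady state, log(nu_ss_b / nu_ss_a)."""
        return float(np.log(self.nu_ss_b / self.nu_ss_a))

    @property
    def h_ss(self) -> float:
        """Reference value of the conserved-direction coordinate h."""
        return 0.5 * float(np.log(0.25 - self.nu_ss**2))


@dataclass(frozen=True)
class TwoStateBoundary:
    """Initial base mean offset, final tilt offset, and horizon in tau units."""

    nu_bar_0: float
    nu_under_T: float
    T: float

    def __post_init__(self) -> None:
        for v, nm in ((self.nu_bar_0, "nu_bar_0"), (self.nu_under_T, "nu_under_T")):
            if not -0.5 < v < 0.5:
                raise ValueError(f"{nm} must lie strictly inside (-1/2, 1/2)")
        if self.T <= 0:
            raise ValueError("horizon T must be positive")


def overlap_lambda(params: TwoStateParams, boundary: TwoStateBoundary) -> float:
    """Overlap parameter Lambda between initial base and final tilt data."""
    v = params.nu_ss
    return float(
        (boundary.nu_bar_0 - v) * (boundary.nu_under_T - v) / (0.25 - v**2)
    )


def phi0_and_invariant_cgf(
    params: TwoStateParams, boundary: TwoStateBoundary
) -> tuple[float, float]:
    """Conserved density PhiHat0 and the invariant scaled CGF psi/N.

    Also evaluates psi/N from the bracket form
    log[(nu_under_a/nu_ss_a) nu_bar_a + (nu_under_b/nu_ss_b) nu_bar_b]
    at tau = 0 and tau = T and asserts agreement within 1e-12; as T grows,
    PhiHat0 -> 1 and the extractable information vanishes.
    """
    lam = overlap_lambda(params, boundary)
    denom = 1.0 + lam * np.exp(-boundary.T)
    if denom <= 0:
        raise ValueError(
            f"1 + Lambda e^-T = {denom} <= 0: boundary data outside the "
            "domain of the stationary-path family"
        )
    phi0 = 1.0 / denom
    psi_over_N = -float(np.log(phi0))
    for tau in (0.0, boundary.T):
        nb, nu_u, _ = trajectories(params, boundary, np.array([tau]))
        bracket = _psi_bracket(params, float(nu_u[0]), float(nb[0]))
        if abs(bracket - psi_over_N) > 1e-12:
            raise AssertionError(
                f"invariant-CGF bracket at tau={tau} deviates: "
                f"{bracket} vs {psi_over_N}"
            )
    return float(phi0), psi_over_N


def _psi_bracket(params: TwoStateParams, nu_under: float, nu_bar: float) -> float:
    """psi/N = log[(nu_under_a/nu_ss_a) nu_bar_a + (nu_under_b/nu_ss_b) nu_bar_b]."""
    ua, ub = 0.5 - nu_under, 0.5 + nu_under
    ba, bb = 0.5 - nu_bar, 0.5 + nu_bar
    return float(np.log(ua / params.nu_ss_a * ba + ub / params.nu_ss_b * bb))


def trajectories(params: TwoStateParams, boundary: TwoStateBoundary, tau_grid):
    """Stationary-path laws nu_bar(tau), nu_under(tau) and the importance
    mean nu(tau).

    nu(tau) comes from the additive exponential-family form
    nu = (1/2) tanh((theta + eta + theta_ss)/2), with theta and eta
    recovered by inverting nu_under = (1/2) tanh((theta + theta_ss)/2) and
    nu_bar = (1/2) tanh((eta + theta_ss)/2).
    """
    tau = np.asarray(tau_grid, dtype=float)
    v = params.nu_ss
    nu_bar = v + (boundary.nu_bar_0 - v) * np.exp(-tau)
    nu_under = v + (boundary.nu_under_T - v) * np.exp(tau - boundary.T)
    th_ss = params.theta_ss
    theta = 2.0 * _ATANH(2.0 * nu_under) - th_ss
    eta = 2.0 * _ATANH(2.0 * nu_bar) - th_ss
    nu = 0.5 * np.tanh(0.5 * (theta + eta + th_ss))
    return nu_bar, nu_under, nu


def nu_of(params: TwoStateParams, nu_under: float, nu_bar: float) -> float:
    """Importance-distribution mean offset at a phase point (nu_under, nu_bar)."""
    A = _ATANH(2.0 * nu_under)
    B = _ATANH(2.0 * nu_bar)
    C = _ATANH(2.0 * params.nu_ss)
    return float(0.5 * np.tanh(A + B - C))


def fisher_eigenvalue(
    params: TwoStateParams,
    nu_under: float | None = None,
    nu_bar: float | None = None,
    theta: float | None = None,
    eta: float | None = None,
    phi0: float | None = None,
) -> dict:
    """Nonzero eigenvalue dnu/dtheta of the (scaled) Fisher metric, both forms.

    Coherent-data form: (1/4 - nu_under^2)(1/4 - nu_bar^2)/(1/4 - nu_ss^2)
    * PhiHat0^2, with PhiHat0 = 1/(1 + uv) from the phase point itself.
    Exponential-coordinate form: 1/4 - nu^2.  The two are asserted equal
    within 1e-10; the full 2x2 metric g/N in the (b, a) species basis is
    rank one with its zero eigenvalue along the conserved (1, 1) direction.
    """
    v = params.nu_ss
    th_ss = params.theta_ss
    if nu_under is None:
        if theta is None or eta is None:
            raise ValueError("supply (nu_under, nu_bar) or (theta, eta)")
        nu_under = float(0.5 * np.tanh(0.5 * (theta + th_ss)))
        nu_bar = float(0.5 * np.tanh(0.5 * (eta + th_ss)))
    if phi0 is None:
        uv = (nu_bar - v) * (nu_under - v) / (0.25 - v**2)
        phi0 = 1.0 / (1.0 + uv)
    coherent = (
        (0.25 - nu_under**2) * (0.25 - nu_bar**2) / (0.25 - v**2) * phi0**2
    )
    nu = nu_of(params, nu_under, nu_bar)
    exponential = 0.25 - nu**2
    if abs(coherent - exponential) > 1e-10:
        raise AssertionError(
            f"Fisher eigenvalue forms disagree: {coherent} vs {exponential}"
        )
    direction = np.array([1.0, -1.0])  # (b, a) basis
    g_over_N = exponential * np.outer(direction, direction)
    return {
        "eigenvalue": float(exponential),
        "coherent_form": float(coherent),
        "exponential_form": float(exponential),
        "nu": nu,
        "g_over_N": g_over_N,
        "zero_direction": np.array([1.0, 1.0]) / np.sqrt(2),
    }


# ---------------------------------------------------------------------------
# conserved volume integral (the Fig.-2 construction)


def descaled_uv(params: TwoStateParams, nu_under, nu_bar):
    """Fully descaled coherent coordinates u (base) and v (tilt)."""
    s = np.sqrt(0.25 - params.nu_ss**2)
    return (np.asarray(nu_bar) - params.nu_ss) / s, (
        np.asarray(nu_under) - params.nu_ss
    ) / s


def phi0_density(u, v):
    """Squared conserved density PhiHat0^2 = (1 + u v)^-2 at a phase point."""
    return (1.0 + np.asarray(u) * np.asarray(v)) ** -2.0


def descaled_uv_and_volume(
    params: TwoStateParams,
    boundary_rect,
    T: float,
    tau_grid,
    n_quad: int = 80,
) -> dict:
    """Transport a boundary rectangle along the flow and integrate the
    conserved density over its image at each time.

    ``boundary_rect = ((nu_under_T_lo, nu_under_T_hi), (nu_bar_0_lo,
    nu_bar_0_hi))``.  The flow maps the rectangle to a rectangle (the laws
    are affine), over which int dv du PhiHat0^2 is computed by Gauss-Legendre
    quadrature; the integral is an invariant of motion, and its per-tau
    values and maximum deviation are reported.
    """
    (ul, uh), (bl, bh) = boundary_rect
    tau = np.asarray(tau_grid, dtype=float)
    v_ss = params.nu_ss
    s = np.sqrt(0.25 - v_ss**2)
    x, wx = np.polynomial.legendre.leggauss(n_quad)
    vals = []
    for t in tau:
        # image of the rectangle at time t (componentwise affine flow)
        nu_u_lo = v_ss + (ul - v_ss) * np.exp(t - T)
        nu_u_hi = v_ss + (uh - v_ss) * np.exp(t - T)
        nu_b_lo = v_ss + (bl - v_ss) * np.exp(-t)
        nu_b_hi = v_ss + (bh - v_ss) * np.exp(-t)
        v_lo, v_hi = sorted(((nu_u_lo - v_ss) / s, (nu_u_hi - v_ss) / s))
        u_lo, u_hi = sorted(((nu_b_lo - v_ss) / s, (nu_b_hi - v_ss) / s))
        vg = 0.5 * (v_hi - v_lo) * x + 0.5 * (v_hi + v_lo)
        ug = 0.5 * (u_hi - u_lo) * x + 0.5 * (u_hi + u_lo)
        W = np.outer(wx, wx) * 0.25 * (v_hi - v_lo) * (u_hi - u_lo)
        vals.append(float(np.sum(W * phi0_density(ug[None, :], vg[:, None]))))
    vals = np.asarray(vals)
    return {
        "tau": tau,
        "integral": vals,
        "max_deviation": float(np.max(np.abs(vals - vals[0]))),
    }


def _vu_point(params: TwoStateParams, theta, n):
    """(v, u) descaled coordinates of a species-chart phase point (theta, n)."""
    s = np.sqrt(0.25 - params.nu_ss**2)
    za, zb = np.exp(theta[0]), np.exp(theta[1])
    wa, wb = za * params.nu_ss_a, zb * params.nu_ss_b
    nu_under = 0.5 * (wb - wa) / (wb + wa)
    phia, phib = np.exp(-theta[0]) * n[0], np.exp(-theta[1]) * n[1]
    nu_bar = 0.5 * (phib - phia) / (phib + phia)
    return np.array([(nu_under - params.nu_ss) / s, (nu_bar - params.nu_ss) / s])


def uv_chart_jacobian(params: TwoStateParams, theta, n, h: float = 1e-6) -> np.ndarray:
    """2x4 Jacobian d(v, u)/d(theta_a, theta_b, n_a, n_b) by central differences."""
    x = np.concatenate([np.asarray(theta, float), np.asarray(n, float)])
    J = np.zeros((2, 4))
    for j in range(4):
        e = np.zeros(4)
        e[j] = h
        J[:, j] = (
            _vu_point(params, x[:2] + e[:2], x[2:] + e[2:])
            - _vu_point(params, x[:2] - e[:2], x[2:] - e[2:])
        ) / (2 * h)
    return J


def uv_chart_monodromy(params: TwoStateParams, traj) -> np.ndarray:
    """Dynamical-block monodromy of a solved stationary path in the (v, u) chart.

    Projects the species-chart monodromy through the chart Jacobians at the
    two endpoints, with gauge-fixed inputs (pure tilt-difference and pure
    number-difference perturbations; the conserved directions decouple).
    For this model the result is diag(e^T, e^-T): tilt discrimination grows
    at exactly the rate base-distribution resolution decays, det = 1.
    """
    from .hamiltonian_paths import monodromy_matrix

    M = monodromy_matrix(traj)
    J0 = uv_chart_jacobian(params, traj.theta[0], traj.n[0])
    JT = uv_chart_jacobian(params, traj.theta[-1], traj.n[-1])
    E = np.array([[-0.5, 0.0], [0.5, 0.0], [0.0, -0.5], [0.0, 0.5]])
    inputs = J0 @ E
    outputs = JT @ M @ E
    return outputs @ np.linalg.inv(inputs)


def uv_tangent_projection(params: TwoStateParams, traj, tangents):
    """(delta v, delta u) images of transported tangent fields along a path.

    delta v comes from the tilt variation through d nu_under/d theta, delta u
    from the base-mean variation through d nu_bar/d n at fixed theta; for
    this model delta v(tau) ~ e^{tau-T} and delta u(tau) ~ e^{-tau}.
    """
    dv, du = [], []
    for k in range(len(traj.t)):
        J = uv_chart_jacobian(params, traj.theta[k], traj.n[k])
        dv.append(float(J[0, :2] @ tangents.dtheta[k]))
        du.append(float(J[1, 2:] @ tangents.dn[k]))
    return np.asarray(dv), np.asarray(du)


# ---------------------------------------------------------------------------
# coherent-state Hessian defect and dual covariant derivatives


def coherent_hessian_defect(
    params: TwoStateParams, nu_under: float, nu_bar: float
) -> dict:
    """Defect of the coherent-state Hessian of psi relative to the Fisher metric.

    Per unit (delta theta)^2 the coherent-state second derivative of psi/N
    along the z-affine contour equals -(nu - nu_under)^2: negative
    semidefinite, degenerating when nu = nu_under (which holds for every
    tilt when nu_bar_0 equals the steady state).  The decomposition
    [Fisher term + advection] - extrinsic term,

        (dnu/dtheta + 2 nu_under nu) - (1/4 + nu_under^2),

    is assembled independently and asserted to match within 1e-10.  The
    direct route evaluates the second nu_under-derivative of the log-affine
    bracket form of psi/N at fixed base data.
    """
    nu = nu_of(params, nu_under, nu_bar)
    # direct route: psi/N = log(c + m nu_under) at fixed nu_bar -> second
    # derivative -(m/(c + m nu_under))^2, times the contour factor (1/4-nu_under^2)^2
    ba, bb = 0.5 - nu_bar, 0.5 + nu_bar
    m = bb / params.nu_ss_b - ba / params.nu_ss_a
    bracket = np.exp(_psi_bracket(params, nu_under, nu_bar))
    direct = -((0.25 - nu_under**2) ** 2) * (m / bracket) ** 2
    fisher = 0.25 - nu**2
    extrinsic = 0.25 + nu_under**2
    advection = 2.0 * nu_under * nu
    assembled = fisher + advection - extrinsic
    closed = -((nu - nu_under) ** 2)
    if abs(assembled - closed) > 1e-10 or abs(direct - closed) > 1e-10:
        raise AssertionError(
            f"coherent Hessian defect decomposition mismatch: direct={direct}, "
            f"assembled={assembled}, closed={closed}"
        )
    return {
        "defect": float(closed),
        "direct": float(direct),
        "fisher_term": float(fisher),
        "extrinsic_term": float(extrinsic),
        "advection_term": float(advection),
    }


def covariant_derivatives(
    params: TwoStateParams, boundary: TwoStateBoundary, tau: float
) -> dict:
    """Dual covariant transport brackets at time tau along the stationary path.

    In the coherent-state-flat connection pair the connection coefficients
    (from the coordinate-transform formula theta(phi+) applied to this
    model) are Gamma_theta = -2 nu_under and Gamma_eta* = -2 nu_bar.  The
    covariant change of the (mixed) Fisher metric along the flow then
    reduces to the density susceptibilities

        theta_dot Cov_theta g = (v_dot d/dv log PhiHat0^2) g,
        eta_dot   Cov_eta*  g = (u_dot d/du log PhiHat0^2) g,

    and the two transport brackets (1 + v_dot d_v log PhiHat0^2) and
    (-1 + u_dot d_u log PhiHat0^2) sum to zero: exponential growth of tilt
    discrimination exactly cancels decay of base-distribution resolution.
    Both routes (connection coefficients vs direct u, v susceptibilities)
    are computed and asserted equal within 1e-10.
    """
    if not 0 <= tau <= boundary.T:
        raise ValueError("tau must lie in [0, T]")
    nb, nu_u, nu_arr = trajectories(params, boundary, np.array([tau]))
    nu_bar, nu_under = float(nb[0]), float(nu_u[0])
    nu = float(nu_arr[0])
    v_ss = params.nu_ss
    u, v = descaled_uv(params, nu_under, nu_bar)
    u, v = float(u), float(v)
    uv = u * v
    # direct susceptibility route: u_dot = -u, v_dot = +v,
    # log PhiHat0^2 = -2 log(1 + uv)
    vdot_dv = -2.0 * uv / (1.0 + uv)
    udot_du = 2.0 * uv / (1.0 + uv)
    # connection route: g = 1/4 - nu^2, d_theta g|_eta = -2 nu g, Gamma = -2 nu_under
    g = 0.25 - nu**2
    theta_dot = (nu_under - v_ss) / (0.25 - nu_under**2)
    eta_dot = -(nu_bar - v_ss) / (0.25 - nu_bar**2)
    cov_theta = theta_dot * (-2.0 * nu * g - (-2.0 * nu_under) * g) / g
    cov_eta = eta_dot * (-2.0 * nu * g - (-2.0 * nu_bar) * g) / g
    if abs(cov_theta - vdot_dv) > 1e-10 or abs(cov_eta - udot_du) > 1e-10:
        raise AssertionError(
            "covariant metric change disagrees between connection and "
            f"susceptibility routes: {cov_theta} vs {vdot_dv}, {cov_eta} vs {udot_du}"
        )
    bracket_theta = 1.0 + vdot_dv
    bracket_eta = -1.0 + udot_du
    return {
        "bracket_theta": float(bracket_theta),
        "bracket_eta": float(bracket_eta),
        "bracket_sum": float(bracket_theta + bracket_eta),
        "susceptibility_theta": float(vdot_dv),
        "susceptibility_eta": float(udot_du),
        "gamma_theta": float(-2.0 * nu_under),
        "gamma_eta_star": float(-2.0 * nu_bar),
        "nu": nu,
        "nu_under": nu_under,
        "nu_bar": nu_bar,
    }
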