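"""Shared fixtures: small lattice distributions and a solved reference path.

The reference stationary path uses the two-state system at steady-state
fraction 2/3 (rates 2/3 and 1/3, so descaled time equals physical time),
initial base mean offset -1/4, final tilt offset -1/6 and horizon 3 — the
configuration for which every quantity has a closed form.
"""

import numpy as np
import pytest

import dpgeom
from dpgeom import two_state as ts
from dpgeom.hamiltonian_paths import build_liouville, multinomial_initial, solve_bvp


@pytest.fixture(scope="session")
def poisson2():
    """Poisson(2) on a 1-D lattice truncated at 40 (truncation error < 1e-12)."""
    return dpgeom.poisson_distribution([2.0], [40])


@pytest.fixture(scope="session")
def binomial_10_half():
    """Binomial(10, 1/2) as a 1-D lattice distribution."""
    from scipy.stats import binom

    tr = dpgeom.LatticeTruncation([10])
    return dpgeom.LatticeDistribution(tr, binom.pmf(np.arange(11), 10, 0.5))


@pytest.fixture(scope="session")
def two_state_params():
    return ts.TwoStateParams(2.0 / 3.0, 1.0 / 3.0, N=100)


@pytest.fixture(scope="session")
def fig2_boundary():
    return ts.TwoStateBoundary(nu_bar_0=-0.25, nu_under_T=-1.0 / 6.0, T=3.0)


@pytest.fixture(scope="session")
def two_state_liouville():
    return build_liouville(dpgeom.two_state_spec(2.0 / 3.0, 1.0 / 3.0))


def boundary_z(params, boundary):
    """Final generating-function argument z for given tilt offset, fixing the
    conserved component: z_b nu_ss_b + z_a nu_ss_a = 1, z_b - z_a = phi+_T."""
    phid_T = (boundary.nu_under_T - params.nu_ss) / (0.25 - params.nu_ss**2)
    A = np.array([[-1.0, 1.0], [params.nu_ss_a, params.nu_ss_b]])
    za, zb = np.linalg.solve(A, [phid_T, 1.0])
    return np.array([za, zb])


@pytest.fixture(scope="session")
def fig2_trajectory(two_state_liouville, two_state_params, fig2_boundary):
    """Solved stationary path for the reference boundary data, N = 100."""
    params, bnd = two_state_params, fig2_boundary
    z = boundary_z(params, bnd)
    psi0 = multinomial_initial(
        params.N, [0.5 - bnd.nu_bar_0, 0.5 + bnd.nu_bar_0]
    )
    return solve_bvp(two_state_liouville, psi0, z, bnd.T, n_steps=300)
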