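"""Liouville functions, stationary-path BVP, conservation laws, transport."""

import numpy as np
import pytest

import dpgeom
from dpgeom import two_state as ts
from dpgeom.hamiltonian_paths import (
    InitialCGF,
    build_liouville,
    hamilton_jacobi_residual,
    lagrangian_dual,
    liouville_volume_check,
    mean_field_steady_state,
    monodromy_matrix,
    multinomial_initial,
    phase_divergence,
    poisson_initial,
    propagate_tangents,
    solve_bvp,
    stationary_path_ode,
    adjoint_transform,
    wigner_split_invariance,
)
from dpgeom.jump_process import JumpProcessSpec, Reaction, two_state_spec

from conftest import boundary_z


class TestBuildLiouville:
    def test_two_state_closed_form(self, two_state_liouville):
        # L = k+ (phi+_a - phi+_b) phi_a + k- (phi+_b - phi+_a) phi_b
        kp, km = 2.0 / 3.0, 1.0 / 3.0
        rng = np.random.default_rng(0)
        for _ in range(5):
            pd = rng.uniform(0.2, 3.0, 2)
            p = rng.uniform(0.2, 3.0, 2)
            expected = kp * (pd[0] - pd[1]) * p[0] + km * (pd[1] - pd[0]) * p[1]
            assert two_state_liouville.cs_value(pd, p) == pytest.approx(
                expected, rel=1e-12
            )

    def test_birth_death(self):
        spec = JumpProcessSpec(
            ("a",), (Reaction((0,), (1,), 2.0), Reaction((1,), (0,), 0.5))
        )
        L = build_liouville(spec)
        for pd, p in [(1.5, 0.7), (0.4, 2.0)]:
            expected = 2.0 * (1 - pd) + 0.5 * (pd - 1) * p
            assert L.cs_value([pd], [p]) == pytest.approx(expected, rel=1e-12)

    def test_probability_conservation_flat_direction(self, two_state_liouville):
        rng = np.random.default_rng(1)
        for _ in range(10):
            p = rng.uniform(0.1, 5.0, 2)
            assert abs(two_state_liouville.cs_value(np.ones(2), p)) < 1e-12


class TestStationaryPathOde:
    def test_charts_agree(self, two_state_liouville):
        L = two_state_liouville
        theta = np.array([0.3, -0.2])
        n = np.array([40.0, 60.0])
        dth, dn = stationary_path_ode(L, (theta, n), "number-potential")
        pd, p = np.exp(theta), np.exp(-theta) * n
        dpd, dp = stationary_path_ode(L, (pd, p), "coherent")
        # phi+ = e^theta: dphi+/dt = phi+ dtheta/dt; phi = e^-theta n
        np.testing.assert_allclose(dpd, pd * dth, atol=1e-8)
        np.testing.assert_allclose(dp, p * (dn / n - dth), atol=1e-8)

    def test_zero_tilt_section_is_mass_action_ode(self, two_state_liouville):
        # dnu/dtau = nu_ss - nu for the two-state model
        n = np.array([30.0, 70.0])
        _, dn = two_state_liouville.velocity(np.zeros(2), n)
        kp, km = 2.0 / 3.0, 1.0 / 3.0
        np.testing.assert_allclose(
            dn, [-kp * n[0] + km * n[1], kp * n[0] - km * n[1]], atol=1e-12
        )

    def test_symplectic_identity(self, two_state_liouville):
        # d(dtheta_i/dt)/dtheta_j + d(dn_j/dt)/dn_i = 0 at random phase points
        L = two_state_liouville
        rng = np.random.default_rng(3)
        h = 1e-5
        for _ in range(5):
            theta = rng.uniform(-0.5, 0.5, 2)
            n = rng.uniform(20.0, 80.0, 2)
            for i in range(2):
                for j in range(2):
                    ei = np.zeros(2); ei[i] = h
                    ej = np.zeros(2); ej[j] = h
                    a = (L.velocity(theta + ej, n)[0][i]
                         - L.velocity(theta - ej, n)[0][i]) / (2 * h)
                    b = (L.velocity(theta, n + ei)[1][j]
                         - L.velocity(theta, n - ei)[1][j]) / (2 * h)
                    assert a + b == pytest.approx(0.0, abs=1e-6)


class TestSolveBvp:
    def test_unit_z_fixed_point(self, two_state_liouville):
        # z = 1 with a steady-state initial CGF: constant trajectory, L = 0
        L = two_state_liouville
        nss = mean_field_steady_state(L, np.array([40.0, 60.0]))
        traj = solve_bvp(L, poisson_initial(nss), np.ones(2), 2.0, n_steps=50)
        np.testing.assert_allclose(traj.theta, 0.0, atol=1e-9)
        assert np.max(np.abs(traj.n - nss)) < 1e-6
        np.testing.assert_allclose(traj.L_values, 0.0, atol=1e-10)

    def test_matches_two_state_closed_form(
        self, fig2_trajectory, two_state_params, fig2_boundary
    ):
        traj = fig2_trajectory
        nu_bar, nu_under, _ = ts.trajectories(
            two_state_params, fig2_boundary, traj.t
        )
        phi, phid = traj.phi, traj.phi_dag
        nb = 0.5 * (phi[:, 1] - phi[:, 0]) / (phi[:, 1] + phi[:, 0])
        wa = phid[:, 0] * two_state_params.nu_ss_a
        wb = phid[:, 1] * two_state_params.nu_ss_b
        nu = 0.5 * (wb - wa) / (wb + wa)
        assert np.max(np.abs(nb - nu_bar)) < 1e-6
        assert np.max(np.abs(nu - nu_under)) < 1e-6

    def test_liouville_conserved(self, fig2_trajectory):
        assert fig2_trajectory.diagnostics["L_drift"] < 1e-8 * max(
            1.0, np.max(np.abs(fig2_trajectory.L_values))
        )

    def test_stationary_cgf_matches_closed_form(
        self, fig2_trajectory, two_state_params, fig2_boundary
    ):
        _, psi_over_N = ts.phi0_and_invariant_cgf(two_state_params, fig2_boundary)
        psi_T = fig2_trajectory.psi_running[-1] / two_state_params.N
        assert psi_T == pytest.approx(psi_over_N, abs=1e-9)

    def test_leading_exponential_matches_lattice_cgf(self, two_state_liouville):
        """psi_T from the stationary path approaches the exact lattice CGF of
        the evolved distribution, per particle, as N grows."""
        params0 = ts.TwoStateParams(2.0 / 3.0, 1.0 / 3.0)
        bnd = ts.TwoStateBoundary(-0.25, -1.0 / 6.0, 3.0)
        z = boundary_z(params0, bnd)
        spec = two_state_spec(2.0 / 3.0, 1.0 / 3.0)
        errs = []
        for N in (50, 100):
            psi0 = multinomial_initial(N, [0.5 - bnd.nu_bar_0, 0.5 + bnd.nu_bar_0])
            traj = solve_bvp(two_state_liouville, psi0, z, 3.0, n_steps=60)
            rho0 = dpgeom.binomial_two_species(N, 0.5 + bnd.nu_bar_0)
            gen = dpgeom.build_generator(spec, rho0.truncation)
            rho_T = dpgeom.evolve_distribution(gen, rho0, 3.0)
            psi_exact = dpgeom.cgf_and_mean(rho_T, np.log(z)).psi
            errs.append(abs(traj.psi_running[-1] - psi_exact) / N)
        # o(1) per particle and decreasing with N (binomial evolution is the
        # exact solution here, so the stationary point is tight)
        assert errs[-1] < 1e-6
        assert errs[-1] <= errs[0] + 1e-12

    def test_wigner_split_invariance(self, fig2_trajectory):
        assert wigner_split_invariance(fig2_trajectory) < 1e-8 * max(
            1.0, abs(fig2_trajectory.psi_running[-1])
        )

    def test_lagrangian_duality(self, fig2_trajectory):
        rep = lagrangian_dual(fig2_trajectory, directions=[[1.0, -1.0]])
        assert rep["invert_gap"] < 1e-9
        assert rep["grad_gap"] < 1e-6
        assert rep["force_gap"] < 1e-6


@pytest.fixture(scope="module")
def ldf_evolver(two_state_params, fig2_boundary):
    """Exact-binomial-evolution oracle for the evolved large-deviation function."""
    spec = two_state_spec(2.0 / 3.0, 1.0 / 3.0)
    rho0 = dpgeom.binomial_two_species(
        two_state_params.N, 0.5 + fig2_boundary.nu_bar_0
    )
    gen = dpgeom.build_generator(spec, rho0.truncation)
    cache = {}

    def evolver(t, n):
        key = round(float(t), 12)
        if key not in cache:
            cache[key] = dpgeom.evolve_distribution(gen, rho0, key)
        pair = dpgeom.legendre_ldf(cache[key], n)
        return pair.psi_star, pair.theta_of_n

    return evolver


class TestHamiltonJacobi:
    def test_steady_trajectory_zero_residual(self, two_state_liouville):
        L = two_state_liouville
        nss = mean_field_steady_state(L, np.array([100.0 / 3, 200.0 / 3]))
        traj = solve_bvp(L, poisson_initial(nss), np.ones(2), 2.0, n_steps=50)
        spec = two_state_spec(2.0 / 3.0, 1.0 / 3.0)
        rho0 = dpgeom.binomial_two_species(100, 2.0 / 3.0)
        gen = dpgeom.build_generator(spec, rho0.truncation)

        def evolver(t, n):
            pair = dpgeom.legendre_ldf(dpgeom.evolve_distribution(gen, rho0, t), n)
            return pair.psi_star, pair.theta_of_n

        rep = hamilton_jacobi_residual(
            traj, evolver, times=[1.0], flat_directions=[[1.0], [1.0]]
        )
        assert rep["max_residual"] < 1e-9

    def test_residual_small_on_reference_path(self, fig2_trajectory, ldf_evolver):
        rep = hamilton_jacobi_residual(
            fig2_trajectory,
            ldf_evolver,
            times=np.linspace(0.5, 2.5, 3),
            dt=1e-3,
            flat_directions=[[1.0], [1.0]],
        )
        assert rep["max_residual"] < 1e-3
        assert rep["max_theta_gap"] < 1e-6

    def test_residual_second_order_in_dt(self, fig2_trajectory, ldf_evolver):
        r1 = hamilton_jacobi_residual(
            fig2_trajectory, ldf_evolver, times=[1.5], dt=1e-3,
            flat_directions=[[1.0], [1.0]],
        )["max_residual"]
        r2 = hamilton_jacobi_residual(
            fig2_trajectory, ldf_evolver, times=[1.5], dt=2e-3,
            flat_directions=[[1.0], [1.0]],
        )["max_residual"]
        assert r2 / r1 == pytest.approx(4.0, rel=0.1)


class TestTangentTransport:
    def test_zero_final_variation_stays_zero(self, fig2_trajectory):
        tf = propagate_tangents(fig2_trajectory, [0.0, 0.0], dn_0=[-0.5, 0.5])
        np.testing.assert_allclose(tf.dtheta, 0.0, atol=1e-14)
        np.testing.assert_allclose(tf.inner, 0.0, atol=1e-14)

    def test_inner_product_conserved(self, fig2_trajectory):
        tf = propagate_tangents(
            fig2_trajectory, [0.01, -0.02], dn_0=[-0.6, 0.6]
        )
        assert tf.inner_drift < 1e-6 * max(1.0, abs(tf.inner[0]))

    def test_closed_form_rates_in_uv_chart(
        self, fig2_trajectory, two_state_params
    ):
        """delta v ~ e^{tau-T} (tilt amplified), delta u ~ e^{-tau} (base
        attenuated); their product is the conserved pairing."""
        tf = propagate_tangents(
            fig2_trajectory, [-0.005, 0.005], dn_0=[-0.5, 0.5]
        )
        dv, du = ts.uv_tangent_projection(two_state_params, fig2_trajectory, tf)
        t = fig2_trajectory.t
        np.testing.assert_allclose(
            dv / dv[-1], np.exp(t - t[-1]), atol=1e-7
        )
        np.testing.assert_allclose(du / du[0], np.exp(-t), atol=1e-6)

    def test_monodromy_against_boundary_perturbation(
        self, fig2_trajectory, two_state_liouville, two_state_params, fig2_boundary
    ):
        """Transported pairing equals the product from central finite
        differences of full BVP re-solves with perturbed boundary data
        (step 1e-4)."""
        traj = fig2_trajectory
        params, bnd = two_state_params, fig2_boundary
        w = np.array([0.5, -0.5])  # final-tilt perturbation direction
        tf = propagate_tangents(traj, w, dn_0=[-0.5, 0.5])
        eps = 1e-4
        grid = traj.t
        z = boundary_z(params, bnd)
        psi0 = multinomial_initial(
            params.N, [0.5 - bnd.nu_bar_0, 0.5 + bnd.nu_bar_0]
        )

        def solve_z(scale):  # perturb the final tilt, same psi_0
            return solve_bvp(
                two_state_liouville, psi0, z * np.exp(scale * w), bnd.T,
                n_steps=len(grid) - 1,
            )

        def solve_b(db):  # perturb the base mean offset at fixed z
            psi0b = multinomial_initial(
                params.N, [0.5 - (bnd.nu_bar_0 + db), 0.5 + (bnd.nu_bar_0 + db)]
            )
            return solve_bvp(
                two_state_liouville, psi0b, z, bnd.T, n_steps=len(grid) - 1
            )

        dtheta_fd = (solve_z(+eps).theta - solve_z(-eps).theta) / (2 * eps)
        dn_fd = (solve_b(+eps).n - solve_b(-eps).n) / (2 * eps)
        np.testing.assert_allclose(dtheta_fd, tf.dtheta, atol=1e-6)
        inner_fd = np.einsum("ki,ki->k", dtheta_fd, dn_fd)
        # same pairing up to the (linear) normalisation of dn_0
        scale = inner_fd[0] / tf.inner[0]
        np.testing.assert_allclose(inner_fd / scale, tf.inner, atol=1e-5)
        # the finite-difference pairing is itself time-invariant within 1e-5
        assert np.max(np.abs(inner_fd - inner_fd[0])) < 1e-5 * max(
            1.0, abs(inner_fd[0])
        )


class TestLiouvilleVolume:
    def test_phase_divergence_zero(self, fig2_trajectory, two_state_liouville):
        for k in (0, 100, 250):
            assert abs(
                phase_divergence(
                    two_state_liouville,
                    fig2_trajectory.phi_dag[k],
                    fig2_trajectory.phi[k],
                )
            ) < 1e-6

    def test_restricted_monodromy_det_one(self, fig2_trajectory):
        basis = np.array([[1.0], [-1.0]]) / np.sqrt(2)
        rep = liouville_volume_check(fig2_trajectory, basis)
        assert rep["max_divergence"] < 1e-6
        assert rep["restricted_det"] == pytest.approx(1.0, abs=1e-5)

    def test_uv_monodromy_eigenvalues(self, fig2_trajectory, two_state_params):
        P = ts.uv_chart_monodromy(two_state_params, fig2_trajectory)
        T = fig2_trajectory.t[-1]
        eig = np.sort(np.real(np.linalg.eigvals(P)))
        np.testing.assert_allclose(eig, [np.exp(-T), np.exp(T)], rtol=1e-6)
        assert np.linalg.det(P) == pytest.approx(1.0, abs=1e-5)


class TestAdjointTransform:
    def test_steady_state_is_origin(self, two_state_liouville):
        L = two_state_liouville
        nss = mean_field_steady_state(L, np.array([40.0, 60.0]))
        traj = solve_bvp(L, poisson_initial(nss), np.ones(2), 1.5, n_steps=40)
        adj = adjoint_transform(traj, nss)
        assert np.max(np.abs(adj.varphi_dag - nss)) < 1e-6
        np.testing.assert_allclose(adj.eta, 0.0, atol=1e-8)

    def test_chart_consistency_on_reference_path(
        self, fig2_trajectory, two_state_params
    ):
        nss = np.array(
            [two_state_params.nu_ss_a, two_state_params.nu_ss_b]
        ) * two_state_params.N
        adj = adjoint_transform(fig2_trajectory, nss)
        assert adj.max_L_mismatch < 1e-10
        assert adj.max_eom_residual < 1e-6
        # theta + eta = log(n / nss) componentwise
        np.testing.assert_allclose(
            fig2_trajectory.theta + adj.eta,
            np.log(fig2_trajectory.n / nss),
            atol=1e-12,
        )

    def test_nu_bar_from_descaled_fields(
        self, fig2_trajectory, two_state_params, fig2_boundary
    ):
        nss = np.array(
            [two_state_params.nu_ss_a, two_state_params.nu_ss_b]
        ) * two_state_params.N
        adj = adjoint_transform(fig2_trajectory, nss)
        phi = fig2_trajectory.phi
        nu_bar_fields = 0.5 * (phi[:, 1] - phi[:, 0]) / (phi[:, 1] + phi[:, 0])
        nu_bar_closed, _, _ = ts.trajectories(
            two_state_params, fig2_boundary, fig2_trajectory.t
        )
        np.testing.assert_allclose(nu_bar_fields, nu_bar_closed, atol=1e-6)

    def test_time_dependent_generator_rejected(self, fig2_trajectory):
        with pytest.raises(NotImplementedError):
            adjoint_transform(fig2_trajectory, [1.0, 2.0], time_dependent=True)
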