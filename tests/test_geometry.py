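"""Conditional moments, synchronisation maps, free energy, flow maps."""

import numpy as np
import pytest

import fepaudit as fa

P6 = fa.Partition(2, 1, 1, 2)


@pytest.fixture(scope="module")
def nonzero_mean_case():
    """The reference system shifted to a nonzero set-point."""
    base = fa.generate_random_system("symmetric_chain", P6, 0.1, 0.1, seed=42)
    rho = np.arange(1.0, 7.0) / 10.0
    system = fa.make_system(
        base.J, rho, base.gamma_diagonal, P6, base.structure
    )
    density = fa.solve_stationary(system)
    return system, density, fa.conditional_moments(density, P6)


class TestConditionalMoments:
    def test_diagonal_covariance_gives_zero_gain(self):
        p = fa.Partition(1, 1, 1, 1)
        system = fa.make_system(-np.eye(4), np.zeros(4), 0.01 * np.eye(4), p)
        moments = fa.conditional_moments(fa.solve_stationary(system), p)
        assert np.allclose(moments.gain_y, 0.0)
        assert np.allclose(moments.m_y(np.array([0.3, -0.2])), 0.0)

    def test_textbook_bivariate_conditioning(self):
        """Sigma = [[1, c], [c, 1]] over (y, b) gives gain c and residual
        variance 1 - c^2."""
        p = fa.Partition(1, 1, 0, 0)
        c = 0.6
        Sigma = np.array([[1.0, c], [c, 1.0]])
        density = fa.StationaryDensity(
            Sigma=Sigma,
            H=np.linalg.inv(Sigma),
            Q=np.zeros((2, 2)),
            rho=np.zeros(2),
            residuals={},
        )
        moments = fa.conditional_moments(density, p)
        assert moments.gain_y[0, 0] == pytest.approx(c)
        assert moments.cond_cov_y[0, 0] == pytest.approx(1 - c**2)

    def test_gain_matches_ensemble_regression(self, fig5a_density, fig5a_moments):
        """Regressing NESS samples of y on b recovers the conditional gain."""
        rng = np.random.default_rng(123)
        samples = rng.multivariate_normal(np.zeros(6), fig5a_density.Sigma, size=20_000)
        y, b = samples[:, :2], samples[:, 2:4]
        gain_hat = np.linalg.lstsq(b, y, rcond=None)[0].T
        assert np.allclose(gain_hat, fig5a_moments.gain_y, atol=0.05)

    def test_conditional_covariance_positive_semidefinite(self, fig5a_moments):
        assert np.linalg.eigvalsh(fig5a_moments.cond_cov_y)[0] > 0

    def test_precision_route_agrees_only_without_blanket_violation(self, fig5a_moments):
        """(H_yy)^-1 equals the Schur complement only when H_yx = 0; the
        reference system violates the blanket, so the gap is small but nonzero."""
        assert 0 < fig5a_moments.mb_cov_gap < 1e-4


class TestSigmaMaps:
    def test_roundtrip_identity(self, fig5a_density, fig5a_moments):
        sig = fa.sigma_map(fig5a_moments, fig5a_density, P6)
        inv = fa.sigma_inverse(fig5a_moments, fig5a_density, P6)
        rng = np.random.default_rng(1)
        for _ in range(5):
            v = rng.normal(size=2)
            assert np.linalg.norm(inv(sig(v)) - v) < 1e-10

    def test_sigma_connects_conditional_modes(self, fig5a_density, fig5a_moments):
        sig = fa.sigma_map(fig5a_moments, fig5a_density, P6)
        b = np.array([0.12, -0.07])
        assert np.allclose(sig(fig5a_moments.m_x(b)), fig5a_moments.m_y(b), atol=1e-12)

    def test_nonzero_setpoint_is_centred(self, nonzero_mean_case):
        _, density, moments = nonzero_mean_case
        sig = fa.sigma_map(moments, density, P6)
        assert np.allclose(sig(moments.rho_x), moments.rho_y, atol=1e-12)

    def test_rank_condition_violation_raises(self):
        """n_x < n_b leaves the internal gain column-deficient by shape."""
        p = fa.Partition(2, 2, 2, 1)
        system = fa.generate_random_system("canonical", p, 0.1, 0.1, seed=0)
        density = fa.solve_stationary(system)
        moments = fa.conditional_moments(density, p)
        with pytest.raises(fa.MappingUndefinedError):
            fa.sigma_map(moments, density, p)


class TestSurprise:
    def test_identity_covariance_at_mode(self):
        density = fa.StationaryDensity(
            Sigma=np.eye(4),
            H=np.eye(4),
            Q=np.zeros((4, 4)),
            rho=np.zeros(4),
            residuals={},
        )
        p = fa.Partition(1, 1, 1, 1)
        assert fa.surprise(np.zeros(2), density, p) == pytest.approx(np.log(2 * np.pi))

    def test_one_standard_deviation_costs_half_nat(self, fig5a_density):
        rho_b = np.zeros(2)
        Sbb = P6.block(fig5a_density.Sigma, "b", "b")
        direction = np.array([1.0, 0.0])
        sd = np.sqrt(Sbb[0, 0])
        # move one marginal-sd along a coordinate whitened by the full block
        whitened = direction * sd
        s0 = fa.surprise(rho_b, fig5a_density, P6)
        s1 = fa.surprise(rho_b + whitened, fig5a_density, P6)
        maha = whitened @ np.linalg.solve(Sbb, whitened)
        assert s1 - s0 == pytest.approx(0.5 * maha)

    def test_mean_surprise_equals_entropy(self, fig5a_density):
        """Monte-Carlo average of -log p(b) over NESS samples matches the
        closed-form differential entropy of the blanket marginal."""
        rng = np.random.default_rng(7)
        Sbb = P6.block(fig5a_density.Sigma, "b", "b")
        samples = rng.multivariate_normal(np.zeros(2), Sbb, size=20_000)
        mc = np.mean([fa.surprise(b, fig5a_density, P6) for b in samples[:2000]])
        entropy = 0.5 * np.linalg.slogdet(2 * np.pi * np.e * Sbb)[1]
        assert mc == pytest.approx(entropy, rel=0.05)


class TestFreeEnergy:
    def test_bound_attained_at_conditional(self, fig5a_density, fig5a_moments):
        b = np.array([0.05, -0.11])
        model = fa.VariationalModel(
            theta=fig5a_moments.m_y(b), Sigma_theta=fig5a_moments.cond_cov_y
        )
        report = fa.free_energy(model, b, fig5a_density, P6, fig5a_moments)
        assert report.kl == pytest.approx(0.0, abs=1e-12)
        assert report.free_energy == pytest.approx(report.surprise)
        assert np.allclose(report.gradient, 0.0, atol=1e-12)

    def test_bound_strict_away_from_conditional(self, fig5a_density, fig5a_moments):
        b = np.array([0.05, -0.11])
        model = fa.VariationalModel(
            theta=fig5a_moments.m_y(b) + 0.02, Sigma_theta=fig5a_moments.cond_cov_y
        )
        report = fa.free_energy(model, b, fig5a_density, P6, fig5a_moments)
        assert report.kl > 0
        assert report.free_energy > report.surprise

    def test_gradient_matches_finite_differences(self, fig5a_density, fig5a_moments):
        rng = np.random.default_rng(3)
        b = rng.normal(size=2) * 0.1
        theta = fig5a_moments.m_y(b) + rng.normal(size=2) * 0.05
        cov = fig5a_moments.cond_cov_y
        report = fa.free_energy(
            fa.VariationalModel(theta, cov), b, fig5a_density, P6, fig5a_moments
        )
        h = 1e-6
        fd = np.zeros(2)
        for i in range(2):
            up, dn = theta.copy(), theta.copy()
            up[i] += h
            dn[i] -= h
            fd[i] = (
                fa.free_energy(fa.VariationalModel(up, cov), b, fig5a_density, P6).free_energy
                - fa.free_energy(fa.VariationalModel(dn, cov), b, fig5a_density, P6).free_energy
            ) / (2 * h)
        assert np.linalg.norm(fd - report.gradient) < 1e-6

    def test_quadratic_minimum_is_conditional_mode(self, fig5a_density, fig5a_moments):
        """Minimizing F over theta at the optimal covariance recovers m_y(b)
        and the surprise bound exactly."""
        b = np.array([-0.03, 0.08])
        cov = fig5a_moments.cond_cov_y
        thetas = [fig5a_moments.m_y(b) + d for d in
                  (np.zeros(2), np.array([0.01, 0]), np.array([0, -0.02]))]
        energies = [
            fa.free_energy(fa.VariationalModel(t, cov), b, fig5a_density, P6).free_energy
            for t in thetas
        ]
        assert energies[0] == min(energies)
        assert energies[0] == pytest.approx(fa.surprise(b, fig5a_density, P6))

    def test_invalid_variational_covariance_rejected(self):
        with pytest.raises(ValueError):
            fa.VariationalModel(np.zeros(2), -np.eye(2))


class TestMarginalFlows:
    def test_flow_vanishes_at_setpoint(self, fig5a_system, fig5a_moments):
        assert np.allclose(fa.marginal_flow_y(np.zeros(2), fig5a_system, fig5a_moments), 0)
        assert np.allclose(fa.marginal_flow_x(np.zeros(2), fig5a_system, fig5a_moments), 0)

    def test_monte_carlo_average_of_true_flow(self, fig5a_system, fig5a_density, fig5a_moments):
        """Averaging f_y over y ~ p(y|b) reproduces the closed form."""
        rng = np.random.default_rng(5)
        b = np.array([0.09, -0.04])
        ys = rng.multivariate_normal(fig5a_moments.m_y(b), fig5a_moments.cond_cov_y, 10_000)
        Jyy = P6.block(fig5a_system.J, "y", "y")
        Jyb = P6.block(fig5a_system.J, "y", "b")
        flows = ys @ Jyy.T + Jyb @ b
        assert np.allclose(
            flows.mean(axis=0),
            fa.marginal_flow_y(b, fig5a_system, fig5a_moments),
            atol=4 * 0.1 / np.sqrt(10_000),
        )

    def test_symmetric_chain_marginal_flow_is_higher_order(self, fig5a_partition):
        """With C_yb = C_by^T the surrogate drive vanishes at first order."""
        norms = []
        for eps in (0.1, 0.05):
            system = fa.generate_random_system(
                "symmetric_chain", fig5a_partition, eps, 0.1, seed=8
            )
            density = fa.solve_stationary(system)
            moments = fa.conditional_moments(density, fig5a_partition)
            b = np.array([0.1, 0.1])
            norms.append(np.linalg.norm(fa.marginal_flow_y(b, system, moments)))
        assert norms[0] / norms[1] > 3.0  # O(eps^2) decay


class TestGradientFlowIdentity:
    def test_exact_in_decoupled_regime(self):
        """Block-decoupled systems satisfy the blanket and block-Q conditions
        exactly, making the flow equal the free-energy-gradient expression."""
        C = np.zeros((6, 6))
        C[0, 1], C[1, 0] = 0.05, -0.05  # inside y
        C[4, 5], C[5, 4] = 0.07, -0.07  # inside x
        system = fa.make_system(-np.eye(6) + C, np.zeros(6), np.full(6, 0.01), P6)
        density = fa.solve_stationary(system)
        assert fa.gradient_flow_identity_residual(system, density) < 1e-8

    def test_generic_violation_is_first_order(self):
        residuals = []
        for eps in (0.1, 0.05):
            system = fa.generate_random_system("canonical", P6, eps, 0.1, seed=3)
            density = fa.solve_stationary(system)
            residuals.append(fa.gradient_flow_identity_residual(system, density))
        assert residuals[0] > 1e-3
        assert residuals[0] / residuals[1] == pytest.approx(2.0, rel=0.4)

    def test_chain_rule_along_path(self, fig5a_system, fig5a_density, fig5a_moments):
        """Increments of m_y(b_t) are the sigma-gradient image of increments
        of m_x(b_t): both are fixed linear images of blanket increments."""
        traj = fa.simulate(fig5a_system, dt=1e-2, T=2.0, seed=0)
        b_path = traj.states[:, P6.slices["b"]]
        m_y = fig5a_moments.rho_y + (b_path - fig5a_moments.rho_b) @ fig5a_moments.gain_y.T
        m_x = fig5a_moments.rho_x + (b_path - fig5a_moments.rho_b) @ fig5a_moments.gain_x.T
        grad_sigma = fa.sigma_map(fig5a_moments, fig5a_density, P6).grad
        dm_y = np.diff(m_y, axis=0)
        dm_x = np.diff(m_x, axis=0)
        assert np.max(np.abs(dm_y - dm_x @ grad_sigma.T)) < 1e-10


class TestPhiMap:
    def test_phi_transports_internal_flow_to_external_flow(self):
        count = 0
        seed = 0
        while count < 10:
            system = fa.generate_random_system("canonical", P6, 0.1, 0.1, seed=seed)
            seed += 1
            density = fa.solve_stationary(system)
            moments = fa.conditional_moments(density, P6)
            try:
                phi = fa.phi_map(system, density)
            except fa.MappingUndefinedError:
                continue  # exact sign alignment can make a block singular
            count += 1
            b = np.random.default_rng(seed).normal(size=2) * 0.1
            lhs = fa.marginal_flow_y(b, system, moments)
            rhs = phi @ fa.marginal_flow_x(b, system, moments)
            assert np.linalg.norm(lhs - rhs) < 1e-10

    def test_phi_differs_from_sigma_gradient(self, fig5a_system, fig5a_density):
        assert fa.flow_map_mismatch(fig5a_system, fig5a_density) > 1e-2

    def test_nonsquare_blocks_rejected(self):
        p = fa.Partition(1, 2, 2, 1)
        system = fa.generate_random_system("canonical", p, 0.05, 0.1, seed=0)
        density = fa.solve_stationary(system)
        with pytest.raises(fa.MappingUndefinedError):
            fa.phi_map(system, density)
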