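"""Model core: within/between equations, stationary covariance, joint density."""

import numpy as np
import pytest
from scipy import stats
from scipy.linalg import solve_discrete_lyapunov

import actdsem as ad
from actdsem.model import joint_log_density, lag_matrix, spectral_radius
from actdsem.types import DsemParams, PersonEffects


def effects_row(mu_sb=0, mu_pa=0, phi_sb=0, phi_pa=0, beta_sb=0, beta_pa=0,
                log_psi_sb=0.0, log_psi_pa=0.0):
    return np.array([mu_sb, mu_pa, phi_sb, phi_pa, beta_sb, beta_pa,
                     log_psi_sb, log_psi_pa], dtype=float)


def random_stable_system(rng):
    while True:
        a = rng.uniform(-0.9, 0.9, size=(2, 2))
        if spectral_radius(a) < 0.95:
            return a, np.exp(rng.uniform(-1, 3, size=2))


class TestWithinEquations:
    def test_zero_dynamics_zero_mean(self):
        mean, cov = ad.within_equations(effects_row(), np.array([5.0, -3.0]))
        np.testing.assert_allclose(mean, [0.0, 0.0])

    def test_unit_autoregression_carries_deviation(self):
        mean, _ = ad.within_equations(effects_row(phi_sb=1.0), np.array([3.0, 0.0]))
        assert mean[0] == pytest.approx(3.0)

    def test_log_variance_scale_in_minutes(self):
        # log psi_SB = 9.10 corresponds to an innovation SD near 95 min/d
        _, cov = ad.within_equations(effects_row(log_psi_sb=9.10), np.zeros(2))
        assert np.sqrt(cov[0, 0]) == pytest.approx(95.0, abs=0.5)

    def test_cross_lag_convention(self):
        # beta_sb acts in the SB equation on the previous PA deviation
        mean, _ = ad.within_equations(effects_row(beta_sb=0.5), np.array([0.0, 10.0]))
        np.testing.assert_allclose(mean, [5.0, 0.0])


class TestBetweenEquations:
    def params(self, gamma1=0.0, tau=1.0, sigma_mu=0.0):
        return DsemParams(
            gamma0=np.arange(8.0),
            gamma1=np.full(8, gamma1),
            tau=np.full(8, tau),
            sigma_mu=sigma_mu,
        )

    def test_zero_slopes_ignore_predictor(self):
        mean, _ = ad.between_equations(self.params(), np.array([-2.0, 0.0, 3.0]))
        assert (mean == np.arange(8.0)).all()

    def test_predictor_at_grand_mean_gives_intercepts(self):
        mean, _ = ad.between_equations(self.params(gamma1=2.0), np.array([0.0]))
        np.testing.assert_allclose(mean[0], np.arange(8.0))

    def test_zero_tau_deterministic(self):
        _, cov = ad.between_equations(self.params(tau=0.0), np.array([0.0]))
        np.testing.assert_allclose(cov, 0.0)

    def test_non_psd_block_rejected(self):
        with pytest.raises(ValueError):
            DsemParams(
                gamma0=np.zeros(8), gamma1=np.zeros(8),
                tau=np.ones(8), sigma_mu=2.0,
            )


class TestStationaryCovariance:
    def test_no_dynamics_gives_innovation_variances(self):
        v = ad.stationary_covariance(np.zeros((2, 2)), np.array([3.0, 7.0]))
        np.testing.assert_allclose(v, np.diag([3.0, 7.0]))

    def test_ar1_closed_form(self):
        a = np.array([[0.5, 0.0], [0.0, 0.0]])
        v = ad.stationary_covariance(a, np.array([3.0, 1.0]))
        assert v[0, 0] == pytest.approx(3.0 / (1 - 0.25))

    def test_nonstationary_rejected(self):
        with pytest.raises(ValueError, match="non-stationary"):
            ad.stationary_covariance(np.eye(2) * 1.01, np.ones(2))

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_scipy_lyapunov(self, seed):
        rng = np.random.default_rng(seed)
        a, psi = random_stable_system(rng)
        got = ad.stationary_covariance(a, psi)
        want = solve_discrete_lyapunov(a, np.diag(psi))
        np.testing.assert_allclose(got, want, rtol=1e-10)

    def test_lyapunov_residual_batched(self):
        rng = np.random.default_rng(10)
        systems = [random_stable_system(rng) for _ in range(200)]
        a = np.stack([s[0] for s in systems])
        psi = np.stack([s[1] for s in systems])
        v = ad.stationary_covariance(a, psi)
        resid = v - np.einsum("nij,njk,nlk->nil", a, v, a)
        resid[:, 0, 0] -= psi[:, 0]
        resid[:, 1, 1] -= psi[:, 1]
        assert np.abs(resid).max() < 1e-10

    def test_matches_long_simulation(self):
        rng = np.random.default_rng(3)
        a, psi = random_stable_system(rng)
        v = ad.stationary_covariance(a, psi)
        t_len = 100_000
        w = np.zeros(2)
        acc = np.zeros((2, 2))
        sd = np.sqrt(psi)
        draws = rng.standard_normal((t_len, 2)) * sd
        series = np.empty((t_len, 2))
        for t in range(t_len):
            w = a @ w + draws[t]
            series[t] = w
        emp = series[500:].T @ series[500:] / (t_len - 500)
        np.testing.assert_allclose(emp, v, rtol=0.05, atol=0.05 * np.abs(v).max())


class TestJointLogDensity:
    def setup_instance(self, phi=0.0, seed=0, n=2, t_len=4):
        rng = np.random.default_rng(seed)
        u = np.stack([effects_row(phi_sb=phi, log_psi_sb=1.0, log_psi_pa=0.5)] * n)
        states = rng.normal(size=(n, t_len, 2))
        obs = np.ones((n, t_len), dtype=bool)
        params = DsemParams(
            gamma0=np.zeros(8), gamma1=np.zeros(8), tau=np.ones(8), sigma_mu=0.2
        )
        return params, PersonEffects(values=u), states, obs, np.zeros(n)

    def test_iid_case_is_sum_of_gaussians(self):
        params, eff, states, obs, c = self.setup_instance()
        got = joint_log_density(params, eff, states, obs, c, initial="stationary")
        # by hand: transitions are iid N(0, psi); initial from psi itself
        psi = np.array([np.e, np.exp(0.5)])
        ll = stats.norm.logpdf(states, 0.0, np.sqrt(psi)).sum()
        ll += stats.multivariate_normal.logpdf(
            eff.values[:, :2], np.zeros(2), np.array([[1.0, 0.2], [0.2, 1.0]])
        ).sum()
        ll += stats.norm.logpdf(eff.values[:, 2:], 0.0, 1.0).sum()
        assert got == pytest.approx(ll)

    def test_doubling_psi_at_zero_residual_costs_half_log_two(self):
        # a Gaussian factor evaluated at its mean loses exactly log(2)/2
        # when its variance doubles
        params, eff, states, obs, c = self.setup_instance()
        states[:] = 0.0
        base = joint_log_density(params, eff, states, obs, c, initial="diffuse")
        u2 = eff.values.copy()
        u2[0, 6] += np.log(2.0)
        bumped = joint_log_density(
            params, PersonEffects(values=u2), states, obs, c, initial="diffuse"
        )
        # person 0 has (T-1) transition factors in the SB coordinate, plus
        # the between-level density of log_psi_sb changes
        t_trans = states.shape[1] - 1
        delta_between = stats.norm.logpdf(1.0 + np.log(2.0)) - stats.norm.logpdf(1.0)
        assert bumped - base == pytest.approx(
            -0.5 * np.log(2.0) * t_trans + delta_between
        )

    def test_matches_bruteforce_evaluation(self):
        rng = np.random.default_rng(8)
        n, t_len = 3, 5
        u = np.column_stack(
            [
                rng.normal(400, 30, n),
                rng.normal(250, 30, n),
                rng.uniform(-0.4, 0.4, n),
                rng.uniform(-0.3, 0.3, n),
                rng.uniform(-0.2, 0.2, n),
                rng.uniform(-0.2, 0.2, n),
                rng.normal(7, 0.3, n),
                rng.normal(6, 0.3, n),
            ]
        )
        states = rng.normal(scale=40, size=(n, t_len, 2))
        obs = np.ones((n, t_len), dtype=bool)
        c = rng.normal(size=n)
        params = DsemParams(
            gamma0=np.array([400, 250, 0.1, 0.1, 0, 0, 7, 6], float),
            gamma1=np.full(8, 0.05),
            tau=np.array([900, 800, 0.05, 0.05, 0.05, 0.05, 0.2, 0.2]),
            sigma_mu=-100.0,
        )
        eff = PersonEffects(values=u)
        got = joint_log_density(params, eff, states, obs, c, initial="stationary")

        # naive factor-by-factor evaluation
        want = 0.0
        mean_u = params.gamma0 + np.outer(c, params.gamma1)
        for i in range(n):
            a = lag_matrix(u[i])
            psi = np.exp(u[i, 6:8])
            v = ad.stationary_covariance(a, psi)
            want += stats.multivariate_normal.logpdf(states[i, 0], np.zeros(2), v)
            for t in range(1, t_len):
                m = a @ states[i, t - 1]
                want += stats.norm.logpdf(states[i, t, 0], m[0], np.sqrt(psi[0]))
                want += stats.norm.logpdf(states[i, t, 1], m[1], np.sqrt(psi[1]))
            block = params.mu_cov()
            want += stats.multivariate_normal.logpdf(u[i, :2], mean_u[i, :2], block)
            for j in range(2, 8):
                want += stats.norm.logpdf(
                    u[i, j], mean_u[i, j], np.sqrt(params.tau[j])
                )
        assert got == pytest.approx(want)

    def test_invariant_to_person_relabeling(self):
        params, eff, states, obs, c = self.setup_instance(phi=0.3, seed=4, n=4)
        base = joint_log_density(params, eff, states, obs, c)
        perm = np.array([2, 0, 3, 1])
        swapped = joint_log_density(
            params,
            PersonEffects(values=eff.values[perm]),
            states[perm],
            obs[perm],
            c[perm],
        )
        assert swapped == pytest.approx(base)

    def test_nonfinite_rejected(self):
        params, eff, states, obs, c = self.setup_instance()
        states[0, 2, 0] = np.inf
        with pytest.raises(ValueError, match="person 0"):
            joint_log_density(params, eff, states, obs, c, initial="diffuse")
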