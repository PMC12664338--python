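"""Reporting: posterior summaries, standardization, descriptives."""

import numpy as np
import pandas as pd
import pytest

import actdsem as ad
from actdsem.model import lag_matrix
from actdsem.report import (
    _person_standardized,
    spearman_with_p,
    standardize_between,
    standardize_within,
    summarize_posterior,
)
from actdsem.types import PosteriorDraws

from conftest import spearman_oracle


class TestSummarizePosterior:
    def test_symmetric_draws_not_significant(self):
        s = summarize_posterior(np.array([-1.0, 1.0] * 50))
        assert s.p_onetailed == 0.5 and not s.significant

    def test_all_positive_significant(self):
        s = summarize_posterior(np.linspace(0.1, 1.0, 200))
        assert s.significant and s.p_onetailed < 1.0 / 200
        assert s.ci_low <= s.median <= s.ci_high

    def test_normal_quantiles(self):
        rng = np.random.default_rng(0)
        s = summarize_posterior(rng.standard_normal(100_000))
        assert s.ci_low == pytest.approx(-1.96, abs=0.03)
        assert s.ci_high == pytest.approx(1.96, abs=0.03)

    def test_needs_two_draws(self):
        with pytest.raises(ValueError):
            summarize_posterior(np.array([1.0]))


def synthetic_draws(person, gamma1=None, tau=None, sigma_mu=None, n_draws=6):
    """PosteriorDraws with every draw equal to the given person matrix."""
    n = person.shape[0]
    person_mat = np.broadcast_to(person, (1, n_draws, n, 8)).copy()
    gamma1 = np.zeros(8) if gamma1 is None else gamma1
    tau = np.ones(8) if tau is None else tau
    return PosteriorDraws(
        gamma0=np.broadcast_to(person.mean(axis=0), (1, n_draws, 8)).copy(),
        gamma1=np.broadcast_to(gamma1, (1, n_draws, 8)).copy(),
        tau=np.broadcast_to(tau, (1, n_draws, 8)).copy(),
        sigma_mu=np.full((1, n_draws), 0.0 if sigma_mu is None else sigma_mu),
        person=person_mat,
        states=np.zeros((1, n_draws, 0, 2)),
        missing_index=np.zeros((0, 2), int),
        deviance=np.zeros((1, n_draws)),
        accept_rate=np.zeros((1, n, 2)),
        person_ids=[f"p{i}" for i in range(n)],
    )


def two_person_panel(sb_scale=1.0, pa_scale=1.0, pain=(1.0, 3.0)):
    rows = []
    for i, p in enumerate(pain):
        for d in range(1, 4):
            rows.append(
                {
                    "person_id": f"p{i}",
                    "day_index": d,
                    "sb_min": 400.0 * sb_scale + 10 * d,
                    "pa_min": 200.0 * pa_scale - 5 * d,
                    "wear_min": 600.0,
                    "pain": p,
                }
            )
    return ad.PanelDataset(data=pd.DataFrame(rows), predictor="pain")


class TestStandardizeWithin:
    def test_zero_dynamics_residual_share_one(self):
        person = np.zeros((3, 8))
        person[:, 6:8] = [1.0, 0.5]
        res = standardize_within(synthetic_draws(person))
        assert res.summaries["zeta_sb"].median == pytest.approx(1.0)
        assert res.summaries["r2_sb"].median == pytest.approx(0.0)
        assert res.exclusion_rate == 0.0

    def test_r2_equals_one_minus_zeta_identity(self, small_draws):
        draws, _ = small_draws
        per, stable = _person_standardized(
            draws.person.reshape(-1, *draws.person.shape[2:])
        )
        mask = np.isfinite(per["zeta_sb"])
        np.testing.assert_allclose(
            per["r2_sb"][mask], 1.0 - per["zeta_sb"][mask], rtol=1e-12
        )

    def test_pure_autoregression_standardized_phi_in_unit_interval(self):
        # without cross-lags, stability is exactly |phi| < 1, so the
        # standardized autoregression must stay inside the unit interval
        rng = np.random.default_rng(11)
        person = np.zeros((50, 8))
        person[:, 2] = rng.uniform(-1.5, 1.5, 50)
        person[:, 3] = rng.uniform(-1.5, 1.5, 50)
        per, stable = _person_standardized(person[None])
        phis = per["phi_sb"][0][stable[0]]
        assert ((phis > -1) & (phis < 1)).all()

    def test_scale_invariance_of_standardized_block(self, small_draws):
        # multiplying SB by 2 and PA by 0.5 in the raw panel maps the
        # posterior deterministically; standardized quantities must not move
        draws, panel = small_draws
        person = draws.person.copy()
        person[..., 0] *= 2.0  # mu_sb
        person[..., 1] *= 0.5  # mu_pa
        person[..., 4] *= 2.0 / 0.5  # beta_sb multiplies a PA lag in the SB eq
        person[..., 5] *= 0.5 / 2.0
        person[..., 6] += 2 * np.log(2.0)
        person[..., 7] += 2 * np.log(0.5)
        rescaled = PosteriorDraws(
            gamma0=draws.gamma0, gamma1=draws.gamma1, tau=draws.tau,
            sigma_mu=draws.sigma_mu, person=person, states=draws.states,
            missing_index=draws.missing_index, deviance=draws.deviance,
            accept_rate=draws.accept_rate, person_ids=draws.person_ids,
        )
        base = standardize_within(draws)
        new = standardize_within(rescaled)
        for name, summary in base.summaries.items():
            assert new.summaries[name].median == pytest.approx(
                summary.median, rel=1e-8, abs=1e-12
            ), name

    def test_standardized_beta_matches_simulated_stationary_sds(self):
        # one stable person: standardized beta from the report equals the
        # correlation-algebra value computed with simulation-estimated SDs
        person = np.array([[0, 0, 0.4, 0.2, 0.3, -0.1, 1.2, 0.6]])
        res = standardize_within(synthetic_draws(person))
        rng = np.random.default_rng(2)
        a = lag_matrix(person[0])
        sd = np.sqrt(np.exp(person[0, 6:8]))
        w = np.zeros(2)
        series = np.empty((200_000, 2))
        noise = rng.standard_normal((200_000, 2)) * sd
        for t in range(200_000):
            w = a @ w + noise[t]
            series[t] = w
        sd_emp = series[1000:].std(axis=0)
        want = person[0, 4] * sd_emp[1] / sd_emp[0]
        assert res.summaries["beta_sb"].median == pytest.approx(want, rel=0.02)

    def test_antipersistence_share_counts_negative_autoregression(self):
        person = np.zeros((4, 8))
        person[:, 2] = [-0.2, 0.3, -0.1, 0.5]  # phi_sb
        person[:, 3] = 0.1
        res = standardize_within(synthetic_draws(person))
        assert res.antipersistence_share["sb"] == pytest.approx(0.5)
        assert res.antipersistence_share["pa"] == 0.0
        lo, hi = res.coefficient_ranges["phi_sb"]
        assert lo == pytest.approx(-0.2) and hi == pytest.approx(0.5)

    def test_nonstationary_persons_excluded_not_fatal(self):
        person = np.zeros((2, 8))
        person[0, 2] = 1.5  # explosive
        person[1, 2] = 0.3
        res = standardize_within(synthetic_draws(person))
        assert res.exclusion_rate == pytest.approx(0.5)
        assert np.isfinite(res.summaries["phi_sb"].median)


class TestStandardizeBetween:
    def test_zero_slope_zero_effect(self):
        person = np.zeros((3, 8))
        res = standardize_between(synthetic_draws(person), two_person_panel())
        assert res.on_predictor["phi_sb"].median == 0.0
        assert res.r2_between["sb"].median == 0.0

    def test_tau_to_zero_limit_is_unit_correlation(self):
        person = np.zeros((3, 8))
        gamma1 = np.full(8, 0.5)
        tau = np.full(8, 1e-12)
        res = standardize_between(
            synthetic_draws(person, gamma1=gamma1, tau=tau), two_person_panel()
        )
        assert abs(res.on_predictor["phi_sb"].median) == pytest.approx(1.0, abs=1e-5)

    def test_matches_effect_predictor_correlation_at_large_n(self):
        # simulate persons with a real slope; the standardized effect is the
        # correlation between the random effect and the predictor
        rng = np.random.default_rng(3)
        n = 4000
        c = rng.normal(0, 2.0, n)
        g1, tau = 0.08, 0.04
        u_phi = 0.1 + g1 * c + rng.normal(0, np.sqrt(tau), n)
        emp_corr = np.corrcoef(u_phi, c)[0, 1]
        var_p = np.var(c, ddof=1)
        std_effect = g1 * np.sqrt(var_p) / np.sqrt(g1**2 * var_p + tau)
        assert std_effect == pytest.approx(emp_corr, abs=0.02)

    def test_sigma_mu_standardized_is_residual_correlation(self):
        person = np.zeros((3, 8))
        tau = np.ones(8)
        tau[0], tau[1] = 4.0, 9.0
        res = standardize_between(
            synthetic_draws(person, tau=tau, sigma_mu=-3.0), two_person_panel()
        )
        assert res.sigma_mu_std.median == pytest.approx(-3.0 / 6.0)

    def test_zero_predictor_variance_rejected(self):
        person = np.zeros((3, 8))
        panel = two_person_panel(pain=(2.0, 2.0))
        with pytest.raises(ValueError, match="variance"):
            standardize_between(synthetic_draws(person), panel)


class TestDescriptives:
    def make_panel(self, sb_by_person, pa_by_person, day=1):
        rows = []
        for i, (sb, pa) in enumerate(zip(sb_by_person, pa_by_person)):
            rows.append(
                {
                    "person_id": f"p{i}",
                    "day_index": day,
                    "sb_min": float(sb),
                    "pa_min": float(pa),
                    "wear_min": float(sb + pa),
                    "pain": 1.0,
                }
            )
        return ad.PanelDataset(data=pd.DataFrame(rows), predictor="pain")

    def test_perfect_negative_monotone_gives_minus_one(self):
        sb = [500, 450, 400, 350]
        pa = [100, 200, 300, 400]
        table = ad.descriptives(self.make_panel(sb, pa))
        assert table.loc[0, "spearman_r"] == pytest.approx(-1.0)

    def test_constant_sb_flagged_undefined(self):
        table = ad.descriptives(self.make_panel([400] * 5, [100, 150, 200, 250, 300]))
        assert np.isnan(table.loc[0, "spearman_r"])

    def test_sb_share_both_conventions(self):
        table = ad.descriptives(self.make_panel([300, 600], [300, 200]))
        assert table.loc[0, "sb_share_mean_ratio"] == pytest.approx(
            0.5 * (300 / 600 + 600 / 800)
        )
        assert table.loc[0, "sb_share_ratio_of_means"] == pytest.approx(900 / 1400)

    @pytest.mark.parametrize("seed", range(20))
    def test_spearman_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        x = rng.integers(0, 8, n).astype(float)  # heavy ties
        y = rng.integers(0, 8, n).astype(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        r_got, p_got = spearman_with_p(x, y)
        r_want, p_want = spearman_oracle(x, y)
        assert r_got == pytest.approx(r_want, abs=1e-12)
        assert p_got == pytest.approx(p_want, abs=1e-10)

    def test_invariant_to_person_order(self, small_draws):
        draws, panel = small_draws
        shuffled = panel.data.sample(frac=1.0, random_state=1).reset_index(drop=True)
        table1 = ad.descriptives(panel)
        table2 = ad.descriptives(ad.PanelDataset(data=shuffled, predictor="pain"))
        pd.testing.assert_frame_equal(table1, table2)

    def test_all_missing_day_emits_row(self):
        panel = self.make_panel([300, 400], [200, 100])
        data = panel.data.copy()
        extra = data.copy()
        extra["day_index"] = 2
        extra["sb_min"] = np.nan
        extra["pa_min"] = np.nan
        panel2 = ad.PanelDataset(
            data=pd.concat([data, extra], ignore_index=True), predictor="pain"
        )
        table = ad.descriptives(panel2)
        assert len(table) == 2 and table.loc[1, "n"] == 0


def test_summary_table_shape_and_blocks(small_draws):
    draws, panel = small_draws
    table = ad.make_summary_table(draws, panel)
    assert set(table["block"]) == {"fixed", "random_variance", "std_within", "r2", "std_between"}
    assert (table[table["block"] == "fixed"].shape[0]) == 16
    assert "dic" in table.attrs and table.attrs["pd"] > 0
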