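"""Cluster permutation test and random-intercept mixed model."""

import numpy as np
import pandas as pd
import pytest

from thetaconflict import simulate as sim
from thetaconflict import stats as stm
from thetaconflict.exceptions import InvalidInputError


class TestThetaConditionTest:
    def _table(self, av, ap):
        rows = []
        for i, (a, b) in enumerate(zip(av, ap)):
            rows += [{"participant_id": f"P{i:02d}", "condition": "AV-AV",
                      "theta_sum_db": a},
                     {"participant_id": f"P{i:02d}", "condition": "AP-AP",
                      "theta_sum_db": b}]
        return pd.DataFrame(rows)

    def test_identical_conditions(self):
        r = stm.theta_condition_test(self._table([1.0, 2, 3], [1.0, 2, 3]))
        assert (r.t_statistic, r.p_value) == (0.0, 0.5)

    def test_one_sided_direction(self):
        av, ap = [5.0, 6.5, 7, 8.2], [1.0, 2, 3.5, 4]
        r = stm.theta_condition_test(self._table(av, ap))
        assert r.t_statistic > 0 and r.p_value < 0.05
        rev = stm.theta_condition_test(self._table(ap, av))
        assert rev.p_value > 0.95

    def test_missing_condition_rejected(self):
        tab = self._table([1.0, 2], [3.0, 4]).iloc[:-1]
        with pytest.raises(InvalidInputError):
            stm.theta_condition_test(tab)


class TestClusterPermutation:
    def _times(self, n):
        return np.arange(n) * 10.0  # 10 ms steps

    def test_zero_difference_no_clusters(self):
        a = np.tile(np.linspace(0, 1, 50), (8, 1))
        r = stm.cluster_permutation_paired(a, a.copy(), self._times(50), 200, seed=0)
        assert r.clusters == []

    def test_constructed_effect_found_with_correct_extent(self, rng):
        n, n_t = 12, 360  # 0..3600 ms in 10 ms steps
        times = self._times(n_t)
        a = 0.05 * rng.standard_normal((n, n_t))
        b = 0.05 * rng.standard_normal((n, n_t))
        effect = (times >= 600) & (times < 3000)
        a[:, effect] += 2.0
        r = stm.cluster_permutation_paired(a, b, times, 500, seed=1)
        assert len(r.clusters) >= 1
        top = r.clusters[0]
        assert top.p_corrected <= 0.01
        assert top.start_ms == pytest.approx(600, abs=50)
        assert top.end_ms == pytest.approx(3000, abs=50)
        assert top.sum_statistic > 0

    def test_monte_carlo_matches_exhaustive_enumeration(self, rng):
        n = 8
        a = rng.standard_normal((n, 60)) + 0.6
        b = rng.standard_normal((n, 60))
        times = self._times(60)
        exact = stm.cluster_permutation_paired(a, b, times, exact=True)
        mc = stm.cluster_permutation_paired(a, b, times, n_permutations=4000, seed=5)
        assert len(exact.clusters) == len(mc.clusters)
        for ce, cm in zip(exact.clusters, mc.clusters):
            se = np.sqrt(ce.p_corrected * (1 - ce.p_corrected) / 4000)
            assert cm.p_corrected == pytest.approx(ce.p_corrected,
                                                   abs=max(3 * se, 0.01))

    def test_relabeling_flips_cluster_sign_not_p(self, rng):
        a = rng.standard_normal((10, 80)) + 0.4
        b = rng.standard_normal((10, 80))
        times = self._times(80)
        r_ab = stm.cluster_permutation_paired(a, b, times, 500, seed=9)
        r_ba = stm.cluster_permutation_paired(b, a, times, 500, seed=9)
        assert len(r_ab.clusters) == len(r_ba.clusters)
        for c1, c2 in zip(r_ab.clusters, r_ba.clusters):
            assert c1.sum_statistic == pytest.approx(-c2.sum_statistic)
            assert c1.p_corrected == pytest.approx(c2.p_corrected)

    def test_null_distribution_length_contract(self, rng):
        a = rng.standard_normal((6, 40)) + 1.0
        b = rng.standard_normal((6, 40))
        r = stm.cluster_permutation_paired(a, b, self._times(40), 200, seed=2)
        assert len(r.null_distribution) == 200
        assert r.n_permutations == 200

    def test_too_few_participants_rejected(self):
        with pytest.raises(InvalidInputError):
            stm.cluster_permutation_paired(np.zeros((1, 10)), np.zeros((1, 10)),
                                           self._times(10))


def _lmm_dataset(n_groups=20, n_per=60, slope=-150.0, interaction=-50.0,
                 intercept_sd=500.0, noise_sd=800.0, seed=0):
    g = np.random.default_rng(seed)
    rows = []
    for p in range(n_groups):
        b = g.normal(0, intercept_sd)
        for cond, code in (("AP-AP", -0.5), ("AV-AV", 0.5)):
            theta = g.standard_normal(n_per)
            rt = (5000 + b + (slope + interaction * code) * theta
                  + 1000 * code + noise_sd * g.standard_normal(n_per))
            rows.append(pd.DataFrame({
                "participant_id": f"P{p:02d}", "condition": cond,
                "theta_db": theta, "rt_ms": rt}))
    return pd.concat(rows, ignore_index=True)


class TestMixedModel:
    def test_matches_statsmodels_mixedlm(self):
        import statsmodels.formula.api as smf

        data = _lmm_dataset(seed=4)
        fit = stm.fit_random_intercept_lmm(data)
        d = stm.prepare_single_trial_frame(data)
        d["theta_x_conflict"] = d["theta_c"] * d["conflict_c"]
        sm_fit = smf.mixedlm("rt_c ~ theta_c + conflict_c + theta_x_conflict",
                             d, groups=d["participant_id"]).fit(reml=True)
        expected = {"intercept": "Intercept", "theta": "theta_c",
                    "conflict_type": "conflict_c",
                    "theta:conflict_type": "theta_x_conflict"}
        for term, sm_term in expected.items():
            ours = fit.coef(term)
            assert ours["estimate"] == pytest.approx(sm_fit.params[sm_term], rel=1e-4, abs=1e-6)
            assert ours["se"] == pytest.approx(sm_fit.bse[sm_term], rel=1e-3)
        assert fit.random_intercept_variance == pytest.approx(
            float(sm_fit.cov_re.iloc[0, 0]), rel=1e-3)
        assert fit.residual_variance == pytest.approx(sm_fit.scale, rel=1e-3)

    def test_no_group_structure_reduces_to_ols(self):
        data = _lmm_dataset(intercept_sd=0.0, seed=11)
        fit = stm.fit_random_intercept_lmm(data)
        d = stm.prepare_single_trial_frame(data)
        X = np.column_stack([np.ones(len(d)), d["theta_c"], d["conflict_c"],
                             d["theta_c"] * d["conflict_c"]])
        beta_ols, *_ = np.linalg.lstsq(X, d["rt_c"].to_numpy(), rcond=None)
        if fit.ols_fallback:
            np.testing.assert_allclose(fit.params["estimate"], beta_ols, atol=1e-6)
        else:
            # tiny estimated variance: coefficients still near OLS
            np.testing.assert_allclose(fit.params["estimate"], beta_ols,
                                       rtol=1e-3, atol=0.5)
            assert fit.random_intercept_variance < 0.05 * fit.residual_variance

    def test_noise_free_balanced_null_gives_zero_coefficients(self):
        data = _lmm_dataset(slope=0.0, interaction=0.0, intercept_sd=0.0,
                            noise_sd=0.0, seed=2)
        data["rt_ms"] = 5000.0 + 1000 * np.where(data.condition == "AV-AV", 0.5, -0.5)
        data.loc[:, "rt_ms"] = 5000.0  # flatten everything
        fit = stm.fit_random_intercept_lmm(data)
        np.testing.assert_allclose(fit.params["estimate"], 0.0, atol=1e-8)

    def test_centering_leaves_slopes_unchanged(self):
        data = _lmm_dataset(seed=6)
        shifted = data.copy()
        shifted["theta_db"] += 7.5
        f1 = stm.fit_random_intercept_lmm(data)
        f2 = stm.fit_random_intercept_lmm(shifted)
        assert f2.coef("theta")["estimate"] == pytest.approx(
            f1.coef("theta")["estimate"], rel=1e-9)
        assert f2.coef("theta:conflict_type")["estimate"] == pytest.approx(
            f1.coef("theta:conflict_type")["estimate"], rel=1e-9)

    def test_reml_criterion_is_local_minimum(self):
        data = _lmm_dataset(seed=8)
        fit = stm.fit_random_intercept_lmm(data)
        d = stm.prepare_single_trial_frame(data)
        X = np.column_stack([np.ones(len(d)), d["theta_c"], d["conflict_c"],
                             d["theta_c"] * d["conflict_c"]])
        y = d["rt_c"].to_numpy()
        groups = d["participant_id"].to_numpy()
        _, n_i, sx, sy = stm._group_sums(X, y, groups)
        lam_hat = fit.random_intercept_variance / fit.residual_variance
        base = stm._reml_criterion(lam_hat, X.T @ X, X.T @ y, float(y @ y),
                                   n_i, sx, sy, len(y), X.shape[1])[0]
        for factor in (0.5, 0.8, 1.25, 2.0):
            alt = stm._reml_criterion(lam_hat * factor, X.T @ X, X.T @ y,
                                      float(y @ y), n_i, sx, sy, len(y),
                                      X.shape[1])[0]
            assert base <= alt + 1e-9

    def test_singular_design_rejected(self):
        data = _lmm_dataset(seed=1)
        data["theta_db"] = 1.0  # constant predictor -> collinear with intercept
        with pytest.raises(InvalidInputError):
            stm.fit_random_intercept_lmm(data)

    def test_summary_mentions_terms(self):
        fit = stm.fit_random_intercept_lmm(_lmm_dataset(seed=3))
        text = fit.summary()
        for term in ("theta", "conflict_type", "random-intercept variance"):
            assert term in text


class TestPerConditionSlopes:
    def test_identical_subsets_identical_fits(self):
        data = _lmm_dataset(seed=7)
        half = data[data.condition == "AV-AV"].copy()
        other = half.copy()
        other["condition"] = "AP-AP"
        fits = stm.per_condition_slopes(pd.concat([half, other], ignore_index=True))
        assert fits["AV-AV"].coef("theta")["estimate"] == pytest.approx(
            fits["AP-AP"].coef("theta")["estimate"])

    def test_generator_slopes_recovered_in_sign_and_order(self):
        cfg = sim.SimConfig(n_participants=12, seed=21)
        table = sim.simulate_behavior_cohort(cfg, n_trials_per_condition=150)
        fits = stm.per_condition_slopes(table)
        s_av = fits["AV-AV"].coef("theta")["estimate"]
        s_ap = fits["AP-AP"].coef("theta")["estimate"]
        assert s_av < 0 and s_ap < 0 and s_av < s_ap

    def test_null_slopes_within_confidence_interval(self):
        cfg = sim.SimConfig(n_participants=10, seed=33,
                            rt_theta_slope_ms_per_db={"AV-AV": 0.0, "AP-AP": 0.0})
        table = sim.simulate_behavior_cohort(cfg, n_trials_per_condition=150)
        for fit in stm.per_condition_slopes(table).values():
            c = fit.coef("theta")
            assert c["ci_low"] <= 0.0 <= c["ci_high"]
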