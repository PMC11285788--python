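"""Statistical stage: OLS, bootstrap, BH correction, sign validation."""

import numpy as np
import pandas as pd
import pytest

from crispr_spread import (InvalidModelInput, baseline_tests,
                           benjamini_hochberg, bootstrap_ci, fig1_parameters,
                           fit_glm, generate_dataset,
                           sign_prediction_accuracy)
from crispr_spread.experiment import NoiseSettings
from crispr_spread.inference import expected_baseline_directions


def linear_table(n, slope, noise_sd, rng, intercept=0.5):
    x = rng.uniform(-1, 1, size=n)
    z = rng.uniform(0, 1, size=n)
    y = intercept + slope * x + rng.normal(0, noise_sd, size=n)
    return pd.DataFrame({"x": x, "z": z, "response": y})


class TestFitGlm:
    def test_exact_linear_response_recovered(self, rng):
        table = linear_table(40, slope=1.7, noise_sd=0.0, rng=rng)
        fit = fit_glm(table, predictors=("x", "z"))
        assert fit.coef("x") == pytest.approx(1.7, abs=1e-8)
        assert fit.coef("z") == pytest.approx(0.0, abs=1e-8)
        assert fit.adj_r_squared == pytest.approx(1.0, abs=1e-10)

    def test_textbook_simple_regression_slope(self, rng):
        # closed-form slope: cov(x, y) / var(x)
        table = linear_table(25, slope=0.8, noise_sd=0.3, rng=rng)
        fit = fit_glm(table, predictors=("x",))
        x, y = table["x"].to_numpy(), table["response"].to_numpy()
        closed_form = np.sum((x - x.mean()) * (y - y.mean())) / np.sum(
            (x - x.mean()) ** 2)
        assert fit.coef("x") == pytest.approx(closed_form, abs=1e-12)

    def test_matches_statsmodels_cross_check(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        table = linear_table(30, slope=1.2, noise_sd=0.4, rng=rng)
        fit = fit_glm(table, predictors=("x", "z"))
        X = sm.add_constant(table[["x", "z"]].to_numpy())
        ref = sm.OLS(table["response"].to_numpy(), X).fit()
        np.testing.assert_allclose(fit.coefficients, ref.params, rtol=1e-9)
        np.testing.assert_allclose(fit.std_errors, ref.bse, rtol=1e-9)
        assert fit.adj_r_squared == pytest.approx(ref.rsquared_adj, rel=1e-9)
        assert fit.f_statistic == pytest.approx(ref.fvalue, rel=1e-9)
        assert fit.f_pvalue == pytest.approx(ref.f_pvalue, rel=1e-6)

    def test_pure_noise_response_is_nonsignificant(self, rng):
        # under the null the F p-value is uniform; a single seeded draw
        # comfortably above a tiny threshold guards against spurious fits
        table = linear_table(60, slope=0.0, noise_sd=1.0, rng=rng)
        fit = bootstrap_ci(table, predictors=("x", "z"), n_boot=1000, seed=1)
        lo, hi = fit.bootstrap_cis["x"]
        assert lo < 0 < hi
        assert fit.f_pvalue > 0.05

    def test_rank_deficiency_names_collinear_columns(self, rng):
        table = linear_table(20, slope=1.0, noise_sd=0.1, rng=rng)
        table["x2"] = 2.0 * table["x"]
        with pytest.raises(InvalidModelInput, match="x2"):
            fit_glm(table, predictors=("x", "x2"))

    def test_synthetic_dataset_recovers_f_delta_effect(self):
        _, wide = generate_dataset(seed=17)
        fit = fit_glm(wide)
        assert fit.coef("f_delta0_obs") > 0
        assert fit.p_values[fit.predictors.index("f_delta0_obs")] < 1e-6
        # initial CRISPR+ frequency does not drive the response
        idx = fit.predictors.index("initial_crispr_freq_obs")
        assert fit.p_values[idx] > 0.05


class TestBootstrap:
    def test_fixed_seed_reproduces_intervals(self, rng):
        table = linear_table(30, slope=1.0, noise_sd=0.3, rng=rng)
        a = bootstrap_ci(table, predictors=("x",), n_boot=1000, seed=5)
        b = bootstrap_ci(table, predictors=("x",), n_boot=1000, seed=5)
        assert a.bootstrap_cis == b.bootstrap_cis

    def test_interval_width_shrinks_with_noise(self, rng):
        widths = []
        for sd in (0.5, 0.05, 0.0):
            table = linear_table(30, slope=1.0, noise_sd=sd,
                                 rng=np.random.default_rng(3))
            fit = bootstrap_ci(table, predictors=("x",), n_boot=1000, seed=2)
            lo, hi = fit.bootstrap_cis["x"]
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]
        assert widths[2] == pytest.approx(0.0, abs=1e-10)

    def test_endpoints_monotone_in_confidence_level(self, rng):
        table = linear_table(30, slope=1.0, noise_sd=0.3, rng=rng)
        fits = {lvl: bootstrap_ci(table, predictors=("x",), n_boot=1000,
                                  seed=4, level=lvl)
                for lvl in (0.8, 0.9, 0.99)}
        los = [fits[l].bootstrap_cis["x"][0] for l in (0.8, 0.9, 0.99)]
        his = [fits[l].bootstrap_cis["x"][1] for l in (0.8, 0.9, 0.99)]
        assert los[0] >= los[1] >= los[2]
        assert his[0] <= his[1] <= his[2]

    def test_coverage_of_true_slope(self):
        # 95% percentile intervals over repeated linear-gaussian datasets;
        # binomial sd at n=250 is ~1.4pp, band allows ~4 sd
        hits = 0
        n_runs = 250
        for i in range(n_runs):
            rng = np.random.default_rng(1000 + i)
            table = linear_table(40, slope=1.0, noise_sd=0.5, rng=rng)
            fit = bootstrap_ci(table, predictors=("x",), n_boot=1000, seed=i)
            lo, hi = fit.bootstrap_cis["x"]
            hits += lo <= 1.0 <= hi
        assert 0.89 <= hits / n_runs <= 0.99


class TestBenjaminiHochberg:
    def test_hand_applied_step_up_rule(self):
        # p*(m/rank) = (.06,.06,.06,.06,.06,.06) after the step-up minimum
        adjusted = benjamini_hochberg([0.01, 0.02, 0.03, 0.04, 0.05, 0.06])
        np.testing.assert_allclose(adjusted, 0.06)
        # a second hand-worked vector with distinct adjusted values
        adjusted = benjamini_hochberg([0.005, 0.04, 0.03, 0.9])
        np.testing.assert_allclose(adjusted, [0.02, 0.053333333333, 0.053333333333, 0.9])

    def test_never_decreases_and_caps_at_one(self, rng):
        p = rng.uniform(0, 1, size=50)
        adj = benjamini_hochberg(p)
        assert np.all(adj >= p) and np.all(adj <= 1)

    def test_preserves_rejection_monotonicity(self, rng):
        p = rng.uniform(0, 1, size=30)
        adj = benjamini_hochberg(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_matches_statsmodels_fdr_bh(self, rng):
        multipletests = pytest.importorskip(
            "statsmodels.stats.multitest").multipletests
        p = rng.uniform(0, 1, size=40)
        np.testing.assert_allclose(benjamini_hochberg(p),
                                   multipletests(p, method="fdr_bh")[1],
                                   rtol=1e-12)


class TestBaselineTests:
    def test_all_zero_deviations_give_unit_adjusted_p(self):
        df = pd.DataFrame({
            "condition": ["a"] * 3 + ["b"] * 3,
            "baseline_deviation": [0.0] * 6})
        out = baseline_tests(df, directions={"a": "greater", "b": "less"})
        assert np.allclose(out["t"], 0.0)
        assert np.allclose(out["p_value"], 0.5)
        assert np.allclose(out["p_adjusted"], 0.5)
        assert not out["significant"].any()

    def test_cost_asymmetry_detected_in_no_phage_arms(self):
        # c_R > c_I: conditions whose protected CRISPR+ cells are mostly
        # surface mutants drift down without phage, and vice versa
        params = fig1_parameters()  # c_R=0.05, c_I=0
        records, _ = generate_dataset(
            params=params, noise=NoiseSettings(kappa=5e4, jitter_sigma=0.002),
            seed=23)
        rows = []
        for rec in records:
            if not rec.phage_added:
                rows.append({
                    "condition": rec.condition_label,
                    "baseline_deviation": sum(rec.freqs_t24[2:5])
                    - sum(rec.freqs_t0[2:5])})
        out = baseline_tests(pd.DataFrame(rows),
                             directions=expected_baseline_directions()
                             ).set_index("condition")
        # the conditions whose protected CRISPR+ cells are predominantly
        # costly surface mutants (C+ <= R+ under f_delta>0) drift down,
        # and those dominated by cost-free immune cells drift up
        assert out.loc["fpos_CeqR", "significant"]
        assert out.loc["fpos_CltR", "significant"]
        assert out.loc["fneg_CgtR", "significant"]
        assert out.loc["fneg_CeqR", "significant"]
        assert (out.loc[["fpos_CeqR", "fpos_CltR"], "mean_deviation"] < 0).all()
        assert (out.loc[["fneg_CgtR", "fneg_CeqR"], "mean_deviation"] > 0).all()

    def test_requires_replication(self):
        df = pd.DataFrame({"condition": ["a"], "baseline_deviation": [0.1]})
        with pytest.raises(InvalidModelInput):
            baseline_tests(df, directions={})


class TestSignPredictionAccuracy:
    def test_perfect_and_chance_levels(self, rng):
        obs = rng.normal(0, 1, size=200)
        assert sign_prediction_accuracy(obs, obs) == 1.0
        pred = rng.choice([-1.0, 1.0], size=200)
        chance = sign_prediction_accuracy(pred, rng.normal(0, 1, size=200))
        assert 0.35 <= chance <= 0.65

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidModelInput):
            sign_prediction_accuracy([1.0], [1.0, -1.0])

    def test_dead_band_zeros_agree(self):
        assert sign_prediction_accuracy([1e-9, 0.5], [-1e-9, 0.4]) == 1.0
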