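"""Logistic calibration: majority labels, fitting, diagnostics, prediction."""

import warnings

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit
from statsmodels.tools.sm_exceptions import PerfectSeparationError

import simcal as sc
from simcal import CalibrationModel
from simcal.calibration import calibrate_profiles

from conftest import make_profiles


def simulate_binary(beta0, beta1, n, seed, lo=0.116, hi=1.0):
    rng = np.random.default_rng(seed)
    s = rng.uniform(lo, hi, n)
    p = expit(beta0 + beta1 * 10 * s)
    return s, (rng.random(n) < p).astype(float)


def oracle_fit(s, y, scale=10.0):
    """Independent ML route: direct minimization of the negative log-likelihood."""
    x = scale * np.asarray(s)

    def nll(b):
        lp = b[0] + b[1] * x
        return -(y * lp - np.log1p(np.exp(lp))).sum()

    res = minimize(nll, x0=[0.0, 0.0], method="BFGS")
    return res.x


class TestLabelMajority:
    @pytest.mark.parametrize("frac,label", [(0.51, True), (0.50, False), (0.0, False), (1.0, True)])
    def test_strict_majority_rule(self, frac, label):
        assert sc.label_majority(frac) is label

    @pytest.mark.parametrize("bad", [-0.01, 1.01])
    def test_out_of_range_rejected(self, bad):
        with pytest.raises(ValueError):
            sc.label_majority(bad)


class TestFitLogistic:
    def test_recovers_generating_coefficients_within_3se(self):
        s, y = simulate_binary(-12.754, 2.524, 10_000, seed=1)
        m = sc.fit_logistic(s, y)
        assert abs(m.beta0 - (-12.754)) < 3 * m.se_beta0
        assert abs(m.beta1 - 2.524) < 3 * m.se_beta1
        assert not m.separation

    def test_agrees_with_direct_likelihood_maximization(self):
        s, y = simulate_binary(-6.0, 1.4, 800, seed=2)
        m = sc.fit_logistic(s, y)
        b = oracle_fit(s, y)
        assert m.beta0 == pytest.approx(b[0], abs=1e-4)
        assert m.beta1 == pytest.approx(b[1], abs=1e-4)

    def test_scale_contract_reparameterization_invariance(self):
        # fitting on raw similarity and multiplying the slope by 10 must give
        # the same curve as the packaged 0.1-similarity parameterization
        s, y = simulate_binary(-6.0, 1.4, 800, seed=3)
        m = sc.fit_logistic(s, y)
        a0, a1 = oracle_fit(s, y, scale=1.0)
        assert m.beta0 == pytest.approx(a0, abs=1e-3)
        assert 10 * m.beta1 == pytest.approx(a1, abs=1e-3)
        grid = np.linspace(0, 1, 21)
        p_pkg = sc.predict_probability(m, grid)[0]
        p_raw = expit(a0 + a1 * grid)
        np.testing.assert_allclose(p_pkg, p_raw, atol=1e-5)

    def test_null_slope_not_significant(self):
        # labels independent of similarity: |z| < 2 in >= 90% of replicates
        rng = np.random.default_rng(10)
        ok = tot = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(200):
                s = rng.uniform(0, 1, 100)
                y = (rng.random(100) < 0.5).astype(float)
                try:
                    m = sc.fit_logistic(s, y)
                except ValueError:
                    continue
                tot += 1
                ok += abs(m.beta1 / m.se_beta1) < 2
        assert ok / tot >= 0.90

    def test_one_class_input_rejected(self):
        with pytest.raises(ValueError):
            sc.fit_logistic([0.1, 0.5, 0.9], [1.0, 1.0, 1.0])

    def test_separation_flagged_with_finite_threshold(self):
        s = np.concatenate([np.linspace(0.1, 0.45, 20), np.linspace(0.55, 0.95, 20)])
        y = np.concatenate([np.zeros(20), np.ones(20)])
        m = sc.fit_logistic(s, y)
        assert m.separation and m.method == "firth"
        assert np.isfinite(m.beta0) and np.isfinite(m.beta1)
        assert 0.45 < m.t_lr < 0.55
        with pytest.raises(PerfectSeparationError):
            sc.fit_logistic(s, y, on_separation="error")

    def test_grouped_binomial_fit_recovers_population_curve(self):
        cfg = sc.PanelSimConfig(seed=5, expert_sd=0.0)
        s = sc.simulate_similarities(cfg)
        f = sc.simulate_votes(s, cfg)
        m = sc.fit_logistic(s, f, trials=cfg.n_experts)
        assert abs(m.beta0 - cfg.beta0_true) < 3 * m.se_beta0
        assert abs(m.beta1 - cfg.beta1_true) < 3 * m.se_beta1


class TestNagelkerkeR2:
    def test_no_improvement_gives_zero(self):
        assert sc.nagelkerke_r2(-69.3, -69.3, 100) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_prediction_gives_one(self):
        assert sc.nagelkerke_r2(100 * np.log(0.5), -1e-12, 100) == pytest.approx(1.0, abs=1e-9)

    def test_balanced_halfway_example_matches_closed_form(self):
        ll0 = 100 * np.log(0.5)
        ll1 = ll0 / 2
        r2_cs = 1 - np.exp(2 * (ll0 - ll1) / 100)
        expected = r2_cs / (1 - np.exp(2 * ll0 / 100))
        assert sc.nagelkerke_r2(ll0, ll1, 100) == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(2 / 3, abs=1e-12)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            sc.nagelkerke_r2(-10.0, -5.0, 0)
        with pytest.raises(ValueError):
            sc.nagelkerke_r2(-5.0, -10.0, 100)


class TestHosmerLemeshow:
    def test_constant_probability_balanced_labels_statistic_zero(self):
        probs = np.full(100, 0.5)
        labels = np.tile([0.0, 1.0], 50)
        with pytest.warns(UserWarning):
            stat, _ = sc.hosmer_lemeshow(probs, labels)
        assert stat == pytest.approx(0.0, abs=1e-9)

    def test_gross_misspecification_detected(self):
        # fit a logistic curve to step-function labels: HL must reject
        rng = np.random.default_rng(0)
        rejected = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for rep in range(20):
                s = rng.uniform(0, 1, 1000)
                y = (rng.random(1000) < np.where(s > 0.5, 0.85, 0.35)).astype(float)
                m = sc.fit_logistic(s, y)
                rejected += m.hl_pvalue < 0.05
        assert rejected >= 18  # >= 90% of replicates

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            sc.hosmer_lemeshow([0.5] * 10, [1] * 10, n_groups=2)
        with pytest.raises(ValueError):
            sc.hosmer_lemeshow([0.5] * 5, [1] * 5, n_groups=10)


class TestPredictProbability:
    @pytest.mark.parametrize(
        "beta0,beta1,s,expected",
        [
            # Operating-point probabilities implied by the published calibrations
            (-12.758, 2.128, 0.606, 0.534),  # BCI at its t_ROC
            (-9.022, 1.380, 0.650, 0.487),  # MDL at its t_ROC
        ],
    )
    def test_published_operating_point_probabilities(self, beta0, beta1, s, expected):
        model = CalibrationModel.from_coefficients(beta0, beta1)
        assert round(sc.predict_probability(model, s)[0], 3) == expected

    def test_probability_half_at_t_lr(self):
        model = CalibrationModel.from_coefficients(-12.754, 2.524)
        assert sc.predict_probability(model, model.t_lr)[0] == pytest.approx(0.5, abs=1e-10)

    def test_t_lr_identity_and_monotonicity_on_fitted_model(self):
        s, y = simulate_binary(-8.0, 1.7, 600, seed=4)
        m = sc.fit_logistic(s, y)
        assert sc.predict_probability(m, m.t_lr)[0] == pytest.approx(0.5, abs=1e-10)
        grid = np.linspace(0, 1, 50)
        p, lo, hi = sc.predict_probability(m, grid)
        assert np.all(np.diff(p) > 0)
        assert np.all(lo <= p) and np.all(p <= hi)


class TestFlagOutliers:
    def test_high_vote_low_similarity_pair_flagged(self):
        # a pair judged similar by >70% of experts at similarity 0.217 sits far
        # below a steep calibration curve and must be flagged
        model = CalibrationModel.from_coefficients(-12.347, 1.956)
        s = np.array([0.217, 0.3, 0.7, 0.8])
        y = np.array([1.0, 0.0, 1.0, 1.0])
        assert 0 in sc.flag_outliers(model, s, y)

    def test_well_calibrated_data_unflagged_and_refit_stable(self):
        s, y = simulate_binary(-6.0, 1.4, 400, seed=6)
        m = sc.fit_logistic(s, y)
        idx = sc.flag_outliers(m, s, y)
        assert idx.size <= 4  # |r|>3 is rare under a correct model
        profiles = make_profiles(s, yes_fractions=y)
        res = calibrate_profiles(profiles, sc.REFERENCE_SCHEME, refit_without_flagged=True)
        if res.model_without_flagged is not None:
            m2 = res.model_without_flagged
            assert abs(m2.beta1 - m.beta1) < 3 * m.se_beta1
            assert m2.excluded_pairs == res.flagged_pairs
        assert res.model.beta1 == pytest.approx(m.beta1, rel=1e-6)
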