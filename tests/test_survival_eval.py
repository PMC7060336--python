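"""Tests of KM, log-rank, Cox, C-index, calibration, CV and nomogram."""

import numpy as np
import pandas as pd
import pytest

from gliorad.signature import standardized_logrank_statistic
from gliorad.survival_eval import (
    build_nomogram,
    clinical_design_matrix,
    compare_cindex,
    cox_fit,
    crossval_cindex,
    dagostino_nam_calibration,
    harrell_cindex,
    km_estimate,
    logrank_test,
)
from gliorad.synthetic import generate_survival


def brute_force_cindex(pred, time, event):
    """Exhaustive O(n^2) usable-pair enumeration oracle."""
    conc = disc = tied = 0
    n = len(time)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            # usable: i fails first (observed event) before j's time
            if event[i] == 1 and time[i] < time[j]:
                if pred[i] > pred[j]:
                    conc += 1
                elif pred[i] < pred[j]:
                    disc += 1
                else:
                    tied += 1
    total = conc + disc + tied
    return (conc + 0.5 * tied) / total, conc, disc, tied


class TestKm:
    def test_no_censoring_matches_ecdf(self, rng):
        times = rng.uniform(1, 100, 40)
        curve = km_estimate(times, np.ones(40, int))
        for t in times:
            ecdf = (times <= t).mean()
            assert curve.at(t) == pytest.approx(1.0 - ecdf)

    def test_single_censored_subject_flat(self):
        curve = km_estimate([10.0], [0])
        assert curve.at(5.0) == 1.0
        assert curve.at(10.0) == 1.0

    def test_hand_product_limit_three_subjects(self):
        # times 1, 2, 3; events 1, 0, 1: S(1) = 2/3, S(3) = 2/3 * (1 - 1/1) = 0
        curve = km_estimate([1.0, 2.0, 3.0], [1, 0, 1])
        assert curve.at(1.0) == pytest.approx(2.0 / 3.0)
        assert curve.at(2.5) == pytest.approx(2.0 / 3.0)
        assert curve.at(3.0) == pytest.approx(0.0)

    def test_agrees_with_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        times = rng.uniform(1, 100, 60)
        events = rng.integers(0, 2, 60)
        curve = km_estimate(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        for t in (10.0, 40.0, 80.0):
            assert curve.at(t) == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0]))


class TestLogrank:
    def test_identical_groups_null_statistic(self):
        times = np.array([3.0, 5.0, 8.0, 12.0] * 2)
        events = np.array([1, 0, 1, 1] * 2)
        group = np.array([0] * 4 + [1] * 4)
        chi2, df, p = logrank_test(times, events, group)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        n_sig = 0
        for seed in range(25):
            lp = np.concatenate([np.zeros(500), np.full(500, np.log(2.0))])
            recs = generate_survival(lp, 600.0, 0.1, seed=seed)
            t = [r.time_days for r in recs]
            e = [r.event for r in recs]
            _, _, p = logrank_test(t, e, lp > 0)
            n_sig += p < 0.001
        assert n_sig >= 24  # >= 95% of seeds

    def test_hand_computed_six_subject_table(self):
        # groups A: (1, event), (3, event), (5, censored)
        #        B: (2, event), (4, censored), (6, event)
        # per-time O-E for group B: t=1: 0-3/6; t=2: 1-3/5; t=3: 0-2/4; t=6: 1-1
        # O-E = -0.5 + 0.4 - 0.5 + 0 = 0.4... computed below with variance
        t = np.array([1.0, 3.0, 5.0, 2.0, 4.0, 6.0])
        e = np.array([1, 1, 0, 1, 0, 1])
        g = np.array([0, 0, 0, 1, 1, 1])
        o_minus_e = 0.0
        var = 0.0
        for tt in np.unique(t[e == 1]):
            at = t >= tt
            n = at.sum()
            n1 = (at & (g == 1)).sum()
            d = ((t == tt) & (e == 1)).sum()
            d1 = ((t == tt) & (e == 1) & (g == 1)).sum()
            o_minus_e += d1 - d * n1 / n
            if n > 1:
                var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        expected_chi2 = o_minus_e**2 / var
        chi2, df, p = logrank_test(t, e, g)
        assert df == 1
        assert chi2 == pytest.approx(expected_chi2, rel=1e-9)

    def test_matches_maxstat_statistic_at_same_split(self, rng):
        times = rng.uniform(1, 100, 50)
        events = rng.integers(0, 2, 50)
        scores = rng.normal(size=50)
        high = scores > 0.0
        chi2, _, _ = logrank_test(times, events, high)
        z = standardized_logrank_statistic(high, times, events)
        assert z**2 == pytest.approx(chi2, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1.0, 2.0], [1, 1], [0, 0])


class TestCoxFit:
    def test_two_group_hazard_ratio_recovered(self):
        x = np.concatenate([np.zeros(1000), np.ones(1000)])
        recs = generate_survival(x * np.log(2.0), 600.0, 0.1, seed=3)
        df = pd.DataFrame({"grp": x})
        fit = cox_fit(df, [r.time_days for r in recs], [r.event for r in recs])
        beta = fit.coef["grp"]
        se = fit.se["grp"]
        assert abs(beta - np.log(2.0)) < 2 * se
        assert fit.hazard_ratios["grp"] == pytest.approx(np.exp(beta))

    def test_null_covariate_unbiased(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(300)
            recs = generate_survival(np.zeros(300), 600.0, 0.1, seed=seed)
            fit = cox_fit(pd.DataFrame({"x": x}),
                          [r.time_days for r in recs], [r.event for r in recs])
            hits += abs(fit.coef["x"]) < 2 * fit.se["x"]
        assert hits >= 16  # ~95% coverage, allow sampling slack

    def test_loglik_at_mle_beats_null(self, rng):
        from gliorad.signature import _breslow_neg_log_partial_likelihood

        x = rng.standard_normal(200)
        recs = generate_survival(x, 600.0, 0.0, seed=9)
        t = np.array([r.time_days for r in recs])
        e = np.array([r.event for r in recs])
        fit = cox_fit(pd.DataFrame({"x": x}), t, e)
        # continuous times carry no ties, so the Breslow null equals Efron's
        null_loglik = -_breslow_neg_log_partial_likelihood(np.zeros(200), t, e)
        assert fit.log_partial_likelihood >= null_loglik

    def test_constant_column_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            cox_fit(pd.DataFrame({"c": np.ones(30)}),
                    np.arange(1, 31), np.ones(30, int))


class TestCindex:
    def test_perfect_concordance(self):
        times = np.array([5.0, 3.0, 8.0, 1.0])
        res = harrell_cindex(-times, times, np.ones(4, int))
        assert res.cindex == 1.0

    def test_constant_predictor_half(self):
        res = harrell_cindex(np.ones(10), np.arange(1.0, 11.0), np.ones(10, int))
        assert res.cindex == 0.5

    def test_matches_brute_force_with_censoring(self, rng):
        for trial in range(5):
            n = 15
            pred = rng.normal(size=n)
            times = rng.uniform(1, 50, n)
            events = rng.integers(0, 2, n)
            if events.sum() == 0:
                events[0] = 1
            res = harrell_cindex(pred, times, events)
            c, conc, disc, tied = brute_force_cindex(pred, times, events)
            assert res.cindex == pytest.approx(c, abs=1e-12)
            assert (res.concordant, res.discordant, res.tied_risk) == (conc, disc, tied)

    def test_monotone_transform_invariance(self, rng):
        pred = rng.normal(size=30)
        times = rng.uniform(1, 50, 30)
        events = rng.integers(0, 2, 30)
        events[0] = 1
        a = harrell_cindex(pred, times, events).cindex
        b = harrell_cindex(np.exp(2.0 * pred), times, events).cindex
        assert a == b


class TestCompareCindex:
    def test_identical_predictors_null(self, rng):
        pred = rng.normal(size=50)
        times = rng.uniform(1, 50, 50)
        events = np.ones(50, int)
        delta, p = compare_cindex(pred, pred.copy(), times, events, seed=0)
        assert delta == 0.0
        assert p == 1.0

    def test_informative_beats_noise(self):
        wins = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            x = rng.standard_normal(400)
            recs = generate_survival(1.2 * x, 600.0, 0.1, seed=seed)
            t = np.array([r.time_days for r in recs])
            e = np.array([r.event for r in recs])
            noise = rng.standard_normal(400)
            delta, p = compare_cindex(x, noise, t, e, n_boot=200, seed=seed)
            wins += (delta > 0) and (p < 0.05)
        assert wins >= 9

    def test_swap_negates_delta(self, rng):
        a = rng.normal(size=60)
        b = rng.normal(size=60)
        times = rng.uniform(1, 50, 60)
        events = np.ones(60, int)
        d1, p1 = compare_cindex(a, b, times, events, n_boot=200, seed=4)
        d2, p2 = compare_cindex(b, a, times, events, n_boot=200, seed=4)
        assert d1 == pytest.approx(-d2, abs=1e-12)

    def test_too_few_bootstraps_rejected(self, rng):
        with pytest.raises(ValueError):
            compare_cindex(np.ones(5), np.zeros(5), np.arange(1.0, 6.0),
                           np.ones(5, int), n_boot=10)


class TestCalibration:
    @staticmethod
    def _well_specified(seed, n=1000, shift=0.0):
        rng = np.random.default_rng(seed)
        lp = rng.normal(0, 0.8, n)
        recs = generate_survival(lp, 646.0, 0.0, seed=seed, weibull_shape=1.2)
        t = np.array([r.time_days for r in recs])
        e = np.array([r.event for r in recs])
        # closed-form true survival at the horizon under the Weibull model
        from gliorad.synthetic import weibull_baseline_scale
        lam = weibull_baseline_scale(646.0, 1.2)
        horizon = 400.0
        s_true = np.exp(-((horizon / lam) ** 1.2) * np.exp(lp))
        pred = np.clip(s_true + shift, 1e-6, 1 - 1e-6)
        return pred, t, e, horizon

    def test_groupwise_km_predictions_give_zero_chi2(self, rng):
        # 10 groups of 20; in group g, g+5 subjects die before the horizon and
        # the rest are censored after it, so KM(horizon) = 1 - (g+5)/20 exactly
        horizon = 100.0
        times, events, pred = [], [], []
        for g in range(10):
            k = g + 5
            km = 1.0 - k / 20.0
            times += list(rng.uniform(1, 90, k)) + list(rng.uniform(110, 200, 20 - k))
            events += [1] * k + [0] * (20 - k)
            pred += [km] * 20
        times, events, pred = map(np.asarray, (times, events, pred))
        chi2, p = dagostino_nam_calibration(pred, times, events, horizon)
        assert chi2 == pytest.approx(0.0, abs=1e-9)

    def test_correct_model_calibrated(self):
        passes = 0
        n_seeds = 10
        for seed in range(n_seeds):
            pred, t, e, horizon = self._well_specified(seed)
            chi2, p = dagostino_nam_calibration(pred, t, e, horizon)
            passes += p > 0.05
        assert passes >= 9

    def test_shifted_predictions_worse(self):
        pred, t, e, horizon = self._well_specified(0)
        chi2_good, _ = dagostino_nam_calibration(pred, t, e, horizon)
        shifted = np.clip(pred + 0.2, 1e-6, 1 - 1e-6)
        chi2_bad, _ = dagostino_nam_calibration(shifted, t, e, horizon)
        assert chi2_bad > chi2_good

    def test_out_of_range_predictions_rejected(self):
        with pytest.raises(ValueError):
            dagostino_nam_calibration(np.linspace(0, 1, 60), np.arange(1.0, 61.0),
                                      np.ones(60, int), 30.0)


class TestCrossval:
    @staticmethod
    def _feature_cohort(seed, n=120, p=20, beta_img=1.0):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal((n, p))
        lp = beta_img * x[:, 0] - beta_img * x[:, 1]
        recs = generate_survival(lp, 600.0, 0.2, seed=seed)
        feats = pd.DataFrame(x, columns=[f"f{i}" for i in range(p)])
        t = np.array([r.time_days for r in recs])
        e = np.array([r.event for r in recs])
        return feats, t, e

    def test_null_features_near_chance(self):
        feats, t, e = self._feature_cohort(0, beta_img=0.0)
        try:
            res = crossval_cindex(feats, None, t, e, folds=5, seed=0,
                                  selection_cv_folds=3, n_alphas=15)
            assert 0.35 < res["mean"] < 0.65
        except ValueError:
            pass  # all-null cohorts may select nothing in some folds: acceptable

    def test_planted_signal_predictive(self):
        feats, t, e = self._feature_cohort(1, beta_img=1.2)
        res = crossval_cindex(feats, None, t, e, folds=5, seed=0,
                              selection_cv_folds=3, n_alphas=15)
        assert res["mean"] > 0.65

    def test_same_seed_reproducible(self):
        feats, t, e = self._feature_cohort(2, beta_img=1.0)
        r1 = crossval_cindex(feats, None, t, e, folds=5, seed=3,
                             selection_cv_folds=3, n_alphas=15)
        r2 = crossval_cindex(feats, None, t, e, folds=5, seed=3,
                             selection_cv_folds=3, n_alphas=15)
        assert r1["per_fold"] == r2["per_fold"]


class TestNomogram:
    @staticmethod
    def _fitted(seed=0, n=300):
        rng = np.random.default_rng(seed)
        cov = pd.DataFrame({
            "radscore": rng.normal(0, 1, n),
            "age": rng.uniform(35, 80, n),
            "kps_low": (rng.uniform(size=n) < 0.2).astype(float),
        })
        lp = 0.8 * cov["radscore"] + 0.02 * (cov["age"] - 60) + 0.5 * cov["kps_low"]
        recs = generate_survival(lp.to_numpy(), 646.0, 0.2, seed=seed)
        t = np.array([r.time_days for r in recs])
        e = np.array([r.event for r in recs])
        fit = cox_fit(cov, t, e)
        return build_nomogram(fit, cov, t, e), cov, t, e

    def test_reference_value_zero_points(self):
        model, cov, _, _ = self._fitted()
        for covname, rule in model.points.items():
            x = pd.DataFrame({c: [r["ref"]] for c, r in model.points.items()})
            assert model.total_points(x)[0] == pytest.approx(0.0, abs=1e-9)

    def test_largest_effect_spans_100_points(self):
        model, cov, _, _ = self._fitted()
        assert max(r["max_points"] for r in model.points.values()) == pytest.approx(100.0)

    def test_survival_at_time_zero_is_one(self):
        model, cov, _, _ = self._fitted()
        s = model.predict_survival(cov.iloc[:5], 0.0)
        np.testing.assert_allclose(s, 1.0)

    def test_baseline_survival_monotone(self):
        model, _, _, _ = self._fitted()
        assert (np.diff(model.baseline_survival) <= 1e-12).all()
        assert model.baseline_survival[0] <= 1.0

    def test_points_round_trip_matches_direct_prediction(self):
        model, cov, _, _ = self._fitted()
        rng = np.random.default_rng(42)
        patterns = pd.DataFrame({
            "radscore": rng.normal(0, 1, 100),
            "age": rng.uniform(35, 80, 100),
            "kps_low": (rng.uniform(size=100) < 0.5).astype(float),
        })
        for horizon in (365.0, 730.0):
            direct = model.predict_survival(patterns, horizon)
            via_points = model.survival_from_points(model.total_points(patterns), horizon)
            np.testing.assert_allclose(via_points, direct, atol=1e-6)


class TestClinicalDesign:
    def test_kps_threshold_configurable(self):
        clin = pd.DataFrame({"age": [60.0, 70.0], "kps": [70, 90],
                             "extent": ["GTR", "biopsy"]})
        d80 = clinical_design_matrix(clin, kps_threshold=80)
        d70 = clinical_design_matrix(clin, kps_threshold=70)
        assert d80["kps_low"].tolist() == [1.0, 0.0]
        assert d70["kps_low"].tolist() == [0.0, 0.0]
        assert d80["extent_GTR"].tolist() == [1.0, 0.0]
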