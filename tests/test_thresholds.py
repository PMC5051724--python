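import warnings

import numpy as np
import pandas as pd
import pytest

from accelcut import (
    ValidationError,
    auroc,
    compare_brands,
    fit_logistic,
    loocv_auroc,
    optimal_threshold,
    roc_curve,
    run_threshold_battery,
)


def brute_force_auroc(values, labels):
    """All-pairs enumeration with ties half-credited; independent oracle."""
    pos = [v for v, y in zip(values, labels) if y == 1]
    neg = [v for v, y in zip(values, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestFitLogistic:
    def test_uninformative_data_gives_flat_fit(self):
        rng = np.random.default_rng(0)
        x = np.r_[rng.normal(10, 2, 200), rng.normal(10, 2, 200)]
        y = np.r_[np.zeros(200, int), np.ones(200, int)]
        fit = fit_logistic((x, y))
        assert fit.converged
        assert abs(fit.slope) < 0.1
        np.testing.assert_allclose(fit.predict_proba(np.array([10.0])), 0.5, atol=0.05)

    def test_perfect_separation_triggers_fallback(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([0, 0, 1, 1])
        fit = fit_logistic((x, y))
        assert fit.fallback and not fit.converged
        # fallback still ranks correctly
        p = fit.predict_proba(x)
        assert p[0] < p[2] and p[1] < p[3]

    def test_parameter_recovery_within_3_se(self):
        rng = np.random.default_rng(2024)
        n = 2000
        x = rng.uniform(0, 100, n)
        eta = -2.0 + 0.1 * x
        y = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(int)
        fit = fit_logistic((x, y))
        assert fit.converged
        # observed-information standard errors
        p = fit.predict_proba(x)
        X = np.column_stack([np.ones_like(x), x])
        cov = np.linalg.inv((X * (p * (1 - p))[:, None]).T @ X)
        se = np.sqrt(np.diag(cov))
        assert abs(fit.intercept - (-2.0)) < 3 * se[0]
        assert abs(fit.slope - 0.1) < 3 * se[1]

    def test_matches_statsmodels_mle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        x = rng.normal(20, 5, 300)
        y = (rng.uniform(size=300) < 1 / (1 + np.exp(-(-3 + 0.15 * x)))).astype(int)
        fit = fit_logistic((x, y))
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        np.testing.assert_allclose(
            [fit.intercept, fit.slope], ref.params, rtol=1e-6, atol=1e-8
        )
        assert fit.log_likelihood == pytest.approx(ref.llf, rel=1e-9)

    def test_single_class_is_error(self):
        with pytest.raises(ValidationError):
            fit_logistic((np.arange(5.0), np.ones(5, int)))


class TestRocCurve:
    def test_perfectly_separated_pair(self):
        roc = roc_curve(np.array([5.0, 1.0]), np.array([1, 0]))
        perfect = roc[(roc.sensitivity == 1.0) & (roc.specificity == 1.0)]
        assert len(perfect) == 1
        assert perfect.iloc[0]["threshold"] == 5.0

    def test_all_tied_scores_only_degenerate_points(self):
        roc = roc_curve(np.array([2.0, 2.0, 2.0, 2.0]), np.array([0, 1, 0, 1]))
        pairs = set(zip(roc.sensitivity, roc.specificity))
        assert pairs == {(0.0, 1.0), (1.0, 0.0)}

    def test_hand_enumerated_four_points(self):
        values = np.array([3.0, 5.0, 1.0, 4.0])
        labels = np.array([1, 1, 0, 0])
        roc = roc_curve(values, labels).set_index("threshold")
        assert roc.loc[5.0, "sensitivity"] == 0.5
        assert roc.loc[5.0, "specificity"] == 1.0
        assert roc.loc[3.0, "sensitivity"] == 1.0
        assert roc.loc[3.0, "specificity"] == 0.5
        # 4 distinct score thresholds + 1 degenerate endpoint survive dedup
        assert np.isfinite(roc.index).sum() == 4


class TestOptimalThreshold:
    def test_tie_break_prefers_higher_sensitivity(self):
        roc = roc_curve(np.array([3.0, 5.0, 1.0, 4.0]), np.array([1, 1, 0, 0]))
        thr, sens, spec = optimal_threshold(roc)
        # J = 0.5 at thresholds 3 (sens 1.0) and 5 (sens 0.5): pick 3
        assert (thr, sens, spec) == (3.0, 1.0, 0.5)

    def test_perfect_separation_picks_lowest_perfect_threshold(self):
        roc = roc_curve(
            np.array([10.0, 11.0, 1.0, 2.0]), np.array([1, 1, 0, 0])
        )
        thr, sens, spec = optimal_threshold(roc)
        assert (sens, spec) == (1.0, 1.0)
        assert thr == 10.0

    def test_sens_spec_recomputable_from_threshold(self):
        rng = np.random.default_rng(8)
        values = np.round(rng.normal(10, 4, 60), 1)
        labels = (rng.uniform(size=60) < 0.4).astype(int)
        thr, sens, spec = optimal_threshold(roc_curve(values, labels))
        pos, neg = values[labels == 1], values[labels == 0]
        assert sens == pytest.approx(np.mean(pos >= thr))
        assert spec == pytest.approx(np.mean(neg < thr))

    def test_anti_discriminating_scores_warn(self):
        roc = roc_curve(np.array([1.0, 2.0, 9.0, 10.0]), np.array([1, 1, 0, 0]))
        with pytest.warns(UserWarning, match="J <= 0"):
            optimal_threshold(roc)

    def test_single_distinct_score_is_degenerate(self):
        roc = roc_curve(np.full(6, 3.0), np.array([0, 1, 0, 1, 0, 1]))
        with pytest.raises(ValidationError, match="degenerate"):
            optimal_threshold(roc)


class TestAuroc:
    def test_all_tied_scores_give_half(self):
        res = auroc(np.full(10, 7.0), np.array([0, 1] * 5))
        assert res.auroc == 0.5

    def test_hand_counted_example(self):
        res = auroc(np.array([3.0, 5.0, 1.0, 4.0]), np.array([1, 1, 0, 0]))
        assert res.auroc == pytest.approx(0.75)  # (1 + 0 + 1 + 1) / 4

    def test_brute_force_agreement_on_200_random_datasets(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            n1, n0 = rng.integers(1, 16, 2)
            # integer-ish scores force plenty of ties
            values = np.r_[rng.integers(0, 8, n1), rng.integers(0, 8, n0)].astype(float)
            labels = np.r_[np.ones(n1, int), np.zeros(n0, int)]
            assert auroc(values, labels).auroc == pytest.approx(
                brute_force_auroc(values, labels), abs=1e-12
            )

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(17)
        for _ in range(20):
            values = rng.normal(size=50)
            labels = rng.integers(0, 2, 50)
            if labels.min() == labels.max():
                continue
            assert auroc(values, labels).auroc == pytest.approx(
                roc_auc_score(labels, values), abs=1e-12
            )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        values = rng.normal(10, 3, 80)
        labels = rng.integers(0, 2, 80)
        probs = 1 / (1 + np.exp(-(-5 + 0.5 * values)))
        assert auroc(values, labels).auroc == pytest.approx(
            auroc(probs, labels).auroc, abs=1e-12
        )

    def test_null_ci_coverage_at_least_90_percent(self):
        """DeLong 95% CI should cover 0.5 in >= 90% of null replicates."""
        rng = np.random.default_rng(314)
        covered = 0
        for _ in range(200):
            values = rng.normal(size=66)
            labels = np.r_[np.ones(33, int), np.zeros(33, int)]
            lo, hi = auroc(values, labels).ci
            covered += lo <= 0.5 <= hi
        assert covered >= 0.90 * 200

    def test_power_with_3sd_separation(self):
        rng = np.random.default_rng(271)
        good = 0
        for _ in range(200):
            values = np.r_[rng.normal(3, 1, 33), rng.normal(0, 1, 33)]
            labels = np.r_[np.ones(33, int), np.zeros(33, int)]
            good += auroc(values, labels).auroc > 0.95
        assert good >= 0.95 * 200


class TestLoocv:
    def test_perfectly_separable_data_scores_one(self):
        rng = np.random.default_rng(10)
        x = np.r_[rng.normal(0, 1, 30), rng.normal(20, 1, 30)]
        y = np.r_[np.zeros(30, int), np.ones(30, int)]
        res = loocv_auroc((x, y))
        assert res.auroc == pytest.approx(1.0)

    def test_participant_unit_holds_out_whole_subjects(self):
        rng = np.random.default_rng(12)
        frames = []
        for p in range(8):
            frames.append(
                pd.DataFrame(
                    {
                        "value_mg": np.r_[rng.normal(5, 1, 4), rng.normal(15, 1, 2)],
                        "label": [0] * 4 + [1] * 2,
                        "participant_id": f"P{p}",
                    }
                )
            )
        from accelcut import DiscriminationDataset

        ds = DiscriminationDataset("walk", "mad", "epoch", pd.concat(frames))
        res = loocv_auroc(ds, unit="participant")
        assert res.auroc > 0.95

    def test_single_class_training_folds_use_prevalence(self):
        x = np.array([1.0, 2.0, 3.0, 10.0])
        y = np.array([0, 0, 0, 1])
        with pytest.warns(UserWarning, match="prevalence"):
            loocv_auroc((x, y))


class TestCompareBrands:
    def test_identical_groups(self):
        res = compare_brands([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_large_shift_tiny_variance(self):
        a = np.array([1.0, 2.0, 3.0])
        res = compare_brands(a, a + 10.0)
        assert res.p < 0.001

    def test_hand_computed_pooled_t(self):
        res = compare_brands([1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0])
        # pooled s^2 = 5/3, se = sqrt(5/6), t = -1/se = -1.095 (3 s.f.)
        assert res.t == pytest.approx(-1.095, abs=5e-4)
        assert res.df == 6

    def test_zero_variance_equal_means_flagged(self):
        res = compare_brands([2.0, 2.0], [2.0, 2.0])
        assert res.flagged and res.p == 1.0


class TestBattery:
    def test_full_strata_counts_and_walk_separation(self, small_labeled):
        battery = run_threshold_battery(small_labeled)
        assert len(battery) == 2 * 2 * 2 * 5  # metric x brand x placement x disc
        walk = battery[battery.discrimination == "walk"]
        assert (walk.auroc > 0.9).all()

    def test_single_brand_input_gives_20_reports(self, small_labeled):
        one = small_labeled[small_labeled.brand == "AG"]
        battery = run_threshold_battery(one)
        assert len(battery) == 20

    def test_loocv_not_wildly_optimistic(self, small_labeled):
        battery = run_threshold_battery(small_labeled)
        motion = battery[battery.discrimination != "standing"]
        assert (motion.loocv_auroc <= motion.auroc + 0.05).all()

    def test_missing_stratum_warns_and_skips(self, small_labeled):
        no_walk = small_labeled[small_labeled.activity_id != 16]
        with pytest.warns(UserWarning, match="walk"):
            with warnings.catch_warnings():
                warnings.simplefilter("always")
                battery = run_threshold_battery(
                    no_walk[no_walk.brand == "AG"]
                )
        assert set(battery.discrimination) == {
            "standing", "washing_pots", "dusting", "sweeping",
        }
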