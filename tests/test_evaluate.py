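import numpy as np
import pandas as pd
import pytest

from bedtherm.evaluate import (AgreementUndefinedError,
                               ConstantReferenceError, bland_altman,
                               change_curve, grand_average_and_correlate,
                               make_subject_folds, learning_curve, run_cv,
                               r_squared, smooth_estimate)
from bedtherm.datasets import fold_accuracy_table


def brute_force_agreement(s, y):
    """Independent single-pass reference: loop-based bias / SD_d / LoA."""
    pairs = [(a, b) for a, b in zip(s, y)
             if np.isfinite(a) and np.isfinite(b)]
    m = len(pairs)
    diffs = [a - b for a, b in pairs]
    bias = sum(diffs) / m
    sd = (sum((d - bias) ** 2 for d in diffs) / (m - 1)) ** 0.5
    return bias, sd, bias - 1.96 * sd, bias + 1.96 * sd


class TestBlandAltman:
    def test_perfect_agreement(self):
        s = np.linspace(30, 32, 50)
        ba = bland_altman(s, s.copy())
        assert ba.bias == 0.0 and ba.sd_d == 0.0
        assert ba.lower_loa == 0.0 and ba.upper_loa == 0.0

    def test_hand_computed_differences(self):
        """Differences {0.2, 0.4, 0.6}: bias 0.4, SD_d 0.2 (n-1 denominator),
        LoA (0.008, 0.792)."""
        s = np.array([30.2, 30.4, 30.6])
        y = np.array([30.0, 30.0, 30.0])
        ba = bland_altman(s, y)
        assert ba.bias == pytest.approx(0.4)
        assert ba.sd_d == pytest.approx(0.2)
        assert ba.lower_loa == pytest.approx(0.008)
        assert ba.upper_loa == pytest.approx(0.792)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        s = rng.normal(31, 0.5, size=300)
        y = s + rng.normal(0, 0.3, size=300)
        ba = bland_altman(s, y)
        bias, sd, lo, hi = brute_force_agreement(s, y)
        assert abs(ba.bias - bias) < 1e-10 and abs(ba.sd_d - sd) < 1e-10
        assert abs(ba.lower_loa - lo) < 1e-10 and abs(ba.upper_loa - hi) < 1e-10

    def test_loa_identity(self):
        rng = np.random.default_rng(4)
        s, y = rng.normal(size=100), rng.normal(size=100)
        ba = bland_altman(s, y)
        assert ba.upper_loa - ba.lower_loa == pytest.approx(
            2 * 1.96 * ba.sd_d, abs=1e-12)

    def test_shift_equivariance(self):
        rng = np.random.default_rng(5)
        s, y = rng.normal(31, 1, 80), rng.normal(31, 1, 80)
        base = bland_altman(s, y)
        shifted = bland_altman(s, y + 0.7)
        assert shifted.bias == pytest.approx(base.bias - 0.7, abs=1e-12)
        assert shifted.sd_d == pytest.approx(base.sd_d, abs=1e-12)

    def test_series_alignment(self):
        s = pd.Series([30.0, 30.5, 31.0], index=[5, 6, 7])
        y = pd.Series([30.2, 30.4], index=[6, 7])
        assert bland_altman(s, y).m == 2

    def test_too_few_pairs(self):
        with pytest.raises(AgreementUndefinedError):
            bland_altman([30.0], [30.0])


class TestRSquared:
    def test_perfect_fit(self):
        s = np.linspace(30, 32, 40)
        assert r_squared(s, s.copy()) == pytest.approx(1.0)

    def test_mean_predictor_zero(self):
        rng = np.random.default_rng(6)
        s = rng.normal(31, 1, 50)
        y = np.full(50, s.mean())
        assert r_squared(s, y) == pytest.approx(0.0, abs=1e-12)

    def test_direct_formula_oracle(self):
        rng = np.random.default_rng(7)
        s = rng.normal(31, 1, 200)
        y = s + rng.normal(0, 0.4, 200)
        expected = 1 - np.sum((s - y) ** 2) / np.sum((s - s.mean()) ** 2)
        assert r_squared(s, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_reference_rejected(self):
        with pytest.raises(ConstantReferenceError):
            r_squared(np.full(10, 31.0), np.arange(10.0))


class TestSubjectFolds:
    def test_balanced_sizes_18_by_5(self):
        folds = make_subject_folds([f"S{i:02d}" for i in range(18)], k=5, seed=0)
        assert sorted(len(f) for f in folds) == [3, 3, 4, 4, 4]

    def test_single_fold(self):
        subjects = ["a", "b", "c"]
        folds = make_subject_folds(subjects, k=1, seed=0)
        assert sorted(folds[0]) == subjects

    def test_disjoint_and_exhaustive(self):
        subjects = [f"S{i}" for i in range(17)]
        for seed in range(20):
            folds = make_subject_folds(subjects, k=5, seed=seed)
            flat = [s for f in folds for s in f]
            assert len(flat) == len(set(flat)) == len(subjects)

    def test_deterministic(self):
        a = make_subject_folds(list("abcdefgh"), k=3, seed=9)
        assert a == make_subject_folds(list("abcdefgh"), k=3, seed=9)

    def test_too_many_folds_rejected(self):
        with pytest.raises(ValueError):
            make_subject_folds(["a", "b"], k=3)


class TestFoldAggregation:
    def test_bundled_fold_table_grand_means(self):
        """Unweighted means of the bundled five-fold accuracy table
        reproduce its grand means."""
        t = fold_accuracy_table()
        assert round(t["r2"].mean(), 2) == 0.87
        assert t["bias"].mean() == pytest.approx(-0.002)
        assert round(t["lower_loa"].mean(), 2) == -0.79
        assert round(t["upper_loa"].mean(), 2) == 0.79


@pytest.fixture(scope="module")
def cv_and_curve(small_features):
    res = run_cv(small_features, k=3, seed=2)
    lc = learning_curve(small_features, fractions=(0.5, 1.0), k=3, seed=2)
    return res, lc


class TestSmallStudyCV:
    def test_no_leakage(self, small_features, cv_and_curve):
        res, _ = cv_and_curve
        for fold in res.folds:
            assert not set(fold.train_subjects) & set(fold.val_subjects)
            assert (set(fold.train_subjects) | set(fold.val_subjects)
                    == set(small_features.subjects))

    def test_fold_means_are_session_means(self, cv_and_curve):
        res, _ = cv_and_curve
        f = res.folds[0]
        assert f.bias == pytest.approx(
            np.mean([s.bias for _, s in f.session_stats]))
        assert f.r2 == pytest.approx(
            np.mean([s.r2 for _, s in f.session_stats]))

    def test_learning_curve_full_fraction_matches_cv(self, cv_and_curve):
        res, lc = cv_and_curve
        full = lc[lc["fraction"] == 1.0].iloc[0]
        assert full["val_r2"] == pytest.approx(res.grand_means["r2"], abs=1e-12)

    def test_train_at_least_validation(self, cv_and_curve):
        _, lc = cv_and_curve
        assert (lc["train_r2"] >= lc["val_r2"] - 0.02).all()


class TestChangeCurve:
    def test_constant_series_all_zero(self):
        s = pd.Series(np.full(120, 31.0), index=np.arange(1, 121))
        np.testing.assert_array_equal(change_curve(s, lights_off=600.0),
                                      np.zeros(61))

    def test_linear_ramp_closed_form(self):
        """+0.02 degC/min gives delta(60) = 1.2 degC."""
        s = pd.Series(31.0 + 0.02 * np.arange(120), index=np.arange(1, 121))
        curve = change_curve(s, lights_off=600.0)
        assert curve[0] == 0.0
        assert curve[60] == pytest.approx(1.2)

    def test_anchor_always_zero(self):
        rng = np.random.default_rng(8)
        s = pd.Series(rng.normal(31, 1, 120), index=np.arange(1, 121))
        assert change_curve(s, lights_off=1234.0)[0] == 0.0

    def test_missing_lights_off_rejected(self):
        s = pd.Series(np.full(120, 31.0), index=np.arange(1, 121))
        with pytest.raises(ValueError):
            change_curve(s, lights_off=None)

    def test_missing_minutes_propagate(self):
        idx = [i for i in range(1, 121) if i != 20]
        s = pd.Series(np.full(119, 31.0), index=idx)
        curve = change_curve(s, lights_off=600.0)
        assert np.isnan(curve[9]) and np.isfinite(curve[10])


class TestGrandAverage:
    def test_identical_groups_r_one(self):
        rng = np.random.default_rng(9)
        curves = [np.cumsum(rng.normal(0.02, 0.01, 61)) for _ in range(4)]
        _, _, r, p = grand_average_and_correlate(curves, [c.copy() for c in curves])
        assert r == pytest.approx(1.0)

    def test_negated_group_r_minus_one(self):
        rng = np.random.default_rng(10)
        curves = [np.cumsum(rng.normal(0.02, 0.01, 61)) for _ in range(4)]
        _, _, r, _ = grand_average_and_correlate(curves, [-c for c in curves])
        assert r == pytest.approx(-1.0)

    def test_too_few_curves_rejected(self):
        with pytest.raises(ValueError):
            grand_average_and_correlate([np.zeros(61)], [np.zeros(61)])


class TestSmoothEstimate:
    def test_preserves_index(self):
        y = pd.Series(np.random.default_rng(11).normal(31, 0.2, 100),
                      index=np.arange(5, 105))
        sm = smooth_estimate(y)
        assert list(sm.index) == list(y.index)

    def test_reduces_noise_variance(self):
        rng = np.random.default_rng(12)
        y = pd.Series(31.0 + rng.normal(0, 0.3, 200), index=np.arange(1, 201))
        assert smooth_estimate(y).var() < y.var()
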