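import numpy as np
import pandas as pd
import pytest
from scipy.stats import median_test

import hfopipe.stats as stats
from hfopipe.stats import (
    BONFERRONI_ALPHA,
    DEFAULT_PARAM_GRID,
    leave_one_patient_out_cv,
    moods_median_test,
    nested_cv_rf,
    remove_outliers,
    run_contrasts,
    smote_oversample,
    zscore_features,
)

FEATS = ["am_fr", "am_ripples", "fr_fr", "fr_ripples", "d_hfo"]
FAST_GRID = {"n_estimators": [50], "max_depth": [None], "max_features": ["sqrt"], "max_samples": [0.8]}


def make_table(n1=60, n2=40, shift=0.0, seed=0, n_patients=4, region_effect=False):
    rng = np.random.default_rng(seed)
    rows = []
    for cls, n, sh in (("Class-1", n1, shift), ("Class-2", n2, 0.0)):
        X = rng.standard_normal((n, 5)) + 10
        X[:, 0] += sh
        for i, x in enumerate(X):
            region = "MTL" if (i % 2 == 0 or not region_effect) else "Neocortex"
            rows.append(
                dict(zip(FEATS, x), patient_id=f"p{i % n_patients}", channel="c",
                     region=region, **{"class": cls})
            )
    return pd.DataFrame(rows)


class TestZscore:
    def test_standardized_moments(self):
        t = make_table()
        z, scaler = zscore_features(t)
        for c in FEATS:
            assert abs(z[c].mean()) < 1e-9
            assert z[c].std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_stored_scaler_reproduces(self):
        t = make_table()
        z, scaler = zscore_features(t)
        z2 = stats.apply_scaler(t, scaler)
        pd.testing.assert_frame_equal(z, z2)

    def test_single_event_rejected(self):
        with pytest.raises(ValueError):
            zscore_features(make_table(n1=1, n2=0))

    def test_zero_variance_feature_named(self):
        t = make_table()
        t["d_hfo"] = 5.0
        with pytest.raises(ValueError, match="d_hfo"):
            zscore_features(t)


class TestMoodsMedianTest:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0]
        stat, p, _ = moods_median_test(x, x)
        assert stat == 0.0 and p == 1.0

    def test_hand_computed_extreme_table(self):
        stat, p, extras = moods_median_test([1, 1, 1, 5], [9, 9, 9, 9])
        assert stat == pytest.approx(8.0)
        assert extras["table"] == ((0, 4), (4, 0))

    def test_degenerate_all_identical(self):
        stat, p, extras = moods_median_test([2.0, 2.0], [2.0, 2.0, 2.0])
        assert stat == 0.0 and p == 1.0 and extras["degenerate"]

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            moods_median_test([], [1.0])

    def test_matches_scipy_oracle(self):
        """Chi-square equals scipy's median_test with ties='below', no correction."""
        rng = np.random.default_rng(7)
        for _ in range(300):
            x = rng.integers(0, 8, rng.integers(3, 25)).astype(float)
            y = rng.integers(0, 8, rng.integers(3, 25)).astype(float)
            stat, p, extras = moods_median_test(x, y)
            if extras["degenerate"]:
                continue
            ref_stat, ref_p, _, _ = median_test(x, y, ties="below", correction=False)
            assert stat == pytest.approx(ref_stat, abs=1e-9)
            assert p == pytest.approx(ref_p, abs=1e-9)


class TestSmote:
    def test_balances_classes_and_keeps_originals(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((30, 5))
        y = np.array([0] * 20 + [1] * 10)
        Xb, yb = smote_oversample(X, y, seed=1)
        assert (yb == 0).sum() == (yb == 1).sum() == 20
        np.testing.assert_array_equal(Xb[:30], X)

    def test_synthetic_points_in_minority_convex_hull_segments(self):
        rng = np.random.default_rng(2)
        Xm = rng.uniform(5, 6, (10, 5))
        X = np.vstack([rng.uniform(0, 1, (30, 5)), Xm])
        y = np.array([0] * 30 + [1] * 10)
        Xb, yb = smote_oversample(X, y, seed=3)
        new = Xb[40:]
        assert np.all(new >= 5.0) and np.all(new <= 6.0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((25, 5))
        y = np.array([0] * 15 + [1] * 10)
        a = smote_oversample(X, y, seed=9)[0]
        b = smote_oversample(X, y, seed=9)[0]
        np.testing.assert_array_equal(a, b)

    def test_balanced_input_passthrough(self):
        X = np.zeros((10, 2))
        y = np.array([0] * 5 + [1] * 5)
        Xb, yb = smote_oversample(X, y, seed=0)
        assert Xb.shape == X.shape


class TestRemoveOutliers:
    def test_planted_extreme_point_removed(self):
        rng = np.random.default_rng(5)
        t = make_table(n1=100, n2=0, n_patients=1)
        extreme = t.iloc[0].copy()
        extreme[FEATS] = 10 + 20 * t[FEATS].std().values  # ~20 SD away
        t = pd.concat([t, extreme.to_frame().T], ignore_index=True)
        t[FEATS] = t[FEATS].astype(float)
        kept = remove_outliers(t, seed=0)
        assert len(kept) < len(t)
        assert 100 not in kept.index  # the planted point is gone

    def test_removal_bounded_by_contamination(self):
        t = make_table(n1=200, n2=0, n_patients=1)
        kept = remove_outliers(t, contamination=0.05, seed=0)
        assert len(t) - len(kept) <= 10

    def test_small_group_passthrough(self):
        t = make_table(n1=5, n2=0, n_patients=1)
        pd.testing.assert_frame_equal(remove_outliers(t, seed=0), t)


class TestNestedCV:
    def test_perfectly_separable_single_feature(self):
        t = make_table(n1=60, n2=60, shift=50.0, seed=1)
        rep = nested_cv_rf(t, "class", seed=0, param_grid=FAST_GRID)
        assert rep["auc_mean"] >= 99.0

    def test_importances_sum_to_one(self):
        t = make_table(n1=60, n2=60, shift=2.0, seed=2)
        rep = nested_cv_rf(t, "class", seed=0, param_grid=FAST_GRID)
        assert sum(rep["importances"].values()) == pytest.approx(1.0, abs=1e-6)
        assert all(v >= 0 for v in rep["importances"].values())

    def test_permuting_feature_degrades_its_importance(self):
        t = make_table(n1=80, n2=80, shift=3.0, seed=3)
        rep = nested_cv_rf(t, "class", seed=0, param_grid=FAST_GRID)
        assert max(rep["importances"], key=rep["importances"].get) == "am_fr"
        rng = np.random.default_rng(0)
        t2 = t.copy()
        t2["am_fr"] = rng.permutation(t2["am_fr"].values)
        rep2 = nested_cv_rf(t2, "class", seed=0, param_grid=FAST_GRID)
        assert rep2["importances"]["am_fr"] < rep["importances"]["am_fr"] / 2

    def test_single_class_rejected(self):
        t = make_table(n1=40, n2=0)
        with pytest.raises(ValueError):
            nested_cv_rf(t, "class", seed=0, param_grid=FAST_GRID)

    def test_smote_never_sees_evaluation_folds(self, monkeypatch):
        """Every SMOTE call operates on a training subset, never the full data."""
        t = make_table(n1=60, n2=40, shift=1.0, seed=4)
        calls = []
        original = stats.smote_oversample

        def spy(X, y, seed=None, k=5):
            calls.append(len(X))
            return original(X, y, seed=seed, k=k)

        monkeypatch.setattr(stats, "smote_oversample", spy)
        nested_cv_rf(t, "class", seed=0, param_grid=FAST_GRID)
        assert calls and all(n < len(t) for n in calls)

    def test_deterministic_given_seed(self):
        t = make_table(n1=50, n2=40, shift=1.0, seed=5)
        r1 = nested_cv_rf(t, "class", seed=7, param_grid=FAST_GRID)
        r2 = nested_cv_rf(t, "class", seed=7, param_grid=FAST_GRID)
        assert r1["auc_mean"] == r2["auc_mean"]
        assert r1["importances"] == r2["importances"]


class TestLeaveOnePatientOut:
    def test_homogeneous_effect_consistent_with_nested(self):
        t = make_table(n1=150, n2=100, shift=3.0, seed=6, n_patients=5)
        lopo = leave_one_patient_out_cv(t, "class", seed=0, param_grid=FAST_GRID)
        nested = nested_cv_rf(t, "class", seed=0, param_grid=FAST_GRID)
        assert abs(lopo["auc_mean"] - nested["auc_mean"]) <= 5.0

    def test_reversed_effect_patient_scores_below_chance(self):
        t = make_table(n1=120, n2=120, shift=3.0, seed=7, n_patients=4)
        flip = t["patient_id"] == "p0"
        # mirror about the pooled midpoint: the effect reverses but the
        # values stay inside the training range
        mid = t["am_fr"].mean()
        t.loc[flip, "am_fr"] = 2 * mid - t.loc[flip, "am_fr"]
        rep = leave_one_patient_out_cv(t, "class", seed=0, param_grid=FAST_GRID)
        assert min(rep["fold_aucs"]) < 50.0

    def test_two_patients_rejected(self):
        t = make_table(n1=40, n2=40, n_patients=2)
        with pytest.raises(ValueError):
            leave_one_patient_out_cv(t, "class", seed=0, param_grid=FAST_GRID)


class TestRunContrasts:
    def test_twenty_five_tests_emitted(self):
        t = make_table(n1=80, n2=60, shift=1.0, seed=8, region_effect=True)
        tests, reports = run_contrasts(t, seed=0)
        assert len(tests) == 25
        assert reports == []

    def test_bonferroni_threshold(self):
        assert BONFERRONI_ALPHA == pytest.approx(0.05 / 25)

    def test_missing_stratum_skipped(self):
        t = make_table(n1=80, n2=60, shift=1.0, seed=9)  # all MTL
        tests, _ = run_contrasts(t, seed=0)
        groupings = {x.grouping for x in tests}
        assert "class1-vs-class2-neocortex" not in groupings
        assert "class1-vs-class2-all" in groupings
        assert len(tests) == 10  # only the two all-MTL-feasible contrasts
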