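"""Evaluation protocol: SMOTE, stratified folds, metrics, the paired test,
and the experiment/results objects."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import neojaundice as nj
from neojaundice.evaluation import METRIC_NAMES


class TestSmote:
    def test_equalizes_counts(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(68, 4))
        y = np.array([1] * 24 + [0] * 44)
        Xb, yb = nj.smote_balance(X, y, seed=1)
        _, counts = np.unique(yb, return_counts=True)
        assert counts.tolist() == [44, 44]
        np.testing.assert_array_equal(Xb[:68], X)  # originals untouched

    def test_already_balanced_unchanged(self):
        X = np.arange(20.0).reshape(10, 2)
        y = np.array([0] * 5 + [1] * 5)
        Xb, yb = nj.smote_balance(X, y, seed=1)
        np.testing.assert_array_equal(Xb, X)
        np.testing.assert_array_equal(yb, y)

    def test_synthetic_points_stay_on_minority_segment(self):
        """Minority samples on a line: every interpolate lies on that line."""
        t = np.linspace(0.0, 1.0, 5)
        minority = np.stack([t, 2 * t + 1], axis=1)
        majority = np.random.default_rng(3).normal(5.0, 0.1, size=(20, 2))
        X = np.vstack([minority, majority])
        y = np.array([1] * 5 + [0] * 20)
        Xb, yb = nj.smote_balance(X, y, seed=4)
        new = Xb[len(X):]
        np.testing.assert_allclose(new[:, 1], 2 * new[:, 0] + 1, atol=1e-9)
        assert new[:, 0].min() >= -1e-9 and new[:, 0].max() <= 1 + 1e-9

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 3))
        y = np.array([0] * 22 + [1] * 8)
        a = nj.smote_balance(X, y, seed=9)
        b = nj.smote_balance(X, y, seed=9)
        np.testing.assert_array_equal(a[0], b[0])

    def test_single_sample_minority_raises(self):
        X = np.zeros((5, 2))
        y = np.array([0, 0, 0, 0, 1])
        with pytest.raises(ValueError):
            nj.smote_balance(X, y)


class TestStratifiedFolds:
    def test_exactly_balanced_split(self):
        y = np.array([0] * 20 + [1] * 20)
        folds = nj.stratified_kfold_split(y, k=5, seed=0)
        for f in folds:
            assert len(f) == 8
            assert (y[f] == 1).sum() == 4

    def test_study_sized_split(self):
        y = np.array(["healthy"] * 44 + ["jaundiced"] * 24)
        folds = nj.stratified_kfold_split(y, k=5, seed=1)
        sizes = sorted(len(f) for f in folds)
        assert set(sizes) <= {13, 14}
        for f in folds:
            assert (y[f] == "jaundiced").sum() in (4, 5)

    def test_folds_partition_indices(self):
        y = np.array([0] * 31 + [1] * 17)
        folds = nj.stratified_kfold_split(y, k=4, seed=2)
        joined = np.concatenate(folds)
        assert len(joined) == len(set(joined)) == len(y)

    def test_class_smaller_than_k_raises(self):
        y = np.array([0] * 10 + [1] * 3)
        with pytest.raises(ValueError):
            nj.stratified_kfold_split(y, k=5)


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array(["jaundiced", "healthy", "jaundiced", "healthy"])
        fm = nj.compute_metrics(y, y, [0.9, 0.1, 0.8, 0.2])
        assert (fm.accuracy, fm.precision, fm.recall, fm.f1, fm.auc) == (1, 1, 1, 1, 1)

    def test_constant_scores_give_chance_auc(self):
        y = np.array(["jaundiced", "healthy", "jaundiced", "healthy"])
        fm = nj.compute_metrics(y, y, [0.5] * 4)
        assert fm.auc == 0.5

    def test_hand_worked_confusion_table(self):
        """2x2 table worked by hand: macro precision 5/6, macro recall 3/4."""
        true = np.array(["jaundiced", "jaundiced", "healthy", "healthy"])
        pred = np.array(["jaundiced", "healthy", "healthy", "healthy"])
        fm = nj.compute_metrics(true, pred, [0.9, 0.4, 0.3, 0.2])
        assert fm.accuracy == 0.75
        np.testing.assert_allclose(fm.precision, 5 / 6)
        np.testing.assert_allclose(fm.recall, 0.75)
        assert fm.auc == 1.0  # all 4 jaundiced-healthy score pairs ordered correctly

    def test_auc_equals_pairwise_counting(self):
        """Tie-handling AUC definition checked by brute-force pair counting."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(4, 20))
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                continue
            s = np.round(rng.random(n), 1)  # coarse scores force ties
            wins = half = total = 0
            for i in np.nonzero(y == 1)[0]:
                for j in np.nonzero(y == 0)[0]:
                    total += 1
                    wins += s[i] > s[j]
                    half += s[i] == s[j]
            expected = (wins + 0.5 * half) / total
            fm = nj.compute_metrics(y, y, s)
            np.testing.assert_allclose(fm.auc, expected, atol=1e-12)

    def test_single_class_truth_raises(self):
        y = np.array(["healthy"] * 4)
        with pytest.raises(ValueError):
            nj.compute_metrics(y, y, [0.1] * 4)


class TestPairedTTest:
    def test_identical_scores(self):
        res = nj.cv_paired_ttest([0.8, 0.7, 0.9], [0.8, 0.7, 0.9])
        assert res.t_statistic == 0.0 and res.p_value == 1.0
        assert res.degrees_of_freedom == 2

    def test_antisymmetry(self):
        a = [0.9, 0.8, 0.85, 0.7, 0.95]
        b = [0.8, 0.75, 0.9, 0.6, 0.85]
        ab = nj.cv_paired_ttest(a, b)
        ba = nj.cv_paired_ttest(b, a)
        assert ab.t_statistic == -ba.t_statistic
        assert ab.p_value == ba.p_value

    def test_hand_evaluated_statistic(self):
        """diffs (0.1,0.2,0.0,0.1,0.1): mean 0.1, s=sqrt(0.005), t=sqrt(10)."""
        b = np.array([0.5, 0.5, 0.5, 0.5, 0.5])
        a = b + [0.1, 0.2, 0.0, 0.1, 0.1]
        res = nj.cv_paired_ttest(a, b)
        np.testing.assert_allclose(res.t_statistic, np.sqrt(10.0), rtol=1e-12)
        assert res.degrees_of_freedom == 4

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            a = rng.random(5)
            b = rng.random(5)
            res = nj.cv_paired_ttest(a, b)
            ref = sps.ttest_rel(a, b)
            np.testing.assert_allclose(res.t_statistic, ref.statistic, atol=1e-10)
            np.testing.assert_allclose(res.p_value, ref.pvalue, atol=1e-10)

    def test_degenerate_constant_difference(self):
        res = nj.cv_paired_ttest([0.9] * 5, [0.8] * 5)
        assert res.degenerate and res.p_value == 0.0
        assert np.isinf(res.t_statistic) and res.t_statistic > 0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            nj.cv_paired_ttest([0.1, 0.2], [0.1, 0.2, 0.3])


class TestExperiment:
    def test_report_shape(self, small_results):
        mm = small_results.mean_metrics
        assert len(mm) == 3 * 4  # feature sets x models
        assert set(METRIC_NAMES) <= set(mm.columns)
        assert set(mm.feature_set) == {"skin", "eye", "fusion"}

    def test_means_equal_fold_averages(self, small_results):
        mm = small_results.mean_metrics.set_index(["feature_set", "model"])
        for (fs, model), row in mm.iterrows():
            for metric in METRIC_NAMES:
                folds = small_results.fold_scores(fs, model, metric)
                assert len(folds) == 5
                np.testing.assert_allclose(row[metric], folds.mean(), atol=1e-12)

    def test_pairwise_table_covers_model_and_featureset_pairs(self, small_results):
        pt = small_results.pairwise_tests()
        within = pt[pt.feature_set_a == pt.feature_set_b]
        across = pt[pt.model_a == pt.model_b]
        assert len(within) == 3 * 6 * 5   # sets x model pairs x metrics
        assert len(across) == 4 * 3 * 5   # models x set pairs x metrics
        assert len(pt) == len(within) + len(across)
        assert ((pt.p >= 0) & (pt.p <= 1)).all()
        assert (pt.df == 4).all()

    def test_experiment_deterministic_under_seed(self, small_cohort_features):
        feats = small_cohort_features
        y = feats["label"].to_numpy()
        kw = dict(feature_sets=("skin",), k=4,
                  model_configs={"dt": nj.ModelConfig("dt"), "rf": nj.ModelConfig("rf")})
        r1 = nj.run_experiment(feats, y, seed=13, **kw)
        r2 = nj.run_experiment(feats, y, seed=13, **kw)
        pd.testing.assert_frame_equal(r1.metrics, r2.metrics)

    def test_summary_mentions_every_model(self, small_results):
        text = small_results.summary()
        for name in ("mlp", "svm", "dt", "rf"):
            assert name in text

    def test_csv_report_layout(self, small_results, tmp_path):
        paths = small_results.to_csv(tmp_path)
        table = pd.read_csv(paths["metrics"])
        assert list(table.columns) == ["Features", "Classifier", "Accuracy",
                                       "Precision", "Recall", "F1", "AUC"]
        assert len(table) == 12
        assert paths["pairwise_tests"].exists()
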