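"""Logistic classification, metrics and repeated cross-validation."""

import numpy as np
import pytest

from eegresp import (ConfusionMatrix, DEFAULT_SUBSET_SIZES, combine_features,
                     confusion_metrics, cross_validate, fit_logistic, predict,
                     subset_sweep)
from eegresp.classify import LogisticModel, _fold_standardize
from eegresp.selection import auc_rank, prune_correlated, take_top

from conftest import gaussian_feature_matrix


class TestFit:
    def test_separable_data(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(-3, 0.3, 100), rng.normal(3, 0.3, 100)])
        y = np.array([-1] * 100 + [1] * 100)
        model = fit_logistic(x, y)
        assert model.beta[0] > 0
        _, pred = predict(model, x)
        assert np.mean(pred == (y == 1)) == 1.0

    def test_intercept_only_balanced(self):
        x = np.zeros((40, 2))
        y = np.array([1, -1] * 20)
        model = fit_logistic(x, y)
        proba, pred = predict(model, x)
        np.testing.assert_allclose(proba, 0.5, atol=1e-6)
        assert not pred.any()           # F(z) = 0.5 is not > 0.5

    def test_parameter_recovery(self):
        rng = np.random.default_rng(1)
        alpha, beta = 0.5, np.array([1.2, -0.8])
        x = rng.standard_normal((5000, 2))
        p = 1 / (1 + np.exp(-(alpha + x @ beta)))
        y = np.where(rng.random(5000) < p, 1, -1)
        model = fit_logistic(x, y)
        assert abs(model.alpha - alpha) / abs(alpha) < 0.1
        np.testing.assert_allclose(model.beta, beta, rtol=0.1)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_logistic(np.zeros((5, 1)), np.ones(5))


class TestPredict:
    def test_closed_forms(self):
        model = LogisticModel(alpha=0.0, beta=np.array([1.0]))
        proba, pred = predict(model, np.array([[0.0], [np.log(3)], [50.0]]))
        assert proba[0] == pytest.approx(0.5) and not pred[0]
        assert proba[1] == pytest.approx(0.75) and pred[1]
        assert proba[2] == pytest.approx(1.0, abs=1e-9) and pred[2]

    def test_dimension_mismatch(self):
        model = LogisticModel(alpha=0.0, beta=np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            predict(model, np.zeros((3, 3)))


class TestMetrics:
    @pytest.mark.parametrize("cm,expected", [
        (ConfusionMatrix(5, 0, 5, 0),
         dict(sensitivity=1, specificity=1, accuracy=1, f_measure=1)),
        (ConfusionMatrix(3, 2, 2, 1),
         dict(sensitivity=0.75, specificity=0.5, accuracy=0.625,
              f_measure=6 / 9)),
        (ConfusionMatrix(0, 0, 8, 2),
         dict(sensitivity=0.0, specificity=1.0, accuracy=0.8, f_measure=0.0)),
    ])
    def test_examples(self, cm, expected):
        got = confusion_metrics(cm)
        for k, v in expected.items():
            assert got[k] == pytest.approx(v)

    def test_empty_denominator_is_undefined(self):
        got = confusion_metrics(ConfusionMatrix(0, 0, 5, 0))
        assert np.isnan(got["sensitivity"])
        assert got["specificity"] == 1.0

    def test_matches_per_instance_recount(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            n = int(rng.integers(4, 50))
            truth = rng.random(n) < 0.5
            pred = rng.random(n) < 0.5
            cm = ConfusionMatrix(
                TP=int(np.sum(pred & truth)), FP=int(np.sum(pred & ~truth)),
                TN=int(np.sum(~pred & ~truth)), FN=int(np.sum(~pred & truth)))
            m = confusion_metrics(cm)
            assert cm.total == n
            assert m["accuracy"] == pytest.approx(np.mean(pred == truth))
            if truth.any():
                assert m["sensitivity"] == pytest.approx(
                    np.mean(pred[truth]))


class TestCrossValidate:
    def test_planted_signal_beats_null(self):
        rng = np.random.default_rng(3)
        fm = gaussian_feature_matrix(rng, shift=2.5, shifted_cols=(0, 1, 2))
        rep = cross_validate(fm, k_features=3, repeats=10, seed=4)
        null = cross_validate(fm, k_features=3, repeats=10, seed=4,
                              permute_labels=True)
        acc, null_acc = rep.summary()["accuracy"][0], null.summary()["accuracy"][0]
        assert acc > 0.85
        assert abs(null_acc - 0.5) < 0.15
        assert acc > null_acc + 0.2

    def test_confusion_counts_sum_to_n(self):
        rng = np.random.default_rng(5)
        fm = gaussian_feature_matrix(rng, shift=1.0, shifted_cols=(0,))
        rep = cross_validate(fm, k_features=2, repeats=3, seed=6)
        for cm in rep.confusions:
            assert cm.total == fm.n_instances

    def test_selection_uses_training_rows_only(self):
        """Recomputing the per-fold selection from the training rows alone
        reproduces the recorded indices, so the test fold cannot leak."""
        rng = np.random.default_rng(7)
        fm = gaussian_feature_matrix(rng, shift=1.5, shifted_cols=(4,))
        seed = 11
        rep = cross_validate(fm, k_features=3, repeats=2, seed=seed,
                             record_selection=True)
        # replicate the fold sequence with the same seed stream
        from sklearn.model_selection import StratifiedGroupKFold
        check_rng = np.random.default_rng(seed)
        y01 = (fm.labels("R") == 1).astype(int)
        groups = fm.instance_meta["subject_id"].to_numpy()
        for r in range(2):
            rs = int(check_rng.integers(0, 2 ** 31 - 1))
            splitter = StratifiedGroupKFold(n_splits=10, shuffle=True,
                                            random_state=rs)
            for (tr, _te), recorded in zip(splitter.split(fm.values, y01, groups),
                                           rep.selected_indices[r]):
                ztr, _, dead = _fold_standardize(fm.values[tr], fm.values[:1])
                ranked = auc_rank(ztr, np.where(y01[tr] == 1, 1, -1))
                ranked = prune_correlated(ranked, ztr, r_max=0.9, max_keep=3)
                np.testing.assert_array_equal(take_top(ranked, 3), recorded)

    def test_grouping_keeps_subject_conditions_together(self):
        rng = np.random.default_rng(8)
        fm = gaussian_feature_matrix(rng, shift=1.0, shifted_cols=(0,))
        from sklearn.model_selection import StratifiedGroupKFold
        y01 = (fm.labels("R") == 1).astype(int)
        groups = fm.instance_meta["subject_id"].to_numpy()
        splitter = StratifiedGroupKFold(n_splits=10, shuffle=True, random_state=0)
        for _tr, te in splitter.split(fm.values, y01, groups):
            te_subjects = set(groups[te])
            # both instances of each test subject are in the test fold
            assert np.sum(np.isin(groups, list(te_subjects))) == len(te)


class TestSubsetSweep:
    def test_default_size_list(self):
        assert len(DEFAULT_SUBSET_SIZES) == 12

    def test_one_report_per_size(self):
        rng = np.random.default_rng(9)
        fm = gaussian_feature_matrix(rng, shift=2.0, shifted_cols=(0,))
        out = subset_sweep(fm, sizes=(1, 3, 5), repeats=2, seed=10)
        assert sorted(out) == [1, 3, 5]
        assert out[1].summary()["accuracy"][0] > 0.6   # single planted feature

    def test_size_exceeding_features(self):
        rng = np.random.default_rng(10)
        fm = gaussian_feature_matrix(rng, n_features=4)
        with pytest.raises(ValueError):
            subset_sweep(fm, sizes=(50,))


class TestCombine:
    def test_three_methods_give_45_columns(self):
        rng = np.random.default_rng(11)
        mats = [gaussian_feature_matrix(rng, n_features=20) for _ in range(3)]
        for m in mats[1:]:
            m.instance_meta = mats[0].instance_meta.copy()
        combined = combine_features(mats, k_each=15)
        assert combined.n_features == 45
        assert combined.n_instances == mats[0].n_instances

    def test_single_method_identity(self):
        rng = np.random.default_rng(12)
        fm = gaussian_feature_matrix(rng, n_features=10)
        out = combine_features([fm], k_each=10)
        np.testing.assert_array_equal(out.values, fm.values)

    def test_instance_mismatch(self):
        rng = np.random.default_rng(13)
        a = gaussian_feature_matrix(rng, n_subjects=10)
        b = gaussian_feature_matrix(rng, n_subjects=12)
        with pytest.raises(ValueError):
            combine_features([a, b])

    def test_duplicated_method_flagged_by_prune(self):
        rng = np.random.default_rng(14)
        fm = gaussian_feature_matrix(rng, n_features=5)
        dup = combine_features([fm, fm], k_each=5)
        y = dup.labels("R")
        ranked = prune_correlated(auc_rank(dup.values, y), dup.values, r_max=0.9)
        assert len(ranked.retained) == 5     # each duplicate pair collapses
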