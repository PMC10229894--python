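"""Feature selection and SVM classification: the t-test filter, the
contribution-guided RFE, LOOCV machinery, metrics, and leakage checks."""

import numpy as np
import pytest
from scipy.stats import binom
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from dcx.classify import (
    ContributionRFE,
    StandardizedLinearSVM,
    TTestFilter,
    _fit_linear_svm_fast,
    compute_metrics,
    inner_loocv_accuracy,
    nested_evaluate,
    pair_count_auc,
    rfe_svm,
    ttest_filter,
)


def _two_group(rng, n_per_group, n_features, shift=None):
    X = rng.standard_normal((2 * n_per_group, n_features))
    y = np.array([1] * n_per_group + [0] * n_per_group)
    if shift is not None:
        X[y == 1] += shift
    return X, y


class TestFastSvmPath:
    def test_matches_public_svc_exactly(self, rng):
        """The low-level solver used in the LOOCV loop reproduces
        SVC(kernel='linear') weights and bias to machine precision."""
        for _ in range(30):
            n1, n0 = rng.integers(3, 20, size=2)
            p = rng.integers(1, 8)
            X = rng.standard_normal((n1 + n0, p))
            y = np.array([1] * n1 + [0] * n0)
            perm = rng.permutation(n1 + n0)
            X, y = X[perm], y[perm]
            w, b = _fit_linear_svm_fast(X, y, 1.0)
            ref = SVC(kernel="linear", C=1.0).fit(X, y)
            np.testing.assert_allclose(w, ref.coef_.ravel(), atol=1e-8)
            assert b == pytest.approx(ref.intercept_[0], abs=1e-8)


class TestTTestFilter:
    def test_identical_groups_nothing_retained(self):
        X = np.tile(np.arange(6.0)[:, None], (1, 4))
        y = np.array([1, 1, 1, 0, 0, 0])
        X[y == 0] = X[y == 1]
        assert len(ttest_filter(X, y)) == 0

    def test_extreme_separation_retained(self, rng):
        X, y = _two_group(rng, 5, 3)
        X = 0.1 * X
        X[y == 1, 0] += 10.0
        assert 0 in ttest_filter(X, y)

    def test_null_retention_fraction_near_alpha(self):
        rng = np.random.default_rng(99)
        X, y = _two_group(rng, 22, 1000)
        frac = len(ttest_filter(X, y)) / 1000
        assert 0.03 < frac < 0.07

    def test_fallback_keeps_best_feature(self, rng):
        X, y = _two_group(rng, 3, 2)
        X[:] = 0.001 * rng.standard_normal(X.shape)
        filt = TTestFilter(alpha=1e-12).fit(X, y)
        assert filt.support_.sum() == 1

    def test_degenerate_features(self):
        y = np.array([1, 1, 0, 0])
        X = np.column_stack([np.ones(4), [2.0, 2.0, 3.0, 3.0]])
        filt = TTestFilter().fit(X, y)
        assert filt.pvalues_[0] == 1.0  # constant, equal means
        assert filt.pvalues_[1] == 0.0  # constant within group, unequal means
        assert filt.support_.tolist() == [False, True]


class TestInnerLoocv:
    def test_perfect_separation(self, rng):
        n = 10
        X = np.concatenate([1 + 0.01 * rng.standard_normal(n), -1 + 0.01 * rng.standard_normal(n)])[:, None]
        y = np.array([1] * n + [0] * n)
        assert inner_loocv_accuracy(X, y) == 1.0

    def test_pure_noise_never_above_chance_over_seeds(self):
        """LOOCV on a single noise feature shows no optimistic bias; its
        mean accuracy sits at or below chance (leave-one-out training
        folds are slightly tilted against the held-out subject's class,
        the well-known pessimistic LOOCV bias)."""
        _, hi = binom.interval(0.95, 44, 0.5)
        accs = []
        for seed in range(20):
            rng = np.random.default_rng(400 + seed)
            X, y = _two_group(rng, 22, 1)
            accs.append(inner_loocv_accuracy(X, y))
        assert np.mean(accs) <= hi / 44

    def test_feature_order_invariance(self, rng):
        X, y = _two_group(rng, 8, 5, shift=0.8)
        perm = rng.permutation(5)
        assert inner_loocv_accuracy(X, y) == inner_loocv_accuracy(X[:, perm], y)

    def test_single_class_fold_errors(self):
        X = np.arange(6.0)[:, None]
        y = np.array([1, 0, 0, 0, 0, 0])
        with pytest.raises(ValueError, match="single class"):
            inner_loocv_accuracy(X, y)


class TestRfeSvm:
    def test_separator_plus_noise_chooses_separator(self, rng):
        n = 8
        sep = np.concatenate([1 + 0.01 * rng.standard_normal(n), -1 + 0.01 * rng.standard_normal(n)])
        noise = rng.standard_normal(2 * n)
        X = np.column_stack([sep, noise])
        y = np.array([1] * n + [0] * n)
        trace = rfe_svm(X, y)
        assert trace.chosen == (0,)
        assert trace.chosen_accuracy == 1.0

    def test_identical_copies_of_separator(self, rng):
        n = 8
        sep = np.concatenate([1 + 0.01 * rng.standard_normal(n), -1 + 0.01 * rng.standard_normal(n)])
        X = np.tile(sep[:, None], (1, 4))
        y = np.array([1] * n + [0] * n)
        trace = rfe_svm(X, y)
        assert len(trace.chosen) >= 1
        assert trace.chosen_accuracy == inner_loocv_accuracy(sep[:, None], y)

    def test_sizes_strictly_decrease_to_one(self, rng):
        X, y = _two_group(rng, 6, 6, shift=0.5)
        trace = rfe_svm(X, y)
        sizes = [len(it.active) for it in trace.iterations]
        assert all(a > b for a, b in zip(sizes, sizes[1:]))
        assert sizes[-1] == 1
        assert trace.chosen_accuracy == max(it.accuracy for it in trace.iterations)

    def test_selector_estimator_interface(self, rng):
        X, y = _two_group(rng, 6, 5, shift=1.0)
        sel = ContributionRFE().fit(X, y)
        reduced = sel.transform(X)
        assert reduced.shape[1] == sel.support_.sum() == len(sel.trace_.chosen)


class TestStandardizedLinearSVM:
    def test_weight_sign_convention(self, rng):
        """Positive weight = higher feature values in the expertise (+1) group."""
        X, y = _two_group(rng, 10, 2)
        X[y == 1, 0] += 3.0  # feature 0 higher in expertise
        model = StandardizedLinearSVM().fit(X, y)
        assert model.weights_[0] > 0
        assert (model.predict(X) == y).mean() > 0.9

    def test_label_swap_negates_weights_and_swaps_rates(self, rng):
        # symmetry holds to the solver's convergence tolerance
        X, y = _two_group(rng, 10, 3, shift=1.0)
        m1 = StandardizedLinearSVM().fit(X, y)
        m2 = StandardizedLinearSVM().fit(X, 1 - y)
        np.testing.assert_allclose(m1.weights_, -m2.weights_, atol=1e-2)
        np.testing.assert_array_equal(m1.predict(X), 1 - m2.predict(X))


class TestMetrics:
    def test_worked_confusion_example(self):
        rep = compute_metrics(tp=18, fn=4, tn=21, fp=1)
        assert rep.accuracy_pct == 88.64
        assert rep.sensitivity_pct == 81.82
        assert rep.specificity_pct == 95.45

    def test_all_correct(self):
        d = np.array([1.0, 2.0, -1.0, -2.0])
        y = np.array([1, 1, 0, 0])
        rep = compute_metrics(2, 0, 2, 0, decision_values=d, labels=y)
        assert rep.accuracy_pct == 100.0 and rep.auc == 1.0

    def test_auc_pair_count_identity(self):
        """436 of 484 correctly ordered pairs, no ties -> AUC 0.9008."""
        neg = np.arange(22, dtype=float)
        beats = [22] * 19 + [18, 0, 0]
        assert sum(beats) == 436
        # positive i placed strictly between negative ranks m_i-1 and m_i
        pos = np.array([m - 0.1 - 0.01 * i for i, m in enumerate(beats)])
        d = np.concatenate([pos, neg])
        assert len(np.unique(d)) == 44  # all values distinct
        y = np.array([1] * 22 + [0] * 22)
        assert pair_count_auc(d, y) == pytest.approx(436 / 484)
        rep = compute_metrics(22, 0, 0, 22, decision_values=d, labels=y)
        assert rep.auc == 0.9008

    def test_auc_equals_trapezoid_and_sklearn(self, rng):
        d = rng.standard_normal(30)
        y = rng.integers(0, 2, 30)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        assert pair_count_auc(d, y) == pytest.approx(roc_auc_score(y, d), abs=1e-12)

    def test_roc_is_monotone_staircase(self, rng):
        d = rng.standard_normal(40)
        y = np.array([1] * 20 + [0] * 20)
        pred_pos = (d > 0)
        tp = int((pred_pos & (y == 1)).sum()); fn = 20 - tp
        tn = int((~pred_pos & (y == 0)).sum()); fp = 20 - tn
        rep = compute_metrics(tp, fn, tn, fp, decision_values=d, labels=y)
        pts = np.array(rep.roc_points)
        assert np.all(np.diff(pts[:, 0]) >= 0) and np.all(np.diff(pts[:, 1]) >= 0)
        assert pts[-1].tolist() == [1.0, 1.0]

    def test_mismatched_totals_error(self):
        with pytest.raises(ValueError, match="totals"):
            compute_metrics(3, 0, 1, 0, decision_values=np.zeros(4), labels=np.array([1, 1, 0, 0]))


class TestNestedEvaluate:
    def test_no_leakage_of_held_out_subject(self, rng):
        """Corrupting the held-out subject's features never changes that
        fold's selection (the held-out row enters nothing but scoring)."""
        X, y = _two_group(rng, 5, 6, shift=1.2)
        sel_a, sel_b = {}, {}
        nested_evaluate(X, y, fold_hook=lambda i, tr, te, s: sel_a.__setitem__(i, s))
        for i in (0, 7):
            Xc = X.copy()
            Xc[i] = 1e3 * rng.standard_normal(6)
            nested_evaluate(Xc, y, fold_hook=lambda j, tr, te, s: sel_b.__setitem__(j, s))
            assert sel_b[i] == sel_a[i]

    def test_hook_sees_disjoint_train_test(self, rng):
        X, y = _two_group(rng, 4, 3, shift=1.0)
        def hook(i, tr, te, sel):
            assert te[0] == i and i not in tr and len(tr) == len(y) - 1
        nested_evaluate(X, y, fold_hook=hook)

    def test_deterministic_report(self, rng):
        X, y = _two_group(rng, 5, 8, shift=0.6)
        r1 = nested_evaluate(X, y)
        r2 = nested_evaluate(X, y)
        assert r1.to_dict() == r2.to_dict()

    def test_subject_order_invariance(self, rng):
        X, y = _two_group(rng, 6, 4, shift=1.5)
        perm = rng.permutation(len(y))
        r1 = nested_evaluate(X, y)
        r2 = nested_evaluate(X[perm], y[perm])
        assert (r1.tp, r1.fn, r1.tn, r1.fp) == (r2.tp, r2.fn, r2.tn, r2.fp)

    def test_permuted_labels_near_chance(self):
        accs = []
        for seed in range(10):
            rng = np.random.default_rng(500 + seed)
            X, y = _two_group(rng, 11, 10, shift=1.0)
            y_perm = rng.permutation(y)
            try:
                rep = nested_evaluate(X, y_perm)
                accs.append(rep.accuracy_pct / 100)
            except ValueError:
                pass
        assert 0.25 <= np.mean(accs) <= 0.75

    def test_pooled_biased_above_nested_on_null(self):
        diffs = []
        for seed in range(20):
            rng = np.random.default_rng(600 + seed)
            X, y = _two_group(rng, 8, 12)
            nested = nested_evaluate(X, y, mode="nested").accuracy_pct
            pooled = nested_evaluate(X, y, mode="pooled").accuracy_pct
            diffs.append(pooled - nested)
        assert np.mean(diffs) > 0
        rep = nested_evaluate(X, y, mode="pooled")
        assert "biased" in rep.note

    def test_consensus_weights_use_feature_names(self, rng):
        X, y = _two_group(rng, 5, 4, shift=1.0)
        rep = nested_evaluate(X, y, feature_names=["a", "b", "c", "d"])
        assert set(rep.consensus_weights) <= {"a", "b", "c", "d"}
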