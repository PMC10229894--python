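"""Two-stage feature selection and linear-SVM classification with LOOCV.

The classification substrate is the subjects-by-ROIs degree-centrality
matrix. Selection is two-stage, run strictly inside each training fold:

1. a pooled-variance two-sample t-test per ROI keeps features with
   uncorrected two-sided p below ``alpha`` (default 0.05);
2. contribution-guided recursive feature elimination (RFE-SVM): for the
   active set S, each feature's contribution is the drop in leave-one-out
   SVM accuracy caused by removing it; features contributing nothing
   (contribution <= 0) are eliminated together, and the recorded subset
   with the highest LOO accuracy is kept.

The classifier is a soft-margin linear SVM (hinge loss) on per-training-
fold standardized features, with the expertise group coded +1 so that a
positive weight means higher degree centrality in the expertise group.
Model evaluation is leave-one-out cross-validation; the default
``nested`` mode repeats both selection stages inside every outer fold
(no leakage), while ``pooled`` mode selects once on all subjects and is
reported as optimistically biased.

Metrics follow the usual confusion-matrix definitions (sensitivity =
true-positive rate on the expertise group, specificity = true-negative
rate on controls), with AUC computed by the Mann-Whitney pair-counting
identity (ties scored 0.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.feature_selection import SelectorMixin
from sklearn.metrics import roc_curve
from sklearn.svm import SVC
from sklearn.svm import _libsvm as _libsvm  # low-level path for the LOOCV hot loop

__all__ = [
    "TTestFilter",
    "ContributionRFE",
    "StandardizedLinearSVM",
    "SelectionTrace",
    "ClassificationReport",
    "ttest_filter",
    "inner_loocv_accuracy",
    "rfe_svm",
    "nested_evaluate",
    "compute_metrics",
    "pair_count_auc",
]

_libsvm.set_verbosity_wrap(0)


# ---------------------------------------------------------------------------
# fast internal linear-SVM primitives

def _fit_linear_svm_fast(X: np.ndarray, y01: np.ndarray, C: float) -> tuple[np.ndarray, float]:
    """Weights and bias of ``SVC(kernel="linear", C=C)`` via the low-level
    libsvm binding (identical solver, far lower per-call overhead)."""
    out = _libsvm.fit(
        np.ascontiguousarray(X, dtype=np.float64),
        y01.astype(np.float64),
        svm_type=0,
        kernel="linear",
        C=C,
    )
    sv, dual_coef, rho = out[1], out[3], out[4]
    w = -(dual_coef @ sv).ravel()
    return w, -float(rho[0])


def _standardize_train(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    return (X - mean) / sd, mean, sd


def _loocv_decisions(X: np.ndarray, y01: np.ndarray, C: float) -> np.ndarray:
    """Leave-one-out decision value for every subject.

    Each fold standardizes on the remaining subjects, fits the linear SVM
    on them, and scores the held-out subject. Errors if a training fold
    loses an entire class.
    """
    n = X.shape[0]
    dec = np.empty(n)
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        ytr = y01[tr]
        if ytr.min() == ytr.max():
            raise ValueError("a LOOCV training fold contains a single class")
        Xtr, mean, sd = _standardize_train(X[tr])
        w, b = _fit_linear_svm_fast(Xtr, ytr, C)
        dec[i] = ((X[i] - mean) / sd) @ w + b
    return dec


def inner_loocv_accuracy(X, y, C: float = 1.0) -> float:
    """Leave-one-out accuracy of the standardized linear SVM.

    Deterministic: per fold, features are standardized on the training
    subjects only, the SVM is fit on them, and the held-out subject is
    predicted (decision value > 0 -> expertise).
    """
    X = np.asarray(X, dtype=float)
    y01 = np.asarray(y).astype(int)
    dec = _loocv_decisions(X, y01, C)
    pred = (dec > 0).astype(int)
    return float(np.mean(pred == y01))


# ---------------------------------------------------------------------------
# stage 1: fold-wise t-test filter

def _ttest_pvalues(X: np.ndarray, y01: np.ndarray) -> np.ndarray:
    """Per-feature pooled-variance two-sample t-test p-values.

    Degenerate features (zero pooled variance) get p = 1 when the group
    means are equal and p = 0 when they differ.
    """
    a = X[y01 == 1]
    b = X[y01 == 0]
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = sps.ttest_ind(a, b, axis=0, equal_var=True)
    var_a = a.var(axis=0, ddof=1)
    var_b = b.var(axis=0, ddof=1)
    degenerate = (var_a == 0) & (var_b == 0)
    equal_means = a.mean(axis=0) == b.mean(axis=0)
    p = np.asarray(p, dtype=float)
    p[degenerate & equal_means] = 1.0
    p[degenerate & ~equal_means] = 0.0
    return p


def ttest_filter(X, y, alpha: float = 0.05) -> np.ndarray:
    """Indices of features whose two-sample t-test p-value is below `alpha`."""
    X = np.asarray(X, dtype=float)
    y01 = np.asarray(y).astype(int)
    p = _ttest_pvalues(X, y01)
    return np.nonzero(p < alpha)[0]


class TTestFilter(SelectorMixin, BaseEstimator):
    """Univariate filter retaining features with two-sample t-test p < alpha.

    Pooled-variance Student's t per feature, two-sided, uncorrected. When
    nothing passes and ``fallback_best=True`` (default) the single
    smallest-p feature is kept so downstream estimators always see at
    least one column.

    Attributes
    ----------
    pvalues_ : ndarray
        Per-feature p-values.
    support_ : boolean ndarray
        Retained-feature mask.
    """

    def __init__(self, alpha: float = 0.05, fallback_best: bool = True):
        self.alpha = alpha
        self.fallback_best = fallback_best

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y01 = np.asarray(y).astype(int)
        self.n_features_in_ = X.shape[1]
        self.pvalues_ = _ttest_pvalues(X, y01)
        support = self.pvalues_ < self.alpha
        if not support.any() and self.fallback_best:
            support = np.zeros_like(support)
            support[int(np.argmin(self.pvalues_))] = True
        self.support_ = support
        return self

    def _get_support_mask(self):
        return self.support_


# ---------------------------------------------------------------------------
# stage 2: contribution-guided RFE

@dataclass
class RFEIteration:
    active: tuple[int, ...]  # original column indices
    accuracy: float  # inner-LOOCV accuracy of the active set
    contributions: dict[int, float]
    removed: tuple[int, ...]


@dataclass
class SelectionTrace:
    """Record of the elimination loop: one entry per iteration, plus the
    chosen subset (highest recorded accuracy; ties -> smaller set, then
    earlier iteration)."""

    iterations: list[RFEIteration] = field(default_factory=list)
    chosen: tuple[int, ...] = ()
    chosen_accuracy: float = 0.0


def rfe_svm(X, y, C: float = 1.0, feature_indices=None) -> SelectionTrace:
    """Contribution-based recursive feature elimination with SVM-LOOCV.

    At each iteration, the contribution of feature ``f`` to the active set
    ``S`` is ``acc(S) - acc(S \\ {f})`` where ``acc`` is leave-one-out SVM
    accuracy. All features with contribution <= 0 are removed together;
    when every feature contributes positively, the single feature with the
    smallest contribution is removed (ties broken by removing the larger
    original column index). The loop stops at one feature, and the chosen
    subset is the recorded active set with the highest accuracy.
    """
    X = np.asarray(X, dtype=float)
    y01 = np.asarray(y).astype(int)
    cols = list(range(X.shape[1])) if feature_indices is None else list(feature_indices)
    trace = SelectionTrace()

    active = list(cols)
    acc_active = inner_loocv_accuracy(X[:, active], y01, C)
    while True:
        if len(active) == 1:
            trace.iterations.append(
                RFEIteration(tuple(active), acc_active, {}, ())
            )
            break
        contributions: dict[int, float] = {}
        acc_without: dict[int, float] = {}
        for f in active:
            rest = [g for g in active if g != f]
            acc_without[f] = inner_loocv_accuracy(X[:, rest], y01, C)
            contributions[f] = acc_active - acc_without[f]
        drop = [f for f in active if contributions[f] <= 0]
        if not drop:
            # smallest contribution; ties -> larger original index first
            drop = [min(active, key=lambda f: (contributions[f], -f))]
        if len(drop) == len(active):
            # never empty the set: keep the feature whose removal hurts most
            keep = min(active, key=lambda f: (acc_without[f], f))
            drop = [f for f in active if f != keep]
        trace.iterations.append(
            RFEIteration(tuple(active), acc_active, dict(contributions), tuple(drop))
        )
        new_active = [f for f in active if f not in drop]
        if len(drop) == 1:
            acc_new = acc_without[drop[0]]
        else:
            acc_new = inner_loocv_accuracy(X[:, new_active], y01, C)
        active, acc_active = new_active, acc_new

    best = max(
        enumerate(trace.iterations),
        key=lambda kv: (kv[1].accuracy, -len(kv[1].active), -kv[0]),
    )[1]
    trace.chosen = best.active
    trace.chosen_accuracy = best.accuracy
    return trace


def _weight_ranked_rfe(X, y, C: float, feature_indices=None) -> SelectionTrace:
    """Classic RFE: drop the smallest-|weight| feature each round."""
    X = np.asarray(X, dtype=float)
    y01 = np.asarray(y).astype(int)
    active = list(range(X.shape[1])) if feature_indices is None else list(feature_indices)
    trace = SelectionTrace()
    while True:
        acc = inner_loocv_accuracy(X[:, active], y01, C)
        if len(active) == 1:
            trace.iterations.append(RFEIteration(tuple(active), acc, {}, ()))
            break
        Xs, _, _ = _standardize_train(X[:, active])
        w, _ = _fit_linear_svm_fast(Xs, y01, C)
        scores = dict(zip(active, np.abs(w)))
        f = min(active, key=lambda g: (scores[g], -g))
        trace.iterations.append(RFEIteration(tuple(active), acc, scores, (f,)))
        active = [g for g in active if g != f]
    best = max(
        enumerate(trace.iterations),
        key=lambda kv: (kv[1].accuracy, -len(kv[1].active), -kv[0]),
    )[1]
    trace.chosen = best.active
    trace.chosen_accuracy = best.accuracy
    return trace


class ContributionRFE(SelectorMixin, BaseEstimator):
    """Recursive feature elimination guided by LOOCV-accuracy contributions.

    sklearn-compatible selector wrapping :func:`rfe_svm`. With
    ``strategy="weight"`` a classic smallest-|weight| elimination is used
    instead.

    Attributes
    ----------
    trace_ : SelectionTrace
    support_ : boolean mask of the chosen subset
    """

    def __init__(self, C: float = 1.0, strategy: str = "contribution"):
        self.C = C
        self.strategy = strategy

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        if self.strategy == "contribution":
            self.trace_ = rfe_svm(X, y, C=self.C)
        elif self.strategy == "weight":
            self.trace_ = _weight_ranked_rfe(X, y, C=self.C)
        else:
            raise ValueError("strategy must be 'contribution' or 'weight'")
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[list(self.trace_.chosen)] = True
        return self

    def _get_support_mask(self):
        return self.support_


# ---------------------------------------------------------------------------
# the classifier

class StandardizedLinearSVM(ClassifierMixin, BaseEstimator):
    """Soft-margin linear SVM on per-fit standardized features.

    Labels are 0 (control) / 1 (expertise); the decision value is
    ``w . standardized(x) + b`` with positive meaning expertise, so a
    positive weight corresponds to higher feature values (degree
    centrality) in the expertise group.

    Attributes
    ----------
    weights_ : ndarray, shape (n_features,)
    bias_ : float
    mean_, scale_ : training-fold standardization parameters
    """

    def __init__(self, C: float = 1.0):
        self.C = C

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y01 = np.asarray(y).astype(int)
        if set(np.unique(y01)) - {0, 1}:
            raise ValueError("labels must be coded 0 (control) / 1 (expertise)")
        if y01.min() == y01.max():
            raise ValueError("training data contains a single class")
        Xs, self.mean_, self.scale_ = _standardize_train(X)
        svc = SVC(kernel="linear", C=self.C).fit(Xs, y01)
        self.weights_ = svc.coef_.ravel().copy()
        self.bias_ = float(svc.intercept_[0])
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=float)
        return ((X - self.mean_) / self.scale_) @ self.weights_ + self.bias_

    def predict(self, X):
        return (self.decision_function(X) > 0).astype(int)


# ---------------------------------------------------------------------------
# metrics and the nested evaluation

def _round_half_up(x: float, digits: int) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("1." + "0" * digits), rounding=ROUND_HALF_UP))


def pair_count_auc(decision_values, y) -> float:
    """AUC by the Mann-Whitney pair-counting identity.

    The fraction of (positive, negative) pairs where the positive's
    decision value exceeds the negative's, ties counted 0.5.
    """
    d = np.asarray(decision_values, dtype=float)
    y01 = np.asarray(y).astype(int)
    pos = d[y01 == 1]
    neg = d[y01 == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("AUC undefined with an empty class")
    diff = pos[:, None] - neg[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / (pos.size * neg.size))


@dataclass
class ClassificationReport:
    """LOOCV classification outcome: confusion counts, rates, ROC and AUC."""

    tp: int
    fn: int
    tn: int
    fp: int
    accuracy_pct: float
    sensitivity_pct: float
    specificity_pct: float
    auc: float
    roc_points: list[tuple[float, float]]
    decision_values: np.ndarray = None
    predictions: np.ndarray = None
    labels: np.ndarray = None
    fold_selections: list[tuple[int, ...]] = None
    consensus_weights: dict[str, float] = None
    mode: str = "nested"
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "note": self.note,
            "confusion": {"tp": self.tp, "fn": self.fn, "tn": self.tn, "fp": self.fp},
            "accuracy_pct": self.accuracy_pct,
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
            "auc": self.auc,
            "roc_points": [list(p) for p in self.roc_points],
            "decision_values": None if self.decision_values is None else list(map(float, self.decision_values)),
            "predictions": None if self.predictions is None else list(map(int, self.predictions)),
            "labels": None if self.labels is None else list(map(int, self.labels)),
            "fold_selections": None
            if self.fold_selections is None
            else [list(map(int, s)) for s in self.fold_selections],
            "consensus_weights": self.consensus_weights,
        }


def compute_metrics(tp: int, fn: int, tn: int, fp: int, decision_values=None, labels=None) -> ClassificationReport:
    """Confusion-count metrics, plus ROC/AUC when decision values are given.

    Accuracy/sensitivity/specificity are percentages rounded half-up to
    two decimals; AUC (pair counting, ties 0.5) is rounded to four.
    """
    for v in (tp, fn, tn, fp):
        if v < 0:
            raise ValueError("confusion counts must be non-negative")
    n_pos, n_neg = tp + fn, tn + fp
    if n_pos == 0 or n_neg == 0:
        raise ValueError("metrics undefined with an empty class")
    acc = _round_half_up(100.0 * (tp + tn) / (n_pos + n_neg), 2)
    sens = _round_half_up(100.0 * tp / n_pos, 2)
    spec = _round_half_up(100.0 * tn / n_neg, 2)
    auc = float("nan")
    roc_pts: list[tuple[float, float]] = []
    if decision_values is not None:
        if labels is None:
            raise ValueError("labels required alongside decision values")
        labels = np.asarray(labels).astype(int)
        if tp + fn != int((labels == 1).sum()) or tn + fp != int((labels == 0).sum()):
            raise ValueError("confusion totals do not match label counts")
        auc = _round_half_up(pair_count_auc(decision_values, labels), 4)
        fpr, tpr, _ = roc_curve(labels, decision_values)
        roc_pts = list(zip(fpr.tolist(), tpr.tolist()))
    return ClassificationReport(
        tp=tp, fn=fn, tn=tn, fp=fp,
        accuracy_pct=acc, sensitivity_pct=sens, specificity_pct=spec,
        auc=auc, roc_points=roc_pts,
        decision_values=None if decision_values is None else np.asarray(decision_values, dtype=float),
        labels=None if labels is None else labels,
    )


def _select_features(X, y01, alpha, C, strategy) -> tuple[int, ...]:
    """Run both selection stages on (X, y01) and return chosen column indices."""
    filt = TTestFilter(alpha=alpha).fit(X, y01)
    kept = np.nonzero(filt.support_)[0]
    if kept.size == 1:
        return tuple(int(k) for k in kept)
    if strategy == "contribution":
        trace = rfe_svm(X, y01, C=C, feature_indices=kept.tolist())
    else:
        trace = _weight_ranked_rfe(X, y01, C=C, feature_indices=kept.tolist())
    return tuple(int(f) for f in trace.chosen)


def nested_evaluate(
    X,
    y,
    alpha: float = 0.05,
    C: float = 1.0,
    mode: str = "nested",
    strategy: str = "contribution",
    feature_names=None,
    fold_hook=None,
) -> ClassificationReport:
    """Outer-LOOCV evaluation of the full selection + SVM pipeline.

    In ``nested`` mode (the scientific default) the t-test filter and the
    RFE-SVM selection are re-run on the training subjects of every outer
    fold, so the held-out subject never influences its own selection or
    standardization. ``pooled`` mode selects once on all subjects before
    the LOOCV and its report is annotated as optimistically biased.

    Parameters
    ----------
    X : (n_subjects, n_features) array
    y : 0/1 labels (1 = expertise)
    alpha, C : selection threshold and SVM regularization
    mode : {"nested", "pooled"}
    strategy : {"contribution", "weight"}
        RFE elimination rule.
    feature_names : sequence of str, optional
        Used for the consensus-weight table.
    fold_hook : callable, optional
        ``fold_hook(fold, train_idx, test_idx, selected)`` called per outer
        fold; intended for leakage instrumentation in tests.

    Returns
    -------
    ClassificationReport
        Confusion counts, percent metrics, ROC points, pair-counting AUC,
        per-fold selections, and a descriptive consensus-weight table from
        a pooled-selection model refit on all subjects.
    """
    X = np.asarray(X, dtype=float)
    y01 = np.asarray(y).astype(int)
    n = X.shape[0]
    if min((y01 == 1).sum(), (y01 == 0).sum()) < 3:
        raise ValueError("need at least 3 subjects per group")
    if mode not in ("nested", "pooled"):
        raise ValueError("mode must be 'nested' or 'pooled'")

    pooled_selected = _select_features(X, y01, alpha, C, strategy) if mode == "pooled" else None

    preds = np.empty(n, dtype=int)
    decs = np.empty(n)
    selections: list[tuple[int, ...]] = []
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        if mode == "nested":
            selected = _select_features(X[tr], y01[tr], alpha, C, strategy)
        else:
            selected = pooled_selected
        sel = list(selected)
        Xtr, mean, sd = _standardize_train(X[np.nonzero(tr)[0]][:, sel])
        w, b = _fit_linear_svm_fast(Xtr, y01[tr], C)
        decs[i] = ((X[i, sel] - mean) / sd) @ w + b
        preds[i] = int(decs[i] > 0)
        selections.append(selected)
        if fold_hook is not None:
            fold_hook(i, np.nonzero(tr)[0], np.array([i]), selected)

    tp = int(((preds == 1) & (y01 == 1)).sum())
    fn = int(((preds == 0) & (y01 == 1)).sum())
    tn = int(((preds == 0) & (y01 == 0)).sum())
    fp = int(((preds == 1) & (y01 == 0)).sum())
    report = compute_metrics(tp, fn, tn, fp, decision_values=decs, labels=y01)
    report.predictions = preds
    report.fold_selections = selections
    report.mode = mode
    if mode == "pooled":
        report.note = "pooled selection before LOOCV: optimistically biased"

    # descriptive consensus model: pooled selection + fit on all subjects
    consensus = pooled_selected if pooled_selected is not None else _select_features(X, y01, alpha, C, strategy)
    model = StandardizedLinearSVM(C=C).fit(X[:, list(consensus)], y01)
    names = (
        [str(feature_names[f]) for f in consensus]
        if feature_names is not None
        else [f"f{f}" for f in consensus]
    )
    report.consensus_weights = dict(zip(names, map(float, model.weights_)))
    return report
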