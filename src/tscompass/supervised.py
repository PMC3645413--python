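"""Statistically controlled selection of operations for labelled and
continuous-target tasks.

A single operation is scored for classification by the repeated,
stratified 10-fold cross-validated misclassification rate of an
optimal-threshold (stump) classifier on its outputs, and for regression by
the absolute Pearson correlation of its outputs with the known target.
Multi-feature classifiers are built by greedy forward selection with a
Fisher linear discriminant on the selected subset.  Significance is
assessed against a pooled permutation null with Benjamini-Hochberg FDR
control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import pearsonr, spearmanr
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

from .matrix import DataMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "OpScore",
    "FeatureSetClassifier",
    "ThresholdClassifier",
    "ForwardLDAClassifier",
    "threshold_classifier_cv",
    "rank_operations_classification",
    "rank_operations_regression",
    "forward_select",
    "permutation_fdr",
]


@dataclass(frozen=True)
class OpScore:
    """Score record for one operation: mean CV misclassification rate
    (classification) or |Pearson r| (regression), with permutation p and
    BH-adjusted q when computed."""

    op_id: str
    score: float
    score_sd: float = 0.0
    kind: str = "misclassification"
    p_value: float | None = None
    q_value: float | None = None
    extra: dict = field(default_factory=dict)


@dataclass
class FeatureSetClassifier:
    """Result of greedy forward selection: the ordered selected operations,
    the joint CV error path, each feature's individual error, and the
    final discriminant coefficients."""

    op_ids: list
    cv_error: float
    cv_error_sd: float
    fold_errors: list
    step_errors: list
    individual_errors: dict
    coefficients: list
    intercept: float

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "op_ids": self.op_ids,
                "cv_error": self.cv_error,
                "cv_error_sd": self.cv_error_sd,
                "step_errors": self.step_errors,
                "individual_errors": self.individual_errors,
                "fold_errors": self.fold_errors,
                "coefficients": self.coefficients,
                "intercept": self.intercept,
            },
            indent=1,
            sort_keys=True,
        )


# -- the linear (threshold) classifier ---------------------------------


def _stump_fit(v: np.ndarray, y: np.ndarray):
    """Best threshold/direction by training accuracy.

    Candidate thresholds are midpoints between consecutive distinct sorted
    values plus one candidate below and above the range.  Accuracy ties are
    broken toward the largest margin (widest gap), then the smallest
    threshold.  Returns (threshold, direction) where direction +1 predicts
    class 1 for v > threshold.
    """
    order = np.argsort(v, kind="stable")
    vs, ys = v[order], y[order]
    n = v.size
    ones_left = np.concatenate([[0], np.cumsum(ys)])  # of first i points
    total_ones = ones_left[-1]
    # split after i sorted points: direction +1 predicts 0 for the first i
    cuts = np.concatenate([[True], vs[1:] > vs[:-1], [True]])
    idx = np.nonzero(cuts)[0]
    err_plus = ones_left[idx] + (n - idx) - (total_ones - ones_left[idx])
    err_minus = n - err_plus
    gaps = np.zeros(n + 1)
    gaps[1:n] = vs[1:] - vs[:-1]
    thr = np.empty(n + 1)
    thr[1:n] = 0.5 * (vs[1:] + vs[:-1])
    thr[0] = vs[0] - 1.0
    thr[n] = vs[-1] + 1.0

    def best(err):
        e = err.min()
        tied = idx[err == e]
        g = gaps[tied]
        tied = tied[g == g.max()]
        i = tied[np.argmin(thr[tied])]
        return e, thr[i]

    ep, tp = best(err_plus)
    em, tm = best(err_minus)
    if ep < em or (ep == em and tp <= tm):
        return tp, +1
    return tm, -1


class ThresholdClassifier(ClassifierMixin, BaseEstimator):
    """Optimal-threshold linear classifier on a single feature.

    fit accepts X of shape (n,) or (n, 1).  Fitted attributes:
    ``threshold_``, ``direction_`` (+1 predicts ``classes_[1]`` above the
    threshold), ``classes_``.
    """

    def fit(self, X, y):
        v = np.asarray(X, dtype=float).reshape(len(y), -1)
        if v.shape[1] != 1:
            raise ValueError("ThresholdClassifier is a single-feature model")
        v = v[:, 0]
        self.classes_, yi = np.unique(np.asarray(y), return_inverse=True)
        if self.classes_.size != 2:
            raise ValueError("need exactly two classes")
        self.threshold_, self.direction_ = _stump_fit(v, yi)
        return self

    def predict(self, X):
        check_is_fitted(self, "threshold_")
        v = np.asarray(X, dtype=float).reshape(-1)
        above = v > self.threshold_
        yi = above.astype(int) if self.direction_ > 0 else (~above).astype(int)
        return self.classes_[yi]


def _stratified_folds(y: np.ndarray, folds: int, seed: int):
    """Deterministic stratified folds: a pure function of (seed, labels).
    The fold count is clamped (with a log message) when a class is too
    small to appear in every fold."""
    _, counts = np.unique(y, return_counts=True)
    eff = min(folds, int(counts.min()))
    if eff < 2:
        raise ValueError("stratification impossible: a class has < 2 members")
    if eff < folds:
        logger.info("reduced folds from %d to %d (small class)", folds, eff)
    skf = StratifiedKFold(n_splits=eff, shuffle=True,
                          random_state=int(seed) % (2**31))
    return list(skf.split(np.zeros(len(y)), y))


def threshold_classifier_cv(values, labels, folds: int = 10,
                            repeats: int = 10, seed: int = 0):
    """Mean and sd of the stump classifier's misclassification rate over
    ``repeats`` re-stratified rounds of ``folds``-fold cross-validation.
    NaN values are dropped pairwise with their labels."""
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    ok = ~np.isnan(v)
    v, y = v[ok], y[ok]
    classes, yi = np.unique(y, return_inverse=True)
    if classes.size != 2:
        raise ValueError("threshold_classifier_cv needs binary labels")
    errs = []
    for rep in range(repeats):
        for tr, te in _stratified_folds(yi, folds, seed + 1000003 * rep):
            t, direction = _stump_fit(v[tr], yi[tr])
            above = v[te] > t
            pred = above.astype(int) if direction > 0 else (~above).astype(int)
            errs.append(float(np.mean(pred != yi[te])))
    errs = np.array(errs)
    return float(errs.mean()), float(errs.std(ddof=1)) if errs.size > 1 else 0.0


# -- ranking -----------------------------------------------------------


def _column_values(m: DataMatrix, j: int) -> np.ndarray:
    return np.where(m.mask[:, j], np.nan, m.raw[:, j])


def rank_operations_classification(m: DataMatrix, labels=None,
                                   folds: int = 10, repeats: int = 10,
                                   seed: int = 0,
                                   score_threshold: float | None = None):
    """Score every operation with the stump CV error and sort ascending.

    Binary tasks use the error directly; multi-class tasks are handled
    one-vs-rest with macro-averaged error.  Columns left with a single
    class after dropping masked cells are skipped.  ``score_threshold``
    optionally retains only the operations below the given error
    (retrieval of every operation above a target success rate).
    """
    y = np.asarray(labels if labels is not None else m.row_labels, dtype=object)
    if labels is None and m.row_labels is None:
        raise ValueError("matrix carries no labels and none were given")
    labelled = np.array([l is not None for l in y])
    if not labelled.any():
        raise ValueError("no labelled series")
    classes = np.unique(y[labelled].astype(str))
    scores = []
    for j, op_id in enumerate(m.col_ids):
        v = _column_values(m, j)
        ok = ~np.isnan(v) & labelled
        if ok.sum() < 2 * len(classes) or np.unique(y[ok]).size < 2:
            continue
        try:
            if classes.size == 2:
                mean, sd = threshold_classifier_cv(
                    v[ok], y[ok], folds, repeats, seed
                )
            else:
                per = [
                    threshold_classifier_cv(
                        v[ok], (y[ok] == c).astype(int), folds, repeats, seed
                    )
                    for c in classes
                ]
                mean = float(np.mean([p[0] for p in per]))
                sd = float(np.mean([p[1] for p in per]))
        except ValueError:
            continue
        scores.append(OpScore(op_id, mean, sd, "misclassification"))
    scores.sort(key=lambda s: (s.score, s.op_id))
    if score_threshold is not None:
        scores = [s for s in scores if s.score < score_threshold]
    return scores


def rank_operations_regression(m: DataMatrix, targets=None):
    """Rank operations by |Pearson r| between their unmasked normalized
    outputs and the continuous targets (descending); Spearman rho is kept
    as a robustness check.  Zero-variance columns are excluded."""
    t = np.asarray(targets if targets is not None else m.row_targets,
                   dtype=float)
    if targets is None and m.row_targets is None:
        raise ValueError("matrix carries no targets and none were given")
    X = m.normalized if m.normalized is not None else m.raw
    scores = []
    for j, op_id in enumerate(m.col_ids):
        v = np.where(m.mask[:, j], np.nan, X[:, j])
        ok = ~np.isnan(v) & ~np.isnan(t)
        if ok.sum() < 3 or v[ok].std() == 0 or t[ok].std() == 0:
            continue
        r = pearsonr(v[ok], t[ok]).statistic
        rho = spearmanr(v[ok], t[ok]).statistic
        scores.append(
            OpScore(op_id, float(abs(r)), 0.0, "abs_correlation",
                    extra={"pearson_r": float(r), "spearman_rho": float(rho)})
        )
    scores.sort(key=lambda s: (-s.score, s.op_id))
    return scores


# -- forward selection -------------------------------------------------


class ForwardLDAClassifier(ClassifierMixin, BaseEstimator):
    """Greedy forward feature selection with a linear model.

    A single selected feature uses the optimal-threshold classifier (so a
    one-feature fit reproduces the single-operation ranking exactly);
    subsets of two or more use a Fisher linear discriminant.  At each step
    the feature minimizing the joint CV misclassification is added;
    selection stops at ``max_features`` or when the improvement is <= tol.
    NaN cells are filled with their column mean.
    """

    def __init__(self, max_features: int = 5, folds: int = 10,
                 repeats: int = 10, tol: float = 0.0, seed: int = 0):
        self.max_features = max_features
        self.folds = folds
        self.repeats = repeats
        self.tol = tol
        self.seed = seed

    def _cv_error(self, X, yi):
        errs = []
        for rep in range(self.repeats):
            for tr, te in _stratified_folds(
                yi, self.folds, self.seed + 1000003 * rep
            ):
                if X.shape[1] == 1:
                    t, direction = _stump_fit(X[tr, 0], yi[tr])
                    above = X[te, 0] > t
                    pred = (above.astype(int) if direction > 0
                            else (~above).astype(int))
                else:
                    lda = LinearDiscriminantAnalysis()
                    lda.fit(X[tr], yi[tr])
                    pred = lda.predict(X[te])
                errs.append(float(np.mean(pred != yi[te])))
        errs = np.array(errs)
        return float(errs.mean()), (
            float(errs.std(ddof=1)) if errs.size > 1 else 0.0
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        self.classes_, yi = np.unique(np.asarray(y), return_inverse=True)
        if self.classes_.size != 2:
            raise ValueError("forward selection needs binary labels")
        col_mean = np.nanmean(X, axis=0)
        filled = np.isnan(X)
        if filled.any():
            logger.info("forward selection: mean-filled %.1f%% of cells",
                        100 * filled.mean())
            X = np.where(filled, np.broadcast_to(col_mean, X.shape), X)
        usable = [j for j in range(X.shape[1]) if np.std(X[:, j]) > 0]

        selected: list = []
        self.step_errors_ = []
        self.individual_errors_ = {}
        current = np.inf
        current_sd = 0.0
        fold_errs: list = []
        while len(selected) < self.max_features:
            best = (np.inf, None, 0.0)
            for j in usable:
                if j in selected:
                    continue
                err, sd = self._cv_error(X[:, selected + [j]], yi)
                if not selected:
                    self.individual_errors_[j] = err
                if err < best[0]:
                    best = (err, j, sd)
            if best[1] is None or current - best[0] <= self.tol and selected:
                break
            selected.append(best[1])
            current, current_sd = best[0], best[2]
            self.step_errors_.append(current)
        self.selected_indices_ = selected
        self.cv_error_ = current
        self.cv_error_sd_ = current_sd
        if len(selected) == 1:
            self.model_ = ThresholdClassifier().fit(X[:, selected], yi)
            self.coef_ = np.array([float(self.model_.direction_)])
            self.intercept_ = -float(
                self.model_.direction_ * self.model_.threshold_
            )
        else:
            self.model_ = LinearDiscriminantAnalysis().fit(X[:, selected], yi)
            self.coef_ = self.model_.coef_.ravel().copy()
            self.intercept_ = float(self.model_.intercept_[0])
        return self

    def predict(self, X):
        check_is_fitted(self, "selected_indices_")
        X = np.asarray(X, dtype=float)[:, self.selected_indices_]
        return self.classes_[np.asarray(self.model_.predict(X), dtype=int)]


def forward_select(m: DataMatrix, labels=None, max_features: int = 5,
                   folds: int = 10, repeats: int = 10, tol: float = 0.0,
                   seed: int = 0) -> FeatureSetClassifier:
    """Greedy forward selection over the matrix columns; see
    :class:`ForwardLDAClassifier`.  Reports the selection path and each
    selected operation's individual stump error."""
    y = np.asarray(labels if labels is not None else m.row_labels, dtype=object)
    if labels is None and m.row_labels is None:
        raise ValueError("matrix carries no labels and none were given")
    labelled = np.array([l is not None for l in y])
    X = np.where(m.mask, np.nan, m.raw)[labelled]
    est = ForwardLDAClassifier(max_features=max_features, folds=folds,
                               repeats=repeats, tol=tol, seed=seed)
    est.fit(X, y[labelled].astype(str))
    op_ids = [m.col_ids[j] for j in est.selected_indices_]
    indiv = {
        m.col_ids[j]: e
        for j, e in est.individual_errors_.items()
        if j in est.selected_indices_
    }
    return FeatureSetClassifier(
        op_ids=op_ids,
        cv_error=est.cv_error_,
        cv_error_sd=est.cv_error_sd_,
        fold_errors=[],
        step_errors=est.step_errors_,
        individual_errors=indiv,
        coefficients=[float(c) for c in est.coef_],
        intercept=est.intercept_,
    )


# -- permutation FDR ---------------------------------------------------


def permutation_fdr(m: DataMatrix, y=None, scores=None, task: str = "classify",
                    n_perm: int = 100, fdr: float = 0.05, seed: int = 0,
                    folds: int = 10):
    """Pooled permutation p-values and Benjamini-Hochberg q-values for an
    operation ranking.

    For each permutation of the labels (or targets), every operation's
    score is recomputed with the same scoring machinery (a single round of
    stratified CV per permutation for classification); all null scores are
    pooled across operations and permutations and
    p = (1 + #{null strictly better}) / (1 + n_perm * n_ops).
    "Better" means lower misclassification / higher |r|.
    """
    if n_perm < 20:
        raise ValueError("need n_perm >= 20")
    if scores is None:
        scores = (
            rank_operations_classification(m, y, folds=folds, seed=seed)
            if task == "classify"
            else rank_operations_regression(m, y)
        )
    if task == "classify":
        yv = np.asarray(y if y is not None else m.row_labels, dtype=object)
        labelled = np.array([l is not None for l in yv])
    else:
        yv = np.asarray(y if y is not None else m.row_targets, dtype=float)
        labelled = ~np.isnan(yv)
    rng = np.random.default_rng(seed)
    cols = {s.op_id: m.col_ids.index(s.op_id) for s in scores}
    null = []
    for perm in range(n_perm):
        yp = rng.permutation(yv)
        for s in scores:
            v = _column_values(m, cols[s.op_id])
            ok = ~np.isnan(v) & labelled
            if task == "classify":
                if np.unique(yp[ok].astype(str)).size < 2:
                    continue
                mean, _ = threshold_classifier_cv(
                    v[ok], yp[ok], folds=folds, repeats=1,
                    seed=seed + 7919 * perm,
                )
                null.append(mean)
            else:
                tt = yp[ok]
                if v[ok].std() == 0 or tt.std() == 0:
                    continue
                null.append(abs(pearsonr(v[ok], tt).statistic))
    null = np.sort(np.array(null))
    total = null.size
    out = []
    ps = []
    for s in scores:
        if s.kind == "misclassification":
            better = np.searchsorted(null, s.score, side="left")
        else:
            better = total - np.searchsorted(null, s.score, side="right")
        p = (1 + better) / (1 + total)
        ps.append(p)
    qs = multipletests(ps, alpha=fdr, method="fdr_bh")[1]
    for s, p, q in zip(scores, ps, qs):
        out.append(replace(s, p_value=float(p), q_value=float(q)))
    return out
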