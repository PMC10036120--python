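"""Benchmark tasks comparing deviation scores against raw features.

Three tasks, each runnable on either a deviation-score matrix or a
residualized raw-feature matrix:

1. mass-univariate two-sample t-tests with Benjamini-Hochberg FDR across
   features (metric: number of significant features), plus summaries of
   extreme individual deviations (|Z| > 2) and rank-based group
   comparisons of the extreme-deviation counts;
2. linear support-vector classification with stratified k-fold
   cross-validation (metric: fold-mean AUC);
3. Brain-Basis-Set regression — principal-component regression with k
   retained components (metric: test-set mean squared error).

Labels are boolean arrays (True = patient) for tasks 1-2 and a real
phenotype vector for task 3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupDifferenceResult",
    "task1_group_difference",
    "ExtremeDeviationSummary",
    "summarize_extreme_deviations",
    "compare_extreme_counts",
    "ClassificationResult",
    "task2_svc_classification",
    "BBSModel",
    "RegressionResult",
    "fit_bbs",
    "task3_bbs_regression",
]


def _as_matrix_labels(features, labels):
    x = np.asarray(features, dtype=float)
    lab = np.asarray(labels)
    if lab.dtype != bool:
        lab = lab.astype(int).astype(bool)
    if x.ndim != 2 or x.shape[0] != lab.shape[0]:
        raise ValueError(f"features {x.shape} and labels {lab.shape} are misaligned")
    return x, lab


# ---------------------------------------------------------------------------
# task 1: mass-univariate group differences


@dataclass
class GroupDifferenceResult:
    t: np.ndarray
    p_raw: np.ndarray
    p_fdr: np.ndarray
    significant: np.ndarray
    count: int
    alpha: float
    excluded: np.ndarray  # zero-variance features left out of the count


def task1_group_difference(features, labels, alpha=0.05, equal_var=True):
    """Per-feature two-sample t-tests with BH-FDR correction.

    The default is the classical pooled-variance two-sided test; Welch is
    available via ``equal_var=False``. Features with zero within-group
    variance in both groups are flagged, given undefined p, and excluded
    from the significant count.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    x, lab = _as_matrix_labels(features, labels)
    g1, g0 = x[lab], x[~lab]
    if len(g1) == 0 or len(g0) == 0:
        raise ValueError("single class: both groups must be present")
    if len(g1) < 2 or len(g0) < 2:
        raise ValueError(
            f"both groups need >= 2 subjects (got {len(g1)} patients / {len(g0)} controls)"
        )
    degenerate = (g1.var(axis=0) == 0) & (g0.var(axis=0) == 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} feature(s) have zero within-group variance; "
            "excluded from the significant count",
            RuntimeWarning,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(g1, g0, axis=0, equal_var=equal_var)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    p[degenerate] = np.nan
    p_fdr = np.full_like(p, np.nan)
    significant = np.zeros(p.shape, dtype=bool)
    valid = ~np.isnan(p)
    if valid.any():
        reject, p_adj, *_ = multipletests(p[valid], alpha=alpha, method="fdr_bh")
        p_fdr[valid] = p_adj
        significant[valid] = reject
    return GroupDifferenceResult(
        t=t,
        p_raw=p,
        p_fdr=p_fdr,
        significant=significant,
        count=int(significant.sum()),
        alpha=alpha,
        excluded=degenerate,
    )


# ---------------------------------------------------------------------------
# extreme deviations


@dataclass
class ExtremeDeviationSummary:
    """Per-feature counts of subjects beyond +/- threshold, per group."""

    positive_patient: np.ndarray
    negative_patient: np.ndarray
    positive_control: np.ndarray
    negative_control: np.ndarray
    threshold: float
    n_patients: int
    n_controls: int


def summarize_extreme_deviations(z, labels, threshold=2.0):
    """Count extreme deviations (Z > threshold, Z < -threshold; strict)
    per feature, separately for positive/negative tails and each group."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    x, lab = _as_matrix_labels(z, labels)
    zp, zc = x[lab], x[~lab]
    return ExtremeDeviationSummary(
        positive_patient=(zp > threshold).sum(axis=0),
        negative_patient=(zp < -threshold).sum(axis=0),
        positive_control=(zc > threshold).sum(axis=0),
        negative_control=(zc < -threshold).sum(axis=0),
        threshold=float(threshold),
        n_patients=int(lab.sum()),
        n_controls=int((~lab).sum()),
    )


def compare_extreme_counts(counts_a, counts_b):
    """Mann-Whitney U test on per-feature extreme-deviation counts.

    Count distributions are skewed, so a rank-based test is used: exact
    enumeration when the combined length is <= 20 and there are no ties,
    the tie/continuity-corrected normal approximation otherwise.

    Returns ``(U, two-sided p)`` with U for the first sample.
    """
    a = np.asarray(counts_a, dtype=float)
    b = np.asarray(counts_b, dtype=float)
    if a.size == 0 or b.size == 0 or a.size != b.size:
        raise ValueError("count vectors must be nonempty and of equal length")
    method = "exact" if (a.size + b.size) <= 20 and len(np.unique(np.r_[a, b])) == a.size + b.size else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# task 2: linear SVC classification


@dataclass
class ClassificationResult:
    fold_aucs: list
    mean_auc: float
    fold_assignments: list = field(repr=False, default_factory=list)
    seed: int = 0

    def __post_init__(self):
        assert np.isclose(self.mean_auc, float(np.mean(self.fold_aucs)))


def stratified_folds(labels, n_folds, seed):
    """Stratified fold index pairs, deterministic in (labels, seed)."""
    lab = np.asarray(labels).astype(bool)
    counts = np.bincount(lab.astype(int), minlength=2)
    if counts.min() == 0:
        raise ValueError("single class: both classes must be present")
    if n_folds < 2 or n_folds > counts.min():
        raise ValueError(f"n_folds must lie in [2, minority class size {counts.min()}]")
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(lab)), lab)]


def task2_svc_classification(features, labels, n_folds=10, seed=0, C=1.0):
    """Linear-kernel SVC under stratified k-fold cross-validation.

    Held-out subjects are scored with the decision function and summarized
    as the ROC AUC per fold; the benchmark metric is the fold-mean AUC.
    Regularization stays at the default C=1 (no tuning).
    """
    x, lab = _as_matrix_labels(features, labels)
    folds = stratified_folds(lab, n_folds, seed)
    aucs = []
    for tr, te in folds:
        clf = SVC(kernel="linear", C=C)
        clf.fit(x[tr], lab[tr])
        scores = clf.decision_function(x[te])
        aucs.append(float(roc_auc_score(lab[te], scores)))
    return ClassificationResult(
        fold_aucs=aucs,
        mean_auc=float(np.mean(aucs)),
        fold_assignments=[(tr.tolist(), te.tolist()) for tr, te in folds],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# task 3: Brain Basis Set regression


@dataclass
class BBSModel:
    """Trained BBS regressor: train-set column means, top-k principal
    components, and the fitted coefficient vector B with intercept."""

    train_means: np.ndarray
    components: np.ndarray  # (k, n_features), rows orthonormal
    coef: np.ndarray  # (k,)
    intercept: float
    k: int

    def expression_scores(self, features):
        x = np.asarray(features, dtype=float)
        return (x - self.train_means) @ self.components.T

    def predict(self, features):
        return self.intercept + self.expression_scores(features) @ self.coef


@dataclass
class RegressionResult:
    predictions: np.ndarray
    mse: float
    k: int
    model: BBSModel = field(repr=False, default=None)


def fit_bbs(train_features, train_y, k=15):
    """Fit the BBS model: PCA (centering only) then OLS on expression scores."""
    x = np.asarray(train_features, dtype=float)
    y = np.asarray(train_y, dtype=float).ravel()
    if x.shape[0] != y.shape[0]:
        raise ValueError("train features/target row mismatch")
    if k < 1 or k > min(x.shape[0] - 1, x.shape[1]):
        raise ValueError(
            f"k={k} must lie in [1, min(n_train - 1, n_features) = "
            f"{min(x.shape[0] - 1, x.shape[1])}]"
        )
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(x)
    design = np.column_stack([np.ones(len(y)), scores])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return BBSModel(
        train_means=pca.mean_,
        components=pca.components_,
        coef=coef[1:],
        intercept=float(coef[0]),
        k=k,
    )


def task3_bbs_regression(train_features, train_y, test_features, test_y, k=15):
    """BBS regression benchmark: fit on the train partition, report the
    test-set mean squared error of the predicted phenotype."""
    train_features = np.asarray(train_features, dtype=float)
    test_features = np.asarray(test_features, dtype=float)
    if train_features.shape[1] != test_features.shape[1]:
        raise ValueError("train/test feature columns are misaligned")
    model = fit_bbs(train_features, train_y, k=k)
    pred = model.predict(test_features)
    y = np.asarray(test_y, dtype=float).ravel()
    if y.shape[0] != pred.shape[0]:
        raise ValueError("test features/target row mismatch")
    mse = float(np.mean((pred - y) ** 2))
    return RegressionResult(predictions=pred, mse=mse, k=k, model=model)
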