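"""Performance-difference statistic theta and its shared-shuffle permutation test.

For each benchmark task the statistic of interest is the difference in
performance between the deviation-score arm (Z) and the raw-feature arm
(R), oriented so that positive theta favors the deviation scores:

* task 1: ``theta = Count_Z - Count_R`` (significant-feature counts)
* task 2: ``theta = AUC_Z - AUC_R``
* task 3: ``theta = MSE_R - MSE_Z`` (lower MSE is better)

The null distribution is built by shuffling the outcome labels (diagnosis
for tasks 1-2, the cognition phenotype for task 3) with the *same* row
permutation applied to both arms in every iteration; feature matrices are
never permuted and the normative models are never refit (labels play no
role in their estimation). With C the number of permutations where
``theta_perm >= theta_observed``, the permuted p-value is exactly
``(C + 1) / (n_permutations + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import sklearn
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.svm import _libsvm

from .benchmarks import stratified_folds, task1_group_difference

__all__ = [
    "ThetaResult",
    "compute_theta",
    "run_permutation_test",
    "make_task1_runner",
    "make_task2_runner",
    "make_task3_runner",
]

TASK_NAMES = {1: "group difference", 2: "classification", 3: "regression"}


def compute_theta(task, metric_z, metric_r):
    """Oriented performance difference between the two feature arms."""
    if task in (1, 2):
        return float(metric_z) - float(metric_r)
    if task == 3:
        return float(metric_r) - float(metric_z)
    raise ValueError(f"unknown task id {task!r}; expected 1, 2 or 3")


@dataclass
class ThetaResult:
    """Observed theta, its permutation null, and the permuted p-value."""

    task: int
    theta_observed: float
    theta_perm: np.ndarray = field(repr=False)
    C: int
    n_permutations: int
    p_value: float
    seed: int
    metric_z: float = np.nan
    metric_r: float = np.nan

    def __post_init__(self):
        if self.task not in TASK_NAMES:
            raise ValueError(f"unknown task id {self.task!r}")
        if not 0 <= self.C <= self.n_permutations:
            raise ValueError("C must lie between 0 and n_permutations")
        if self.p_value != (self.C + 1) / (self.n_permutations + 1):
            raise ValueError("p_value must equal (C + 1)/(n_permutations + 1) exactly")

    def to_dict(self, full_null=False):
        d = {
            "task": self.task,
            "task_name": TASK_NAMES[self.task],
            "theta_observed": self.theta_observed,
            "metric_z": self.metric_z,
            "metric_r": self.metric_r,
            "C": self.C,
            "n_permutations": self.n_permutations,
            "p_value": self.p_value,
            "seed": self.seed,
            "null_digest": {
                "mean": float(np.mean(self.theta_perm)),
                "sd": float(np.std(self.theta_perm)),
                "q05": float(np.quantile(self.theta_perm, 0.05)),
                "q95": float(np.quantile(self.theta_perm, 0.95)),
                "max": float(np.max(self.theta_perm)),
            },
        }
        if full_null:
            d["theta_perm"] = self.theta_perm.tolist()
        return d


def run_permutation_test(task, runner, features_z, features_r, labels, n_permutations=499, seed=0):
    """Shared-shuffle permutation test of theta for one task.

    ``runner(features, labels) -> scalar metric`` must evaluate the task on
    one feature arm; it is called with identically shuffled labels on both
    arms each iteration (see the runner factories below, which freeze fold
    and split assignments so only label exchangeability is tested).
    """
    features_z = np.asarray(features_z, dtype=float)
    features_r = np.asarray(features_r, dtype=float)
    labels = np.asarray(labels)
    if not (len(features_z) == len(features_r) == len(labels)):
        raise ValueError(
            f"row misalignment: Z has {len(features_z)}, R has {len(features_r)}, "
            f"labels have {len(labels)}"
        )
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    metric_z = runner(features_z, labels)
    metric_r = runner(features_r, labels)
    theta_obs = compute_theta(task, metric_z, metric_r)
    rng = np.random.default_rng(seed)
    theta_perm = np.empty(n_permutations)
    n = len(labels)
    with sklearn.config_context(assume_finite=True):
        for i in range(n_permutations):
            perm = rng.permutation(n)
            shuffled = labels[perm]
            try:
                mz = runner(features_z, shuffled)
                mr = runner(features_r, shuffled)
            except Exception as exc:  # noqa: BLE001 - annotate and re-raise
                raise RuntimeError(f"task runner failed at permutation iteration {i}") from exc
            theta_perm[i] = compute_theta(task, mz, mr)
    C = int(np.sum(theta_perm >= theta_obs))
    return ThetaResult(
        task=task,
        theta_observed=theta_obs,
        theta_perm=theta_perm,
        C=C,
        n_permutations=n_permutations,
        p_value=(C + 1) / (n_permutations + 1),
        seed=seed,
        metric_z=float(metric_z),
        metric_r=float(metric_r),
    )


# ---------------------------------------------------------------------------
# runner factories (fixed design, shuffled labels)


def make_task1_runner(alpha=0.05):
    """Task-1 metric: number of BH-significant features."""

    def runner(features, labels):
        return task1_group_difference(features, labels, alpha=alpha).count

    return runner


def _rank_auc(labels, scores):
    """ROC AUC via the rank-sum identity (average ranks handle ties)."""
    ranks = stats.rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    return (ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def make_task2_runner(labels, n_folds=10, seed=0, C=1.0):
    """Task-2 metric with fold assignments frozen from the observed labels.

    Folds are stratified on the *observed* labels and reused for every
    permutation (only the labels shuffle). Each fold trains the linear
    max-margin classifier directly through libsvm on a per-fold Gram
    matrix cached per feature arm — numerically identical to
    ``SVC(kernel="linear")`` (asserted in the test suite) but cheap enough
    for thousands of permutation refits. Under a permuted labeling a
    held-out fold can end up single-class; such folds are dropped from the
    fold-mean AUC.
    """
    folds = stratified_folds(np.asarray(labels).astype(bool), n_folds, seed)
    kernel_cache = {}
    _libsvm.set_verbosity_wrap(0)

    def runner(features, labels):
        key = id(features)
        if key not in kernel_cache:
            x = np.asarray(features, dtype=float)
            gram = x @ x.T
            # hold a reference to the features so the id key stays valid
            kernel_cache[key] = (
                features,
                [
                    (
                        np.ascontiguousarray(gram[np.ix_(tr, tr)]),
                        np.ascontiguousarray(gram[np.ix_(te, tr)]),
                    )
                    for tr, te in folds
                ],
            )
        lab = np.asarray(labels).astype(bool)
        aucs = []
        for (tr, te), (k_train, k_test) in zip(folds, kernel_cache[key][1]):
            ytr, yte = lab[tr], lab[te]
            if ytr.all() or (~ytr).all() or yte.all() or (~yte).all():
                continue
            support, _, _, coef, intercept, *_ = _libsvm.fit(
                k_train, ytr.astype(np.float64), svm_type=0, kernel="precomputed", C=C
            )
            # sklearn's binary decision_function is the negated libsvm value
            scores = -(k_test[:, support] @ coef.ravel() + intercept[0])
            aucs.append(_rank_auc(yte, scores))
        if not aucs:
            raise ValueError("every fold was single-class under this labeling")
        return float(np.mean(aucs))

    return runner


def make_task3_runner(train_idx, test_idx, k=15):
    """Task-3 metric with the train/test split frozen.

    The PCA basis depends only on the (never-permuted) feature matrix, so
    per arm the expression scores are computed once and cached; each
    permutation refits only the coefficient vector B on the shuffled
    phenotype and reports the test-set MSE.
    """
    train_idx = np.asarray(train_idx, dtype=int)
    test_idx = np.asarray(test_idx, dtype=int)
    score_cache = {}

    def runner(features, target):
        key = id(features)
        if key not in score_cache:
            x = np.asarray(features, dtype=float)
            pca = PCA(n_components=k, svd_solver="full")
            s_train = pca.fit_transform(x[train_idx])
            s_test = pca.transform(x[test_idx])
            # hold a reference to the features so the id key stays valid
            score_cache[key] = (
                features,
                np.column_stack([np.ones(len(train_idx)), s_train]),
                np.column_stack([np.ones(len(test_idx)), s_test]),
            )
        _, d_train, d_test = score_cache[key]
        y = np.asarray(target, dtype=float)
        coef, *_ = np.linalg.lstsq(d_train, y[train_idx], rcond=None)
        pred = d_test @ coef
        return float(np.mean((pred - y[test_idx]) ** 2))

    return runner
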