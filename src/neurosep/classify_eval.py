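"""SVM training policy and the evaluation / statistics harness.

Classifiers follow one fixed policy: SVMs with margin parameter C = 1,
linear kernel for non-linear (sigmoid-bounded) features and RBF kernel
for linear time-course features, with the RBF width gamma chosen from
{0.1 * 2^i | i = 0..10} by internal stratified 5-fold cross-validation
(ties broken towards the smallest gamma).

Evaluation reports accuracy, sensitivity, specificity and Youden's
J statistic (sensitivity + specificity - 1), with exact one-sided
binomial tests against a baseline rate, exact McNemar tests between
classifiers, label-permutation tests, and site-confound audits
(site-only models and site-balanced test subsets).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .cohort_io import CohortTable
from .fmri_reduction import SubjectTimecourses

__all__ = [
    "default_gamma_grid",
    "ClassifierSpec",
    "TrainedModel",
    "EvalReport",
    "PermutationResult",
    "train_svm",
    "combine_features",
    "evaluate_predictions",
    "mcnemar_test",
    "permutation_test",
    "site_balanced_subsets",
    "site_only_model",
    "component_group_comparison",
]

POSITIVE_LABEL = "case"

logger = logging.getLogger("neurosep")


def default_gamma_grid() -> list[float]:
    """RBF width grid {0.1 * 2^i | i = 0..10}."""
    return [0.1 * 2.0**i for i in range(11)]


@dataclass
class ClassifierSpec:
    kernel: str = "linear"
    C_margin: float = 1.0
    gamma_grid: list[float] = field(default_factory=default_gamma_grid)
    standardize: bool = False

    def __post_init__(self) -> None:
        if self.kernel not in ("linear", "rbf"):
            raise ValueError(f"unknown kernel {self.kernel!r}")


@dataclass
class TrainedModel:
    model: SVC
    scaler: StandardScaler | None
    spec: ClassifierSpec
    gamma: float | None
    cv_accuracy: float | None
    cv_accuracy_sd: float | None = None

    def predict(self, features: np.ndarray) -> np.ndarray:
        X = np.asarray(features, dtype=float)
        if self.scaler is not None:
            X = self.scaler.transform(X)
        return self.model.predict(X)


@dataclass
class EvalReport:
    accuracy: float
    sensitivity: float
    specificity: float
    jstat: float
    n_correct: int
    n_total: int
    binomial_p: float
    tp: int
    fp: int
    tn: int
    fn: int

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "jstat": self.jstat,
            "n_correct": self.n_correct,
            "n_total": self.n_total,
            "binomial_p": self.binomial_p,
            "confusion": {"tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn},
        }


@dataclass
class PermutationResult:
    null_accuracies: np.ndarray
    observed: float
    p_value: float
    iters: int


def train_svm(
    features: np.ndarray,
    labels: Sequence[str] | np.ndarray,
    spec: ClassifierSpec | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> TrainedModel:
    """Fit an SVM under the fixed hyperparameter policy.

    For the RBF kernel, gamma is the argmax of internal stratified
    ``cv_folds``-fold CV accuracy over the grid, ties to the smallest
    gamma; the model is then refit on all the data.  With
    ``standardize`` set, features are z-scored with statistics stored
    from this training set.
    """
    spec = spec or ClassifierSpec()
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes")
    scaler = None
    if spec.standardize:
        scaler = StandardScaler().fit(X)
        X = scaler.transform(X)
    min_class = int(np.unique(y, return_counts=True)[1].min())
    if min_class < cv_folds:
        logger.warning("reducing cv_folds from %d to %d (smallest class)", cv_folds, min_class)
        cv_folds = max(2, min_class)
    cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    gamma = None
    cv_acc = None
    cv_sd = None
    if spec.kernel == "rbf":
        best = None
        for g in sorted(spec.gamma_grid):
            scores = cross_val_score(
                SVC(kernel="rbf", C=spec.C_margin, gamma=g), X, y, cv=cv
            )
            mean = float(scores.mean())
            if best is None or mean > best[0]:  # strict: ties keep smaller gamma
                best = (mean, float(scores.std()), g)
        cv_acc, cv_sd, gamma = best
        model = SVC(kernel="rbf", C=spec.C_margin, gamma=gamma)
    else:
        scores = cross_val_score(SVC(kernel="linear", C=spec.C_margin), X, y, cv=cv)
        cv_acc, cv_sd = float(scores.mean()), float(scores.std())
        model = SVC(kernel="linear", C=spec.C_margin)
    model.fit(X, y)
    return TrainedModel(
        model=model,
        scaler=scaler,
        spec=spec,
        gamma=gamma,
        cv_accuracy=cv_acc,
        cv_accuracy_sd=cv_sd,
    )


def combine_features(mri: np.ndarray, fmri: np.ndarray) -> np.ndarray:
    """Horizontal concatenation, structural block first."""
    mri = np.asarray(mri, dtype=float)
    fmri = np.asarray(fmri, dtype=float)
    if mri.shape[0] != fmri.shape[0]:
        raise ValueError("subject counts differ")
    return np.hstack([mri, fmri])


def evaluate_predictions(
    pred: Sequence[str] | np.ndarray,
    truth: Sequence[str] | np.ndarray,
    baseline_rate: float = 0.5,
    positive: str = POSITIVE_LABEL,
) -> EvalReport:
    """Confusion-matrix metrics plus an exact one-sided binomial test of
    the correct count against ``baseline_rate``."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("length mismatch")
    pos_t = truth == positive
    pos_p = pred == positive
    tp = int(np.sum(pos_t & pos_p))
    fn = int(np.sum(pos_t & ~pos_p))
    tn = int(np.sum(~pos_t & ~pos_p))
    fp = int(np.sum(~pos_t & pos_p))
    n_total = len(truth)
    n_correct = tp + tn
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("truth must contain both classes")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    binom_p = float(
        stats.binomtest(n_correct, n_total, baseline_rate, alternative="greater").pvalue
    )
    return EvalReport(
        accuracy=n_correct / n_total,
        sensitivity=sens,
        specificity=spec,
        jstat=sens + spec - 1.0,
        n_correct=n_correct,
        n_total=n_total,
        binomial_p=binom_p,
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
    )


def mcnemar_test(
    pred_a: Sequence | np.ndarray,
    pred_b: Sequence | np.ndarray,
    truth: Sequence | np.ndarray,
) -> float:
    """Exact McNemar test on the discordant pairs.

    b = subjects classifier A gets right and B wrong, c = the reverse;
    p is the exact two-sided binomial probability of b out of b + c at
    rate 1/2 (p = 1 when there are no discordant pairs).
    """
    pred_a = np.asarray(pred_a)
    pred_b = np.asarray(pred_b)
    truth = np.asarray(truth)
    if not (pred_a.shape == pred_b.shape == truth.shape):
        raise ValueError("length mismatch")
    a_ok = pred_a == truth
    b_ok = pred_b == truth
    b = int(np.sum(a_ok & ~b_ok))
    c = int(np.sum(~a_ok & b_ok))
    if b + c == 0:
        return 1.0
    return float(stats.binomtest(b, b + c, 0.5, alternative="two-sided").pvalue)


def permutation_test(
    features: np.ndarray,
    labels: Sequence | np.ndarray,
    train_fn: Callable[[np.ndarray, np.ndarray], TrainedModel],
    iters: int = 1000,
    seed: int = 0,
    test_fraction: float = 0.3,
    observed: float | None = None,
) -> PermutationResult:
    """Label-permutation null distribution of test accuracy.

    Each iteration permutes the labels (class counts preserved), makes a
    stratified train/test split, trains via ``train_fn`` and scores the
    held-out part.  The p-value uses the add-one estimator
    (count(null >= observed) + 1) / (iters + 1).
    """
    if iters < 1:
        raise ValueError("iters must be >= 1")
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)

    def split_and_score(y_use: np.ndarray, split_seed: int) -> float:
        Xtr, Xte, ytr, yte = train_test_split(
            X,
            y_use,
            test_size=test_fraction,
            stratify=y_use,
            random_state=split_seed,
        )
        model = train_fn(Xtr, ytr)
        return float(np.mean(model.predict(Xte) == yte))

    if observed is None:
        observed = split_and_score(y, int(rng.integers(2**31 - 1)))
    null = np.array(
        [
            split_and_score(rng.permutation(y), int(rng.integers(2**31 - 1)))
            for _ in range(iters)
        ]
    )
    p = (int(np.sum(null >= observed)) + 1) / (iters + 1)
    return PermutationResult(null_accuracies=null, observed=observed, p_value=p, iters=iters)


def site_balanced_subsets(cohort: CohortTable, seed: int = 0) -> CohortTable:
    """Per-site subsample so the case:control ratio is 1:1.

    Within each site the majority class is downsampled (seeded) to the
    minority count; sites lacking either class are dropped entirely.
    """
    rng = np.random.default_rng(seed)
    kept = []
    for _, group in cohort.frame.groupby("site", sort=True):
        cases = group[group["label"] == "case"]
        controls = group[group["label"] == "control"]
        n = min(len(cases), len(controls))
        if n == 0:
            continue
        for sub in (cases, controls):
            idx = rng.choice(len(sub), size=n, replace=False)
            kept.append(sub.iloc[np.sort(idx)])
    if not kept:
        return CohortTable(cohort.frame.iloc[0:0].copy())
    return CohortTable(pd.concat(kept).sort_index().reset_index(drop=True))


def site_only_model(cohort: CohortTable, seed: int = 0) -> EvalReport:
    """Confound ceiling: how well one-hot site IDs alone predict labels.

    Fits a linear SVM on site indicators and scores it on the same
    subjects; the resulting in-sample accuracy is the per-site majority
    rate that any site-proxy classifier could reach.
    """
    sites = pd.get_dummies(cohort.frame["site"]).to_numpy(dtype=float)
    labels = cohort.labels
    majority_rate = max(np.mean(labels == "case"), np.mean(labels == "control"))
    if len(np.unique(labels)) < 2:
        raise ValueError("need both classes for a site audit")
    model = SVC(kernel="linear", C=1.0)
    model.fit(sites, labels)
    pred = model.predict(sites)
    return evaluate_predictions(pred, labels, baseline_rate=majority_rate)


def component_group_comparison(
    timecourses: Sequence[SubjectTimecourses],
    labels: Sequence | np.ndarray,
    component: int,
    alpha: float = 0.05,
) -> tuple[int, int, np.ndarray]:
    """Per-timepoint comparison of one component's weights between groups.

    At each time point t the case and control means of A_i[t, h] are
    compared with a Welch two-sample t-test (no multiplicity
    correction).  Returns (number of time points where the case mean is
    below the control mean, number with p <= alpha, the p-values).
    """
    labels = np.asarray(labels)
    weights = np.stack([tc.A[:, component] for tc in timecourses])  # n x T
    if weights.std() == 0:
        raise ValueError("zero-variance component")
    cases = weights[labels == "case"]
    controls = weights[labels == "control"]
    if len(cases) < 2 or len(controls) < 2:
        raise ValueError("each group needs at least 2 subjects")
    res = stats.ttest_ind(cases, controls, axis=0, equal_var=False)
    pvals = np.asarray(res.pvalue)
    n_reduced = int(np.sum(cases.mean(axis=0) < controls.mean(axis=0)))
    n_significant = int(np.sum(pvals <= alpha))
    return n_reduced, n_significant, pvals
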