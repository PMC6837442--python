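"""Feature selectors: two-sample t-test ranking and SVM-RFE.

Both selectors operate *only* on the sample rows they are given, which is the
property the validation schemes rely on to prove (or deliberately break)
train/test separation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from ._fastsvm import FastSVC
from .exceptions import InvalidArgumentError
from .folds import stratified_folds
from .seeding import derive_rng
from .synthetic_data import Dataset

__all__ = [
    "SelectionResult",
    "compute_t_statistics",
    "ttest_select",
    "svm_rfe",
]


@dataclass
class SelectionResult:
    """Outcome of one selector call.

    ``selected`` holds feature indices; for the t-test selector they are
    ordered by decreasing \\|t\\| (ties broken by lower index), for SVM-RFE by
    ascending index.  ``scores`` is \\|t\\| per feature for the t-test and the
    1-based elimination position for RFE (features never eliminated share
    ``len(elimination_order) + 1``).  ``step_accuracies`` (RFE only) records
    the evaluated accuracy of each successively smaller subset.
    """

    selected: list[int]
    scores: np.ndarray
    method: str
    elimination_order: list[int] = field(default_factory=list)
    step_accuracies: list[float] = field(default_factory=list)
    step_sizes: list[int] = field(default_factory=list)
    converged: bool = True

    def to_json(self) -> str:
        return json.dumps(
            {
                "method": self.method,
                "selected": [int(i) for i in self.selected],
                "scores": [float(s) for s in self.scores],
                "elimination_order": [int(i) for i in self.elimination_order],
                "step_accuracies": [float(a) for a in self.step_accuracies],
                "step_sizes": [int(s) for s in self.step_sizes],
                "converged": self.converged,
            }
        )


def _class_rows(dataset: Dataset, rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    rows = np.asarray(rows, dtype=int)
    y = dataset.labels[rows]
    r0, r1 = rows[y == 0], rows[y == 1]
    if r0.size < 2 or r1.size < 2:
        raise InvalidArgumentError(
            "both classes must be present with >= 2 samples each among the "
            f"given rows (got {r0.size} and {r1.size})"
        )
    return r0, r1


def compute_t_statistics(dataset: Dataset, rows: np.ndarray) -> np.ndarray:
    """Classic pooled-variance two-sample t statistic per feature.

    Returns class-1 minus class-0 mean difference in units of pooled standard
    error.  Zero pooled variance yields a signed infinity sentinel when the
    means differ and 0 when they do not, so degenerate perfectly separating
    features outrank everything finite.
    """
    r0, r1 = _class_rows(dataset, rows)
    x0 = dataset.features[r0]
    x1 = dataset.features[r1]
    n0, n1 = x0.shape[0], x1.shape[0]
    m0, m1 = x0.mean(axis=0), x1.mean(axis=0)
    v0 = x0.var(axis=0, ddof=1)
    v1 = x1.var(axis=0, ddof=1)
    sp2 = ((n0 - 1) * v0 + (n1 - 1) * v1) / (n0 + n1 - 2)
    se = np.sqrt(sp2 * (1.0 / n0 + 1.0 / n1))
    diff = m1 - m0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    # zero pooled variance: +/-inf sentinel if means differ, 0 otherwise
    degenerate = se == 0
    t[degenerate & (diff > 0)] = np.inf
    t[degenerate & (diff < 0)] = -np.inf
    t[degenerate & (diff == 0)] = 0.0
    return t


def ttest_select(dataset: Dataset, rows: np.ndarray, k: int = 10) -> SelectionResult:
    """Select the ``k`` features with the highest absolute t statistic."""
    p = dataset.n_features
    if k > p:
        raise InvalidArgumentError(f"k={k} exceeds the number of features ({p})")
    if k < 1:
        raise InvalidArgumentError(f"k must be >= 1, got {k}")
    t = compute_t_statistics(dataset, rows)
    abs_t = np.abs(t)
    # sort by decreasing |t|, ties by lower feature index
    order = np.lexsort((np.arange(p), -abs_t))
    return SelectionResult(
        selected=[int(i) for i in order[:k]],
        scores=abs_t,
        method="t-test",
    )


def _linear_svm_cv_accuracy(
    dataset: Dataset,
    rows: np.ndarray,
    features: np.ndarray,
    rfe_c: float,
    folds: list[np.ndarray] | None,
) -> float:
    """Mean stratified-CV accuracy (%) of a linear SVM on the given subset.

    ``folds=None`` means resubstitution: fit and score on the same rows.
    """
    X = dataset.features[np.ix_(rows, features)]
    y = dataset.labels[rows]
    if folds is None:
        clf = FastSVC(kernel="linear", C=rfe_c)
        clf.fit(X, y)
        return 100.0 * float(np.mean(clf.predict(X) == y))
    row_pos = {int(r): i for i, r in enumerate(rows)}
    accs = []
    for fold in folds:
        test_pos = np.array([row_pos[int(r)] for r in fold])
        train_mask = np.ones(len(rows), dtype=bool)
        train_mask[test_pos] = False
        clf = FastSVC(kernel="linear", C=rfe_c)
        clf.fit(X[train_mask], y[train_mask])
        accs.append(100.0 * float(np.mean(clf.predict(X[test_pos]) == y[test_pos])))
    return float(np.mean(accs))


def svm_rfe(
    dataset: Dataset,
    rows: np.ndarray,
    elimination_step: int = 1,
    rfe_c: float = 1.0,
    eval_mode: str = "cv",
    eval_folds: int = 10,
    seed: int = 0,
) -> SelectionResult:
    """Recursive feature elimination driven by linear-SVM weights.

    Starting from the full feature set, a linear max-margin classifier
    (penalty ``rfe_c``) is fitted on ``rows``; each iteration removes the
    ``elimination_step`` features with the smallest squared weight components
    (ties broken by lower feature index).  Each evaluated subset receives an
    accuracy — stratified ``eval_folds``-fold CV of the same linear
    classifier by default (``eval_mode="resub"`` scores on the training rows
    instead).  The returned set is the subset attaining the maximum step
    accuracy; ties go to the smaller subset.
    """
    rows = np.asarray(rows, dtype=int)
    p = dataset.n_features
    if p < 1:
        raise InvalidArgumentError("dataset must have at least one feature")
    if elimination_step < 1:
        raise InvalidArgumentError(
            f"elimination_step must be >= 1, got {elimination_step}"
        )
    if eval_mode not in ("cv", "resub"):
        raise InvalidArgumentError(f"unknown eval_mode {eval_mode!r}")
    _class_rows(dataset, rows)  # validates both classes present

    folds: list[np.ndarray] | None = None
    if eval_mode == "cv":
        k = min(eval_folds, rows.size)
        rng = derive_rng(seed, "rfe-eval-folds")
        folds = stratified_folds(dataset.labels, rows, k, rng)

    current = np.arange(p)
    elimination_order: list[int] = []
    step_accuracies: list[float] = []
    step_sizes: list[int] = []
    subsets: list[np.ndarray] = []
    converged = True

    while True:
        acc = _linear_svm_cv_accuracy(dataset, rows, current, rfe_c, folds)
        subsets.append(current.copy())
        step_accuracies.append(acc)
        step_sizes.append(current.size)
        if current.size == 1:
            break
        X = dataset.features[np.ix_(rows, current)]
        y = dataset.labels[rows]
        clf = FastSVC(kernel="linear", C=rfe_c)
        clf.fit(X, y)
        if clf.fit_status_ != 0:  # solver hit its iteration cap
            converged = False
        w2 = np.ravel(clf.coef_) ** 2
        n_remove = min(elimination_step, current.size - 1)
        # smallest squared weight removed first; ties by lower feature index
        order = np.lexsort((current, w2))
        removed = current[order[:n_remove]]
        elimination_order.extend(int(f) for f in sorted(removed))
        keep = np.setdiff1d(current, removed)
        current = keep

    best = int(np.argmax(step_accuracies))
    # ties: prefer the smallest subset (later steps are smaller)
    best_acc = step_accuracies[best]
    for i in range(len(step_accuracies) - 1, -1, -1):
        if step_accuracies[i] == best_acc:
            best = i
            break
    selected = subsets[best]

    scores = np.full(p, len(elimination_order) + 1, dtype=float)
    for pos, f in enumerate(elimination_order, start=1):
        scores[f] = pos

    # report only the eliminations taken to reach the selected subset, so
    # elimination_order + selected is a disjoint permutation of all features
    reported_order = elimination_order[: p - selected.size]

    return SelectionResult(
        selected=[int(i) for i in selected],
        scores=scores,
        method="svm-rfe",
        elimination_order=reported_order,
        step_accuracies=step_accuracies,
        step_sizes=step_sizes,
        converged=converged,
    )
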