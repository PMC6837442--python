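"""Hyperparameter grids, inner-CV grid search and fit/predict plumbing.

Two classifier families are supported:

* ``"rbf-svm"`` — SVM with a radial-basis kernel, tuned over
  ``C = 2**j`` and ``gamma = 2**i``.
* ``"logistic"`` — penalised logistic regression, tuned over
  ``penalty in {l1, l2}`` and ``C = e**i``.

Grid combos are ordered by ascending C (then ascending gamma; L2 before L1
for logistic), and :func:`grid_search` keeps the *first* combo attaining the
maximum inner-CV accuracy, so ties resolve toward stronger regularisation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import sklearn
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from ._fastsvm import FastSVC
from .exceptions import InvalidArgumentError
from .folds import stratified_folds
from .seeding import derive_rng
from .synthetic_data import Dataset

__all__ = [
    "TuningGrid",
    "TunedModel",
    "default_grid",
    "make_grid",
    "grid_search",
    "fit_classifier",
    "predict_labels",
]

CLASSIFIER_KINDS = ("rbf-svm", "logistic")

LOGISTIC_TOL = 1e-6
# cap hits are logged (not fatal): strongly under-regularised L1 combos on
# noise can otherwise spin liblinear for a very long time
LOGISTIC_MAX_ITER = 1_000

_logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TuningGrid:
    """An ordered sequence of hyperparameter combos for one classifier kind."""

    classifier_kind: str
    combos: tuple[dict[str, Any], ...]

    def __post_init__(self) -> None:
        if self.classifier_kind not in CLASSIFIER_KINDS:
            raise InvalidArgumentError(
                f"unknown classifier kind {self.classifier_kind!r}; "
                f"expected one of {CLASSIFIER_KINDS}"
            )
        if len(self.combos) < 1:
            raise InvalidArgumentError("grid must contain at least one combo")
        for combo in self.combos:
            if combo.get("C", 1.0) <= 0:
                raise InvalidArgumentError("all C values must be > 0")
            if combo.get("gamma", 1.0) <= 0:
                raise InvalidArgumentError("all gamma values must be > 0")

    def __len__(self) -> int:
        return len(self.combos)


@dataclass
class TunedModel:
    """Result of a grid search: chosen combo, its inner-CV accuracy and the
    refitted estimator."""

    classifier_kind: str
    params: dict[str, Any]
    inner_cv_accuracy: float
    estimator: Any
    combo_scores: list[float] = field(default_factory=list)
    feature_indices: np.ndarray | None = None


def default_grid(classifier_kind: str) -> TuningGrid:
    """The canonical tuning grids: 7x7 for rbf-svm, 2x10 for logistic."""
    if classifier_kind == "rbf-svm":
        # gamma ascending within each C so the first-max tie-break prefers
        # the smoother (more regularised) boundary
        combos = tuple(
            {"C": float(2.0**j), "gamma": float(2.0**-i)}
            for j in range(1, 8)
            for i in range(7, 0, -1)
        )
        return TuningGrid("rbf-svm", combos)
    if classifier_kind == "logistic":
        combos = tuple(
            {"C": float(np.exp(i)), "penalty": penalty}
            for i in range(0, 10)
            for penalty in ("l2", "l1")
        )
        return TuningGrid("logistic", combos)
    raise InvalidArgumentError(f"unknown classifier kind {classifier_kind!r}")


def make_grid(classifier_kind: str, size: int) -> TuningGrid:
    """Build a grid of controlled size for the grid-size sweep.

    rbf-svm: an ``size x size`` grid with ``C = 2**j, j = 2..size+1`` and
    ``gamma = 2**i, i = -2..-(size+1)``.  logistic: ``size`` C values with
    exponents evenly spaced over [-4, 4] crossed with both penalties.
    """
    if size < 2:
        raise InvalidArgumentError(f"grid size must be >= 2, got {size}")
    if classifier_kind == "rbf-svm":
        combos = tuple(
            {"C": float(2.0**j), "gamma": float(2.0**-i)}
            for j in range(2, size + 2)
            for i in range(size + 1, 1, -1)
        )
        return TuningGrid("rbf-svm", combos)
    if classifier_kind == "logistic":
        exponents = np.linspace(-4.0, 4.0, size)
        combos = tuple(
            {"C": float(np.exp(e)), "penalty": penalty}
            for e in exponents
            for penalty in ("l2", "l1")
        )
        return TuningGrid("logistic", combos)
    raise InvalidArgumentError(f"unknown classifier kind {classifier_kind!r}")


def fit_classifier(
    kind: str,
    hyperparams: dict[str, Any],
    X: np.ndarray,
    y: np.ndarray,
):
    """Fit one classifier of the given kind and return the fitted estimator."""
    if kind == "rbf-svm":
        est = FastSVC(kernel="rbf", C=hyperparams["C"], gamma=hyperparams["gamma"])
    elif kind == "logistic":
        # grids speak "penalty" (l1/l2); recent scikit-learn wants l1_ratio
        est = LogisticRegression(
            l1_ratio=1 if hyperparams.get("penalty", "l2") == "l1" else 0,
            C=hyperparams["C"],
            solver="liblinear",
            tol=LOGISTIC_TOL,
            max_iter=LOGISTIC_MAX_ITER,
        )
    else:
        raise InvalidArgumentError(f"unknown classifier kind {kind!r}")
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        est.fit(X, y)
    if any(issubclass(w.category, ConvergenceWarning) for w in caught):
        _logger.debug(
            "iteration cap hit for %s with %s on %d rows", kind, hyperparams, len(y)
        )
    return est


def predict_labels(estimator, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    n_expected = estimator.n_features_in_
    if X.ndim != 2 or X.shape[1] != n_expected:
        raise InvalidArgumentError(
            f"estimator was trained on {n_expected} features, "
            f"got input of shape {X.shape}"
        )
    return estimator.predict(X)


def grid_search(
    dataset: Dataset,
    rows: np.ndarray,
    feature_indices: np.ndarray,
    grid: TuningGrid,
    inner_folds: int = 10,
    seed: int = 0,
    strict_folds: bool = True,
) -> TunedModel:
    """Score every combo by stratified inner-CV mean accuracy on ``rows``
    (restricted to ``feature_indices``), then refit the best combo on all of
    ``rows``.

    With ``strict_folds=True`` (default) ``inner_folds`` exceeding the
    per-class count is an error.  ``strict_folds=False`` degrades gracefully
    for tiny row sets (used by the validation schemes and toy experiments):
    the fold count is capped at the smaller per-class count, so folds stay
    stratified with at least one sample of each class where possible.
    """
    rows = np.asarray(rows, dtype=int)
    feature_indices = np.asarray(feature_indices, dtype=int)
    y = dataset.labels[rows]
    counts = np.bincount(y, minlength=2)
    if counts[0] == 0 or counts[1] == 0:
        raise InvalidArgumentError("rows must contain both classes")
    if inner_folds < 2:
        raise InvalidArgumentError(f"inner_folds must be >= 2, got {inner_folds}")
    if strict_folds and inner_folds > counts.min():
        raise InvalidArgumentError(
            f"inner_folds={inner_folds} exceeds the smaller per-class count "
            f"({counts.min()}); pass strict_folds=False to degrade to "
            "leave-one-out-sized folds"
        )
    k = min(inner_folds, rows.size)
    if k > counts.min():
        k = max(2, int(counts.min()))
    rng = derive_rng(seed, "inner-folds")
    folds = stratified_folds(dataset.labels, rows, k, rng)

    X = dataset.features[np.ix_(rows, feature_indices)]
    row_pos = {int(r): i for i, r in enumerate(rows)}
    fold_pos = [np.array([row_pos[int(r)] for r in f]) for f in folds]

    combo_scores: list[float] = []
    # inputs are finite arrays built above; skip sklearn's per-fit validation
    # in this hot loop (tens of thousands of tiny fits per sweep)
    with sklearn.config_context(assume_finite=True, skip_parameter_validation=True):
        for combo in grid.combos:
            accs = []
            for test in fold_pos:
                train_mask = np.ones(rows.size, dtype=bool)
                train_mask[test] = False
                est = fit_classifier(
                    grid.classifier_kind, combo, X[train_mask], y[train_mask]
                )
                accs.append(100.0 * float(np.mean(est.predict(X[test]) == y[test])))
            combo_scores.append(float(np.mean(accs)))

        best = int(np.argmax(combo_scores))  # first max -> grid-order tie-break
        best_combo = grid.combos[best]
        estimator = fit_classifier(grid.classifier_kind, best_combo, X, y)
    return TunedModel(
        classifier_kind=grid.classifier_kind,
        params=dict(best_combo),
        inner_cv_accuracy=combo_scores[best],
        estimator=estimator,
        combo_scores=combo_scores,
        feature_indices=feature_indices,
    )
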