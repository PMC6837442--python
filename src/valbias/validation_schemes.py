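"""The five validation protocols, with an auditable row ledger.

Each scheme runs one model-development recipe (a :class:`PipelineSpec`) over
a dataset and returns a :class:`ValidationResult` whose per-fold records name
the exact sample rows each development stage (feature selection, tuning,
final fit) and the evaluation stage touched.  The ledger is what the test
suite uses to prove each scheme is what it claims:

* ``split``     — all development on the training portion only.
* ``kfold``     — selection and tuning ONCE on all rows (the biased,
                  non-nested protocol under study), classifier refitted per
                  fold with frozen features/hyperparameters.
* ``nested``    — full development redone inside every outer fold.
* ``fs_out``    — selection once on all rows; tuning nested per fold.
* ``tune_out``  — tuning once on all rows; selection nested per fold.

Accuracies are percentages; the overall accuracy is the unweighted mean of
fold accuracies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from . import feature_selection as fs
from . import model_tuning as mt
from .exceptions import InvalidArgumentError
from .folds import stratified_folds
from .seeding import derive_rng, derive_seed
from .synthetic_data import Dataset

__all__ = [
    "PipelineSpec",
    "FoldRecord",
    "ValidationResult",
    "preset",
    "train_test_split_validate",
    "kfold_validate",
    "nested_cv_validate",
    "partial_nested_fs_out",
    "partial_nested_tune_out",
    "validate",
    "SCHEMES",
]

SELECTOR_KINDS = ("ttest", "svm-rfe", "none")


@dataclass(frozen=True)
class PipelineSpec:
    """Declarative description of one model-development recipe."""

    selector: str = "ttest"
    selector_k: int = 10
    rfe_c: float = 1.0
    rfe_step: int = 1
    rfe_eval_mode: str = "cv"
    rfe_eval_folds: int = 10
    classifier_kind: str = "logistic"
    grid: mt.TuningGrid | None = None
    inner_folds: int = 10
    # feature space seen by the global tuning step of tune_out:
    # "selected" (features chosen on all rows) or "all"
    tune_out_feature_space: str = "selected"

    def __post_init__(self) -> None:
        if self.selector not in SELECTOR_KINDS:
            raise InvalidArgumentError(
                f"unknown selector {self.selector!r}; expected one of {SELECTOR_KINDS}"
            )
        if self.classifier_kind not in mt.CLASSIFIER_KINDS:
            raise InvalidArgumentError(
                f"unknown classifier kind {self.classifier_kind!r}"
            )
        if self.tune_out_feature_space not in ("selected", "all"):
            raise InvalidArgumentError(
                "tune_out_feature_space must be 'selected' or 'all'"
            )

    def resolved_grid(self) -> mt.TuningGrid:
        return self.grid if self.grid is not None else mt.default_grid(self.classifier_kind)


def preset(name: str, **overrides: Any) -> PipelineSpec:
    """The two canonical pipelines: ``"svm"`` (SVM-RFE + RBF-SVM) and
    ``"logreg"`` (t-test + penalised logistic regression)."""
    if name == "svm":
        spec = PipelineSpec(selector="svm-rfe", classifier_kind="rbf-svm")
    elif name == "logreg":
        spec = PipelineSpec(selector="ttest", classifier_kind="logistic")
    else:
        raise InvalidArgumentError(f"unknown pipeline preset {name!r}")
    return replace(spec, **overrides) if overrides else spec


@dataclass
class FoldRecord:
    """Row-level audit of one fold: which rows each stage touched."""

    fold: int
    selection_rows: list[int]
    tuning_rows: list[int]
    fit_rows: list[int]
    evaluation_rows: list[int]
    features: list[int]
    params: dict[str, Any]
    accuracy: float

    def development_rows(self) -> set[int]:
        return set(self.selection_rows) | set(self.tuning_rows) | set(self.fit_rows)


@dataclass
class ValidationResult:
    scheme: str
    fold_accuracies: list[float]
    accuracy: float
    folds: list[FoldRecord] = field(default_factory=list)
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def ledger(self) -> dict[str, list[list[int]]]:
        return {
            "selection": [f.selection_rows for f in self.folds],
            "tuning": [f.tuning_rows for f in self.folds],
            "fit": [f.fit_rows for f in self.folds],
            "evaluation": [f.evaluation_rows for f in self.folds],
        }

    def to_json(self) -> str:
        return json.dumps(
            {
                "scheme": self.scheme,
                "accuracy": self.accuracy,
                "fold_accuracies": self.fold_accuracies,
                "folds": [
                    {
                        "fold": f.fold,
                        "selection_rows": f.selection_rows,
                        "tuning_rows": f.tuning_rows,
                        "fit_rows": f.fit_rows,
                        "evaluation_rows": f.evaluation_rows,
                        "features": f.features,
                        "params": f.params,
                        "accuracy": f.accuracy,
                    }
                    for f in self.folds
                ],
                "meta": self.meta,
            }
        )


# ---------------------------------------------------------------------------
# shared building blocks
# ---------------------------------------------------------------------------


def _select_features(
    dataset: Dataset, rows: np.ndarray, spec: PipelineSpec, seed: int
) -> list[int]:
    if spec.selector == "none":
        return list(range(dataset.n_features))
    if spec.selector == "ttest":
        return fs.ttest_select(dataset, rows, k=spec.selector_k).selected
    return fs.svm_rfe(
        dataset,
        rows,
        elimination_step=spec.rfe_step,
        rfe_c=spec.rfe_c,
        eval_mode=spec.rfe_eval_mode,
        eval_folds=spec.rfe_eval_folds,
        seed=seed,
    ).selected


def _tune(
    dataset: Dataset,
    rows: np.ndarray,
    features: list[int],
    spec: PipelineSpec,
    seed: int,
) -> mt.TunedModel:
    # inner folds degrade to leave-one-out-sized folds at tiny n (strict
    # per-class validation is exposed on grid_search itself)
    return mt.grid_search(
        dataset,
        rows,
        np.asarray(features, dtype=int),
        spec.resolved_grid(),
        inner_folds=spec.inner_folds,
        seed=seed,
        strict_folds=False,
    )


def _score(
    dataset: Dataset, estimator: Any, features: list[int], rows: np.ndarray
) -> float:
    X = dataset.features[np.ix_(rows, features)]
    y = dataset.labels[rows]
    return 100.0 * float(np.mean(mt.predict_labels(estimator, X) == y))


def _outer_folds(
    dataset: Dataset, n_folds: int, seed: int
) -> list[np.ndarray]:
    n = dataset.n_samples
    if n_folds < 2:
        raise InvalidArgumentError(f"K must be >= 2, got {n_folds}")
    if n_folds > n:
        raise InvalidArgumentError(f"K={n_folds} exceeds the sample count ({n})")
    rng = derive_rng(seed, "outer-folds")
    return stratified_folds(dataset.labels, np.arange(n), n_folds, rng)


def _train_rows(n: int, test_rows: np.ndarray) -> np.ndarray:
    mask = np.ones(n, dtype=bool)
    mask[test_rows] = False
    return np.flatnonzero(mask)


# ---------------------------------------------------------------------------
# the five schemes
# ---------------------------------------------------------------------------


def train_test_split_validate(
    dataset: Dataset,
    spec: PipelineSpec,
    test_fraction: float = 0.2,
    seed: int = 0,
) -> ValidationResult:
    """Hold out a stratified test portion before any development step."""
    n = dataset.n_samples
    per_class_test = int(round(test_fraction * n / 2))
    if per_class_test < 1 or per_class_test >= n // 2:
        raise InvalidArgumentError(
            f"test_fraction={test_fraction} leaves a degenerate split for n={n}"
        )
    rng = derive_rng(seed, "split")
    test_parts = []
    for cls in (0, 1):
        cls_rows = np.flatnonzero(dataset.labels == cls)
        test_parts.append(rng.permutation(cls_rows)[:per_class_test])
    test_rows = np.sort(np.concatenate(test_parts))
    train_rows = _train_rows(n, test_rows)

    features = _select_features(dataset, train_rows, spec, derive_seed(seed, "selection", 0))
    tuned = _tune(dataset, train_rows, features, spec, derive_seed(seed, "tuning", 0))
    acc = _score(dataset, tuned.estimator, features, test_rows)

    record = FoldRecord(
        fold=0,
        selection_rows=train_rows.tolist(),
        tuning_rows=train_rows.tolist(),
        fit_rows=train_rows.tolist(),
        evaluation_rows=test_rows.tolist(),
        features=list(features),
        params=tuned.params,
        accuracy=acc,
    )
    return ValidationResult(
        scheme="split",
        fold_accuracies=[acc],
        accuracy=acc,
        folds=[record],
        meta={"test_fraction": test_fraction, "seed": seed},
    )


def kfold_validate(
    dataset: Dataset, spec: PipelineSpec, n_folds: int = 10, seed: int = 0
) -> ValidationResult:
    """Non-nested K-fold: one model developed on ALL rows, then scored by CV.

    Selection and tuning see every row (including each fold's evaluation
    rows) — this is the biased protocol under study.
    """
    n = dataset.n_samples
    all_rows = np.arange(n)
    features = _select_features(dataset, all_rows, spec, derive_seed(seed, "selection", 0))
    tuned = _tune(dataset, all_rows, features, spec, derive_seed(seed, "tuning", 0))

    folds = _outer_folds(dataset, n_folds, seed)
    records, accs = [], []
    for i, test_rows in enumerate(folds):
        train_rows = _train_rows(n, test_rows)
        est = mt.fit_classifier(
            spec.classifier_kind,
            tuned.params,
            dataset.features[np.ix_(train_rows, features)],
            dataset.labels[train_rows],
        )
        acc = _score(dataset, est, features, test_rows)
        accs.append(acc)
        records.append(
            FoldRecord(
                fold=i,
                selection_rows=all_rows.tolist(),
                tuning_rows=all_rows.tolist(),
                fit_rows=train_rows.tolist(),
                evaluation_rows=test_rows.tolist(),
                features=list(features),
                params=tuned.params,
                accuracy=acc,
            )
        )
    return ValidationResult(
        scheme="kfold",
        fold_accuracies=accs,
        accuracy=float(np.mean(accs)),
        folds=records,
        meta={"n_folds": n_folds, "seed": seed},
    )


def nested_cv_validate(
    dataset: Dataset, spec: PipelineSpec, n_folds: int = 10, seed: int = 0
) -> ValidationResult:
    """Nested CV: a complete model developed from scratch inside each fold."""
    n = dataset.n_samples
    folds = _outer_folds(dataset, n_folds, seed)
    records, accs = [], []
    for i, test_rows in enumerate(folds):
        train_rows = _train_rows(n, test_rows)
        features = _select_features(
            dataset, train_rows, spec, derive_seed(seed, "selection", i)
        )
        tuned = _tune(dataset, train_rows, features, spec, derive_seed(seed, "tuning", i))
        acc = _score(dataset, tuned.estimator, features, test_rows)
        accs.append(acc)
        records.append(
            FoldRecord(
                fold=i,
                selection_rows=train_rows.tolist(),
                tuning_rows=train_rows.tolist(),
                fit_rows=train_rows.tolist(),
                evaluation_rows=test_rows.tolist(),
                features=list(features),
                params=tuned.params,
                accuracy=acc,
            )
        )
    return ValidationResult(
        scheme="nested",
        fold_accuracies=accs,
        accuracy=float(np.mean(accs)),
        folds=records,
        meta={"n_folds": n_folds, "seed": seed},
    )


def partial_nested_fs_out(
    dataset: Dataset, spec: PipelineSpec, n_folds: int = 10, seed: int = 0
) -> ValidationResult:
    """Feature selection non-nested (once, on all rows); tuning nested."""
    n = dataset.n_samples
    all_rows = np.arange(n)
    features = _select_features(dataset, all_rows, spec, derive_seed(seed, "selection", 0))
    folds = _outer_folds(dataset, n_folds, seed)
    records, accs = [], []
    for i, test_rows in enumerate(folds):
        train_rows = _train_rows(n, test_rows)
        tuned = _tune(dataset, train_rows, features, spec, derive_seed(seed, "tuning", i))
        acc = _score(dataset, tuned.estimator, features, test_rows)
        accs.append(acc)
        records.append(
            FoldRecord(
                fold=i,
                selection_rows=all_rows.tolist(),
                tuning_rows=train_rows.tolist(),
                fit_rows=train_rows.tolist(),
                evaluation_rows=test_rows.tolist(),
                features=list(features),
                params=tuned.params,
                accuracy=acc,
            )
        )
    return ValidationResult(
        scheme="fs_out",
        fold_accuracies=accs,
        accuracy=float(np.mean(accs)),
        folds=records,
        meta={"n_folds": n_folds, "seed": seed},
    )


def partial_nested_tune_out(
    dataset: Dataset, spec: PipelineSpec, n_folds: int = 10, seed: int = 0
) -> ValidationResult:
    """Tuning non-nested (once, on all rows); feature selection nested.

    The global tuning step needs a feature space; by default it uses features
    selected on all rows (that selection feeds tuning only), configurable to
    the full feature set via ``spec.tune_out_feature_space``.
    """
    n = dataset.n_samples
    all_rows = np.arange(n)
    if spec.tune_out_feature_space == "selected":
        tuning_features = _select_features(
            dataset, all_rows, spec, derive_seed(seed, "tune-out-selection", 0)
        )
    else:
        tuning_features = list(range(dataset.n_features))
    tuned = _tune(dataset, all_rows, tuning_features, spec, derive_seed(seed, "tuning", 0))

    folds = _outer_folds(dataset, n_folds, seed)
    records, accs = [], []
    for i, test_rows in enumerate(folds):
        train_rows = _train_rows(n, test_rows)
        features = _select_features(
            dataset, train_rows, spec, derive_seed(seed, "selection", i)
        )
        est = mt.fit_classifier(
            spec.classifier_kind,
            tuned.params,
            dataset.features[np.ix_(train_rows, features)],
            dataset.labels[train_rows],
        )
        acc = _score(dataset, est, features, test_rows)
        accs.append(acc)
        records.append(
            FoldRecord(
                fold=i,
                selection_rows=train_rows.tolist(),
                tuning_rows=all_rows.tolist(),
                fit_rows=train_rows.tolist(),
                evaluation_rows=test_rows.tolist(),
                features=list(features),
                params=tuned.params,
                accuracy=acc,
            )
        )
    return ValidationResult(
        scheme="tune_out",
        fold_accuracies=accs,
        accuracy=float(np.mean(accs)),
        folds=records,
        meta={"n_folds": n_folds, "seed": seed},
    )


SCHEMES = {
    "split": train_test_split_validate,
    "kfold": kfold_validate,
    "nested": nested_cv_validate,
    "fs_out": partial_nested_fs_out,
    "tune_out": partial_nested_tune_out,
}


def validate(
    scheme: str,
    dataset: Dataset,
    spec: PipelineSpec,
    seed: int = 0,
    n_folds: int = 10,
    test_fraction: float = 0.2,
) -> ValidationResult:
    """Dispatch a scheme by name (CLI/config enum)."""
    if scheme not in SCHEMES:
        raise InvalidArgumentError(
            f"unknown scheme {scheme!r}; expected one of {sorted(SCHEMES)}"
        )
    if scheme == "split":
        return train_test_split_validate(dataset, spec, test_fraction, seed)
    return SCHEMES[scheme](dataset, spec, n_folds, seed)
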