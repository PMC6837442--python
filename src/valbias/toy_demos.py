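"""Two small illustrations of where validation bias comes from.

* :func:`toy_boundary` — a 10-sample, 2-feature noise problem where an
  RBF-SVM tuned and fitted on the pooled data (including the 2 validation
  points) scores far above chance on those points, while the identically
  configured model that never saw them scores at chance.
* :func:`toy_selection` — top-k t-test feature selection on 50 noise samples:
  selecting on pooled data makes the held-out 20% look discriminative too,
  and the effect grows with the size of the feature pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from . import model_tuning as mt
from .exceptions import InvalidArgumentError
from .feature_selection import compute_t_statistics, ttest_select
from .seeding import derive_rng, derive_seed
from .synthetic_data import Dataset, generate_noise

__all__ = [
    "ToyBoundaryResult",
    "ToySelectionResult",
    "toy_boundary",
    "toy_selection",
    "render_boundary",
]


@dataclass
class ToyBoundaryResult:
    """Per-repeat and aggregate accuracies (%) of the pooled vs held-out toy
    models.  Each repeat is scored on 2 validation points, so per-repeat
    validation accuracies are in {0, 50, 100}."""

    per_repeat: pd.DataFrame  # pooled_val, heldout_val, pooled_train, heldout_train
    pooled_validation_mean: float
    heldout_validation_mean: float
    pooled_training_mean: float
    heldout_training_mean: float
    train_rows: list[int]
    validation_rows: list[int]
    meta: dict[str, Any] = field(default_factory=dict)


@dataclass
class ToySelectionResult:
    """Mean |t| of the k selected features, per feature-pool size, computed on
    the training and on the validation portion, for both selection regimes."""

    table: pd.DataFrame  # pool_size, pooled_train, pooled_val, split_train, split_val
    meta: dict[str, Any] = field(default_factory=dict)


def _toy_dataset(rng: np.random.Generator) -> Dataset:
    """10 standard-normal samples, 2 features, labels 5/5 class-blocked."""
    features = rng.standard_normal((10, 2))
    labels = np.repeat([0, 1], 5)
    return Dataset(features=features, labels=labels, meta={"generator": "toy"})


def toy_boundary(
    reps: int = 1000,
    seed: int = 0,
    fixed_params: dict[str, Any] | None = None,
) -> ToyBoundaryResult:
    """Run the pooled vs held-out boundary experiment ``reps`` times.

    Per repeat: draw 10 N(0,1) samples with 2 features (5 per class); the
    last row of each class is the validation pair.  Model A is grid-tuned
    (default RBF-SVM grid, inner folds degrading to leave-one-out) and fitted
    on all 10 rows; model B identically on the 8 training rows.  Both are
    scored on the 2 validation rows and on their own training rows.
    ``fixed_params`` skips tuning and fits both models with the given
    ``{"C": ..., "gamma": ...}``.
    """
    if reps < 1:
        raise InvalidArgumentError(f"reps must be >= 1, got {reps}")
    grid = mt.default_grid("rbf-svm")
    all_rows = np.arange(10)
    val_rows = np.array([4, 9])  # last row of each class-block
    train_rows = np.setdiff1d(all_rows, val_rows)
    features = np.array([0, 1])

    records = []
    for rep in range(reps):
        ds = _toy_dataset(derive_rng(seed, "toy-boundary", rep))
        models = {}
        for name, rows in (("pooled", all_rows), ("heldout", train_rows)):
            if fixed_params is not None:
                est = mt.fit_classifier(
                    "rbf-svm",
                    fixed_params,
                    ds.features[np.ix_(rows, features)],
                    ds.labels[rows],
                )
            else:
                est = mt.grid_search(
                    ds,
                    rows,
                    features,
                    grid,
                    inner_folds=10,
                    seed=derive_seed(seed, "toy-tuning", rep, name),
                    strict_folds=False,
                ).estimator
            models[name] = (est, rows)

        def acc(name: str, rows: np.ndarray) -> float:
            est = models[name][0]
            x = ds.features[np.ix_(rows, features)]
            return 100.0 * float(np.mean(est.predict(x) == ds.labels[rows]))

        records.append(
            {
                "rep": rep,
                "pooled_val": acc("pooled", val_rows),
                "heldout_val": acc("heldout", val_rows),
                "pooled_train": acc("pooled", all_rows),
                "heldout_train": acc("heldout", train_rows),
            }
        )

    per_repeat = pd.DataFrame(records)
    return ToyBoundaryResult(
        per_repeat=per_repeat,
        pooled_validation_mean=float(per_repeat["pooled_val"].mean()),
        heldout_validation_mean=float(per_repeat["heldout_val"].mean()),
        pooled_training_mean=float(per_repeat["pooled_train"].mean()),
        heldout_training_mean=float(per_repeat["heldout_train"].mean()),
        train_rows=train_rows.tolist(),
        validation_rows=val_rows.tolist(),
        meta={"reps": reps, "seed": seed, "fixed_params": fixed_params},
    )


def toy_selection(
    pool_sizes: Sequence[int] = tuple(range(20, 101, 10)),
    reps: int = 100,
    n_samples: int = 50,
    k: int = 10,
    val_fraction: float = 0.2,
    seed: int = 0,
) -> ToySelectionResult:
    """Mean |t| of the selected features under pooled vs split selection.

    Per repeat and pool size ``p``: draw ``n_samples`` noise rows with ``p``
    features; hold out ``val_fraction`` stratified; regime "pooled" selects
    the top-``k`` |t| features on all rows, regime "split" on the training
    rows only; mean |t| of each regime's selection is then measured separately
    on the training rows and on the validation rows.
    """
    pool_sizes = tuple(int(p) for p in pool_sizes)
    if k > min(pool_sizes):
        raise InvalidArgumentError(
            f"k={k} exceeds the smallest feature pool ({min(pool_sizes)})"
        )
    per_class_val = int(round(val_fraction * n_samples / 2))
    if per_class_val < 2:
        raise InvalidArgumentError(
            "validation portion must keep >= 2 samples per class for the "
            "t statistic"
        )

    rows_out = []
    for p in pool_sizes:
        sums = {"pooled_train": 0.0, "pooled_val": 0.0, "split_train": 0.0, "split_val": 0.0}
        for rep in range(reps):
            ds = generate_noise(n_samples, p, derive_seed(seed, "toy-selection", p, rep))
            rng = derive_rng(seed, "toy-selection-split", p, rep)
            val_parts = [
                rng.permutation(np.flatnonzero(ds.labels == cls))[:per_class_val]
                for cls in (0, 1)
            ]
            val_rows = np.sort(np.concatenate(val_parts))
            train_rows = np.setdiff1d(np.arange(n_samples), val_rows)

            abs_t_train = np.abs(compute_t_statistics(ds, train_rows))
            abs_t_val = np.abs(compute_t_statistics(ds, val_rows))

            sel_pooled = ttest_select(ds, np.arange(n_samples), k=k).selected
            sel_split = ttest_select(ds, train_rows, k=k).selected

            sums["pooled_train"] += float(abs_t_train[sel_pooled].mean())
            sums["pooled_val"] += float(abs_t_val[sel_pooled].mean())
            sums["split_train"] += float(abs_t_train[sel_split].mean())
            sums["split_val"] += float(abs_t_val[sel_split].mean())
        rows_out.append(
            {"pool_size": p, **{key: val / reps for key, val in sums.items()}}
        )

    return ToySelectionResult(
        table=pd.DataFrame(rows_out),
        meta={
            "pool_sizes": list(pool_sizes),
            "reps": reps,
            "n_samples": n_samples,
            "k": k,
            "val_fraction": val_fraction,
            "seed": seed,
        },
    )


def render_boundary(
    dataset: Dataset,
    estimators: dict[str, Any],
    feature_pair: tuple[int, int] = (0, 1),
    grid_points: int = 100,
    padding: float = 1.0,
) -> dict[str, np.ndarray]:
    """Evaluate fitted 2-D models over a mesh covering the data range.

    Returns ``{"x": 1-D grid, "y": 1-D grid, <name>: (grid, grid) labels}``
    suitable for ``matplotlib.pyplot.pcolormesh``.
    """
    fx, fy = feature_pair
    x = dataset.features[:, fx]
    y = dataset.features[:, fy]
    gx = np.linspace(x.min() - padding, x.max() + padding, grid_points)
    gy = np.linspace(y.min() - padding, y.max() + padding, grid_points)
    xx, yy = np.meshgrid(gx, gy)
    mesh = np.column_stack([xx.ravel(), yy.ravel()])
    out: dict[str, np.ndarray] = {"x": gx, "y": gy}
    for name, est in estimators.items():
        out[name] = mt.predict_labels(est, mesh).reshape(xx.shape)
    return out
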