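"""Synthetic dataset generators.

Two families are provided:

* :func:`generate_noise` — i.i.d. standard-normal features with balanced
  binary labels carrying no relationship to the features, so the expected
  accuracy of any classifier is the 50% chance level.
* :func:`generate_discriminable` — same layout but a chosen number of
  "informative" columns receive a class-conditional mean shift (class coded
  ``1`` carries the shift), making the classes separable in expectation.

Both generators lay samples out class-blocked, then shuffle rows with the
seeded generator, so downstream fold construction can never silently rely on
input order.  The ``meta`` dict stored on each :class:`Dataset` suffices to
regenerate the identical matrix bit-for-bit (see :func:`regenerate`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .exceptions import InvalidArgumentError

__all__ = [
    "Dataset",
    "GeneratorConfig",
    "generate_noise",
    "generate_discriminable",
    "generate",
    "regenerate",
    "dataset_to_csv",
    "dataset_from_csv",
]


@dataclass
class Dataset:
    """A feature matrix with balanced binary labels and generator provenance.

    Attributes
    ----------
    features : (N, p) float array, finite, no missing values.
    labels : (N,) int array of 0/1 with exactly N/2 samples per class.
    meta : generator name, parameters and seed; sufficient to regenerate.
    """

    features: np.ndarray
    labels: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def validate(self) -> None:
        if self.features.ndim != 2:
            raise InvalidArgumentError("features must be a 2-D matrix")
        if self.labels.shape != (self.features.shape[0],):
            raise InvalidArgumentError("labels must align with feature rows")
        if not np.all(np.isfinite(self.features)):
            raise InvalidArgumentError("features must be finite with no missing values")
        counts = np.bincount(self.labels, minlength=2)
        if counts[0] != counts[1]:
            raise InvalidArgumentError(
                f"classes must be balanced, got counts {counts.tolist()}"
            )


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of one synthetic dataset draw."""

    n_samples: int
    n_features: int
    n_informative: int = 0
    mean_shift: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 4:
            raise InvalidArgumentError(
                f"n_samples must be >= 4, got {self.n_samples}"
            )
        if self.n_samples % 2 != 0:
            raise InvalidArgumentError(
                f"n_samples must be even for balanced classes, got {self.n_samples}"
            )
        if self.n_features < 1:
            raise InvalidArgumentError(
                f"n_features must be >= 1, got {self.n_features}"
            )
        if not (0 <= self.n_informative <= self.n_features):
            raise InvalidArgumentError(
                "n_informative must satisfy 0 <= n_informative <= n_features, "
                f"got {self.n_informative} with n_features={self.n_features}"
            )


def generate(config: GeneratorConfig) -> Dataset:
    """Draw one dataset from a :class:`GeneratorConfig`.

    Rows are generated class-blocked (class 0 first, then class 1), the mean
    shift is added to the first ``n_informative`` columns of the class-1
    block, and finally rows are shuffled by the seeded generator.  The draw
    order is fixed (matrix, then permutation) so regeneration is exact.
    """
    rng = np.random.default_rng(config.seed)
    n, p = config.n_samples, config.n_features
    half = n // 2

    features = rng.standard_normal((n, p))
    labels = np.repeat([0, 1], half)
    if config.n_informative > 0 and config.mean_shift != 0.0:
        features[half:, : config.n_informative] += config.mean_shift

    order = rng.permutation(n)
    features = features[order]
    labels = labels[order]

    meta = {
        "generator": "discriminable" if config.n_informative > 0 else "noise",
        "n_samples": n,
        "n_features": p,
        "n_informative": config.n_informative,
        "mean_shift": config.mean_shift,
        "seed": config.seed,
        "informative_indices": list(range(config.n_informative)),
    }
    return Dataset(features=features, labels=labels, meta=meta)


def generate_noise(n_samples: int, n_features: int, seed: int) -> Dataset:
    """Pure-noise dataset: i.i.d. N(0, 1) features, balanced 0/1 labels."""
    return generate(
        GeneratorConfig(n_samples=n_samples, n_features=n_features, seed=seed)
    )


def generate_discriminable(
    n_samples: int,
    seed: int,
    n_features: int = 50,
    n_informative: int = 10,
    mean_shift: float = 0.5,
) -> Dataset:
    """Discriminable dataset: ``n_informative`` columns get mean ``mean_shift``
    in class 1 and mean 0 in class 2 (label 0); the rest are pure noise."""
    return generate(
        GeneratorConfig(
            n_samples=n_samples,
            n_features=n_features,
            n_informative=n_informative,
            mean_shift=mean_shift,
            seed=seed,
        )
    )


def regenerate(meta: dict[str, Any]) -> Dataset:
    """Rebuild the identical dataset from a ``Dataset.meta`` record."""
    return generate(
        GeneratorConfig(
            n_samples=meta["n_samples"],
            n_features=meta["n_features"],
            n_informative=meta.get("n_informative", 0),
            mean_shift=meta.get("mean_shift", 0.0),
            seed=meta["seed"],
        )
    )


def dataset_to_csv(dataset: Dataset, path: str | Path) -> None:
    """Write a dataset as CSV with header ``f1..fp,label``."""
    p = dataset.n_features
    df = pd.DataFrame(dataset.features, columns=[f"f{i + 1}" for i in range(p)])
    df["label"] = dataset.labels
    df.to_csv(path, index=False)


def dataset_from_csv(path: str | Path) -> Dataset:
    """Read a dataset written by :func:`dataset_to_csv`."""
    df = pd.read_csv(path)
    if "label" not in df.columns:
        raise InvalidArgumentError("CSV must contain a 'label' column")
    labels = df.pop("label").to_numpy(dtype=int)
    return Dataset(
        features=df.to_numpy(dtype=float),
        labels=labels,
        meta={"generator": "csv", "source": str(path)},
    )
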