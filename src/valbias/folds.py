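"""Stratified fold assignment used by tuning and the validation schemes.

Rows of each class are shuffled by the seeded generator and dealt round-robin
into folds with a single global counter, so total fold sizes differ by at
most one and classes stay as balanced as the counts allow.
"""

from __future__ import annotations

import numpy as np

from .exceptions import InvalidArgumentError

__all__ = ["stratified_folds"]


def stratified_folds(
    labels: np.ndarray,
    rows: np.ndarray,
    n_folds: int,
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Partition ``rows`` into ``n_folds`` stratified folds.

    Returns a list of row-index arrays (disjoint, union = ``rows``).
    Fold sizes differ by at most one.  When ``n_folds`` exceeds the
    per-class count some folds are single-class; callers that require
    two-class folds must validate beforehand.
    """
    rows = np.asarray(rows)
    if n_folds < 2:
        raise InvalidArgumentError(f"n_folds must be >= 2, got {n_folds}")
    if n_folds > rows.size:
        raise InvalidArgumentError(
            f"n_folds={n_folds} exceeds the number of rows ({rows.size})"
        )
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    counter = 0
    for cls in np.unique(labels[rows]):
        cls_rows = rows[labels[rows] == cls]
        cls_rows = rng.permutation(cls_rows)
        for r in cls_rows:
            folds[counter % n_folds].append(int(r))
            counter += 1
    return [np.array(sorted(f), dtype=int) for f in folds]
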