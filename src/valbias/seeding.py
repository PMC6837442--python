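"""Deterministic seed derivation.

Every stochastic operation in the package receives an integer seed and, when
it needs several independent random streams, derives child seeds with
:func:`derive_seed`.  The scheme is a documented counter scheme built on
:class:`numpy.random.SeedSequence`:

    SeedSequence(entropy=master_seed, spawn_key=(k1, k2, ...))

where each ``k`` is either an integer (run index, fold index, sample size
point, ...) or a short string label (stage name) mapped to an integer via
CRC-32.  Because the spawn key is an explicit function of the *logical*
position of the consumer (not of execution order), results are reproducible
regardless of the order in which sub-computations run.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed", "derive_rng"]


def _key_to_int(key: int | str) -> int:
    if isinstance(key, str):
        return zlib.crc32(key.encode("utf-8"))
    return int(key) & 0xFFFFFFFF


def derive_seed(master_seed: int, *path: int | str) -> int:
    """Derive a child seed from ``master_seed`` and a logical path.

    The same ``(master_seed, path)`` pair always yields the same child seed;
    distinct paths yield (with overwhelming probability) distinct streams.
    """
    ss = np.random.SeedSequence(
        entropy=int(master_seed) & 0xFFFFFFFFFFFFFFFF,
        spawn_key=tuple(_key_to_int(k) for k in path),
    )
    return int(ss.generate_state(1, dtype=np.uint64)[0] & 0x7FFFFFFF)


def derive_rng(master_seed: int, *path: int | str) -> np.random.Generator:
    """Return a :class:`numpy.random.Generator` seeded by :func:`derive_seed`."""
    return np.random.default_rng(derive_seed(master_seed, *path))
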