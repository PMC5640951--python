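"""Deterministic seed derivation for reproducible, parallelizable experiments.

A single master seed plus a tuple of context keys (dataset id, method, size,
replicate index, ...) identifies every random stream in the package, so results
are invariant to execution order and safe to parallelize.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_rng", "derive_seed"]


def _key_to_int(key: object) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(str(key).encode("utf-8"))


def derive_seed(master_seed: int, *keys: object) -> np.random.SeedSequence:
    """Derive a child SeedSequence from a master seed and context keys."""
    return np.random.SeedSequence([int(master_seed)] + [_key_to_int(k) for k in keys])


def derive_rng(master_seed: int, *keys: object) -> np.random.Generator:
    """Deterministic Generator for a (master seed, context) pair."""
    return np.random.default_rng(derive_seed(master_seed, *keys))
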