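"""Seed fan-out.

A single user-facing seed is expanded into independent per-stage seeds via a
stable CRC32 hash of the stage name, so any stage can be re-run in isolation
from the run manifest. Derived seeds stay below 2**31.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed", "rng_for"]


def derive_seed(seed: int, *keys: str | int) -> int:
    """Derive a deterministic sub-seed from ``seed`` and a sequence of keys."""
    h = zlib.crc32(repr(int(seed)).encode())
    for k in keys:
        h = zlib.crc32(repr(k).encode(), h)
    return int(h % (2**31 - 1))


def rng_for(seed: int, *keys: str | int) -> np.random.Generator:
    """A Generator seeded from :func:`derive_seed`."""
    return np.random.default_rng(derive_seed(seed, *keys))
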