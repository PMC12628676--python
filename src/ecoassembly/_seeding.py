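"""Deterministic, order-independent random substreams.

Every stochastic routine in the package takes one integer master seed and
derives a private stream from it plus a tuple of string tags (stage name,
sample id, ...).  Tags are hashed with CRC32 so the derived entropy does not
depend on Python's per-process string hashing, and streams for the same tags
are identical regardless of evaluation order — which keeps pairwise analyses
symmetric and makes parallel execution reproducible.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(master_seed: int, *tags: object) -> np.random.Generator:
    """Return a :class:`numpy.random.Generator` keyed by ``(master_seed, *tags)``."""
    entropy = [int(master_seed) & 0x7FFFFFFF]
    for tag in tags:
        entropy.append(zlib.crc32(str(tag).encode("utf-8")))
    return np.random.default_rng(np.random.SeedSequence(entropy))
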