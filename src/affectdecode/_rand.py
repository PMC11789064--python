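"""Deterministic stream-splitting for all randomness in the package.

Every stochastic routine derives its generator from a single integer seed
plus a tuple of string/int tags naming the consumer (e.g. the model and
layer a projection matrix belongs to).  Tags are hashed with CRC32, which is
stable across platforms and Python versions, so the same (seed, tags) pair
always yields the same stream and distinct tags yield independent streams.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed"]


def _tag_to_int(tag: object) -> int:
    if isinstance(tag, (int, np.integer)):
        return int(tag) & 0xFFFFFFFF
    return zlib.crc32(str(tag).encode("utf-8"))


def child_seed(seed: int, *tags: object) -> np.random.SeedSequence:
    """A SeedSequence for the stream identified by ``(seed, *tags)``."""
    entropy = [int(seed) & 0xFFFFFFFF] + [_tag_to_int(t) for t in tags]
    return np.random.SeedSequence(entropy)


def child_rng(seed: int, *tags: object) -> np.random.Generator:
    """A Generator for the stream identified by ``(seed, *tags)``."""
    return np.random.default_rng(child_seed(seed, *tags))
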