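"""Seed plumbing: every stage derives its generator from one integer seed."""

from __future__ import annotations

import zlib

import numpy as np


def spawn(seed: int, *tags: object) -> np.random.Generator:
    """A named child generator, reproducible across sessions.

    The same (seed, tags) always yields the same stream; different tags
    yield independent streams.
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    for tag in tags:
        entropy.append(zlib.crc32(str(tag).encode()))
    return np.random.default_rng(np.random.SeedSequence(entropy))


def child_seed(seed: int, *tags: object) -> int:
    """A derived integer seed below 2**31 for nested stages."""
    return int(spawn(seed, *tags).integers(0, 2**31 - 1))
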