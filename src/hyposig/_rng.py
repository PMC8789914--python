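"""Seed-derivation contract for every stochastic component.

Each generated artifact draws from its own stream, keyed by a stable string,
so adding a new generator never perturbs the output of an existing one.
The child seed is ``SeedSequence([master_seed, crc32(key)])``; crc32 is
stable across platforms and Python versions, unlike ``hash``.
"""

from __future__ import annotations

import zlib

import numpy as np


def child_rng(master_seed: int, key: str) -> np.random.Generator:
    """Return the RNG stream for artifact ``key`` under ``master_seed``."""
    if master_seed < 0:
        raise ValueError("master seed must be non-negative")
    entropy = [int(master_seed), zlib.crc32(key.encode("utf-8"))]
    return np.random.default_rng(np.random.SeedSequence(entropy))
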