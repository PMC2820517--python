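"""Deterministic seed derivation.

Every stochastic stage of a pipeline draws its seed from a single master
seed plus a short stage name, so that re-running any stage in isolation
reproduces the run exactly.
"""

from __future__ import annotations

import zlib

import numpy as np

_MOD = 2**31 - 1


def substream_seed(master_seed: int, name: str, index: int = 0) -> int:
    """Derive a stable child seed for a named substream.

    The derivation hashes ``(master_seed, crc32(name), index)`` through a
    ``SeedSequence`` and folds the result below 2**31 so the seed is safe
    for any integer-seeded RNG.
    """
    tag = zlib.crc32(name.encode("utf-8"))
    ss = np.random.SeedSequence([int(master_seed) & _MOD, tag, int(index)])
    return int(ss.generate_state(1)[0]) % _MOD


def rng_for(master_seed: int, name: str, index: int = 0) -> np.random.Generator:
    """A ``numpy`` Generator on the named substream."""
    return np.random.default_rng(substream_seed(master_seed, name, index))
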