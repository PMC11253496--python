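"""Deterministic seed derivation.

Every random stage of the pipeline draws its seed from the master seed plus a
tuple of tokens naming the stage and the axis values it depends on. Two
consequences:

* adding or removing a strategy never changes the randomness seen by the
  remaining strategies, and
* two strategies that share a preprocessing path receive bitwise-identical
  preprocessing, so caching shared stages cannot change any p-value.
"""

from __future__ import annotations

from zlib import crc32

import numpy as np


def seed_sequence(master: int, *tokens: object) -> np.random.SeedSequence:
    """A SeedSequence keyed by the master seed and a stable token tuple."""
    key = tuple(crc32(repr(t).encode("utf8")) for t in tokens)
    return np.random.SeedSequence(entropy=int(master), spawn_key=key)


def rng_for(master: int, *tokens: object) -> np.random.Generator:
    return np.random.default_rng(seed_sequence(master, *tokens))


def int_seed(master: int, *tokens: object) -> int:
    """A 31-bit integer seed for libraries that take plain ints."""
    return int(seed_sequence(master, *tokens).generate_state(1)[0] % (2**31))
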