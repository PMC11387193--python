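"""Seeded random-number substreams.

All randomness in the package flows from a single integer seed; each
stage derives an independent, named substream so that re-running one
stage in isolation reproduces its output bit for bit.
"""

from __future__ import annotations

import zlib

import numpy as np


def rng_for(seed: int, stage: str) -> np.random.Generator:
    """Return a Generator for a named substream of ``seed``.

    The stage name is hashed with CRC-32 so the mapping is stable across
    sessions and platforms.
    """
    tag = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed) % 2**31, spawn_key=(tag,)))
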