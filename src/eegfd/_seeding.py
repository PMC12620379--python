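"""Named-substream seeding.

A single user seed fans out to per-stage / per-subject streams keyed by
name, so adding a stage or subject never perturbs the draws of another.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, *names: str | int) -> np.random.Generator:
    """A Generator for the substream identified by ``names`` under ``seed``."""
    key = [zlib.crc32(str(n).encode()) for n in names]
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=key))


def substream_int(seed: int, *names: str | int) -> int:
    """A derived 31-bit integer seed for libraries that take plain ints."""
    return int(substream(seed, *names).integers(0, 2**31 - 1))
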