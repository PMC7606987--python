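"""Stable sub-seed derivation.

One master seed drives a whole simulated study; independent streams for
each (subject, stage) pair are derived by hashing the stage name, so adding
a stage or reordering subjects never perturbs the other streams.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(master_seed: int, *keys: str | int) -> np.random.Generator:
    """Return a Generator for the stream identified by ``keys``.

    The derivation is stable across sessions and platforms: string keys are
    CRC32-hashed, integer keys are used as-is, and all entropy is combined
    through :class:`numpy.random.SeedSequence`.
    """
    entropy: list[int] = [int(master_seed)]
    for k in keys:
        if isinstance(k, (int, np.integer)):
            entropy.append(int(k))
        else:
            entropy.append(zlib.crc32(str(k).encode("utf-8")))
    return np.random.default_rng(np.random.SeedSequence(entropy))
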