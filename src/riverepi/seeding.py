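"""Named random substreams.

Every randomised procedure (simulation, AMOVA, Mantel, MRM) draws from an
independent substream derived from one master seed and a stream name, so
toggling one analysis never perturbs another's permutation p-values.
"""

from __future__ import annotations

import zlib

import numpy as np


def named_rng(seed: int | None, name: str) -> np.random.Generator:
    """Generator for the substream ``name`` of master ``seed``."""
    if seed is None:
        return np.random.default_rng()
    entropy = [int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode("utf-8"))]
    return np.random.default_rng(np.random.SeedSequence(entropy))
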