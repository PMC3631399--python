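"""Named random substreams.

All stochastic stages derive an independent generator from one master seed
and a stage name, so any stage can be re-run in isolation and the full
pipeline is byte-reproducible for a given (config, seed).
"""

from __future__ import annotations

import zlib

import numpy as np


def substream_seed(master_seed: int, name: str) -> np.random.SeedSequence:
    tag = zlib.crc32(name.encode("utf8")) & 0x7FFFFFFF
    return np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, tag])


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Generator for the substream ``name`` of ``master_seed``."""
    return np.random.default_rng(substream_seed(master_seed, name))
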