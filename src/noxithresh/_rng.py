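"""Deterministic RNG substreams.

One global integer seed expands into independent per-participant, per-block
streams via ``numpy.random.SeedSequence`` spawn keys, so adding a participant
or block never perturbs the draws of any other.  The splitting rule is
``SeedSequence(entropy=seed, spawn_key=(hash(stream), participant, block))``.
"""

from __future__ import annotations

import zlib

import numpy as np


def _stream_key(stream: str) -> int:
    return zlib.crc32(stream.encode())


def block_rng(
    seed: int, participant: int, block: int, stream: str = "block"
) -> np.random.Generator:
    """Independent generator for one (participant, block) pair."""
    ss = np.random.SeedSequence(
        entropy=seed, spawn_key=(_stream_key(stream), participant, block)
    )
    return np.random.default_rng(ss)


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent generator for a named top-level stream."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(_stream_key(stream),))
    return np.random.default_rng(ss)
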