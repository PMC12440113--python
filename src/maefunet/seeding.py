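"""Deterministic seeding: one global seed fans out to named substreams."""
from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Generator for a named purpose ('masking', 'init', ...), decoupled from
    every other substream of the same global seed."""
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence((int(seed), key)))
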