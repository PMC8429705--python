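"""Small shared helpers: rounding, seeding, reverse complement."""

from __future__ import annotations

import math
import zlib

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def round_half_away(x: float) -> int:
    """Round to the nearest integer, ties away from zero.

    Python's built-in ``round`` uses banker's rounding; printed integer
    tables in the genomics literature follow the away-from-zero convention,
    so summary statistics here do too.
    """
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def substream_rng(seed: int, name: str) -> np.random.Generator:
    """Named substream of a single global seed.

    Each operation draws from its own stream (seed, crc32(name)) so pipeline
    stages can be re-run independently without perturbing one another.
    """
    return np.random.default_rng([int(seed), zlib.crc32(name.encode())])
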