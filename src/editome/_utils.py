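"""Small shared helpers: base arithmetic, rounding, seeded substreams."""
from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP
from hashlib import blake2b
import math

import numpy as np

BASES = ("A", "C", "G", "T")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero, as summary tables conventionally do."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """100 * numerator / denominator rounded half-up; NaN on empty denominator."""
    if denominator == 0:
        return math.nan
    return round_half_up(100.0 * numerator / denominator, ndigits)


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator derived from a master seed and a stream name.

    Every source of randomness in the package goes through a named
    substream so that stages are reproducible in isolation.
    """
    digest = blake2b(name.encode(), digest_size=8).digest()
    return np.random.default_rng([int.from_bytes(digest, "big"), int(seed)])
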