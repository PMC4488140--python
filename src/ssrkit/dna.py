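"""Small DNA sequence helpers shared across the pipeline."""

from __future__ import annotations

import math

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_BASES = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """Fraction of G+C among non-N bases (0.0 for all-N/empty input)."""
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / acgt


def is_primitive(motif: str) -> bool:
    """True if the motif is not a whole-number repetition of a shorter unit."""
    n = len(motif)
    for d in range(1, n):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return False
    return True


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (28.5 -> 29)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def truncate2(x: float) -> float:
    """Truncate (not round) to two decimals: 4.3086 -> 4.30."""
    return math.floor(x * 100) / 100
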