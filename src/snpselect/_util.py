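"""Small shared helpers: DNA string ops and table/percent formatting."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_dna(seq: str) -> bool:
    """True if *seq* is non-empty uppercase A/C/G/T."""
    return bool(seq) and set(seq) <= DNA_ALPHABET


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def percent(fraction: float, decimals: int = 1) -> float:
    """Format a fraction as a percentage rounded half-up.

    Reports use one decimal place with round-half-up (so 0.8103 -> 81.0,
    0.9757 -> 97.6), matching common table conventions.
    """
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(fraction * 100).quantize(q, rounding=ROUND_HALF_UP))


def derive_seed(seed: int, stream: int) -> int:
    """Derive a per-component seed below 2**31 from a master seed."""
    return (seed * 1_000_003 + stream * 7919 + 17) % (2**31 - 1)
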