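"""Small shared helpers: alphabet conversion and significant-figure rounding."""

from __future__ import annotations

import math
from decimal import ROUND_HALF_UP, Decimal

_COMPLEMENT_RNA = str.maketrans("ACGU", "UGCA")

RNA_BASES = "ACGU"
SENSE_CODONS: tuple[str, ...] = tuple(
    a + b + c
    for a in RNA_BASES
    for b in RNA_BASES
    for c in RNA_BASES
    if a + b + c not in ("UAA", "UAG", "UGA")
)

STOP_CODONS = frozenset({"UAA", "UAG", "UGA"})


def to_rna(seq: str) -> str:
    """Uppercase and convert a DNA/RNA string to the RNA alphabet (T -> U)."""
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    """Uppercase and convert a DNA/RNA string to the DNA alphabet (U -> T)."""
    return seq.upper().replace("U", "T")


def revcomp_rna(seq: str) -> str:
    return to_rna(seq).translate(_COMPLEMENT_RNA)[::-1]


def _round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def round_sig(x: float, sig: int = 3) -> float:
    """Round to `sig` significant figures, halves away from zero (the
    convention of the printed reference tables, e.g. 396.5 -> 397)."""
    if x == 0 or not math.isfinite(x):
        return x
    ndigits = -int(math.floor(math.log10(abs(x)))) + (sig - 1)
    return _round_half_up(x, ndigits)


def render_tau(x: float) -> float:
    """Display convention for inverse-proportion translation times.

    Values below 100 are rounded to three significant figures; values of 100 or
    more to the nearest integer. The integer rule is what keeps four-digit sums
    of integers (e.g. a mean of 1100 and 1170) at unit precision instead of
    collapsing them to tens.
    """
    if not math.isfinite(x):
        return x
    if abs(x) >= 100:
        return _round_half_up(x, 0)
    return round_sig(x, 3)
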