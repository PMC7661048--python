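"""Codon counting and usage fractions from annotated CDS collections."""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Data.CodonTable import standard_rna_table

from .utils import STOP_CODONS, to_rna

log = logging.getLogger(__name__)

# amino-acid family of each sense codon under the standard code
CODON_TO_AA: dict[str, str] = dict(standard_rna_table.forward_table)


@dataclass
class CodonUsageTable:
    """Per-codon counts plus within-family and global fractions.

    Stop codons never enter the fractions. Family fractions sum to 1 within
    each amino-acid family that has nonzero counts; global fractions sum to 1.
    """

    counts: dict[str, int]

    @property
    def total(self) -> int:
        return sum(n for c, n in self.counts.items() if c not in STOP_CODONS)

    @property
    def family_fraction(self) -> dict[str, float]:
        fam_tot: Counter = Counter()
        for codon, n in self.counts.items():
            if codon in CODON_TO_AA:
                fam_tot[CODON_TO_AA[codon]] += n
        return {
            codon: n / fam_tot[CODON_TO_AA[codon]]
            for codon, n in self.counts.items()
            if codon in CODON_TO_AA and fam_tot[CODON_TO_AA[codon]] > 0
        }

    @property
    def global_fraction(self) -> dict[str, float]:
        tot = self.total
        return {
            codon: n / tot
            for codon, n in self.counts.items()
            if codon not in STOP_CODONS and tot > 0
        }

    def to_frame(self) -> pd.DataFrame:
        fam = self.family_fraction
        glob = self.global_fraction
        rows = [
            {
                "codon": c,
                "aa": CODON_TO_AA.get(c, "Stop"),
                "count": n,
                "family_fraction": fam.get(c),
                "global_fraction": glob.get(c),
            }
            for c, n in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows)


def count_codons(cds: str | Path | Iterable) -> CodonUsageTable:
    """Count codons over a CDS FASTA (or iterable of SeqRecords).

    Reading frame starts at position 1 of each record. Records whose length is
    not a multiple of 3 are skipped with a warning; codons containing
    ambiguous bases are skipped (counts are exact or absent).
    """
    if isinstance(cds, (str, Path)):
        records = list(SeqIO.parse(str(cds), "fasta"))
    else:
        records = list(cds)
    if not records:
        raise ValueError("empty CDS input")
    counts: Counter = Counter()
    for rec in records:
        seq = to_rna(str(rec.seq))
        if len(seq) % 3 != 0:
            log.warning("skipping %s: length %d not divisible by 3", rec.id, len(seq))
            continue
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            if set(codon) <= set("ACGU"):
                counts[codon] += 1
    return CodonUsageTable(counts=dict(counts))


def codon_ratio(table: CodonUsageTable, a: str, b: str) -> float:
    """count(a) / count(b); scale-invariant relative usage of two codons."""
    a, b = to_rna(a), to_rna(b)
    nb = table.counts.get(b, 0)
    if nb == 0:
        raise ZeroDivisionError(f"codon {b} has zero count")
    return table.counts.get(a, 0) / nb


def message_from_usage(table: CodonUsageTable, codons: Iterable[str]):
    """Codon weights proportional to counts, scaled so the minimum weight is 1.

    The result is the ``MessageSpec`` consumed by the translation model: an
    artificial message whose codon multiplicities reflect relative usage.
    """
    from .translation_model import MessageSpec

    codons = [to_rna(c) for c in codons]
    counts = {c: table.counts.get(c, 0) for c in codons}
    if any(n == 0 for n in counts.values()):
        missing = [c for c, n in counts.items() if n == 0]
        raise ValueError(f"codons absent from usage table: {missing}")
    m = min(counts.values())
    return MessageSpec(weights={c: n / m for c, n in counts.items()})
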