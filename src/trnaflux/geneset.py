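"""Data model and summaries for a genome's tRNA gene complement.

A *gene* is a chromosomal locus with its mature tRNA sequence; a *type* is the
anticodon-level identity (amino acid + anticodon) that one or more gene copies
encode. Initiator tRNA (fMet) and the lysidine-modified AUA decoder (Ile2) are
kept as amino-acid labels distinct from Met/Ile so their types never merge.
"""

from __future__ import annotations

import importlib.resources
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .utils import to_rna

REQUIRED_COLUMNS = [
    "locus_id",
    "amino_acid",
    "anticodon",
    "sequence",
    "start",
    "end",
    "strand",
    "canonical",
]


class GenesetSchemaError(ValueError):
    """Raised when a gene table is missing required columns."""


class GenesetValidationError(ValueError):
    """Raised when a gene row violates a field invariant."""


@dataclass(frozen=True)
class TRNAGene:
    """One tRNA gene locus.

    Coordinates are 1-based inclusive chromosome positions. ``anticodon`` and
    ``sequence`` are held in the RNA alphabet, anticodon written 5'->3'.
    """

    locus_id: str
    amino_acid: str
    anticodon: str
    sequence: str
    start: int
    end: int
    strand: str
    canonical: bool = True

    def __post_init__(self) -> None:
        if len(self.anticodon) != 3 or any(b not in "ACGU" for b in self.anticodon):
            raise GenesetValidationError(
                f"gene {self.locus_id!r}: anticodon {self.anticodon!r} is not a "
                "3-mer over A/C/G/U"
            )
        if self.start > self.end:
            raise GenesetValidationError(
                f"gene {self.locus_id!r}: start {self.start} > end {self.end}"
            )
        if self.canonical and self.anticodon not in self.sequence:
            raise GenesetValidationError(
                f"gene {self.locus_id!r}: canonical gene sequence does not "
                "contain its anticodon"
            )

    @property
    def type_id(self) -> str:
        return f"{self.amino_acid}-{self.anticodon}"


@dataclass
class TRNAType:
    """An anticodon-level tRNA type with its encoding gene copies."""

    amino_acid: str
    anticodon: str
    gene_ids: list[str] = field(default_factory=list)
    distinct_sequences: int = 0

    @property
    def type_id(self) -> str:
        return f"{self.amino_acid}-{self.anticodon}"

    @property
    def copy_number(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class GenesetSummary:
    n_genes: int
    n_types: int
    n_multicopy: int
    max_copy: int


def load_geneset(path: str | Path) -> list[TRNAGene]:
    """Read a TSV gene table into :class:`TRNAGene` records.

    The table must carry a header row with the columns in
    :data:`REQUIRED_COLUMNS`. Anticodons and sequences are normalized to the
    uppercase RNA alphabet.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise GenesetSchemaError(f"gene table {path} is missing columns: {missing}")
    genes: list[TRNAGene] = []
    for i, row in df.iterrows():
        try:
            genes.append(
                TRNAGene(
                    locus_id=str(row["locus_id"]),
                    amino_acid=str(row["amino_acid"]),
                    anticodon=to_rna(str(row["anticodon"])),
                    sequence=to_rna(str(row["sequence"])),
                    start=int(row["start"]),
                    end=int(row["end"]),
                    strand=str(row["strand"]),
                    canonical=str(row["canonical"]).strip().lower()
                    in ("true", "1", "yes"),
                )
            )
        except GenesetValidationError as exc:
            raise GenesetValidationError(f"row {i}: {exc}") from exc
    return genes


def write_geneset(genes: Iterable[TRNAGene], path: str | Path) -> None:
    """Write genes back out as the TSV schema accepted by :func:`load_geneset`."""
    rows = [
        {
            "locus_id": g.locus_id,
            "amino_acid": g.amino_acid,
            "anticodon": g.anticodon,
            "sequence": g.sequence,
            "start": g.start,
            "end": g.end,
            "strand": g.strand,
            "canonical": g.canonical,
        }
        for g in genes
    ]
    pd.DataFrame(rows, columns=REQUIRED_COLUMNS).to_csv(path, sep="\t", index=False)


def group_types(
    genes: Iterable[TRNAGene], canonical_only: bool = True
) -> list[TRNAType]:
    """Group gene copies into anticodon-level types.

    Non-canonical genes (e.g. a pseudo-tRNA with aberrant predicted structure)
    are excluded by default. Output order is deterministic: sorted by type_id.
    """
    buckets: dict[tuple[str, str], list[TRNAGene]] = defaultdict(list)
    for g in genes:
        if canonical_only and not g.canonical:
            continue
        buckets[(g.amino_acid, g.anticodon)].append(g)
    types = []
    for (aa, ac), members in buckets.items():
        members = sorted(members, key=lambda g: g.locus_id)
        types.append(
            TRNAType(
                amino_acid=aa,
                anticodon=ac,
                gene_ids=[m.locus_id for m in members],
                distinct_sequences=len({m.sequence for m in members}),
            )
        )
    return sorted(types, key=lambda t: t.type_id)


def summarize(types: Iterable[TRNAType]) -> GenesetSummary:
    types = list(types)
    copies = [t.copy_number for t in types]
    return GenesetSummary(
        n_genes=sum(copies),
        n_types=len(types),
        n_multicopy=sum(1 for c in copies if c >= 2),
        max_copy=max(copies, default=0),
    )


def export_fasta(genes: Iterable[TRNAGene], path: str | Path) -> None:
    """Write mature sequences as FASTA, one record per gene (id = locus_id)."""
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f">{g.locus_id}\n{g.sequence}\n")


def sbw25_geneset_path() -> Path:
    """Path to the packaged SBW25-like tRNA gene table.

    The table is a synthetic reconstruction of the P. fluorescens SBW25
    complement: the anticodon/type composition and copy-number structure match
    the published gene set (67 genes, 66 canonical, 39 types), but sequences
    and coordinates are generated stand-ins, not the genomic ones.
    """
    return Path(
        importlib.resources.files("trnaflux.data") / "sbw25_trna_genes.synthetic.tsv"
    )


def load_sbw25() -> list[TRNAGene]:
    """Load the packaged SBW25-like gene complement (see sbw25_geneset_path)."""
    return load_geneset(sbw25_geneset_path())
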