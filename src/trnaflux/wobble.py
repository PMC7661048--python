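"""Codon-tRNA decoding under Watson-Crick + wobble + modification rules.

The first anticodon base (position 34) pairs with the third codon base, and
non-standard "wobble" pairings are tolerated there; most of them require a
post-transcriptional modification of base 34 (e.g. cmo5U/mcmo5U on U34 expands
decoding from A-ending codons to A/G/U-ending ones, inosine at A34 reads
U/C/A-ending codons, lysidine at C34 reassigns a Met-like anticodon to AUA).
Positions 35 and 36 must always be exact reverse complements of codon
positions 2 and 1.

A type is *essential* if it uniquely decodes at least one sense codon (no
other type reads that codon), and the essential set must jointly cover all 61
sense codons. Initiator tRNA (amino-acid label "fMet") is a special case: it
reads AUG only during initiation, so it does not compete with the elongator
Met tRNA for unique coverage, and it is essential by virtue of being the sole
initiator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .geneset import TRNAType
from .utils import SENSE_CODONS, STOP_CODONS, revcomp_rna, to_rna

INITIATOR_LABELS = frozenset({"fMet"})


class WobbleConfigError(ValueError):
    """Raised when a rule set cannot resolve an anticodon's position-34 base."""


@dataclass
class WobbleRuleSet:
    """Configurable position-34 pairing table plus modification predicates.

    ``base34_rules`` maps (base34, modification label) -> codon third-position
    bases matched. ``modification_predicates`` is an ordered list of records
    ``{"amino_acids": [...] | None, "anticodons": [...] | None,
    "base34": "U" | None, "label": str}``; the first predicate whose selectors
    all match a type assigns its modification label, otherwise "none".
    Predicates are data, not code, so the whole rule set serializes to YAML.
    """

    base34_rules: dict[tuple[str, str], frozenset[str]]
    modification_predicates: list[dict] = field(default_factory=list)

    def modification_of(self, trna_type: TRNAType) -> str:
        base34 = trna_type.anticodon[0]
        for pred in self.modification_predicates:
            aas = pred.get("amino_acids")
            acs = pred.get("anticodons")
            b34 = pred.get("base34")
            if aas is not None and trna_type.amino_acid not in aas:
                continue
            if acs is not None and trna_type.anticodon not in acs:
                continue
            if b34 is not None and base34 != b34:
                continue
            return pred["label"]
        return "none"

    def third_position_partners(self, trna_type: TRNAType) -> frozenset[str]:
        base34 = trna_type.anticodon[0]
        mod = self.modification_of(trna_type)
        key = (base34, mod)
        if key not in self.base34_rules:
            raise WobbleConfigError(
                f"no rule for position-34 base {base34!r} with modification "
                f"{mod!r} (type {trna_type.type_id})"
            )
        return self.base34_rules[key]

    # -- serialization -------------------------------------------------------

    def to_yaml(self) -> str:
        doc = {
            "base34_rules": [
                {"base34": b, "modification": m, "codon_third": sorted(s)}
                for (b, m), s in sorted(self.base34_rules.items())
            ],
            "modification_predicates": self.modification_predicates,
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "WobbleRuleSet":
        doc = yaml.safe_load(text)
        rules = {
            (r["base34"], r["modification"]): frozenset(r["codon_third"])
            for r in doc["base34_rules"]
        }
        return cls(
            base34_rules=rules,
            modification_predicates=doc.get("modification_predicates", []),
        )


def default_rules() -> WobbleRuleSet:
    """The packaged default pairing table.

    Watson-Crick pairs are always present; wobble extensions follow the
    standard bacterial repertoire: G34 additionally reads U-ending codons,
    unmodified U34 reads A- and G-ending codons, cmo5U/mcmo5U-modified U34
    additionally reads U-ending codons, inosine (deaminated A34) reads
    U/C/A-ending codons, and lysidine converts C34 from a G-reader into an
    A-reader (the Ile2 AUA decoder).
    """
    rules = {
        ("G", "none"): frozenset({"C", "U"}),
        ("C", "none"): frozenset({"G"}),
        ("A", "none"): frozenset({"U"}),
        ("A", "inosine"): frozenset({"U", "C", "A"}),
        ("U", "none"): frozenset({"A", "G"}),
        ("U", "cmo5U"): frozenset({"A", "G", "U"}),
        ("U", "mcmo5U"): frozenset({"A", "G", "U"}),
        ("C", "lysidine"): frozenset({"A"}),
    }
    predicates = [
        # xmo5U34 pathway (CmoA/B/M): four-codon family boxes whose U34 tRNAs
        # are uridine-5-oxyacetate modified; Ser carries the methylated form.
        {"amino_acids": ["Ser"], "base34": "U", "label": "mcmo5U"},
        {"amino_acids": ["Pro", "Ala", "Thr", "Val"], "base34": "U", "label": "cmo5U"},
        {"amino_acids": ["Arg"], "base34": "A", "label": "inosine"},
        {"amino_acids": ["Ile2"], "base34": "C", "label": "lysidine"},
    ]
    return WobbleRuleSet(base34_rules=rules, modification_predicates=predicates)


@dataclass
class MatchMatrix:
    """Boolean 61-sense-codon x tRNA-type decoding capability matrix."""

    codons: list[str]
    types: list[TRNAType]
    cells: np.ndarray  # bool, shape (len(codons), len(types))

    @property
    def type_ids(self) -> list[str]:
        return [t.type_id for t in self.types]

    def decoders_of(self, codon: str) -> set[str]:
        """Type ids with a true cell for `codon` (sense codons only)."""
        codon = to_rna(codon)
        if codon in STOP_CODONS:
            raise ValueError(f"{codon} is a stop codon, not decoded by tRNA")
        if codon not in self.codons:
            return set()
        i = self.codons.index(codon)
        return {t.type_id for t, hit in zip(self.types, self.cells[i]) if hit}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.cells.astype(int), index=self.codons, columns=self.type_ids
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def build_match_matrix(
    types: Sequence[TRNAType], rules: WobbleRuleSet | None = None
) -> MatchMatrix:
    """Evaluate the decoding rule for every (sense codon, type) pair.

    A cell is true iff codon positions 1/2 are exact reverse complements of
    anticodon positions 36/35 and the codon's third base is in the rule set's
    partner set for the anticodon's (base34, modification).
    """
    rules = rules or default_rules()
    codons = list(SENSE_CODONS)
    cells = np.zeros((len(codons), len(types)), dtype=bool)
    for j, t in enumerate(types):
        partners = rules.third_position_partners(t)
        # anticodon 35/36 read 3'->5' against codon 1/2: revcomp of positions
        # 35,36 gives the required first two codon bases.
        stem = revcomp_rna(t.anticodon[1:])
        for third in partners:
            codon = stem + third
            if codon in STOP_CODONS:
                continue
            cells[codons.index(codon), j] = True
    return MatchMatrix(codons=codons, types=list(types), cells=cells)


@dataclass
class EssentialityPartition:
    essential: set[str]
    non_essential: set[str]
    uncovered_codons: set[str]
    witness: dict[str, str]
    greedy_completed: bool = False


def classify_essentiality(matrix: MatchMatrix) -> EssentialityPartition:
    """Partition types into essential and non-essential by unique coverage.

    Essential types are those that uniquely decode at least one codon among
    elongator tRNAs, plus initiator types (sole providers of initiation).
    If the unique-coverage essential set fails to cover all 61 codons, a
    minimal greedy completion is added and flagged via ``greedy_completed``.
    """
    ids = matrix.type_ids
    initiators = {
        t.type_id for t in matrix.types if t.amino_acid in INITIATOR_LABELS
    }
    elong_cols = np.array([tid not in initiators for tid in ids])

    witness: dict[str, str] = {}
    essential: set[str] = set(initiators)
    for i, codon in enumerate(matrix.codons):
        row = matrix.cells[i] & elong_cols
        if row.sum() == 1:
            tid = ids[int(np.flatnonzero(row)[0])]
            witness[codon] = tid
            essential.add(tid)

    def covered(by: set[str]) -> set[str]:
        cols = np.array([tid in by for tid in ids])
        return {
            matrix.codons[i]
            for i in range(len(matrix.codons))
            if matrix.cells[i][cols].any()
        }

    all_codons = set(matrix.codons)
    decodable = covered(set(ids))
    uncovered = all_codons - covered(essential) - (all_codons - decodable)
    greedy = False
    while uncovered:
        # add the type covering the most currently-uncovered codons
        greedy = True
        best, best_gain = None, -1
        for j, tid in enumerate(ids):
            if tid in essential:
                continue
            gain = sum(
                1
                for i, c in enumerate(matrix.codons)
                if c in uncovered and matrix.cells[i, j]
            )
            if gain > best_gain:
                best, best_gain = tid, gain
        if best is None or best_gain == 0:
            break
        essential.add(best)
        uncovered = all_codons - covered(essential) - (all_codons - decodable)

    return EssentialityPartition(
        essential=essential,
        non_essential=set(ids) - essential,
        uncovered_codons=all_codons - decodable,
        witness=witness,
        greedy_completed=greedy,
    )


def decoders_of(matrix: MatchMatrix, codon: str) -> set[str]:
    return matrix.decoders_of(codon)


def brute_force_match(
    types: Iterable[TRNAType], rules: WobbleRuleSet
) -> dict[str, set[str]]:
    """Independent enumeration oracle: for each sense codon, test every type
    directly against the rule table (used to cross-check build_match_matrix)."""
    pair = {"A": "U", "U": "A", "G": "C", "C": "G"}
    out: dict[str, set[str]] = {c: set() for c in SENSE_CODONS}
    for codon in SENSE_CODONS:
        for t in types:
            wc_ok = (
                t.anticodon[2] == pair[codon[0]] and t.anticodon[1] == pair[codon[1]]
            )
            if wc_ok and codon[2] in rules.third_position_partners(t):
                out[codon].add(t.type_id)
    return out
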