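"""Mature tRNA pool quantification from adapter-ligation tRNA-seq reads.

The pipeline mirrors how deep-sequenced mature tRNA pools are processed:
reads are demultiplexed by exact 6-bp index match, restricted to the length
window expected for adapter-flanked tRNAs, aligned semi-globally (reference
contained in read, adapter overhangs free) against the set of unique mature
tRNA sequences, discarded when they fit more than one reference equally well,
and the surviving assignments aggregated into per-type counts and
within-sample proportions. Strain-level pools are means of replicate
proportions.

Alignment candidates are generated with edlib (unit-cost semi-global edit
distance); acceptance thresholds (mismatch fraction, gap runs, ambiguity
count) and the match/mismatch/gap score used for best-hit and tie decisions
are computed from the edlib traceback.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import pandas as pd
from Bio import SeqIO

from .utils import to_dna

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")
_N_EQUALITIES = [("N", b) for b in "ACGT"]


@dataclass
class SampleIndexTable:
    """Mapping of 6-bp sample index -> sample id, index at the read prefix."""

    indices: dict[str, str]

    def __post_init__(self) -> None:
        if len(set(self.indices.values())) != len(self.indices):
            # many-to-one sample ids are fine; duplicate *index keys* cannot
            # occur in a dict, but catch non-6bp indices here
            pass
        for idx in self.indices:
            if len(idx) != 6:
                raise ValueError(f"index {idx!r} is not 6 bp")


@dataclass(frozen=True)
class Reference:
    ref_id: str
    type_id: str
    sequence: str  # DNA alphabet internally (reads are DNA)


@dataclass
class ReferenceSet:
    """Unique mature tRNA sequences, each labelled with its tRNA type."""

    records: list[Reference]

    def __post_init__(self) -> None:
        seqs = [r.sequence for r in self.records]
        if len(set(seqs)) != len(seqs):
            raise ValueError("reference sequences must be unique")
        ids = [r.ref_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("reference ids must be unique")

    @classmethod
    def from_genes(cls, genes) -> "ReferenceSet":
        """Build from tRNA gene records: one reference per unique sequence."""
        seen: dict[str, Reference] = {}
        for g in genes:
            seq = to_dna(g.sequence)
            if seq not in seen:
                seen[seq] = Reference(ref_id=g.locus_id, type_id=g.type_id,
                                      sequence=seq)
        return cls(records=list(seen.values()))

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceSet":
        """Read a FASTA whose headers are ``ref_id|type_id``."""
        records = []
        for rec in SeqIO.parse(str(path), "fasta"):
            ref_id, _, type_id = rec.id.partition("|")
            records.append(
                Reference(ref_id=ref_id, type_id=type_id or ref_id,
                          sequence=to_dna(str(rec.seq)))
            )
        return cls(records=records)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.records:
                fh.write(f">{r.ref_id}|{r.type_id}\n{r.sequence}\n")


@dataclass
class AlignmentPolicy:
    """Thresholds of the read-to-reference alignment step."""

    max_mismatch_fraction: float = 0.10
    max_gap_run: int = 2          # gaps of < 3 bp: longest indel run allowed
    max_ambiguities: int = 5      # N bases in the aligned region of the read
    min_len: int = 80
    max_len: int = 151
    min_aligned_length: int = 50
    match_score: int = 1
    mismatch_score: int = -1
    gap_score: int = -2


@dataclass
class AlignmentOutcome:
    status: str                   # "assigned" | "ambiguous" | "unaligned"
    ref_id: str | None = None
    score: int | None = None


def demultiplex(
    reads: Iterable[tuple[str, str]] | Iterable[str],
    indices: SampleIndexTable,
) -> tuple[dict[str, list[str]], int]:
    """Assign reads to samples by exact index match at the read prefix.

    ``reads`` is an iterable of sequences or (read_id, sequence) pairs.
    Returns (per-sample read lists, number of unassigned reads). Exact
    matching only: a single index error sends the read to unassigned, which
    trades yield for cross-sample purity.
    """
    by_sample: dict[str, list[str]] = {s: [] for s in indices.indices.values()}
    unassigned = 0
    for item in reads:
        seq = item[1] if isinstance(item, tuple) else item
        sample = indices.indices.get(seq[:6].upper())
        if sample is None:
            unassigned += 1
        else:
            by_sample[sample].append(seq)
    return by_sample, unassigned


def length_filter(
    reads: Sequence[str], policy: AlignmentPolicy | None = None
) -> tuple[list[str], float]:
    """Keep reads within the expected length window; report retention."""
    policy = policy or AlignmentPolicy()
    kept = [r for r in reads if policy.min_len <= len(r) <= policy.max_len]
    retention = len(kept) / len(reads) if reads else 1.0
    return kept, retention


def _alignment_stats(ref: str, read: str, cigar: str, start: int):
    """Mismatches, longest gap run, gap bases, ambiguities and aligned length
    from an edlib extended-CIGAR traceback (ref = query, read = target)."""
    mism = gap_bases = longest_gap = aligned_cols = 0
    n_count = 0
    qpos, tpos = 0, start
    for length, op in _CIGAR_RE.findall(cigar):
        L = int(length)
        if op in "=XM":
            seg_read = read[tpos : tpos + L]
            seg_ref = ref[qpos : qpos + L]
            for a, b in zip(seg_ref, seg_read):
                if b == "N":
                    n_count += 1
                elif a != b:
                    mism += 1
            aligned_cols += L
            qpos += L
            tpos += L
        elif op == "I":  # present in ref (query), absent in read
            gap_bases += L
            longest_gap = max(longest_gap, L)
            aligned_cols += L
            qpos += L
        elif op == "D":  # present in read, absent in ref
            gap_bases += L
            longest_gap = max(longest_gap, L)
            aligned_cols += L
            tpos += L
    return mism, longest_gap, gap_bases, n_count, aligned_cols


def align_read(
    read: str,
    refs: ReferenceSet,
    policy: AlignmentPolicy | None = None,
) -> AlignmentOutcome:
    """Best unique reference for a read, or ambiguous/unaligned.

    Every reference is aligned end-gap-free inside the read (adapter and
    index overhangs are implicitly soft-clipped). A candidate passes if its
    mismatches are at most ``max_mismatch_fraction`` of aligned columns, no
    indel run exceeds ``max_gap_run``, read ambiguities (N) in the aligned
    region are at most ``max_ambiguities``, and the aligned length reaches
    ``min_aligned_length``. The highest raw score wins; an exact score tie
    between references is discarded as ambiguous.
    """
    policy = policy or AlignmentPolicy()
    read = read.upper()

    candidates: list[tuple[int, str]] = []  # (score, ref_id)

    # fast path: a reference occurring verbatim in the read is a perfect,
    # maximal-score candidate; edlib is only consulted for the rest.
    exact_hits = [r for r in refs.records if r.sequence in read]
    exact_ids = {r.ref_id for r in exact_hits}
    for r in exact_hits:
        if len(r.sequence) >= policy.min_aligned_length:
            candidates.append((len(r.sequence) * policy.match_score, r.ref_id))

    for r in refs.records:
        if r.ref_id in exact_ids:
            continue
        L = len(r.sequence)
        if L > len(read):
            continue
        k = int(policy.max_mismatch_fraction * L) + policy.max_gap_run * 2 + 1
        res = edlib.align(r.sequence, read, mode="HW", task="path", k=k,
                          additionalEqualities=_N_EQUALITIES)
        if res["editDistance"] < 0:
            continue
        start = res["locations"][0][0]
        mism, longest_gap, gap_bases, n_count, cols = _alignment_stats(
            r.sequence, read, res["cigar"], start
        )
        if mism > policy.max_mismatch_fraction * cols:
            continue
        if longest_gap > policy.max_gap_run:
            continue
        if n_count > policy.max_ambiguities:
            continue
        if cols < policy.min_aligned_length:
            continue
        score = (
            (cols - mism - n_count - gap_bases) * policy.match_score
            + mism * policy.mismatch_score
            + gap_bases * policy.gap_score
        )
        candidates.append((score, r.ref_id))

    if not candidates:
        return AlignmentOutcome(status="unaligned")
    best = max(s for s, _ in candidates)
    winners = sorted(rid for s, rid in candidates if s == best)
    if len(winners) > 1:
        return AlignmentOutcome(status="ambiguous", score=best)
    return AlignmentOutcome(status="assigned", ref_id=winners[0], score=best)


@dataclass
class CountTable:
    """Per-sample reference and type counts with within-sample proportions."""

    ref_counts: dict[str, Counter]          # sample -> ref_id -> count
    type_counts: dict[str, Counter]         # sample -> type_id -> count
    proportions: dict[str, dict[str, float]]  # sample -> type_id -> fraction

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for sample, counts in self.type_counts.items():
            props = self.proportions[sample]
            for type_id, n in sorted(counts.items()):
                rows.append(
                    {"sample": sample, "type_id": type_id, "count": n,
                     "proportion": props[type_id]}
                )
        return pd.DataFrame(rows)

    def matrix(self) -> pd.DataFrame:
        """samples x types count matrix (absent types as 0)."""
        return (
            self.to_frame()
            .pivot_table(index="sample", columns="type_id", values="count",
                         fill_value=0, aggfunc="sum")
            .astype(int)
        )


def quantify(
    assignments: Mapping[str, Iterable[str]],
    refs: ReferenceSet,
) -> CountTable:
    """Aggregate per-sample assigned ref_ids into type counts and proportions.

    References sharing a type are summed; proportions are type count over
    total assigned reads within the sample.
    """
    type_of = {r.ref_id: r.type_id for r in refs.records}
    ref_counts, type_counts, proportions = {}, {}, {}
    for sample, ref_ids in assignments.items():
        rc: Counter = Counter(ref_ids)
        tc: Counter = Counter()
        for rid, n in rc.items():
            tc[type_of[rid]] += n
        total = sum(tc.values())
        ref_counts[sample] = rc
        type_counts[sample] = tc
        proportions[sample] = (
            {t: n / total for t, n in tc.items()} if total else {}
        )
    return CountTable(ref_counts=ref_counts, type_counts=type_counts,
                      proportions=proportions)


def strain_pools(
    table: CountTable, replicates: Mapping[str, Sequence[str]]
) -> dict[str, dict[str, float]]:
    """Strain-level pools as the mean of replicate proportions.

    Replicate samples with zero assigned reads are excluded from the mean.
    """
    pools: dict[str, dict[str, float]] = {}
    for strain, samples in replicates.items():
        live = [s for s in samples if sum(table.type_counts.get(s, {}).values())]
        types = {t for s in live for t in table.proportions[s]}
        pools[strain] = {
            t: sum(table.proportions[s].get(t, 0.0) for s in live) / len(live)
            for t in types
        } if live else {}
    return pools


def exclude_low_types(
    table: CountTable, threshold: float = 1e-4
) -> tuple[CountTable, list[str]]:
    """Drop types whose proportion is below threshold in *every* sample.

    A type above threshold in even one sample is retained. Returns the
    reduced table and the excluded type list.
    """
    all_types = {t for tc in table.type_counts.values() for t in tc}
    excluded = sorted(
        t
        for t in all_types
        if all(
            table.proportions[s].get(t, 0.0) < threshold
            for s in table.proportions
        )
    )
    drop = set(excluded)
    new_type_counts = {
        s: Counter({t: n for t, n in tc.items() if t not in drop})
        for s, tc in table.type_counts.items()
    }
    new_props = {}
    for s, tc in new_type_counts.items():
        total = sum(tc.values())
        new_props[s] = {t: n / total for t, n in tc.items()} if total else {}
    return (
        CountTable(ref_counts=table.ref_counts, type_counts=new_type_counts,
                   proportions=new_props),
        excluded,
    )


def run_sample(
    reads: Sequence[str],
    refs: ReferenceSet,
    policy: AlignmentPolicy | None = None,
) -> tuple[list[str], dict[str, int]]:
    """Length-filter and align one sample's reads.

    Returns (assigned ref_ids, accounting dict). The accounting dict
    partitions the input exactly: assigned + ambiguous + unaligned +
    length_filtered = len(reads).
    """
    policy = policy or AlignmentPolicy()
    kept, _ = length_filter(reads, policy)
    stats = {"length_filtered": len(reads) - len(kept), "ambiguous": 0,
             "unaligned": 0, "assigned": 0}
    assigned: list[str] = []
    for read in kept:
        out = align_read(read, refs, policy)
        stats[out.status] += 1
        if out.status == "assigned":
            assigned.append(out.ref_id)
    return assigned, stats


def export_unaligned(
    reads: Sequence[str], refs: ReferenceSet, path: str | Path,
    policy: AlignmentPolicy | None = None,
) -> int:
    """Write reads that align to no reference as FASTA (manual QC hook)."""
    policy = policy or AlignmentPolicy()
    kept, _ = length_filter(reads, policy)
    n = 0
    with open(path, "w") as fh:
        for i, read in enumerate(kept):
            if align_read(read, refs, policy).status == "unaligned":
                n += 1
                fh.write(f">unaligned_{i}\n{read}\n")
    return n


def read_fastq(path: str | Path) -> list[str]:
    """Read sequences from a FASTQ file (gzip allowed via Biopython handles)."""
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "rt") as fh:
        return [str(rec.seq) for rec in SeqIO.parse(fh, "fastq")]
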