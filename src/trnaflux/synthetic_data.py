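"""Seed-deterministic generators for every input the pipeline consumes.

Each generator emulates one of the study's input classes — mature tRNA
reference sets, adapter-ligation tRNA-seq reads carrying a 6-bp sample index,
binned chromosome depth profiles with an embedded tandem duplication,
plate-reader growth curves, and codon-biased CDS collections — and returns
machine-readable ground truth alongside the data, so recovery can be checked
at every stage. Identical configuration and seed give identical output.

The defaults mirror the study's conditions: ~40 reference sequences of
60-95 nt, pool proportions spanning ~1e-4 to ~0.1, triplicate samples,
reads of 80-151 nt with substitution errors, and a ~6.7 Mb circular
chromosome carrying a 2x segment of tens to hundreds of kb at ~100x depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .yamat_quant import Reference, ReferenceSet

_DNA = np.array(list("ACGT"))


def gen_reference_set(
    n_refs: int = 42,
    n_types: int = 39,
    length_range: tuple[int, int] = (60, 95),
    seed: int = 0,
    near_duplicate_pairs: int = 0,
) -> ReferenceSet:
    """Random unique reference sequences with type labels.

    ``n_refs - n_types`` extra references reuse existing type labels (distinct
    sequences of the same tRNA type). ``near_duplicate_pairs`` appends pairs
    differing by a single substitution, for alignment tie tests; these pairs
    are the designated exception to the otherwise low pairwise identity of
    random sequences.
    """
    if n_refs < n_types:
        raise ValueError("n_refs must be >= n_types")
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    seqs: list[str] = []
    seen = set()
    while len(seqs) < n_refs:
        L = int(rng.integers(lo, hi + 1))
        s = "".join(rng.choice(_DNA, size=L))
        if s not in seen:
            seen.add(s)
            seqs.append(s)
    type_ids = [f"T{i:02d}" for i in range(n_types)]
    labels = type_ids + [
        type_ids[int(rng.integers(0, n_types))] for _ in range(n_refs - n_types)
    ]
    records = [
        Reference(ref_id=f"ref_{i:02d}", type_id=labels[i], sequence=seqs[i])
        for i in range(n_refs)
    ]
    for k in range(near_duplicate_pairs):
        base = records[k].sequence
        pos = int(rng.integers(0, len(base)))
        alt = "".join(b for b in "ACGT" if b != base[pos])[0]
        twin = base[:pos] + alt + base[pos + 1 :]
        if twin in seen:
            continue
        seen.add(twin)
        records.append(
            Reference(ref_id=f"ref_nd{k:02d}", type_id=f"Tnd{k:02d}",
                      sequence=twin)
        )
    return ReferenceSet(records=records)


def gen_pool(
    refs: ReferenceSet,
    seed: int = 0,
    span: tuple[float, float] = (1e-4, 0.1),
    overrides: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Ground-truth type proportions spanning several orders of magnitude.

    Proportions are drawn log-uniformly over ``span`` and normalized to sum
    to 1; ``overrides`` pins chosen types to exact proportions (the rest are
    rescaled to the remaining mass).
    """
    rng = np.random.default_rng(seed)
    types = sorted({r.type_id for r in refs.records})
    raw = 10 ** rng.uniform(np.log10(span[0]), np.log10(span[1]), size=len(types))
    pool = dict(zip(types, raw / raw.sum()))
    if overrides:
        fixed = sum(overrides.values())
        if fixed >= 1:
            raise ValueError("override proportions must sum to < 1")
        free = {t: p for t, p in pool.items() if t not in overrides}
        scale = (1 - fixed) / sum(free.values())
        pool = {t: p * scale for t, p in free.items()} | dict(overrides)
    return pool


def gen_yamat_reads(
    refs: ReferenceSet,
    pool: Mapping[str, float],
    n_reads: int,
    index: str = "ACGTAC",
    error_rate: float = 0.003,
    length_window: tuple[int, int] = (80, 151),
    out_of_range_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[list[str], pd.DataFrame]:
    """Simulate indexed tRNA-seq reads from a ground-truth pool.

    Types are sampled multinomially by proportion, a reference of the type is
    chosen uniformly, substitution errors are applied to the tRNA body at
    ``error_rate`` per base, and the read is assembled as 6-bp index +
    5' adapter stub + body + 3' adapter stub with total length inside
    ``length_window`` (a fraction ``out_of_range_fraction`` of reads is made
    deliberately short, for length-filter accounting tests).

    Returns (reads, truth table) with per-read source ref/type bookkeeping.
    """
    rng = np.random.default_rng(seed)
    types = sorted(pool)
    probs = np.array([pool[t] for t in types], dtype=float)
    if not np.isclose(probs.sum(), 1.0, atol=1e-6):
        raise ValueError("pool proportions must sum to 1 over the reference types")
    probs = probs / probs.sum()
    by_type: dict[str, list[Reference]] = {}
    for r in refs.records:
        by_type.setdefault(r.type_id, []).append(r)
    missing = [t for t in types if t not in by_type]
    if missing:
        raise ValueError(f"pool types without references: {missing}")

    counts = rng.multinomial(n_reads, probs)
    reads: list[str] = []
    rows = []
    lo, hi = length_window
    for t, n in zip(types, counts):
        for _ in range(n):
            ref = by_type[t][int(rng.integers(0, len(by_type[t])))]
            body = np.array(list(ref.sequence))
            errs = rng.random(len(body)) < error_rate
            n_err = int(errs.sum())
            if n_err:
                for p in np.flatnonzero(errs):
                    body[p] = rng.choice([b for b in "ACGT" if b != body[p]])
            body_s = "".join(body)
            total = int(rng.integers(max(lo, len(body_s) + 8), hi + 1))
            flank = total - 6 - len(body_s)
            left = int(rng.integers(1, flank))
            stub5 = "".join(rng.choice(_DNA, size=left))
            stub3 = "".join(rng.choice(_DNA, size=flank - left))
            read = index + stub5 + body_s + stub3
            if rng.random() < out_of_range_fraction:
                read = read[: int(rng.integers(40, lo))]  # deliberately short
            reads.append(read)
            rows.append({"ref_id": ref.ref_id, "type_id": t, "n_errors": n_err,
                         "length": len(read)})
    order = rng.permutation(len(reads))
    reads = [reads[i] for i in order]
    truth = pd.DataFrame([rows[i] for i in order])
    return reads, truth


def write_fastq(reads: Sequence[str], path: str | Path,
                prefix: str = "read") -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@{prefix}_{i}\n{seq}\n+\n{'I' * len(seq)}\n")


def gen_coverage(
    genome_length: int = 6_722_539,
    depth_mean: float = 100.0,
    dup_interval: tuple[int, int] | None = (4_119_923, 4_164_966),
    copy: float = 2.0,
    bin_size: int = 1000,
    noise: str = "poisson",
    seed: int = 0,
):
    """Binned depth profile with an embedded duplicated segment.

    Per-bin depth is Poisson with mean ``depth_mean`` (scaled by ``copy``
    inside the duplication), or exactly the mean when ``noise='none'``.
    Returns (CoverageProfile, truth interval or None).
    """
    from .dup_detect import CoverageProfile

    rng = np.random.default_rng(seed)
    n_bins = -(-genome_length // bin_size)
    mean = np.full(n_bins, depth_mean, dtype=float)
    if dup_interval is not None and copy != 1.0:
        a, b = dup_interval
        if not (1 <= a < b <= genome_length):
            raise ValueError("dup_interval outside genome")
        first = (a - 1) // bin_size
        last = (b - 1) // bin_size
        mean[first : last + 1] *= copy
    if noise == "poisson":
        depth = rng.poisson(mean).astype(float)
    elif noise == "none":
        depth = mean
    else:
        raise ValueError(f"unknown noise model {noise!r}")
    profile = CoverageProfile(chrom_length=genome_length, bin_size=bin_size,
                              depth=depth, circular=True)
    truth = dup_interval if (dup_interval and copy != 1.0) else None
    return profile, truth


def gen_growth_curves(
    k_mod: float = 1000.0,
    rate: float = 0.01,
    t_lag: float = 120.0,
    od0: float = 10.0,
    noise_sd: float = 0.0,
    sampling_min: float = 5.0,
    duration_min: float = 720.0,
    n_replicates: int = 1,
    seed: int = 0,
):
    """Logistic growth curves with Gaussian read noise.

    OD(t) = K / (1 + (K/od0 - 1) * exp(-r (t - t_lag))) in mOD, sampled every
    ``sampling_min`` minutes; returns a list of GrowthCurve.
    """
    from .phenotype_stats import GrowthCurve

    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration_min + sampling_min / 2, sampling_min)
    curves = []
    for i in range(n_replicates):
        od = k_mod / (1 + (k_mod / od0 - 1) * np.exp(-rate * (t - t_lag)))
        if noise_sd > 0:
            od = od + rng.normal(0, noise_sd, size=len(t))
        curves.append(GrowthCurve(times=t, od=od, replicate_id=f"rep{i + 1}"))
    return curves


def gen_cds(
    codon_weights: Mapping[str, float],
    n_genes: int = 10,
    length_codons: int = 100,
    seed: int = 0,
) -> list:
    """CDS records whose internal codons are drawn by weight.

    Each record is AUG + ``length_codons`` weighted codons + UAA, returned as
    Biopython SeqRecords (write with Bio.SeqIO).
    """
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    if any(w <= 0 for w in codon_weights.values()):
        raise ValueError("codon weights must be positive")
    rng = np.random.default_rng(seed)
    codons = list(codon_weights)
    p = np.array([codon_weights[c] for c in codons], dtype=float)
    p = p / p.sum()
    records = []
    for i in range(n_genes):
        picks = rng.choice(len(codons), size=length_codons, p=p)
        seq = "AUG" + "".join(codons[j] for j in picks) + "UAA"
        records.append(SeqRecord(Seq(seq), id=f"cds_{i}", description=""))
    return records
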