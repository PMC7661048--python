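"""Inverse-proportion model of relative codon and mRNA translation times.

During elongation the ribosomal A site samples ternary complexes from the
cellular pool, so the mean time to match a codon scales inversely with the
summed proportion of tRNA types able to read it:

    tau_codon = 1 / sum_t p_t        (t ranges over decoders of the codon)

and the time to translate a message is the weight-summed codon time

    tau_mRNA = sum_c w_c * tau_c.

Proportions come from mature tRNA pool sequencing; the model treats all
mature tRNAs as charged and all decoders of a codon as equally efficient
(both assumptions relaxable via the optional multipliers).

Times are in arbitrary units (inverse proportions); only ratios between
strains are meaningful.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .utils import render_tau, round_sig, to_rna
from .wobble import MatchMatrix


class UntranslatableCodonError(ValueError):
    """No decoder of the codon has positive pool proportion: the model is
    undefined (not infinite) for such a codon."""


@dataclass
class TRNAPool:
    """Per-strain mature tRNA pool proportions (charged + uncharged).

    Proportions are fractions of the pool in [0, 1]; the mapping may list
    only part of the pool (e.g. only the seryl types), so sums <= 1.
    """

    strain_id: str
    proportions: dict[str, float]

    def __post_init__(self) -> None:
        for t, p in self.proportions.items():
            if p < 0:
                raise ValueError(f"{self.strain_id}: negative proportion for {t}")


@dataclass
class MessageSpec:
    """Expected codon multiplicities of an artificial message."""

    weights: dict[str, float]

    def __post_init__(self) -> None:
        if any(w <= 0 for w in self.weights.values()):
            raise ValueError("message weights must be positive")


@dataclass
class TranslationTimes:
    strain_id: str
    group: str
    tau_codon: dict[str, float]
    tau_mrna: float
    relative_tau_mrna: float | None = None


def _decoder_ids(codon: str, matrix: MatchMatrix | Mapping[str, set] | None,
                 pool: TRNAPool) -> set[str]:
    if matrix is None:
        # seryl shorthand: every pool type whose type id is listed decodes the
        # codon only if named; callers without a matrix must pass decoders
        raise ValueError("a MatchMatrix (or codon->decoders mapping) is required")
    if isinstance(matrix, MatchMatrix):
        return matrix.decoders_of(codon)
    return set(matrix[codon])


def codon_time(
    pool: TRNAPool,
    codon: str,
    matrix: MatchMatrix | Mapping[str, set],
    charging: Mapping[str, float] | None = None,
    efficiency: Mapping[tuple[str, str], float] | None = None,
) -> float:
    """1 / (summed proportion of decoding types).

    ``charging`` is an optional per-type charged-fraction multiplier (default
    1: all mature tRNAs charged); ``efficiency`` an optional per-(codon, type)
    decoding-efficiency weight (default 1: wobble reads as fast as
    Watson-Crick).
    """
    codon = to_rna(codon)
    decoders = _decoder_ids(codon, matrix, pool)
    total = 0.0
    for t in decoders:
        p = pool.proportions.get(t, 0.0)
        if charging is not None:
            p *= charging.get(t, 1.0)
        if efficiency is not None:
            p *= efficiency.get((codon, t), 1.0)
        total += p
    if total <= 0:
        raise UntranslatableCodonError(
            f"codon {codon} has no decoder with positive proportion in "
            f"strain {pool.strain_id}"
        )
    return 1.0 / total


def mrna_time(
    pool: TRNAPool,
    message: MessageSpec,
    matrix: MatchMatrix | Mapping[str, set],
    **kw,
) -> float:
    """Sum over message codons of weight x codon time."""
    return sum(
        w * codon_time(pool, c, matrix, **kw) for c, w in message.weights.items()
    )


def table2(
    pools: Sequence[TRNAPool],
    groups: Mapping[str, str],
    reference_group: str,
    message: MessageSpec,
    matrix: MatchMatrix | Mapping[str, set],
) -> pd.DataFrame:
    """Per-strain and per-group translation-time table.

    Returns one row per strain plus one ``<group> mean`` row per group, with
    raw (unrounded) columns ``tau_<codon>``/``tau_mrna`` and display columns
    following the table convention: per-strain times rounded first (3 s.f.,
    integer precision above 100), group means taken over the *rounded* strain
    values, and relative times computed as rounded tau_mrna over the rounded
    reference-group mean. Aggregating after rounding is what the printed
    reference values use; the raw columns carry the unrounded numbers.
    """
    unknown = [p.strain_id for p in pools if p.strain_id not in groups]
    if unknown:
        raise KeyError(f"strains without a group label: {unknown}")
    if reference_group not in set(groups.values()):
        raise KeyError(f"reference group {reference_group!r} has no strains")

    codons = list(message.weights)
    rows = []
    for p in pools:
        taus = {c: codon_time(p, c, matrix) for c in codons}
        tau_m = sum(message.weights[c] * taus[c] for c in codons)
        row = {"strain": p.strain_id, "group": groups[p.strain_id], "is_mean": False}
        for c in codons:
            row[f"tau_{c}"] = taus[c]
            row[f"tau_{c}_display"] = render_tau(taus[c])
        row["tau_mrna"] = tau_m
        row["tau_mrna_display"] = render_tau(tau_m)
        rows.append(row)
    df = pd.DataFrame(rows)

    means = []
    for grp, sub in df.groupby("group", sort=False):
        row = {"strain": f"{grp} mean", "group": grp, "is_mean": True}
        for c in codons:
            row[f"tau_{c}"] = sub[f"tau_{c}"].mean()
            row[f"tau_{c}_display"] = render_tau(sub[f"tau_{c}_display"].mean())
        row["tau_mrna"] = sub["tau_mrna"].mean()
        row["tau_mrna_display"] = render_tau(sub["tau_mrna_display"].mean())
        means.append(row)
    mean_df = pd.DataFrame(means)

    ref_mean = float(
        mean_df.loc[mean_df["group"] == reference_group, "tau_mrna_display"].iloc[0]
    )
    out = pd.concat([df, mean_df], ignore_index=True)
    out["relative_tau_mrna"] = [
        round_sig(v / ref_mean, 3) for v in out["tau_mrna_display"]
    ]
    return out


def fold_time(group_a_mean: float, group_b_mean: float) -> float:
    """Ratio of two group-mean times (a / b)."""
    if group_b_mean == 0:
        raise ZeroDivisionError("zero denominator in fold_time")
    return group_a_mean / group_b_mean


# ---------------------------------------------------------------------------
# Published seryl pool measurements (strain, group, p_UGA, p_CGA): the model's
# reference inputs for the wild-type / deletion / duplication gene sets.
# ---------------------------------------------------------------------------

SERYL_MESSAGE = MessageSpec(weights={"UCA": 1.0, "UCG": 4.5})

#: decoding pattern of the two serine codons by the two seryl types involved:
#: UCA is read by Ser-UGA alone; UCG by Ser-UGA (mcmo5U wobble) and Ser-CGA.
SERYL_DECODERS: dict[str, set[str]] = {
    "UCA": {"Ser-UGA"},
    "UCG": {"Ser-UGA", "Ser-CGA"},
}


def seryl_pool_table_path() -> Path:
    return Path(importlib.resources.files("trnaflux.data") / "seryl_pools.tsv")


def load_seryl_pools() -> tuple[list[TRNAPool], dict[str, str]]:
    """Packaged per-strain seryl pool proportions and group labels."""
    df = pd.read_csv(seryl_pool_table_path(), sep="\t")
    pools = [
        TRNAPool(
            strain_id=r.strain,
            proportions={"Ser-UGA": r.p_UGA, "Ser-CGA": r.p_CGA},
        )
        for r in df.itertuples()
    ]
    groups = dict(zip(df.strain, df.group))
    return pools, groups


def load_pools_tsv(path: str | Path) -> list[TRNAPool]:
    """Read a long-format pools TSV (strain, type, proportion)."""
    df = pd.read_csv(path, sep="\t")
    pools = []
    for strain, sub in df.groupby("strain", sort=False):
        pools.append(
            TRNAPool(strain_id=str(strain),
                     proportions=dict(zip(sub["type"], sub["proportion"])))
        )
    return pools
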