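"""Coverage-based detection of large tandem duplications.

A direct tandem duplication doubles read depth over the duplicated segment,
so on a depth profile normalized by the genome-wide median the segment shows
as a run of bins with ratio near 2. Junction coordinates (from PCR/Sanger or
an external junction caller) are inputs here, not predictions: the module
computes junction-derived fragment sizes and cross-checks them against
coverage segments.

Internally coordinates are 1-based inclusive; BED output converts to 0-based
half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


@dataclass
class CoverageProfile:
    """Binned mean read depth along a (possibly circular) chromosome."""

    chrom_length: int
    bin_size: int
    depth: np.ndarray
    circular: bool = True

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        expected = -(-self.chrom_length // self.bin_size)
        if len(self.depth) != expected:
            raise ValueError(
                f"expected {expected} bins for length {self.chrom_length} at "
                f"bin size {self.bin_size}, got {len(self.depth)}"
            )
        if (self.depth < 0).any():
            raise ValueError("depth must be non-negative")

    @classmethod
    def from_tsv(cls, path: str | Path, circular: bool = True) -> "CoverageProfile":
        """Read a depth TSV with columns chrom, bin_start (1-based), depth."""
        df = pd.read_csv(path, sep="\t")
        starts = df["bin_start"].to_numpy()
        bin_size = int(starts[1] - starts[0]) if len(starts) > 1 else int(starts[0])
        depth = df["depth"].to_numpy(dtype=float)
        length = int(starts[-1]) - 1 + bin_size
        return cls(chrom_length=length, bin_size=bin_size, depth=depth,
                   circular=circular)

    def to_tsv(self, path: str | Path, chrom: str = "chr") -> None:
        starts = np.arange(len(self.depth)) * self.bin_size + 1
        pd.DataFrame({"chrom": chrom, "bin_start": starts, "depth": self.depth}
                     ).to_csv(path, sep="\t", index=False)


@dataclass
class DupCall:
    """A called duplication interval (1-based inclusive)."""

    start: int
    end: int
    copy_ratio: float
    origin_spanning: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("DupCall requires start < end")

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass
class Junction:
    """An emergent tandem-duplication junction.

    side1 is the coordinate of the downstream end of one copy, side2 the
    upstream start of the next; for a tandem duplication side1 > side2.
    """

    side1: int
    side2: int
    name: str = ""


def junction_size(j: Junction) -> int:
    """Duplicated fragment size implied by a junction: side1 - side2."""
    if j.side1 <= j.side2:
        raise ValueError(
            f"junction {j.name or '?'}: side1 ({j.side1}) must exceed side2 "
            f"({j.side2}) for a tandem duplication"
        )
    return j.side1 - j.side2


def segment_coverage(
    profile: CoverageProfile,
    min_ratio: float = 1.6,
    max_ratio: float = 2.4,
    min_length: int = 10_000,
    max_gap: int = 2,
) -> list[DupCall]:
    """Call duplicated segments from a binned depth profile.

    Depth is normalized by the genome-wide median; maximal runs of bins with
    normalized ratio in [min_ratio, max_ratio] are called, runs separated by
    at most ``max_gap`` below-threshold bins are bridged, and runs shorter
    than ``min_length`` bases are discarded. Boundaries are reported at bin
    resolution. On a circular chromosome a run wrapping the origin is
    reported as two linked calls flagged ``origin_spanning``.
    """
    baseline = float(np.median(profile.depth))
    if baseline <= 0:
        raise ValueError("profile baseline (median depth) is not positive")
    ratio = profile.depth / baseline
    inside = (ratio >= min_ratio) & (ratio <= max_ratio)
    n = len(inside)

    # bridge short gaps between qualifying runs
    merged = inside.copy()
    gap_start = None
    for i in range(n):
        if inside[i]:
            gap_start = None
            continue
        if gap_start is None:
            gap_start = i
        gap_len = i - gap_start + 1
        if (
            gap_len <= max_gap
            and gap_start > 0
            and inside[gap_start - 1]
            and i + 1 < n
            and inside[i + 1]
        ):
            merged[gap_start : i + 1] = True

    # extract maximal runs on the (possibly circular) bin sequence
    runs: list[tuple[int, int]] = []  # [first_bin, last_bin] inclusive
    i = 0
    while i < n:
        if merged[i]:
            j = i
            while j + 1 < n and merged[j + 1]:
                j += 1
            runs.append((i, j))
            i = j + 1
        else:
            i += 1
    wrap = False
    if profile.circular and len(runs) >= 2 and runs[0][0] == 0 and runs[-1][1] == n - 1:
        wrap = True

    calls: list[DupCall] = []
    bs = profile.bin_size
    for k, (a, b) in enumerate(runs):
        length = (b - a + 1) * bs
        spanning = wrap and (k == 0 or k == len(runs) - 1)
        if spanning:
            other = runs[-1] if k == 0 else runs[0]
            combined = length + (other[1] - other[0] + 1) * bs
            if combined < min_length:
                continue
        elif length < min_length:
            continue
        start = a * bs + 1
        end = min((b + 1) * bs, profile.chrom_length)
        calls.append(
            DupCall(start=start, end=end,
                    copy_ratio=float(ratio[a : b + 1].mean()),
                    origin_spanning=spanning)
        )
    return calls


def shared_region(calls: Sequence[DupCall]) -> tuple[int, int] | None:
    """Coordinate intersection of all call intervals; None if disjoint."""
    if not calls:
        raise ValueError("shared_region requires at least one call")
    lo = max(c.start for c in calls)
    hi = min(c.end for c in calls)
    if lo > hi:
        return None
    return (lo, hi)


def calls_to_bed(calls: Iterable[DupCall], path: str | Path,
                 chrom: str = "chr") -> None:
    """Write calls as BED (0-based half-open; start-1, end)."""
    with open(path, "w") as fh:
        for c in calls:
            fh.write(f"{chrom}\t{c.start - 1}\t{c.end}\t"
                     f"copy_ratio={c.copy_ratio:.3f}\n")


def calls_from_bed(path: str | Path) -> list[DupCall]:
    calls = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            start0, end = int(parts[1]), int(parts[2])
            ratio = 2.0
            if len(parts) > 3 and "copy_ratio=" in parts[3]:
                ratio = float(parts[3].split("copy_ratio=")[1])
            calls.append(DupCall(start=start0 + 1, end=end, copy_ratio=ratio))
    return calls
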