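"""Growth-curve summaries and competition fitness.

Maximum growth rate is the steepest least-squares slope of absorbance (mOD)
against time over a sliding window of nine consecutive points restricted to
the exponential window of the assay; lag time is where the tangent at that
window meets the baseline absorbance. Competition fitness is the ratio of
the two competitors' Malthusian parameters, ln(final/initial).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class GrowthCurve:
    """One well's absorbance time series (times in minutes, OD in mOD)."""

    times: np.ndarray
    od: np.ndarray
    replicate_id: str = ""
    blank_corrected: bool = False

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if len(self.times) != len(self.od):
            raise ValueError("times and od must have equal length")
        if not (np.diff(self.times) > 0).all():
            raise ValueError("times must be strictly increasing")

    def blank_correct(self, blank_mean: float) -> "GrowthCurve":
        """Subtract the plate's medium-control mean from every reading."""
        return GrowthCurve(self.times, self.od - blank_mean,
                           self.replicate_id, blank_corrected=True)


@dataclass
class VmaxResult:
    vmax: float            # mOD per minute
    window_center: float   # minutes
    window_intercept: float


@dataclass
class CompetitionCounts:
    """Dilution-corrected viable counts for two competitors at start/end."""

    a_initial: float
    a_final: float
    b_initial: float
    b_final: float

    def __post_init__(self) -> None:
        if min(self.a_initial, self.a_final, self.b_initial, self.b_final) <= 0:
            raise ValueError("viable counts must be positive")


def max_growth_rate(
    curve: GrowthCurve,
    window_points: int = 9,
    t_min: float = 120.0,
    t_max: float = 720.0,
) -> VmaxResult:
    """Steepest sliding-window linear slope within [t_min, t_max] minutes."""
    mask = (curve.times >= t_min) & (curve.times <= t_max)
    t = curve.times[mask]
    y = curve.od[mask]
    if len(t) < window_points:
        raise ValueError(
            f"need at least {window_points} points in [{t_min}, {t_max}] min, "
            f"have {len(t)}"
        )
    best = None
    for i in range(len(t) - window_points + 1):
        tw = t[i : i + window_points]
        yw = y[i : i + window_points]
        slope, intercept = np.polyfit(tw, yw, 1)
        if best is None or slope > best[0]:
            best = (slope, float(tw.mean()), intercept)
    return VmaxResult(vmax=float(best[0]), window_center=best[1],
                      window_intercept=float(best[2]))


def lag_time(curve: GrowthCurve, vmax_result: VmaxResult,
             baseline_points: int = 3) -> float:
    """Tangent-intercept lag, in hours.

    The tangent through the vmax window (slope vmax, the window's own fitted
    intercept) is intersected with the baseline OD, taken as the mean of the
    first ``baseline_points`` readings.
    """
    if vmax_result.vmax <= 0:
        raise ValueError("lag time undefined for non-positive vmax")
    baseline = float(np.mean(curve.od[:baseline_points]))
    t_cross = (baseline - vmax_result.window_intercept) / vmax_result.vmax
    return max(t_cross, 0.0) / 60.0


def relative_fitness(counts: CompetitionCounts) -> float:
    """Ratio of Malthusian parameters W = ln(Af/Ai) / ln(Bf/Bi)."""
    denom = np.log(counts.b_final / counts.b_initial)
    if denom <= 0:
        raise ValueError(
            "competitor B did not grow (final <= initial); the ratio of "
            "Malthusian parameters is undefined"
        )
    return float(np.log(counts.a_final / counts.a_initial) / denom)


def fitness_deviation_test(values: Sequence[float]) -> tuple[float, float]:
    """Convenience one-sample t-test of fitness values against 1.

    Returns (t statistic, two-sided p). Standard t machinery, provided for
    completeness of the assay workflow.
    """
    from scipy import stats

    t, p = stats.ttest_1samp(np.asarray(values, dtype=float), 1.0)
    return float(t), float(p)


def load_growth_tsv(path: str | Path) -> list[GrowthCurve]:
    """Read a long-format TSV (time_min, od, replicate) into curves."""
    df = pd.read_csv(path, sep="\t")
    curves = []
    for rep, sub in df.groupby("replicate", sort=False):
        sub = sub.sort_values("time_min")
        curves.append(
            GrowthCurve(times=sub["time_min"].to_numpy(),
                        od=sub["od"].to_numpy(), replicate_id=str(rep))
        )
    return curves
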