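"""Between-strain comparison of tRNA type counts.

Size factors follow median-of-ratios normalization (per-sample median, over
features nonzero in all samples, of count / geometric-mean-across-samples).
Differential abundance is screened with a group-label permutation test on the
|log2 fold change| of normalized group means — a deliberately simple,
assumption-light substitute for negative-binomial Wald machinery — with
Benjamini-Hochberg adjustment across types. For two groups of three the
exact permutation null (all 20 relabelings) is enumerated.

With so few relabelings the attainable p floor is coarse (each relabeling
ties with its complement under |log2FC|, so min p = 2/20), and p alone
cannot discriminate: by exchangeability every null type has a ~10% chance of
sitting at the floor. The screen therefore flags a type only when its p is at
or below ``alpha`` *and* its fold change exceeds ``min_fold`` in either
direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import gmean
from statsmodels.stats.multitest import multipletests


class NormalizationError(ValueError):
    """No feature is nonzero in every sample; suggest a pseudo-count."""


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors; rows = samples, columns = types."""
    mat = counts.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=0)
    if not all_nonzero.any():
        raise NormalizationError(
            "no type has nonzero counts in all samples; consider adding a "
            "pseudo-count before normalizing"
        )
    ref = gmean(mat[:, all_nonzero], axis=0)
    ratios = mat[:, all_nonzero] / ref
    return pd.Series(np.median(ratios, axis=1), index=counts.index,
                     name="size_factor")


def normalize(counts: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Divide each sample's counts by its size factor (zeros stay zero)."""
    sf = size_factors(counts)
    return counts.div(sf, axis=0), sf


@dataclass
class ComparisonResult:
    table: pd.DataFrame   # per type: baseMean1/2, fold.change, log2, p, padj
    flagged: list[str]    # types at/below alpha with fold change >= min_fold

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t")


def _log2fc(norm: np.ndarray, g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    m1 = norm[g1].mean(axis=0)
    m2 = norm[g2].mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.log2(m1 / m2)


def compare(
    counts: pd.DataFrame,
    group1: Sequence[str],
    group2: Sequence[str],
    n_permutations: int = 1000,
    seed: int | None = 0,
    alpha: float = 0.1,
    min_fold: float = 1.5,
    max_exact: int = 200,
) -> ComparisonResult:
    """Fold changes and permutation p-values between two sample groups.

    p-values need >= 2 samples per group and are the fraction of group
    relabelings (the observed one included) whose |log2 fold change| is at
    least the observed value; when the number of relabelings is at most
    ``max_exact`` the null is enumerated exactly, otherwise ``n_permutations``
    are sampled with ``seed``.
    """
    samples = list(group1) + list(group2)
    norm, _ = normalize(counts.loc[samples])
    mat = norm.to_numpy(dtype=float)
    n1 = len(group1)
    idx = np.arange(len(samples))
    g1 = idx[:n1]
    g2 = idx[n1:]

    m1 = mat[g1].mean(axis=0)
    m2 = mat[g2].mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = m1 / m2
        l2fc = np.log2(fc)

    types = list(norm.columns)
    out = pd.DataFrame(
        {"baseMean1": m1, "baseMean2": m2, "fold.change": fc,
         "log2.fold.change": l2fc},
        index=pd.Index(types, name="type_id"),
    )

    can_permute = n1 >= 2 and len(group2) >= 2
    if can_permute:
        obs = np.abs(l2fc)
        all_labelings = list(combinations(range(len(samples)), n1))
        rng = np.random.default_rng(seed)
        if len(all_labelings) <= max_exact:
            chosen = all_labelings
        else:
            picks = rng.choice(len(all_labelings), size=n_permutations,
                               replace=True)
            chosen = [all_labelings[i] for i in picks]
        exceed = np.zeros(mat.shape[1])
        for lab in chosen:
            a = np.array(lab)
            b = np.array([i for i in idx if i not in set(lab)])
            stat = np.abs(_log2fc(mat, a, b))
            with np.errstate(invalid="ignore"):
                exceed += np.where(np.isnan(stat), False, stat >= obs - 1e-12)
        # 0/0 fold changes are undefined, not significant
        pvals = np.where(np.isnan(obs), np.nan, exceed / len(chosen))
        out["pvalue"] = pvals
        ok = np.isfinite(out["pvalue"].to_numpy())
        padj = np.full(len(out), np.nan)
        if ok.any():
            padj[ok] = multipletests(out["pvalue"].to_numpy()[ok],
                                     method="fdr_bh")[1]
        out["padj"] = padj
    else:
        out["pvalue"] = np.nan
        out["padj"] = np.nan

    with np.errstate(divide="ignore", invalid="ignore"):
        effect = np.maximum(out["fold.change"], 1 / out["fold.change"])
    hit = (
        out["pvalue"].notna()
        & (out["pvalue"] <= alpha + 1e-12)
        & (effect >= min_fold)
    )
    return ComparisonResult(table=out, flagged=sorted(out.index[hit]))
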