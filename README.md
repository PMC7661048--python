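# trnaflux

Analysis toolkit for studying how bacterial tRNA gene sets evolve, built
around the *Pseudomonas fluorescens* SBW25 system in which deleting the
single-copy seryl-tRNA gene *serCGA* is compensated by large tandem
chromosomal duplications that raise the copy number of a second gene,
*serTGA*, and with it the proportion of tRNA-Ser(UGA) in the mature tRNA
pool. It is aimed at microbial evolution and translation researchers who
want to run the same analyses on their own gene sets, tRNA-seq data, or
simulations.

## What it does

- **geneset** — parse and summarize a genome's tRNA gene complement
  (gene copies, anticodon-level types, copy-number structure).
- **wobble** — build the 61-sense-codon × tRNA-type decoding matrix under
  configurable Watson–Crick + wobble + modification rules (G:U wobble,
  cmo⁵U/mcmo⁵U, inosine, lysidine), and partition types into *essential*
  (uniquely decoding some codon) and *non-essential* (fully redundant).
- **codon_usage** — codon counts, family/global usage fractions, and
  codon-weighted message specifications from CDS FASTA.
- **translation_model** — relative translation times from mature pool
  proportions: τ_codon = 1 / Σ p(decoders), τ_mRNA = Σ w_c · τ_c, with
  per-strain tables, group means, and ratios.
- **yamat_quant** — mature tRNA pool quantification from adapter-ligation
  tRNA-seq (YAMAT-seq-style) reads: exact 6-bp index demultiplexing,
  80–151 nt length filter, semi-global alignment to unique tRNA reference
  sequences (≤10 % mismatches, gap runs < 3 bp, ≤5 ambiguities),
  multi-mapper discard, per-type proportions, replicate-mean strain pools.
- **diff_abundance** — median-of-ratios normalization, fold changes, and an
  exact-permutation significance screen with Benjamini–Hochberg adjustment.
- **dup_detect** — tandem-duplication calls from binned coverage profiles,
  junction-derived fragment sizes, and cross-isolate shared regions.
- **phenotype_stats** — sliding-window maximum growth rate, tangent-intercept
  lag time, and relative fitness as the ratio of Malthusian parameters.
- **synthetic_data** — seed-deterministic generators (reads, pools, coverage,
  growth curves, CDS) that emit ground truth for every pipeline stage.

The packaged SBW25-like gene table
(`src/trnaflux/data/sbw25_trna_genes.synthetic.tsv`) reconstructs the
published complement's composition — 67 genes, 66 canonical, 39 types — with
synthetic sequences and coordinates; see `docs/methods.md`.

## Worked example

```python
from trnaflux import geneset, wobble
from trnaflux.translation_model import (
    SERYL_DECODERS, SERYL_MESSAGE, load_seryl_pools, table2)

types = geneset.group_types(geneset.load_sbw25())
part = wobble.classify_essentiality(wobble.build_match_matrix(types))
print(len(part.essential), len(part.non_essential))   # 33 6

pools, groups = load_seryl_pools()
df = table2(pools, groups, "wild_type", SERYL_MESSAGE, SERYL_DECODERS)
print(df[df["strain"] == "SBW25"][
    ["tau_UCA_display", "tau_UCG_display", "tau_mrna_display",
     "relative_tau_mrna"]])
```

which prints

```
   tau_UCA_display  tau_UCG_display  tau_mrna_display  relative_tau_mrna
0            169.0             47.8             385.0               0.97
```

i.e. in the wild type, codon UCA takes 169 relative time units to translate
(the inverse of the 0.0059 tRNA-Ser(UGA) pool proportion), UCG takes 47.8
(both seryl decoders pooled), and a message weighting UCG 4.5:1 over UCA
takes 385 — essentially the wild-type group mean (relative time 0.97).
Deleting *serCGA* raises the message time to a mean of 1135 (2.86-fold),
and *serTGA* duplication restores it to 478 (1.20-fold).

The same is available from the shell:

```sh
trnaflux geneset summarize src/trnaflux/data/sbw25_trna_genes.synthetic.tsv
trnaflux wobble classify --geneset src/trnaflux/data/sbw25_trna_genes.synthetic.tsv
trnaflux model table2
```

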