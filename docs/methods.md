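# Methods

## The system being modelled

Bacterial tRNA gene sets vary in which anticodon-level tRNA types they
encode and in how many gene copies encode each type. In *P. fluorescens*
SBW25 the complement is 67 predicted tRNA genes, of which 66 are canonical
(one, *cysGCA-2*, is a structurally aberrant pseudo-tRNA), encoding 39
types; 14 types are encoded by two to five copies. Removing the single-copy
*serCGA* gene leaves codon UCG readable only through the modified wobble
capacity of tRNA-Ser(UGA), and the resulting growth defect is compensated
by large tandem duplications (45–290 kb) spanning the *serTGA* gene, which
roughly double tRNA-Ser(UGA) in the mature pool. The package implements the
analyses needed to establish and quantify each link in that chain.

## Codon–tRNA matching and essentiality

Pairing at anticodon positions 35/36 with codon positions 2/1 is strict
Watson–Crick; the wobble position (anticodon 34 against codon 3) follows a
configurable rule table. Defaults:

| base 34 | modification | codon third positions read |
|---------|--------------|----------------------------|
| G | none | C, U |
| C | none | G |
| C | lysidine | A (Ile2 type) |
| A | none | U |
| A | inosine | U, C, A |
| U | none | A, G |
| U | cmo⁵U / mcmo⁵U | A, G, U |

Modification assignment is data, not code: an ordered list of predicates
keyed on amino acid and base 34 (defaults: mcmo⁵U on Ser U34; cmo⁵U on
Pro/Ala/Thr/Val U34; inosine on Arg A34; lysidine on Ile2 C34). Both the
table and the predicates serialize to YAML, because the essential /
non-essential partition depends on them and must be auditable and
overridable without touching code.

A type is *essential* when it uniquely decodes at least one sense codon;
the essential set must jointly cover all 61 codons, and every codon read by
a *non-essential* type is also read by an essential one. Two deliberate
design choices:

- **Initiator handling.** Elongator Met-CAU and initiator fMet-CAU both
  carry a true cell for AUG in the matrix, but the initiator does not
  participate in elongation, so it is excluded from the unique-coverage
  competition (otherwise neither Met type would uniquely decode AUG and the
  codon would appear orphaned). fMet is classified essential by the
  initiation criterion — it is the sole initiator. With this rule the
  packaged complement partitions into 33 essential and 6 non-essential
  types (Ser-CGA, Leu-CAA, Leu-CAG, Gln-CUG, Gly-CCC, Arg-CCU).
- **Greedy fallback.** If unique coverage fails to cover every decodable
  codon (possible with interchangeable duplicate types), a minimal greedy
  completion is added and the result is flagged; it never triggers on the
  packaged complement.

`brute_force_match` re-derives the matrix by direct per-codon enumeration
of the rule table and serves as the independent oracle in tests.

## The packaged gene table

`data/sbw25_trna_genes.synthetic.tsv` is a *reconstruction*, labelled
synthetic: the type/anticodon composition, copy-number structure (14
multi-copy types, copies 2–5, 12 of them with identical copy sequences,
Asn-GUU and fMet-CAU with sequence-divergent copies, 42 unique sequences
including the pseudo-tRNA) and the seryl gene layout match the published
SBW25 complement, but the 76-nt sequences and most coordinates are
generated. Everything downstream that depends only on composition —
summaries, the decoding matrix, the essentiality partition, reference-set
construction — is therefore faithful; anything that would depend on the
true primary sequences (e.g. cross-mapping rates between real tRNAs) is
not, and is instead exercised on random reference sets with known truth.

## Translation-time model

With pool proportion p_t for type t, the mean time to match codon c is
modelled as τ_c = 1 / Σ_{t decodes c} p_t, and a message with codon weights
w_c takes τ_mRNA = Σ w_c τ_c. The packaged seryl message weights UCG 4.5:1
over UCA, the genomic usage ratio of the two codons. Assumptions: all
mature tRNAs are charged (an optional per-type charging multiplier relaxes
this) and all decoders of a codon are equally efficient (optional
per-(codon, type) weights). Times are arbitrary inverse-proportion units;
only ratios are meaningful.

**Rounding convention.** The reference presentation of this table rounds
each per-strain τ to display precision first and computes group means and
relative values from the rounded numbers (e.g. the deletion-group UCG mean
is (200 + 213)/2 = 206.5 → 207, not the unrounded 206.4 → 206; the
wild-type message mean is (385 + 408)/2 = 396.5 → 397). `table2` therefore
returns both raw unrounded columns and display columns that follow this
round-then-aggregate convention; display precision is three significant
figures below 100 and integer precision above (which keeps a mean of 1100
and 1170 at 1135 rather than 1140), with halves rounded up.

## tRNA-seq quantification

Reads are demultiplexed by exact 6-bp index match at the read prefix
(exactness trades yield for cross-sample purity), filtered to 80–151 nt,
and aligned to the set of unique mature tRNA sequences. Alignment is
semi-global — the reference must be wholly contained in the read, so
adapter and index overhangs are implicitly soft-clipped. Candidates are
generated with edlib (unit-cost edit distance, N in the read matching any
base); from each traceback the module computes mismatches, the longest
indel run, ambiguity count, aligned length, and a raw score
(match +1 / mismatch −1 / gap −2 per base). A candidate is accepted when
mismatches ≤ 10 % of aligned columns, no indel run exceeds 2 bases,
ambiguities ≤ 5, and ≥ 50 nt align (the minimum-aligned-length default is
this module's own choice and is configurable). The best raw score wins; an
exact score tie across references discards the read as ambiguous. Read
accounting is conserved exactly: assigned + ambiguous + unaligned +
length-filtered = input.

Reference counts aggregate to type counts (summing sequence variants of a
type); proportions are within-sample fractions of assigned reads; strain
pools are means of replicate proportions, with zero-read replicates
excluded. Types below 1e-4 proportion in *every* sample are removed and
listed — a type above threshold in even one sample is retained.

## Differential abundance

Size factors are median-of-ratios (per-sample median, over types nonzero
in all samples, of count / geometric-mean-across-samples); the
implementation is cross-checked in tests against an independent reference
implementation of the same estimator. Between-group comparison reports
normalized group means, fold changes, and a permutation p-value on the
|log2 fold change| statistic, enumerating all relabelings exactly when
there are ≤ 200 (a 3 v 3 design has 20), with BH adjustment across types.
Negative-binomial Wald machinery is deliberately not re-implemented; counts
can be exported for external tools.

One consequence of exact 3 v 3 permutation deserves emphasis: under
|log2FC| every relabeling ties with its complement, so the smallest
attainable p is 2/20 = 0.1, and by exchangeability *every* null type has a
~10 % chance of sitting at that floor. A p-threshold alone would therefore
flag spurious types at a high rate regardless of depth. The screen's
`flagged` list consequently requires both p ≤ α (default 0.1, the floor)
and a fold change of at least `min_fold` (default 1.5) in either
direction; at the read depths simulated here null fold changes stay within
a few percent of 1, so the effect-size gate removes the false floor hits
without masking genuine twofold changes.

## Duplication detection

Binned depth is normalized by the genome-wide median (robust while
duplicated regions are a small fraction of the genome); maximal runs of
bins with ratio in [1.6, 2.4] are called, runs separated by ≤ 2
below-threshold bins are bridged (Poisson dropout), and runs shorter than
10 kb are discarded. Boundaries are bin-resolution; circular chromosomes
are unwrapped at the origin with origin-spanning runs reported as two
linked, flagged calls. Junctions are inputs, not predictions; the implied
fragment size is side1 − side2 (no +1), the convention that reproduces the
45,043 and 290,335 bp fragments of the two precisely-resolved isolates.
The two isolates whose junctions fall in range-valued repeat regions do
not admit this arithmetic and are excluded from size verification.

## Growth and fitness

Maximum growth rate is the steepest least-squares slope over nine
consecutive points within hours 2–12 (mOD/min). Lag is the module's own
definition (named but not specified in the assay tradition it follows):
the time, in hours, where the tangent at the vmax window meets the
baseline OD (mean of the first three readings), floored at zero. Relative
fitness is W = ln(A_f/A_i) / ln(B_f/B_i); the identity W(A,B) = 1/W(B,A)
is asserted as a property test. Blank correction subtracts the per-plate
medium-control mean.

## Synthetic data: what it emulates and what it does not

Generators are seed-deterministic and emit truth tables. Reads are 6-bp
index + random adapter stubs + a reference body with i.i.d. substitution
errors (default 0.3 % per base, an ordinary short-read error rate; indels
only via an explicit stress option), 80–151 nt, types drawn multinomially
from pools spanning ~1e-4–0.1 across ~40 references with triplicate
samples. Coverage is per-bin Poisson at 100× over a ~6.7 Mb circular
chromosome with a 2× segment. Growth is logistic plus Gaussian noise.

Not emulated: modification-induced reverse-transcription stops and
misincorporations, tRNA-dependent ligation/RT efficiency differences,
charging states, pre-tRNAs and fragments, GC-coverage bias, and real
cross-mapping structure between homologous tRNA sequences (random
references are far more distinguishable than real tRNA families; the
near-duplicate option restores the hard case for tie handling). Passing
recovery tests therefore demonstrates correctness of the pipeline's logic
and estimators under the stated noise model, not robustness to those
platform biases — which is the same reason the study-scale analyses
compare *between* strains, where such biases largely cancel.

## Problem sizes and numerical choices

Simulation-backed tests use 100k-read triplicates for the pool-recovery
pipeline, 2k/20k reads for convergence checks, and 0.3–6.7 Mb genomes at
1 kb bins for segmentation; these sizes give comfortable separations
(≥3σ) for every asserted recovery while keeping the suite quick. Exact
permutation is preferred to sampling whenever ≤ 200 relabelings exist.
Ties in alignment scores are never broken by reference order (relabeling
invariance is tested). Degenerate inputs raise typed errors rather than
returning sentinels: untranslatable codons (no decoder with positive
proportion), zero-median coverage, non-growing competitor denominators,
and schema-invalid gene tables all fail loudly.

## Known limitations

- The wobble rule table is a curated default; organisms with different
  modification repertoires need a different YAML, and the essentiality
  partition is only as good as the rules.
- The translation model ignores charging dynamics, ternary-complex
  kinetics, and codon context; it is a demand heuristic, not a kinetic
  simulation.
- The permutation screen has low power at 3 v 3 by construction; it
  screens for large effects rather than estimating significance finely.
- Duplication calling assumes a single dominant copy-number state per
  segment and bin-level resolution; split-read junction discovery is out
  of scope.
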