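# Methods

## Study design and data model

The pipeline analyzes cycle-threshold (CT) matrices from microfluidic qPCR:
one row per gene, one column per sample, each sample identified by animal,
brain region (DVC or CeA; one sample per animal per region), and Zeitgeber
time (ZT3, ZT5, ZT9; group sizes 7/18/15). CT is log2-scaled in transcript
abundance and *lower* CT means *more* transcript; all sign conventions
downstream follow from this. Failed reactions are missing values and stay
missing through every stage; readers accept empty cells, `NA`/`NaN`, and a
numeric failure sentinel (any CT ≥ 40 by default, matching common
instrument exports), and reject finite values outside (0, 40].

## Quantile normalization (ΔCT)

Each sample's observed values are rank-mapped onto a common reference
distribution, the pointwise mean of the samples' sorted value vectors.
Samples with missing entries are handled limma-style: each column's sorted
values are linearly interpolated onto a common quantile grid of length
`n_genes` to build the reference, and the column's ranks are mapped back
through linear interpolation of quantile positions. Ties within a sample
receive the mean of the reference values their ranks span. For complete
matrices this reduces exactly to the classic sort/column-mean/inverse-rank
algorithm (tested to 1e−12 against a brute-force oracle).

Two properties worth stating precisely:

* **Column-shift handling.** Adding per-sample constants c_j changes the
  reference by their grand mean, so the normalized output moves by
  mean(c_j) — a single global constant. Invariance is *exact* for mean-zero
  shift vectors, and −ΔΔCT (which subtracts a within-region reference mean)
  is exactly invariant for arbitrary shifts. Loading differences between
  samples are therefore removed in everything the pipeline reports.
* **Rank coupling under heavy differential expression.** Quantile
  normalization assumes most genes are comparable across samples. When a
  large fraction of transcripts genuinely shifts (e.g., half the genes
  moving by a full cycle in a 200-gene panel), the movers change the ranks
  of genuinely flat genes, biasing their normalized values by roughly
  (number of nearby movers)^½ / gene density — measured at ~0.19 cycles SD
  for 200 genes and shrinking as 1/√n_genes (~0.095 at 1000 genes). This
  is a property of the method, not of this implementation; it is why the
  planted-pattern recovery test (below) evaluates the statistics-and-
  classifier chain on the planted ΔCT directly, and why the acceptance
  script reports recovery both with and without the normalization step.

Both regions are normalized jointly by default (a single coordinate system
is also what the all-sample ordination needs); `normalize_per_region`
selects separate per-region normalization.

## Relative expression (−ΔΔCT)

Within each region, ΔΔCT(gene, sample) = ΔCT − mean ΔCT over that region's
ZT5 samples (missing excluded), and −ΔΔCT is its negation, so positive
values mean higher expression than the ZT5 reference and the mean −ΔΔCT at
ZT5 is zero per gene × region by construction. A gene with no usable ZT5
observation in a region is flagged not-quantifiable there and excluded from
that region's pattern universe rather than silently dropped. The reference
time point defaults to ZT5 and is configurable.

## Differential statistics

All tests run on ΔCT at α = 0.05 with **no multiple-testing correction**:
the pipeline's counts are descriptive summaries over a fixed gene panel,
and the accepted false-positive rate is part of their interpretation (the
acceptance suite verifies the empirical type-I error of each test is ~5%
under a matched null simulation).

* **Two-factor ANOVA**: additive fixed-effects model ΔCT ~ region + time,
  no interaction, with Type II sums of squares so the unbalanced design's
  main-effect tests are order-invariant. Implemented as nested-model
  residual-sum-of-squares comparisons (for an additive model Type II is
  exactly the nested F test); cross-checked against statsmodels
  `anova_lm(typ=2)`.
* **One-way ANOVA** on time within each region; with two groups it reduces
  exactly to the squared pooled t (tested to 1e−10).
* **Pairwise t-tests**: classical pooled-variance (Student) two-tailed
  tests for ZT3–ZT5, ZT5–ZT9, ZT3–ZT9.
* **Tukey HSD**: studentized-range tail probabilities with the one-way
  ANOVA's pooled MSE and Tukey–Kramer standard errors for unequal group
  sizes; cross-checked against `scipy.stats.tukey_hsd`.

Degenerate inputs never abort a whole-plate loop: groups that are too small
are flagged `NOT_TESTABLE` (and never count as significant), and zero
within-group variance with distinct means yields p = 0 flagged
`DEGENERATE`.

## Ordination

Classical (Torgerson) MDS: squared Euclidean distances over ΔCT profiles
are double-centered (B = −½ J D² J) and eigendecomposed; coordinates are
the top-k eigenvectors scaled by √eigenvalue (k = 3 by default). Negative
eigenvalues contribute no coordinates; if fewer than k are positive the
result is zero-padded and flagged. Eigenvector signs are fixed by making
each column's largest-magnitude entry positive, so output is reproducible
across platforms. The default missing-data policy drops genes with any
missing value (`complete_genes`); `pairwise_complete` computes each pair's
distance over shared genes rescaled by √(G/G_shared).

## Pattern classification

A gene × region is diurnal if any of: (1) one-way ANOVA p ≤ α; (2) any
pairwise t-test p ≤ α; (3) |mean −ΔΔCT| > 0.25 at ZT3 or ZT9. The 0.25
threshold corresponds to a 2^0.25 − 1 ≈ 19% (≈20%) change in relative
abundance under doubling efficiency. Support is *statistics-based* when
(1) or (2) holds, *threshold-based* when only (3) does.

Direction at each non-reference time point: up if mean −ΔΔCT > 0.25, or if
the t-vs-ZT5 test is significant with a positive mean; down symmetrically;
else flat. The rule is deliberately deterministic and monotone in both α
and the threshold (raising the threshold or lowering α never adds calls).
If a gene is diurnal but both slots resolve flat — possible when only the
ZT3-vs-ZT9 contrast fires — the time point with the larger |mean −ΔΔCT|
lends its sign, and the call is flagged `DIRECTION_FALLBACK`. Untestable
statistics never satisfy a criterion (missing evidence is not evidence).

Cross-region concordance is a 9 × 9 count matrix (8 patterns + none, DVC
rows × CeA columns) over genes quantifiable in both regions, with
region-only genes tallied separately.

## Alignment score

Per gene and region, x̄ = (mean ΔCT at ZT3, ZT5, ZT9); AS\* is the cosine
between the two regions' vectors and AS = −log₁₀(1 − AS\*). The log
transform expands the compressed near-1 cosine range where small but
meaningful ΔCT differences live. 1 − AS\* is clamped at 1e−12, so perfect
alignment reports the finite cap 12 flagged `CAPPED`. Band cutoffs are
fixed at 3.7 / 4.1 / 5.0 / 5.5, with boundary values assigned to the lower
band so the binning is total.

Two geometric caveats, documented rather than "fixed": the cosine is
invariant to *multiplicative* rescaling of either vector but not to
*additive* ΔCT offsets (the natural scale of region effects), and because
mean ΔCT values are typically large and positive, cosines — hence AS — are
usually well above zero even for unrelated patterns. The score is computed
exactly as defined.

## Synthetic data generator

CT(g, s) = baseline(g) + regionOffset(g, r) + δ(g, r, t) + noise + shift(s),
with δ = 0 at ZT5 and sign flipped for "up" patterns (up-regulation = fewer
cycles). Defaults emulate the target study design: 145 genes, group sizes
7/18/15, two regions, baselines uniform on [14, 30] cycles, region offsets
N(0, 1), half the gene × region units diurnal with direction pairs uniform
over the 8 non-flat patterns and |δ| drawn from {0.25, 0.5, 1.0} cycles,
i.i.d. Gaussian observation noise of 0.5 cycles (the standard additive
error model on the log-scale CT axis), per-sample column shifts of 0.5
cycles SD (what quantile normalization must remove), and 2%
missing-completely-at-random reaction failures. One `numpy` Generator
seeded from the single design seed drives everything, so identical seeds
give byte-identical output.

What it does *not* emulate: preamplification bias, probe-efficiency
differences, phase structure beyond three fixed time points,
non-Gaussian heavy-tailed noise, or informative (signal-dependent)
failures. Passing recovery tests therefore demonstrates the statistical
machinery recovers additive planted structure at realistic noise — not
that the pipeline is robust to instrument artifacts the generator omits.

## Test and simulation sizes

Null calibrations use 1000 simulated genes at the study's group sizes;
pattern recovery uses 200 genes at |δ| = 1.0 cycles and noise 0.25 cycles;
oracle fuzzing uses 200 random matrices. These sizes give binomial
uncertainty well inside the asserted bands (e.g., ±1.4% at a 5% rate with
n = 1000) while keeping the full suite fast.

## Known limitations

* Exact reproduction of a specific study's gene counts depends on choices
  its text does not pin down (ANOVA sum-of-squares type, joint vs
  per-region normalization scope, the direction-assignment rule); the
  configuration exposes each choice instead of guessing silently.
* The quantile-normalization rank coupling described above attenuates
  flat-gene estimates on small panels with massive differential
  expression; end-to-end direction-pair recovery through normalization
  plateaus near ~85-90% under the deliberately extreme all-|δ|=1 planting,
  versus ≥95% for the statistics-and-classifier chain itself.
* Three time points across 9 h cannot resolve phase; no rhythm fitting
  (cosinor-style) is attempted or planned.
* Each animal contributes one sample per region, so no repeated-measures
  or mixed-effects structure is modeled.
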