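# Methods

## The measurement and its metrics

`nicheprof` analyses single-endpoint Biolog SF-P2 phenotype plates: one
96-well plate per microbial isolate, 95 wells each carrying a different
single carbon source plus one water control, read as OD590 after a fixed
incubation. The water-control absorbance is subtracted from every substrate
well; an isolate *uses* a substrate when the corrected OD is at least
0.005 (inclusive). Three per-isolate metrics summarise a carbon-use
profile:

- **Niche width** NW — the number of used substrates (0–95).
- **Total growth** TG — the sum of corrected OD over used substrates only;
  positive but sub-threshold wells contribute nothing.
- **Growth efficiency** GE = TG / NW — mean OD per used substrate;
  undefined (empty field, never 0) when NW = 0.
- **Evenness** J = H′ / ln NW, the Pielou index of the used-substrate OD
  proportions; J = 1 means perfectly homogeneous use (a generalist), lower
  J a specialist. Undefined for NW < 2.

Evenness is computed over the used substrates (S = NW), not all 95:
ln-based Shannon entropy is undefined with zero proportions, and with NW
typically 80–90 of 95 the two conventions differ little. This choice is a
documented convention of the package, not a claim about how any particular
dataset was originally processed.

## Directional niche overlap

For an ordered pair of isolates (i → j) and each substrate n that **both**
use, the contribution is the capped ratio ω_n = min(OD_i,n / OD_j,n, 1) —
the fraction of j's growth on n that i can match. The pair statistic is

    ω̄(i→j) = (1/95) Σ_{n=1..95} ω_n ,

with non-co-used substrates contributing 0. It is a proxy for i's
competitive pressure on j and is deliberately asymmetric: ω̄(i→j) and
ω̄(j→i) differ whenever the two isolates differ in niche width or in depth
of use. Three conventions are fixed here:

- the ratio is capped at 1, so ω̄ ∈ [0, 1] and ω̄(i→i) = NW_i/95;
- the denominator is the full plate (95), not the co-used count — a
  switch (`sympatric_only`, and the per-pair arithmetic) exposes
  alternatives for sensitivity analysis but the default is the literal
  mean over all substrates;
- "both grow" is the same usage criterion as everywhere else
  (corrected OD ≥ 0.005), so one consumption definition governs all
  metrics; ratios then never hit 0/0.

Pairs are enumerated within leaves only (sympatric pairs): a leaf with m
isolates yields m(m−1) ordered pairs, each tagged by source:target kingdom
(B:B, F:F, B:F, F:B). Under the emulated design — 6 leaves per treatment,
10 bacteria + 10 fungi per leaf, one control leaf with only 5 bacteria —
this gives 550 ordered B:F pairs under control and 600 under NPKμ.

## Statistical battery

- **Equal proportions**: Yates-corrected chi-squared on the 2×2 table,
  df = 1 (the classic 2-sample test of equal proportions).
- **Two-sample comparisons** are routed by a Shapiro–Wilk gate at
  α = 0.05 on each sample: both pass → Welch's t; otherwise Wilcoxon
  rank-sum (exact enumeration below n = 10 per group when untied,
  normal approximation with continuity and tie corrections otherwise).
  The routing decision is recorded in every result for audit.
- **Multiplicity**: Benjamini–Hochberg step-up across one explicit family
  (the evenness and overlap comparisons the pipeline runs), FDR 0.05.
- **Bray–Curtis** dissimilarity over all 95 substrates on corrected ODs
  clipped at 0 (the index is undefined for negative abundances; a raw
  mode exists for sensitivity checks). All-zero pairs are set to 1.
- **PERMANOVA** uses sequential (Type-I) sums of squares in the order
  kingdom, treatment, kingdom:treatment, computed as traces of hat-matrix
  products with the Gower-centered distance matrix; pseudo-F uses the
  full-model residual, p-values come from free row/column permutations
  (no strata), and term R² plus residual sum to 1.
- **PERMDISP** embeds the distance matrix by principal coordinates,
  retaining negative-eigenvalue axes as an imaginary part; squared
  distance to a group's center is the real-part contribution minus the
  imaginary-part contribution, floored at 0 before the root. The default
  center is the spatial median (geometric median, Weiszfeld iteration,
  computed separately on real and imaginary axes); centroid is an option.
  A one-way F on the distances is permuted (9999 by default) and Tukey
  HSD (Tukey–Kramer for unequal n) compares group means.
- **Mantel**: Pearson correlation of upper-triangle entries, one-sided
  (greater) p from simultaneous row/column permutations of the second
  matrix (999 by default).
- **Dissimilarity–phylogeny regression**: within each kingdom × treatment
  stratum, OLS of pairwise carbon-use dissimilarity on pairwise
  phylogenetic distance. Pairwise observations are not independent, so the
  p-values are nominal; R² is the quantity of interest and the Mantel test
  is the inferential companion.
- **Metric models**: NW is Poisson with log link fitted by GEE with an
  exchangeable working correlation clustered on leaf — a
  population-averaged treatment of the leaf random effect, chosen because
  no frequentist Poisson GLMM is available in the Python stack this
  package builds on. TG and GE are modelled on the natural-log scale by a
  linear mixed model with a random leaf intercept (undefined or
  non-positive values dropped with a recorded warning; a singular fit
  falls back to fixed-effects OLS, also recorded). Estimated marginal
  means per kingdom × treatment cell and all pairwise Wald contrasts are
  reported on the link scale.

All permutation p-values use (b + 1)/(B + 1), where b counts permuted
statistics ≥ the observed one — this avoids p = 0 and matches common
ecology-package convention. Every permutation routine takes an explicit
seed; PERMANOVA and Mantel also run exhaustively (`permutations="all"`,
n ≤ 8), where p is the exact proportion over all n! relabelings.

## Phylogenetic distances

Bacterial (16S) and fungal (ITS) alignments are consumed as inputs
(aligned FASTA) and never mixed. The default distance is the uncorrected
p-distance over pairwise-complete sites — positions where both sequences
carry an unambiguous A/C/G/T (U read as T); gaps, N and IUPAC ambiguity
codes are excluded pairwise (complete deletion optional). The Jukes–Cantor
correction −(3/4)ln(1 − 4p/3) is available and undefined at p ≥ 0.75.
Tree building is out of scope; downstream analyses consume distances.
Matrices are exchanged as labelled square PHYLIP text.

## The synthetic-data generator

The generator exists so every pipeline stage is testable without any
external download. It emulates the sampling design (2 treatments × 2 plots
× 3 plants; 10 + 10 isolates per leaf; one deficient control leaf with 5
bacteria; 235 isolates) and the group-level structure of the emulated
study: kingdom plate-mean ODs (bacteria 0.103, fungi 0.245), treatment
multipliers taken from the reported group means (bacteria 0.098 → 0.107,
fungi 0.273 → 0.217), fungal usage probabilities from the reported niche
widths (85.5/95 and 79.2/95), bacterial usage probabilities inferred from
the reported plate means and growth efficiencies (≈0.845/0.856), and
evenness-concentration parameters calibrated so the expected Pielou J per
kingdom × treatment cell matches the reported means (0.906/0.913 for
bacteria, 0.918/0.900 for fungi; Gamma shapes 3.9/4.9 and 7.4/3.2).

Mechanics per isolate: substrate usage is Bernoulli per substrate; used
substrates draw latent ODs from a Gamma whose mean is kingdom mean ×
treatment multiplier × substrate baseline × isolate factor / usage
probability (so the expected plate mean is kingdom mean × multiplier ×
factor) and whose shape is the concentration parameter; raw wells add a
water baseline (0.05) and Gaussian read noise (sd 0.002); the water well
is baseline + noise.

Values no study reports were fixed once as realistic defaults and
documented here: the per-isolate lognormal heterogeneity (σ = 0.30,
giving between-isolate TG spread large enough that a ~20% fungal shift is
detected near-certainly at n = 60/60 while a ~9% bacterial shift usually
is not), and a substrate-quality baseline shared across kingdoms
(lognormal, σ = 0.9, mean 1, a fixed profile). The shared baseline
matters: substrate lability is substrate-intrinsic, and sharing it keeps
the between-kingdom OD ratios tight enough that the capped-ratio overlap
statistic responds to the planted mean shifts the way the directional
predictions require; with independent per-kingdom profiles the ratio
dispersion washes those responses out. Overlap asymmetry between kingdoms
is emergent — the higher-OD kingdom caps at 1 more often — with no bespoke
mechanism.

What the generator does **not** emulate: taxonomic structure within
kingdoms (no genera, so no composition tests on real taxa), leaf-level
random effects under the null preset (isolates are exchangeable within
treatment, which is what makes free permutation calibration exact),
kinetic growth curves, spatial structure, or any correlation between an
isolate's usage pattern and its latent ODs beyond the shared baseline.
Passing recovery tests therefore show the pipeline detects effects of the
planted kind at the design's sample sizes — not that real plate data meet
these distributional assumptions.

Presets: `paper-like` (the defaults above), `null` (all treatment effects
removed; used for size/calibration checks), `strong` (each effect doubled
on its natural scale). Everything is deterministic under the config seed,
and written studies are byte-identical for a given config.

## Numerical choices

- The usage threshold comparison is inclusive and rounding-tolerant
  (corrected ≥ 0.005 − 1e−12), so a boundary case like raw 0.055 − water
  0.050 counts as used despite IEEE subtraction yielding 0.004999…97.
- GE is stored as the exact float ratio TG/NW; the product GE·NW recovers
  TG to 1 ulp (bit-exactness of a divide-then-multiply round trip is not
  an IEEE guarantee).
- Negative corrected ODs are retained in profiles but clipped to 0
  wherever nonnegative abundances are mathematically required
  (Bray–Curtis, overlap ratios, evenness).
- Preferred-substrate ranking breaks mean-OD ties by substrate name
  ascending; per-substrate means include non-used wells at their clipped
  value.
- PERMANOVA/PERMDISP comparisons of permuted to observed statistics use a
  1e−12 slack so enumeration matches oracle arithmetic exactly.
- Eigenvalues within ±max|λ|·1e−10 of zero are dropped from the PCoA
  embedding.
- The geometric median uses Weiszfeld iteration with the standard
  stalling check at data points (optimum iff the resultant pull of the
  remaining points has norm ≤ the multiplicity).

## Problem sizes used in the shipped checks

Calibration and recovery checks are sized to run on one CPU in minutes,
as the package's own test-design choice: permutation-test size is measured
on 500 reduced null studies (2 leaves per treatment × 6 fungi, 199
permutations each; at B = 199 the attainable rejection rate at α = 0.05 is
exactly 10/200 under exchangeability); direction recovery uses 50 studies
at the full 235-isolate design; the overlap implementation is checked
against a brute-force per-substrate loop on 1000 random pairs; exhaustive
permutation oracles run at n ≤ 6 (720 relabelings) and n = 5 (120).

## Known limitations

- The leaf "random effect" for NW is population-averaged (GEE), not a
  conditional GLMM; conditional and marginal estimates differ under
  strong leaf heterogeneity.
- PERMDISP's permutation scheme permutes distances-to-center among
  samples (label permutation), a common but not unique convention.
- The two-sample router's asymptotic Wilcoxon branch is slightly
  conservative at small n because of the discreteness of the rank
  statistic.
- With the planted bacterial shifts taken from the reported group means,
  bacterial comparisons are not guaranteed non-significant replicate by
  replicate: the bacterial evenness and niche-width spreads the generator
  produces are tighter than real between-taxa heterogeneity, so small
  planted shifts are detected more often than in real data. The
  direction-recovery guarantee covers the five fungal/overlap effects.
- One plate per isolate is assumed; replicate-plate merging is undefined
  here because the emulated design implies none.
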