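# Methods

## The phenomenon and the model

Long-term culture of primary cells leaves continuous, direction-consistent
DNA methylation changes at specific CpGs.  `methdrift` models the beta value
(methylation fraction) of a culture-associated CpG c in a sample at passage
p as

    beta_c(p) = b0_c + m_c * p + eps,    eps ~ N(0, sigma^2),

clipped to [0, 1].  Everything in the package derives from this linear-drift
picture: CpG selection looks for large |Pearson r| between beta and passage;
the passage clock inverts the relationship by ordinary least squares
(passage regressed on a handful of betas); the single-read predictor applies
the same per-CpG lines as Bernoulli success probabilities for individual
molecules.

## Pipeline order and preprocessing

The array pipeline runs: sex-chromosome filter → kNN imputation → quantile
normalization → outlier test → correlation/slope selection.  Choices:

* **kNN imputation** (default k = 10): distance between CpG rows is plain
  Euclidean over the samples observed in both rows; the k nearest donor rows
  observed at the missing sample contribute their mean, ties in distance
  broken by row order, imputed values clipped to [0, 1].  The procedure is
  quadratic in the number of CpGs and intended for candidate-scale matrices.
* **Quantile normalization** is the classical algorithm (rank within sample,
  replace by the across-sample mean of each rank).  Ties receive the mean of
  the tied ranks' reference values; as a consequence exact idempotency and
  exact equality of sorted columns hold only for tie-free data (ties pull
  the affected cells toward their run mean).  This matches the behavior of
  the standard implementations of the method.
* **Outlier test**: Bonferroni-adjusted test on externally studentized
  residuals of the passage regression (statsmodels `outlier_test`, the same
  procedure as R's `car::outlierTest`); samples with adjusted p < alpha
  (default 0.05) are flagged.

## The passage clock

A clock is `passage = intercept + sum_i coef_i * beta_i`.  The published
four-CpG pyrosequencing model ships with its printed coefficients bound to
cg03762994 (ALOX12), cg25968937 (DOK6), cg26683398 (LTC4S), cg05264232
(TNNI3K).  Betas are fractions in [0, 1]; percentage-scale inputs must be
divided by 100 (a unit swing in the TNNI3K beta moves the estimate by ~39
passages, so the scale is forced).  Predictions are not clipped; negative
estimates are reported as-is.

* **Best-subset search** fits every combination of n_hyper hyper- and
  n_hypo hypomethylated candidates (default 2+2) by OLS and keeps the
  minimum-RSS subset, ties broken lexicographically by CpG id.  Size is
  fixed rather than searched per size: the clock's design point is "two
  hypo- plus two hypermethylated CpGs".
* **Cross-validation**: repeats × k-fold (default 10×10).  Each repeat
  shuffles samples with a seeded generator and splits them into folds as
  evenly as possible, the remainder going to the first folds.  Metrics are
  pooled over all held-out predictions.
* **R² convention**: reported R² is the squared Pearson correlation of
  predicted vs true passage (the predicted-vs-real scatter convention).
  Because it is insensitive to affine miscalibration, the variance-explained
  form 1 − SSE/SST is also computed (`r2_variance_explained`); which of the
  two a published number used is often ambiguous, so both are available.
* **Target column**: passage by default; cumulative population doublings can
  be used by passing another sample-sheet column as `target`.

## Single-read passage prediction

For an amplicon with CpGs i = 1..C, per-CpG lines m_i(p) = a_i + b_i·p are
fitted by OLS of the sample-level methylated fraction against passage over
the training samples.  A read with states x_i ∈ {0, 1, missing} gets the
log-likelihood

    l(p) = sum_{i observed} [ x_i ln m_i(p) + (1 - x_i) ln(1 - m_i(p)) ]

on the integer grid p = 0..50, with m_i clipped to
[clip_eps, 1 − clip_eps], clip_eps = 0.001.  The floor prevents a single
extreme state from annihilating the product; its exact value is a numerical
choice, not a fitted quantity.  The read's passage is the argmax (ties go to
the smallest grid passage, so an uninformative model yields 0); a sample is
scored by the count-weighted mean over its reads.  Reads with missing states
participate in prediction over their observed CpGs but are excluded from
pattern spectra, which require complete epialleles.

Neighbor correlation is the Pearson correlation of the binary state vectors
of complete reads, pooled across the supplied samples (pool per donor set
for a training cohort, or pass a single set for per-sample mode); CpGs with
zero variance are flagged as undefined rather than set to 0.

## Primer-anchored amplicon calling

Reads are anchored by an exact match of the bisulfite-converted forward
primer (CpG positions inside the primer accept C or T); full alignment is
unnecessary for short primer-defined amplicons and would add heavyweight
external dependencies.  At each CpG offset, C calls methylated and T
unmethylated.  Reads whose non-CpG cytosines disagree with the fully
converted reference in more than `max_mismatch_frac` (default 0.1) of
covered positions are discarded as conversion failures; the default is a
conventional bisulfite-QC threshold.  Coordinates are 0-based, half-open;
a CpG is identified by the offset of its C on the reference (+) strand.

## Hairpin hemimethylation

Hairpin ligation joins both strands of a molecule, so one read carries the
CpG dyad states of top and bottom strand plus a loop UMI.  The parser splits
reads at the panel's linker arms (layout: top strand, left linker, UMI,
right linker, bottom strand; the bottom-strand C of the dyad at top offset o
sits at position L − 2 − o of the bottom segment).  UMIs are grouped by the
directional rule: edge u → v when Hamming(u, v) ≤ 1 and
count(u) ≥ 2·count(v) − 1, clusters grown from count-descending roots —
the standard directional algorithm, with masked-position bucketing for
O(n·L) neighbor search.  Per cluster, each CpG/strand takes the majority
state (ties → missing).  The hemimethylation rate of a CpG is
discordant / (concordant + discordant) over informative dyads.  No
threshold for "elevated" hemimethylation is hard-coded; rates are reported.

## Reprogramming kinetics

For a time course with day-0 baselines per donor, the signature delta at day
t is mean over donors of (mean over signature CpGs of |beta(t) − beta(0)|):
the absolute difference is taken per donor first, so opposite-signed donor
changes do not cancel.  Trajectory similarity is plain Pearson correlation
of two delta series.  Passage estimates along a course use univariate
per-CpG predictors (passage regressed on beta in a training cohort, then
averaged over the signature's observed CpGs); the published figures'
predictors are training-set artifacts, so here they are always derived from
a user-supplied or simulated training cohort.  The specific published
age- (99 CpG) and pluripotency- (1432 CpG) signatures are external inputs,
not bundled.

## Synthetic data: what it emulates, and what it does not

All generators are pure functions of a `SimConfig`; a single root seed
spawns fixed per-component substreams (cohort/reads/clonal/hairpin/
timecourse), so each generator is bit-reproducible and independent of the
others.  Defaults are chosen to mirror the study conditions the analysis is
built for:

* **Cohort**: 200 CpGs of which 10 hyper- and 10 hypomethylate at
  |slope| = 0.02 beta/passage (the slope filter's own threshold), noise
  sd 0.01 beta units, 24 samples over passages 1–12 (two donors) — a
  typical MSC culture window at array-like noise.
* **Reads**: 2000 reads/sample (amplicon coverage ~3900× in practice;
  2000 keeps simulations fast at the same statistical behavior).
  Independent drift draws each CpG as Bernoulli(clip(a_i + b_i·p)) with
  per-CpG drift direction random and |b_i| from `slope_range`; rising CpGs
  start low (a ∈ [0.1, 0.3]), falling ones high, so lines stay inside
  [0, 1] over the grid.  The targeted-writer model draws one latent block
  state z ~ Bernoulli(q(p)) per molecule and flips each CpG independently
  with `writer_error` — the coherent-modification alternative the
  neighbor-correlation analysis discriminates against.  Probabilities are
  clipped at [0.001, 0.999] before sampling, mirroring the predictor's
  clip_eps.
* **Clonal culture**: 100 founder clones with heritable patterns, 16-nt
  barcodes and an RGB color; per passage, patterns epimutate (per-CpG flip
  1%) and the population passes a multinomial bottleneck
  (`bottleneck_frac`, default 1% of a 10,000-cell census) — strong enough
  drift to reach oligoclonality within ~10 passages, as observed in
  barcoded cultures.
* **Hairpin**: the bottom strand copies the top with per-CpG flip
  probability `hemi_rate` (default 0.1); UMIs (12 nt) are drawn distinct —
  ideal molecular tagging, so molecule identity is well defined and
  UMI collisions are not part of the model — while sequencing errors on
  UMIs are applied per copy at `umi_error_rate`.  PCR copy numbers are
  1 + Poisson(mean − 1).
* **Time course**: beta_c(t) = start_c + (end_c − start_c)·logistic((t −
  t0)/tau) with a switch day t0 = 17.5 and tau = 2 days shared across
  signatures (re-methylation between day 15 and 20), sampled at the
  standard reprogramming time points for 3 donors.  Scaled-down signature
  sizes (30/20/30 CpGs) keep runs desk-scale with the same trajectory
  statistics.

What passing tests on these generators shows is that the *algorithms* are
correct and discriminating under their own generative assumptions.  Real
bisulfite data adds features the generators deliberately omit: sequencing
and conversion errors beyond uniform substitution, coverage bias, donor and
cell-type heterogeneity, nonlinear drift near saturation, and array
batch/probe effects.  Results on real cohorts therefore depend on the usual
upstream QC; the synthetic suite cannot certify those steps.

## Numerical and degenerate-input conventions

Undefined correlations (zero variance, n < 3) are excluded from selection
rather than set to 0 and are flagged in the statistics table.  Samples
missing a clock CpG are reported as unpredictable, never silently dropped.
Best-subset ties and single-read likelihood ties break deterministically
(lexicographic CpG ids; smallest grid passage).  All randomness flows
through seeded `numpy` generators; identical seeds give bit-identical
outputs, including across CLI runs with the same config.

## Known limitations

* kNN imputation is O(n²) in CpGs; genome-scale matrices need a chunked or
  approximate strategy.
* The hairpin parser assumes amplicon-complete reads starting at the
  reference start, as produced by targeted hairpin PCR.
* Only substitution-type UMI errors are modeled; indels in the loop would
  shift the linker match and discard the read.
* The directional UMI rule with max_mismatch > 1 is not implemented (the
  standard algorithm uses 1).
* Reproduction of the original cohort statistics requires the
  non-redistributable supplementary tables (see
  `examples/reproduce_published_cohort.py`).
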