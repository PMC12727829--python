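# Methods

This note documents the models, conventions and numerical choices behind
`silis`, and what the synthetic-data experiments do and do not demonstrate.

## Label-mass arithmetic

Heavy labels are full ¹³C/¹⁵N substitutions of the C-terminal tryptic
residue: 6 carbons plus 2 nitrogens for lysine, 6 carbons plus 4 nitrogens
for arginine.  Shifts are computed from the NIST monoisotopic mass
differences ¹³C−¹²C = 1.0033548378 Da and ¹⁵N−¹⁴N = 0.9970348937 Da,
giving 8.014199 Da (K) and 10.008269 Da (R) at six-decimal precision.
Library refinement keeps the heavy channel only for panel peptides,
applies the shift to the C-terminal residue only, and flags all b-series
fragments `ExcludeFromAssay`: with a C-terminal label, b-ions are
mass-identical between channels and would cross-contaminate quantification,
while y-ions are mass-resolved and carry the quantitative signal.

## Precursor ranking

Per study-pool series, presence is the fraction of runs with a non-missing
intensity and CV is the linear-scale sample SD (n−1 denominator; the
convention is stated here because either denominator is defensible) over
the mean.  Weight = presence / CV.  Conventions:

- **Rank direction** ascends with weight, so the best precursor has
  relative rank 1 and the ≥ 0.5 cutoff keeps the better half — this is
  what makes the selected set's mean CV fall at or below the study's
  median CV (asserted as a property test).
- **Ties** receive the average rank (stable under permutation).
- **CV = 0** (constant intensities) gives infinite weight and hence the
  top rank: perfect reproducibility must not be discarded on a 0/0.
- **Single-observation precursors** have undefined CV; they are ranked
  lowest within the study rather than dropped, so every observed precursor
  has a defined relative rank in (0, 1].
- **Aggregation** averages relative ranks only over studies where the
  precursor appears; absence is penalized by the project-count filter, not
  by zero-imputation.
- **Top-3 per protein** breaks ties by higher mean relative rank, then
  more projects, then lexicographic sequence — deterministic output.

Physicochemical screening drops peptides of length outside 6–25, with a
missed-cleavage motif (KK, KR, RR, RK, KP, RP), cysteine, or N-terminal
glutamine (both chemically labile), unless explicitly excepted; every
triggered flag is reported either way.  Hydropathy is the mean
Kyte–Doolittle index; net charge uses Henderson–Hasselbalch sums with the
Lehninger pKa set at pH 7.0 (the pKa table and pH are documented defaults —
different tables shift absolute charges but not the sign-based screening).
Proteotypicity is read from the annotation table, not recomputed.

## Standard composition

The endogenous-equivalent concentration of a peptide is the spike level at
which the light/heavy ratio crosses 1, interpolated in log-log space;
levels whose ratio is more than two decades from 1 are screened out first,
and crossings outside the measured range return the boundary level with an
extrapolation flag.  Tier assignment picks the nearest tier in log10
distance (ties to the lower tier) and flags assignments more than one
decade from the endogenous level.  The default tiers {10, 100, 500, 2000}
pg/µl are configuration covering the 10 pg/µl–2 ng/µl range with roughly
geometric spacing; any shipped composition table overrides them.

## Normalization and QC

`ratio = light / SIS` is matched on (modified sequence, charge, run); a
missing or non-positive heavy intensity yields a missing ratio — no
imputation at this stage.  `norm_light` divides every light intensity on a
platform by the median of the platform's study-pool light intensities.
The ratio is exactly invariant to per-run channel-shared factors;
`norm_light` only to a platform-global factor.  All quantities remain on
the linear intensity scale throughout.

The robust CV is 1.4826·MAD/median (the normal-consistency constant is
included because the reference statistics environments scale MAD this
way; `cv(..., "robust")` is the single switch point).  The quantification-
precursor gate is strict CV < 40%, matching the stated wording; among
survivors the most abundant precursor wins.  "Same trend" for same-protein
precursors is operationalized as non-negative Spearman correlation between
the candidates' SIL profiles across samples; disagreement is flagged, not
auto-dropped, because low-abundance profiles can disagree by noise alone.

Fragment profiles take the per-fragment median over runs, keep the top 12
fragments and rescale to exactly 100%.

## Calibration

Weighted least squares with weights 1/x; the blank (x = 0) has undefined
weight and is excluded from the fit with a warning — the LOD method used
here relies on intercept dispersion across replicate curves, not blank
noise.  LOD = 3.3σ/S and LOQ = 10σ/S with σ the sample SD of intercepts
and S the mean slope, so LOQ/LOD = 10/3.3 identically.  A curve is
reportable when ≥ 4 levels pass the accuracy rule and pooled r² ≥ 0.98
(documented default; no universal threshold exists).  Note that the sample
SD of three intercepts underestimates σ by the factor c₄(3) ≈ 0.886; the
recovery tests compare against 3.3·c₄·σ/S, the exact expectation of the
estimator, rather than pretending the estimator is unbiased.

## Evaluation battery

- **Kendall trend**: tau-b with tie correction; two-sided p from the
  tie-corrected normal approximation at every n, as ordinal severity
  factors are heavily tied.  BH adjustment is applied within each platform
  / dataset separately — platforms are independent experiments.
- **Wilcoxon signed-rank**: zero differences dropped; exact null for
  n ≤ 25 without ties, else normal approximation with continuity
  correction.
- **ICC**: from the two-way ANOVA decomposition; ICC(3,k) for average-
  measurement consistency across platforms, ICC(2,1) for absolute
  single-measurement agreement per platform pair.  Rows with missing
  values are removed listwise.
- **KNN imputation** (k = 10): the matrix is transposed so samples are
  observations, missing entries get the unweighted mean of the k nearest
  samples under the co-observation-scaled Euclidean distance, and the
  result is transposed back.
- **Variance partitioning**: per peptide, a crossed random-intercepts
  model value ~ (1|platform) + (1|severity) fitted by REML (derivative-
  free Powell optimization, which is markedly more reliable than gradient
  methods on near-degenerate peptide-level fits); non-convergence falls
  back to a flagged method-of-moments estimate.  Fractions are components
  over their sum.
- **Bland–Altman**: bias ± 1.96 SD limits; t-based CIs with SE = sd/√n for
  the bias and the standard sd·√(3/n) approximation for the limits.
- **Composite dataset**: per sample, one non-holdout platform drawn
  uniformly (seeded); the sample set and hence the severity histogram are
  identical to the source cohort by construction.

## Synthetic data

Generators are seeded (`numpy.random.default_rng`) and bit-reproducible;
the CLI fans one global seed out to named per-stage streams via SHA-256 so
stages are reproducible in isolation.

- **Study pools** (defaults: 6 studies × 8 runs, 200 precursors, matrices
  cycling through EDTA/citrate/heparin/serum): log-normal intensities with
  per-precursor linear-scale CV, Bernoulli presence.  30% of precursors
  are planted "good" (presence 0.98, CV 0.12), 30% "bad" (presence 0.55,
  CV 0.9), the rest intermediate — separations wide enough to be
  scientifically meaningful yet overlapping enough that the ranking is
  non-trivial.
- **Cohort** (defaults: 40 samples over severity levels healthy < mild <
  severe < critical, 3 platforms, 60 peptides, 5 pool runs/platform):
  light = baseline × effect^step × platform scale × per-(platform,
  peptide) response × run factor × noise; heavy = spike × the same
  platform/response/run factors × noise.  The peptide-specific platform
  response (log-normal, sd 0.4) models ionization and transfer
  differences between instruments — the component a single per-platform
  median factor cannot remove but the SIL-ratio cancels, which is exactly
  what the variance-partitioning comparison measures.  25% of peptides
  carry a ×1.6-per-severity-step effect, alternating up/down.
  Missingness averages 5% and is intensity-dependent by default —
  logistic dropout in log10 intensity with the threshold at the
  missing-rate quantile of each run, emulating detection limits; an MCAR
  mode exists for tests that need missingness decoupled from abundance.
  A consequence worth knowing: the lowest-abundance peptides absorb most
  of the dropout and can fall below the 2/3 completeness rule, which is
  why recovery experiments gate on completeness first, as the real
  workflow does.
- **Calibration**: response = slope·x + per-replicate intercept ~
  N(0, σ) + point noise, eight levels spanning ~2×10⁴-fold, triplicate.

What passing tests show: the implementations recover planted structure at
these effect sizes and are calibrated under their stated nulls.  What they
do not show: performance under real-data pathologies — interference,
nonlinear detector saturation, intensity-dependent missingness, RT drift —
none of which the generators emulate.

## Problem sizes

Default experiment sizes (500 calibration simulations, 2000 null peptides
for type-I calibration, 25-peptide variance partitions) were chosen as the
smallest sizes at which Monte-Carlo error is clearly smaller than the
effects being measured; all complete in seconds on one CPU.

## Known limitations

- Protein-level roll-up (MaxLFQ-style inference) is deliberately absent;
  the toolkit stops at peptide-level quantities.
- The variance-partition REML profile can be flat when a factor variance
  is near zero; the moments fallback is unbiased but noisier, and is
  always flagged in the output.
- `estimate_endogenous_level` assumes a monotone ratio–level relationship;
  multiple crossings (possible under interference) use the first.
- The net-charge model ignores side-chain pKa shifts from local sequence
  context.
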