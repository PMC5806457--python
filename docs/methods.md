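# Methods

This note documents the models behind `leafagree`: what the synthetic
cohort emulates, how the estimators are defined, which defaults were chosen
and why, and what the package deliberately does not attempt.

## Synthetic cohort

Each plant p carries a latent linear leaf-emergence process

    n_p(t) = n0 + max(0, r(cultivar) + u_p) · t,     u_p ~ N(0, σ_plant²),

with t in days. The visible (true) count at an imaging day is the
half-up-rounded latent count, forced non-decreasing by a running maximum;
leaf k (k > n0) "emerges" when the latent count crosses k − ½, so the
rounded count always equals the number of emerged leaves. Emergence times
drive the observer model: a leaf younger than `young_age_days` at imaging
time is *young*.

Defaults (package choices, with the reasoning):

| parameter | default | unit | why |
|---|---|---|---|
| `n0` | 2 | leaves | a just-germinated rosette enters imaging with its first true leaves |
| `r(wild_type)` | 0.50 | leaves/day | phyllochron of 2 days; ~14 leaves after the 24-day window |
| `r(mutant)` | 0.35 | leaves/day | the starch mutant emits leaves more slowly; ~10 leaves at end |
| `plant_effect_sd` | 0.05 | leaves/day | ±10% biological replicate-to-replicate rate variation |
| `young_age_days` | 2.0 | days | a leaf is hard to see for roughly one imaging interval after emergence |

The design grid is 2 cultivars × 5 replicates × 13 time points at 48 h
(130 images per variant), optionally duplicated at a second optical
resolution (nominal 300 px vs 470 px) and as geometrically transformed
copies; the four sets are labelled A (low), B (high), C (low, transformed),
D (high, transformed). Transforms and optics change appearance metadata
only — all variants of a plant/time share one ground truth.

## Observer model

An observer detects each true leaf independently: young leaves are missed
with probability `p_miss_young[resolution]`, established leaves with
`p_miss_old`; with probability `p_spurious` one phantom count is added.
Counting without the dot-annotation tool ("spreadsheet" mode) adds a
discretized zero-mean Gaussian perturbation (`sd_extra_noise`), emulating
lost track and restarted counts; results are clipped at zero. Tool-mode
annotations can carry per-leaf dot timestamps with exponential gaps
(mean 1.1 s per leaf).

Default profiles encode the qualitative structure that motivates the whole
analysis: experts are resolution-sensitive on young leaves
(p_miss_young = 0.10 high / 0.30 low, p_miss_old = 0.01), non-experts miss
young leaves regardless of resolution (0.35 at either, p_miss_old = 0.02),
and the default citizen behaves like a non-expert with a worse baseline
(p_miss_old = 0.04) and no spurious counts (miss-only, hence systematic
undercounting). The default roster is 5 experts + 4 non-experts with small
deterministic jitter so the pool is heterogeneous but reproducible.

The citizen study assigns each image a uniform 3–8 annotations from
distinct users out of a pool (default 60) sampled with Zipf-like weights
w_i ∝ i^(−activity_skew) (default 1.2), reproducing the long-tailed
contribution pattern of volunteer platforms. Confidence (3/2/1) is drawn
conditioned on how many leaves that user actually missed:
0 missed → (0.80, 0.15, 0.05), 1 → (0.50, 0.30, 0.20),
≥2 → (0.20, 0.40, 0.40) over (3, 2, 1), so self-report correlates with,
but does not equal, accuracy.

## Agreement metrics

For reference counts X_R and comparison counts X_o over the same images,
with d = X_R − X_o (positive ⇒ the other source undercounts):
DiC = (mean, sample SD of d); |DiC| likewise for |d|; MSE = mean d²;
R² is the squared Pearson correlation (symmetric in its arguments and
invariant to affine rescaling; reported as undefined when either vector has
zero variance). Krippendorff's alpha is computed from the coincidence
matrix of pairable values with the ratio-scale difference
δ²(c, k) = ((c − k)/(c + k))², δ²(0, 0) ≡ 0 by continuity; alpha is exactly
1 whenever every image's ratings are unanimous, and the test suite checks
the implementation to 10⁻¹² against a brute-force pair-enumeration oracle.
SDs use the n − 1 denominator throughout; the identity
MSE = DiC_mean² + population-variance(d) is maintained to 10⁻¹⁰.

Annotation timing reduces each image's dot timestamps to the first-to-last
duration; durations above 200 s are treated as interrupted sessions and
excluded (counted separately), and per-leaf gaps pool successive dot-time
differences of included images.

## Bland–Altman concordance for counts

Integer counts make classical BA scatters overplot, so coincident
(pair mean, difference) coordinates are merged into cells with an integer
multiplicity; bias is the mean difference and the limits of agreement are
bias ± 1.96 · SD(differences). Pair means stay at exact half-integer
resolution, so merging needs no floating-point tolerance. Rendering is an
optional thin matplotlib layer; every statistic lives in the data structure.

## Longitudinal model

The scientific question is whether the cultivars' longitudinal count trends
differ. The model is

    count ~ 1 + time + cultivar + time:cultivar
            + (1 | plant) + (0 + time | plant),

time continuous in days, plant = cultivar × replicate as the subject. The
random time slope is essential: replicates genuinely differ in emergence
rate, and omitting it makes the between-cultivar slope test strongly
anticonservative.

Two inference paths serve this model:

- **Balanced tables** (every plant observed at the same time points — the
  native shape of the design and of every subsampling consensus) use the
  classical expected-mean-squares decomposition. Each plant's trajectory is
  reduced to its least-squares intercept and slope; the time:cultivar
  interaction F is the one-way ANOVA of per-plant slopes across cultivars
  — exact F(k − 1, N − k) under the model — the cultivar main effect is the
  one-way ANOVA of per-plant means, and the time main effect tests the
  grand mean slope against the same between-plant slope mean square.
  Reported sums of squares are on the response scale (slope sums of squares
  multiplied by Σ(t − t̄)²).
- **Unbalanced tables** are fit by REML (statsmodels MixedLM with diagonal
  random-effect covariance, variance components then polished on the
  closed-form REML objective), and fixed-effect Wald F tests use
  Satterthwaite denominator degrees of freedom from the numerically
  differentiated variance-component information matrix; this path matches
  R's lmerTest on shared fixtures and the suite cross-checks it against
  that reference. If both random-effect variances are estimated at zero it
  falls back to an OLS ANCOVA.

The exact decomposition is preferred wherever it applies because the
integer quantization of counts leaves autocorrelated within-plant
residuals — at a rate of 0.5 leaves/day the 48-h grid gains almost exactly
one leaf per interval, so rounding residuals are slow ramps rather than
noise — which biases small-sample REML slope-variance estimates low and
inflates the REML-Wald test's type-I error to roughly twice the nominal
level, while the per-plant-slope ANOVA stays calibrated (measured 5.3%
at the 5% level over 1000 null cohorts) with ~95% interval coverage of the
true rate difference. The practical cost is power: a calibrated df = 8 test
detects the default 0.15 leaves/day rate gap in about 95–97% of cohorts,
not always.

Consensus counts enter the model un-rounded (averaging across observers
first, then analyzing), mirroring how multi-observer campaigns are actually
pooled.

## Subsampling study

A sampling matrix is a binary (plant-time rows) × (observers) matrix with
exactly K ones per row, rows independent, columns chosen uniformly without
replacement — with 130 rows and K = 2 it contains exactly 260 ones. Each
trial draws a matrix, averages the selected observers' counts per row, fits
the interaction ANOVA and records the interaction p-value; 500 trials per
(pool, K) are summarized by min, max, mean, sample SD and raw
(non-excess) kurtosis m₄/m₂² (3 for a normal sample; flagged undefined for
constant trials). Trials whose model fit fails are excluded and counted.
Trial t draws its generator from SeedSequence([master, t]) so any single
trial can be replayed alone. Pools "Any" / "ExP only" / "NExP only" are
first-class labels in the study table.

## Citizen consensus

Per image, the consensus citizen is the arithmetic mean, the maximum, or a
uniformly drawn single annotation. Under the miss-only citizen default the
mean systematically undercounts truth while the maximum approaches it from
below, so |DiC(max vs truth)| ≤ |DiC(average vs truth)| — the motivation
for reporting both. The confidence-spread analysis computes each image's
sample SD of counts and mean confidence; images with a single annotation
are excluded and counted. The 2-D histogram puts exactly-zero SD in a
dedicated "none" bin (full agreement) with half-leaf-wide bins above, and
confidence bins of width ½ over [1, 3]; the low-spread / high-confidence
quadrant fraction (SD < 1 count and mean confidence > 2, both configurable)
is computed from the raw per-image values, not from binned mass.

## Files, configuration, reproducibility

All tables are RFC 4180 CSV with header rows (UTF-8); sidecar metadata is
JSON. The citizen export dialect carries one row per annotation with a JSON
array of {x, y} dots (length = count, coordinates fabricated inside the
nominal image size) and accepts confidence as literal 1/2/3 or as the
answer phrases. The CLI reads a single TOML config with CLI overrides; the
master seed is mandatory (no silent nondeterminism), every source of
randomness derives a named sub-stream from it, and each run writes a
manifest (config SHA-256, seed, library versions) sufficient to reproduce
outputs bit-for-bit.

## Problem sizes

Monte-Carlo checks in the test suite and the acceptance script use the
study's native scale throughout: 130-image designs, a 9-observer pool,
500 subsampling trials per condition, 1000 null cohorts for the type-I
calibration check, and 200 cohorts for interval coverage and
consensus-bias comparisons.

## What the generator does not emulate — and known limitations

- No image synthesis: occlusion geometry, dot placement accuracy, lighting
  and segmentation difficulty are outside the model; "resolution" enters
  only through miss probabilities.
- Observer errors are independent across images and leaves — no fatigue
  drift, learning, or visual-memory carry-over between transformed copies
  (the transformed sets share ground truth and differ only in metadata).
- Emergence is deterministic given the plant's rate; real phyllochron
  variability adds within-plant stochasticity that the quantized-line model
  lacks. Consequently, passing tests demonstrate correctness of the
  estimators and calibration under this mechanism, not performance claims
  about any real annotation campaign.
- Krippendorff alpha is implemented for the ratio scale only (counts); no
  nominal/ordinal variants, no bootstrap confidence intervals.
- The BA layer offers no regression-based bias trend or repeated-measures
  limits-of-agreement corrections; the x-axis is the standard pair mean.
- The longitudinal model treats time as continuous with linear trends; no
  categorical-time ANOVA, autocorrelated residual structures, or post-hoc
  contrasts.
- Citizen consensus operates on counts only; clustering dot positions into
  leaf identities, and longitudinal (monotonicity-aware) consensus
  filtering, are out of scope.
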