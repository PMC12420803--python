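# Methods

This note documents the models, statistics and design choices behind
`neurocoloc`, and what the synthetic-data experiments do and do not show.

## Local synchronization (LCOR)

For voxel v with time series x_v, LCOR is the distance-weighted mean
Pearson correlation with the surrounding in-mask voxels:

    LCOR(v) = Σ_{u≠v} w(d(v,u)) corr(x_v, x_u) / Σ_{u≠v} w(d(v,u)),

with w a Gaussian of FWHM 25 mm (σ = FWHM/2.3548) on inter-voxel mm
distance. Choices the definition itself leaves open:

- **Kernel truncation** at 2×FWHM, where weights are below 1e-5 of the
  peak; this bounds compute with negligible bias.
- **Centre voxel excluded** from its own average by default (its
  self-correlation of 1 would inflate the statistic uniformly); an
  `include_self` flag exists for sensitivity runs.
- **Weight normalization over the analysis mask**, not the full grid, so
  edge voxels average only over observed neighbours.
- **Pipeline order**: nuisance regression of the time series (OLS against
  an intercept plus any supplied confound columns; collinear columns are
  dropped with a warning) → LCOR → optional mask-aware Gaussian smoothing
  of the LCOR map (6 mm default, renormalized by the smoothed mask so
  values do not bleed at edges). Robustness variants — no smoothing,
  dropping the first four volumes, omitting a regressor — are expressed by
  changing these inputs, not by separate code paths.

LCOR is invariant to per-voxel affine rescaling of the series (a property
of correlation) and equals a double-loop weighted-correlation oracle to
1e-10 on any small mask; both are asserted in the tests.

## Group inference

Per voxel, OLS `y = Xb + e` with design [intercept | group | age | sex |
FIQ | motion | site dummies] and a group contrast; t = cᵀb̂ / √(σ̂² cᵀ(XᵀX)⁻¹c),
df = n − rank(X). Covariates with zero sample variance are skipped with a
warning. Inference is by Freedman–Lane permutation: residuals of the
reduced (nuisance-only) model are permuted — within site blocks, since
site is the natural exchangeability boundary in multi-site data — added
back to the reduced fit, and the full model is re-estimated. Max-|t| and
max-|TFCE| null distributions give family-wise-corrected p-values
(1 + #{perm ≥ obs})/(n_perm + 1); when fewer distinct permutations exist
than requested, they are enumerated exhaustively. TFCE uses E = 0.5, H = 2,
26-connectivity and dh = max|t|/100 (common defaults); the negative tail is
the transform of the negated map. A voxel is significant only if it passes
*both* the voxel-FWE and the TFCE-FWE threshold at α — the stricter
intersection reading of a combined criterion; the union alternative is a
one-line change and is deliberately not the default.

## Co-localization statistics

Contrast maps are parcellated to region means (non-finite voxels ignored;
empty regions become missing and propagate by pairwise deletion — region
tables behave like ordinary tabular data). The association between a
contrast vector and a template vector is the **partial Spearman
correlation adjusting both vectors for the regional gray-matter
probability**: rank-transform all three (average ranks for ties),
residualize rank-x and rank-y on [1, rank-gm], and correlate the
residuals. Partialling the covariate from both sides (symmetric partial
correlation) is the standard definition; partialling from one side only is
a different estimand and is not offered.

**Null model.** Because smooth maps make value-permutation nulls
anticonservative, p-values come from variogram-matched surrogates: each
surrogate is a random permutation of the template's values, smoothed
across regions by a squared-exponential kernel at one of 15 candidate
length scales, then affinely rescaled — with an optional white-noise
nugget — so that its binned empirical variogram matches the template's by
least squares; the best-fitting scale per surrogate is kept and the mean
RMS relative variogram mismatch is recorded. The variogram is fitted over
pairs up to the 60th-percentile inter-centroid distance: short lags carry
the spatial structure that drives map-to-map rank correlations, and
established surrogate generators truncate similarly. The two-sided
permutation p compares |ρ_obs| with |ρ_surrogate| over n_surr surrogates
(minimum achievable p = 1/(n_surr+1)). Calibration is verified by
simulation: on independent smooth null maps the surrogate test rejects at
the nominal 5% while the naive permutation rejects at several times that.

**Conventions.** Fisher z = atanh(ρ), with |ρ| clipped to 1 − 1e-15 so a
saturated correlation stays finite (a warning is emitted). The 95% CI uses
the normal approximation z ± 1.96/√(n−3). The reported df is n − 2 — the
printed convention for a correlation over n regions (119 regions → df 117)
— while the CI keeps the n − 3 variance; both appear in output metadata.

**Two-cohort protocol.** Stage 1 flags templates with uncorrected
two-sided p < α in the exploration cohort; stage 2 requires p < α *with
the same sign* in the replication cohort; stage 3 combines both cohorts'
p-values per template by Fisher's method (−2Σln p ~ χ²(2k)) and applies
Benjamini–Hochberg FDR across all templates. "Replicated-significant"
means passing all three stages.

## Pharmacological and individual analyses

Δ-scores are per-subject drug-minus-placebo means of LCOR inside the
case-control significance masks; one-sample one-sided t-tests (df = n − 1)
with Cohen's d = |mean Δ|/sd Δ and a one-sided 90% CI open toward the
hypothesized tail. Under this standard definition |t| = d·√n exactly, and
the tests assert that identity. Neurochemical profiles are the 16-element
Fisher-z vectors over the canonical template set; profiles are compared by
Pearson correlation over the 16 systems (df = 14). Individual z-maps are
(case − control mean)/control sd per region (n−1 sd; zero-sd regions
missing); subject-level co-localization is atanh(partial Spearman) of the
z-map with a template, correlated against symptom scores (Pearson,
df = n − 2, missing scores dropped pairwise), reported raw and
BH-adjusted.

## Synthetic data model

Each voxel's series is `w·s_r(t) + (1−w)·σ_noise·ε_v(t)`, where s_r is a
shared low-pass-filtered (Gaussian σ = 2 samples) standardized regional
signal and ε_v is i.i.d. noise. Two same-region voxels correlate at
w²/(w² + (1−w)²σ²), so true LCOR is monotone in the mixing weight w — the
ground-truth synchronization dial, checkable in closed form at the limits
(w=0 → 0, w=1 → 1). The group effect shifts case subjects' w region-wise
by `effect_size · zscore(template)`, making effect_size unit-free; region
baselines vary smoothly (w ≈ 0.5 ± 0.08·GRF), sites add small zero-mean
regional w offsets that the site fixed effect absorbs, and weights are
clipped to [0.02, 0.98].

Atlases are grown from random seed voxels by 6-connected dilation with
random tie-breaking inside an ellipsoidal brain mask, so regions are
contiguous and tile the mask exactly. Template maps are squared-exponential
Gaussian random fields sampled at region centroids (length scale 10 mm by
default over a ~36 mm synthetic brain), min–max rescaled to [0, 100]; a
smooth gray-matter vector in [0.2, 0.95] is generated alongside. Drug
sessions share a per-subject baseline w field across the three conditions;
a condition shifts w inside two disjoint voxel masks. Clinical scores are
`coupling·z(strength) + √(1−coupling²)·noise`, affinely mapped to
plausible symptom-scale ranges (total 12±4, communication 4±2.5, RSI 8±3,
SBRI 2±1.5). Covariates: age log-normal (median 16 y), sex Bernoulli with
mild group imbalance, FIQ ~ N(108, 15), motion |N(0.9, 0.6)| per axis,
site uniform.

Default study conditions: 12×12×12 grid of 3 mm voxels, 40 regions, 20
subjects per group and cohort, 60 timepoints, 2 sites, σ_noise = 1,
effect −0.25 on the injected template. These sizes make a full two-cohort
study run in seconds while leaving enough voxels per region (~30) and
regions per map for the rank statistics to behave like their large-sample
versions.

**What the generator does not emulate**: scanner physics, motion
time-courses, physiological noise, hemodynamic autocorrelation beyond the
low-pass signal, site differences in acquisition protocol, or realistic
receptor-density distributions. Passing tests therefore demonstrate the
*statistical machinery* — calibration, recovery, conventions — not
fidelity to any particular real dataset; effect sizes are free parameters
of the generator, not calibrated to empirical cohorts.

## Numerical choices and degenerate inputs

- All randomness flows from one root seed through named SHA-256-derived
  substreams (`seeds.substream`), so adding a stage never perturbs
  another's stream; two runs with the same config are byte-identical on
  every TSV/JSON output (floats printed with `%.10g`).
- Rank residuals with sum of squares below 1e-20·n³ (a vector fully
  explained by the covariate) yield a partial correlation of exactly 0
  rather than numerical noise.
- TFCE thresholds carry a 1e-9-relative tolerance against float
  accumulation in the height grid.
- Zero-variance voxels are missing in LCOR and excluded from neighbour
  averages; zero-sd regions are missing in z-maps; constant vectors raise
  explicit errors in correlation routines.
- Grid equality tolerance for parcellation is 1e-5 on the affine.
- Motion exclusion uses strict inequalities (exactly 3 mm / 3° is kept).

## Known limitations

- The surrogate generator matches the variogram, not the full spatial
  law; calibration is demonstrated for smooth Gaussian fields at the
  tested sizes, and very small atlases (< ~15 regions) leave few distance
  bins for the fit.
- Site is a fixed effect; no mixed-model alternative is provided.
- Voxel-level (unparcellated) co-localization and surface/CIFTI formats
  are out of scope.
- The Δ-test ignores crossover order and carryover; it analyses simple
  paired differences.
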