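# Methods

This note documents the statistical model behind `fpconn`, the defaults and
why they were chosen, the pinned numerical decisions, and the limits of what
the synthetic-data tests demonstrate.

## The fingerprinting procedure

A *fingerprint* is the vector of one frontal seed's functional connectivity
with eight canonical target regions, in the fixed order
**[M1, Ins, S1, PCC, PPC, Str, Pul, SC]** (five cortical, three subcortical).
The order is arbitrary but must be pinned and applied identically to both
vectors of every comparison — cosine similarity is meaningless across
inconsistent orderings — so it is stored explicitly in every fingerprint file.

Per scan, FC is the Pearson correlation of the seed's mean time course with
each target's mean time course, Fisher-transformed (z = arctanh r) so values
can be averaged. Group fingerprints are the unweighted mean of scan-level z
values (fixed effects over scans, pooling runs and animals equally). After
averaging — and only then — the fingerprint is min–max normalized to [0, 1].
This ordering (average raw, then normalize) is used identically in the
observed statistic and in every permutation iteration, so the two are
exchangeable under the null.

Pattern similarity between a seed of species A and a seed of species B is the
cosine of the angle between their normalized fingerprints. Because normalized
entries are nonnegative, the cosine lies in [0, 1]. Note the statistic is
invariant to the overall FC *level* twice over: Fisher-z fingerprints are
normalized per seed, and cosine is scale-invariant — the comparison is purely
about pattern.

### Significance: scan-level permutation test

For a seed pair with n_A and n_B scans, the observed cosine is referred to a
resampling null: pool the n_A + n_B scan-level *raw* fingerprints, shuffle
them without replacement into pseudo-groups of the original sizes, average,
normalize, and compute the cosine; repeat (default 10,000 iterations). Because
most random re-divisions mix the two species, the null concentrates near 1
("how similar do fingerprints look when group labels carry no information").
The decision is one-sided: a fingerprint pair is *significantly different*
when the observed cosine is **strictly below the lowest 1st percentile** of
the null.

Pinned choices:

- **Percentile definition**: lower empirical quantile — the order statistic at
  1-based index ⌈q/100 · n⌉ (for q = 1, n = 10,000: the 100th smallest value).
  Interpolating definitions differ negligibly at that n but would break
  bit-level reproducibility across implementations.
- **Group sizes are preserved** in every shuffle; this is the standard
  exchangeable choice when the original design is two groups of fixed size.
- Iterations whose averaged pseudo-group fingerprint is constant (min–max
  undefined) are redrawn and counted; if more than 1% of iterations redraw,
  the test aborts rather than silently reporting a null built from a
  degenerate statistic.
- No multiple-comparison correction is applied across matrix cells by
  default; a Benjamini–Hochberg option (`--fdr`) adjusts the per-cell
  empirical p values (the observed value's rank in its null) at q = 0.05.
- The empirical type-I error of the rule, measured over 4,000 simulated null
  datasets, is ~0.95% — consistent with the nominal 20/2001 ≈ 1% implied by
  the strict-inequality rule at 2,000 iterations.

Variants, all off by default: `--group-stat=t_z` replaces the across-scan
mean of z by the one-sample t statistic mapped to a standard normal deviate;
`--two-stage` averages runs within animal before aggregating across animals;
`--exchange-block=animal` constrains shuffles to move whole animals (blocks
must be equally sized and divide the group sizes — an unavoidable restriction
if the permutation is to preserve group sizes exactly).

## Preprocessing (the in-scope tail)

The pipeline consumes registered 4D volumes and applies, in this pinned
order: **smooth → confound regression → band-pass → extract**.

- **Smoothing**: isotropic Gaussian, σ = FWHM/(2√(2 ln 2)) per axis converted
  to voxel units; reflective boundaries (deterministic and mass-preserving).
  Default FWHM 1.0 mm (appropriate for rat-sized brains at 0.4 mm voxels; use
  ~1.5 mm for squirrel/marmoset-sized data at 0.5 mm).
- **Nuisance regression**: OLS residuals on [intercept | linear trend |
  confounds]; the linear trend is on by default (`--no-detrend` to disable).
  Rank-deficient designs are rejected, naming the collinear columns.
- **Band-pass**: 4th-order Butterworth applied forward and backward
  (`sosfiltfilt`), passband 0.01–0.1 Hz. Zero-phase filtering is essential
  here: a causal filter's frequency-dependent lag would distort the
  correlations the whole method is built on. Applied voxelwise in map mode
  and to ROI columns in ROI-table mode — equivalent for ROI means by
  linearity.
- **ROI geometry**: a cube ROI owns a voxel iff the voxel's *center* (via the
  image affine) lies in the closed cube; indices are 0-based; single-voxel
  ROIs take the nearest voxel center. ROIs that straddle the grid edge or
  resolve to zero voxels are rejected, never clipped.

Degenerate inputs are handled explicitly rather than propagated: constant
series are rejected in `pearson_r` (naming which argument), constant targets
become missing values with a logged count, |r| is clamped at 1 − 1e-7 before
arctanh (logged), and constant fingerprints cannot be normalized.

## The synthetic-data generator

The generator emulates the data regime the pipeline targets: per species,
a few animals × a few runs of 600 volumes at TR 1.5 s on isotropic 0.4–0.5 mm
grids. Its purpose is *ground truth*: each seed has a planted 8-vector of
seed–target correlations that the full pipeline should recover.

Signal model, per scan:

- All regions (seeds + 8 targets) share a latent multivariate Gaussian
  process. The correlation matrix is assembled from the planted fingerprints
  (seed–target rows), a constant **target–target correlation 0.1**, and a
  constant **seed–seed correlation 0.1**. Only the seed rows are scientifically
  meaningful; the two constants exist to make the joint covariance
  well-defined and are deliberately small. Non-PSD combinations are
  **rejected, naming the offending seed** — repairing the matrix would break
  the link between planted and recoverable truth.
- Temporal structure is AR(1) (default φ = 0.3) applied to cross-correlated
  innovations; with a common φ the lag-0 cross-correlation equals the planted
  matrix exactly, and each series starts in steady state (200-sample burn-in
  discarded).
- Observation noise is independent AR(1) per region scaled by `noise_sd`
  (default 0.5 against unit signal variance). This attenuates all seed–target
  correlations by the same factor 1/(1 + noise_sd²), which leaves the
  min–max-normalized fingerprint unchanged in expectation — the pattern, not
  the level, is the estimand. At T = 600 these defaults give single-scan
  r estimates a standard error of ≈ 0.04.
- Optional confounds: one slow sinusoidal drift plus six smooth motion-like
  regressors (mirroring stored rigid-body motion parameters), mixed into all
  regions with random loadings scaled by `confound_amplitude`, and emitted as
  the scan's confound table so nuisance regression can remove them.
- In volume mode, every voxel of an ROI cube carries the ROI's observed
  series plus independent white voxel noise (`voxel_noise_sd`, default 0.5);
  non-ROI voxels are pure noise. Volumes round-trip through NIfTI-1 with TR
  in `pixdim[4]`.

All randomness derives from a single `rng_seed` via
`numpy.random.SeedSequence` spawning (one child per scan), so identical specs
reproduce identical data on any platform.

What the generator does **not** emulate: hemodynamic response convolution,
cardiac/respiratory noise, susceptibility distortion, spatially varying
smoothness, inter-subject anatomical variability, or non-stationarity.
Passing tests therefore establish the *statistical machinery* — recovery of
planted patterns, calibration of the decision rule, monotone loss of
similarity with planted angle — not robustness to every artifact of real
animal data.

## Reproducibility machinery

A study run is driven by one YAML/JSON config with a single top-level
`rng_seed`. The permutation seed of matrix cell (i, j) of species pair p is
derived as `SeedSequence(rng_seed, spawn_key=(p, i, j))`, reduced mod 2³¹,
so any cell can be reproduced in isolation. All floating-point outputs are
written with 6 significant digits; the manifest records a SHA-256 hash of
every output file, and a rerun with the same config reproduces the hashes
byte for byte. The run log restates every pinned decision (filter family,
percentile definition, aggregation mode, seeds) for provenance.

## Problem sizes used in the test suite

Unit and acceptance tests run at desk scale, chosen as the smallest sizes at
which each property is cleanly measurable: ROI-mode simulations use 150–600
volumes and 2–6 scans; the volume-mode recovery check uses 16³ grids
(sufficient for nine non-overlapping 1.5 mm cubes at 0.5 mm voxels), 600
volumes, 5 scans, and 20 repeats; calibration checks use 500 replicates of
2,000-iteration tests. The permutation core is vectorized (batched shuffles
via argsort of uniform draws), which keeps the full calibration run in the
order of seconds.

## Known limitations

- Fixed-effects pooling of scans ignores within-animal correlation; the
  two-stage and animal-block options mitigate but do not model it.
- The 1%-percentile decision has granularity 1/n_iterations; with the default
  10,000 iterations the threshold rests on the 100th order statistic.
- Min–max normalization is sensitive to the extremes of the 8-vector; a
  single noisy extreme target shifts all entries. This is inherent to the
  fingerprint definition, not an implementation choice.
- Map mode holds one scan's 4D array in memory (~66 MB at 24³ × 600
  float64); volumes are generated and processed lazily, one scan at a time.
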