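# fpconn — cross-species functional-connectivity fingerprinting

`fpconn` is a tested, reusable pipeline for comparing the **interareal
functional-connectivity (FC) fingerprints** of frontal cortical regions across
species from resting-state fMRI. It is aimed at comparative/small-animal
neuroimaging groups who have registered 4D volumes (or extracted ROI time
series) for two or more species and want a reproducible, scriptable way to ask:
*does this frontal region in species A couple to the rest of the brain the way
that frontal region in species B does?*

## The method

For each frontal **seed** region and each scan:

1. **Preprocess** (the post-registration tail): isotropic Gaussian smoothing
   (FWHM → σ = FWHM / (2√(2 ln 2))), OLS nuisance regression on
   [intercept | linear trend | motion confounds], and zero-phase Butterworth
   band-pass filtering, 0.01–0.1 Hz by default.
2. **Seed FC**: Pearson correlation *r* of the seed's mean time course with
   each target, mapped through the Fisher transform *z* = arctanh(*r*).
3. **Fingerprint**: the ordered vector of the seed's FC with eight canonical
   targets — M1, Ins, S1, PCC, PPC, Str, Pul, SC — averaged across scans
   (fixed effects on *z*), then **min–max normalized** so the weakest
   connection maps to 0 and the strongest to 1. Normalization makes the
   *pattern* comparable between species whose absolute FC levels differ.
4. **Comparison**: for every seed pair (one per species), the **cosine
   similarity** cos θ = **a**·**b** / (‖**a**‖‖**b**‖) of the two normalized
   fingerprints; 1 means identical direction, 0 orthogonal patterns.
5. **Significance**: a scan-level **permutation test**. Scan fingerprints of
   both groups are pooled, randomly re-divided into pseudo-groups of the
   original sizes, averaged, normalized, and compared — 10,000 times. The
   observed cosine is *significantly different* when it falls strictly below
   the lowest 1st percentile of this null distribution.

A synthetic-data module generates multi-species, multi-scan data (ROI tables
or full NIfTI-1 volumes) with *planted* ground-truth fingerprints, AR(1)
temporal noise, and motion-like confounds, so every stage is testable without
access to animal data.

## Worked example

Simulate a rat-like and a marmoset-like species. Rat seeds FrA and MO are
planted with sensorimotor-weighted fingerprints; marmoset 6VA (ventral
premotor) gets a similar pattern while 47L (lateral prefrontal) gets a
parietal-weighted one:

```python
from fpconn import StudyConfig, make_species_spec, run_pipeline, simulate_study

rat_fps = {
    "FrA": [0.45, 0.35, 0.40, 0.10, 0.12, 0.30, 0.15, 0.10],
    "MO":  [0.30, 0.42, 0.28, 0.15, 0.10, 0.35, 0.12, 0.08],
}  # order: M1, Ins, S1, PCC, PPC, Str, Pul, SC
marmoset_fps = {
    "47L": [0.15, 0.10, 0.12, 0.45, 0.42, 0.30, 0.25, 0.20],
    "6VA": [0.40, 0.30, 0.38, 0.12, 0.15, 0.28, 0.10, 0.12],
}
specs = [
    make_species_spec("rat", rat_fps, n_animals=2, runs_per_animal=3,
                      n_volumes=600, voxel_mm=0.4, rng_seed=1),
    make_species_spec("marmoset", marmoset_fps, n_animals=2, runs_per_animal=3,
                      n_volumes=600, voxel_mm=0.5, rng_seed=2),
]
cfg_path = simulate_study(specs, "demo_study", rng_seed=7, n_iterations=10_000)
summary = run_pipeline(StudyConfig.from_file(cfg_path))
matrix = summary["matrices"][("rat", "marmoset")]
print(matrix.cosine.round(3))
print(matrix.significant)
```

prints

```
       47L    6VA
FrA  0.390  0.965
MO   0.339  0.930

      47L    6VA
FrA  True  False
MO   True  False
```

Both rat seeds have high cosine similarity (> 0.9) with premotor-like 6VA and
low similarity (< 0.4) with prefrontal-like 47L; the permutation test flags
only the 47L comparisons as significantly different fingerprints — exactly the
planted structure. `demo_study/results/` now holds fingerprint TSVs, the
similarity matrix as TSV + JSON (per-cell observed cosine, null threshold,
decision, RNG seed), a long-format table ready for spider plots, a run log of
every pinned analysis decision, and a SHA-256 manifest; rerunning the same
config reproduces the manifest byte for byte.

The same workflow is available from the shell:

```bash
fpconn simulate species.yaml -o demo_study   # or --volumes for full NIfTI
fpconn run demo_study/study.yaml
fpconn report demo_study/results/similarity_rat_vs_marmoset.tsv --threshold 0.75
```

plus stage-wise subcommands `preprocess`, `fc`, `fingerprint`, and `compare`,
and flags `--group-stat=t_z`, `--two-stage`, `--fdr`, `--exchange-block=animal`
for the non-default analysis variants.

## Limitations

Upstream preprocessing (despiking, motion correction, skull-stripping,
registration) is out of scope — the pipeline consumes registered volumes. The
synthetic generator plants stationary Gaussian structure and does not emulate
hemodynamics, physiological noise, or anatomical variability; see
`docs/methods.md` for the full model, pinned numerical choices, and what the
tests do and do not establish.
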