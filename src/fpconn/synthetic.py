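"""Synthetic multi-species resting-state data with planted fingerprints.

The generator emulates the data regime of small-animal resting-state fMRI:
per species, a handful of animals each contribute a few runs of ~600 volumes
at TR 1.5 s, on isotropic grids of 0.4–0.5 mm voxels.  Every scan carries a
known ground truth: for each frontal seed, an 8-vector of seed-target Pearson
correlations (the *planted fingerprint*) over the canonical target set.

Signal model
------------
Per scan, all regions (seeds + 8 targets) share a latent zero-mean Gaussian
process.  The region-by-region correlation matrix is assembled from the
planted fingerprints (seed rows), a small constant target-target correlation,
and a small constant seed-seed correlation; it must be positive semi-definite
or the spec is rejected (no silent repair - repaired covariance would decouple
planted truth from recovered truth).  Temporal structure is AR(1) with
coefficient ``ar1_phi`` applied to cross-correlated innovations, which leaves
the lag-0 cross-correlation equal to the planted matrix.  Observation noise is
independent AR(1) per region with the same coefficient, scaled by
``noise_sd``; because seed and targets are attenuated equally, the *pattern*
(and hence the min-max-normalized fingerprint) is preserved in expectation.
Optional confounds (one slow sinusoidal drift + six smooth motion-like
regressors) are mixed into every region with random loadings scaled by
``confound_amplitude`` and emitted alongside the data for nuisance regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy.ndimage import gaussian_filter1d

from .rois import ROISpec
from .volumes import VolumeSeries

__all__ = [
    "SyntheticSpec",
    "ScanTimeseries",
    "generate_roi_timeseries",
    "generate_volumes",
    "make_species_spec",
]

logger = logging.getLogger(__name__)

_AR1_BURN_IN = 200  # samples discarded so every series starts in steady state


@dataclass
class SyntheticSpec:
    """Full description of one species' synthetic data set.

    Defaults mirror the acquisition regime the pipeline targets: 600 volumes
    per run at TR 1.5 s on 0.5 mm isotropic voxels.  ``noise_sd`` defaults to
    0.5 (signal variance 1), giving single-scan seed-target correlation
    estimates a standard error of about 0.04 at T = 600 with ``ar1_phi`` 0.3.
    """

    species_label: str
    seed_rois: list[ROISpec]
    target_rois: list[ROISpec]
    ground_truth_fingerprints: Mapping[str, Sequence[float]]
    n_animals: int = 1
    runs_per_animal: int = 5
    n_volumes: int = 600
    tr_seconds: float = 1.5
    voxel_mm: float = 0.5
    grid_shape: tuple[int, int, int] = (24, 24, 24)
    ar1_phi: float = 0.3
    noise_sd: float = 0.5
    signal_sd: float = 1.0
    voxel_noise_sd: float = 0.5
    confound_amplitude: float = 0.0
    target_target_corr: float = 0.1
    seed_seed_corr: float = 0.1
    rng_seed: int = 0

    # filled in __post_init__
    correlation_matrix: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.n_animals < 1 or self.runs_per_animal < 1 or self.n_volumes < 1:
            raise ValueError("n_animals, runs_per_animal and n_volumes must be positive")
        if not (0 <= self.ar1_phi < 1):
            raise ValueError(f"ar1_phi must be in [0, 1), got {self.ar1_phi}")
        if self.noise_sd < 0 or self.voxel_noise_sd < 0 or self.confound_amplitude < 0:
            raise ValueError("noise_sd, voxel_noise_sd and confound_amplitude must be >= 0")
        if len(self.target_rois) != 8:
            raise ValueError(f"exactly 8 target ROIs required, got {len(self.target_rois)}")

        seed_labels = [r.label for r in self.seed_rois]
        fp_labels = set(self.ground_truth_fingerprints)
        if fp_labels != set(seed_labels):
            raise ValueError(
                f"ground_truth_fingerprints keys {sorted(fp_labels)} do not match "
                f"seed labels {sorted(seed_labels)}"
            )
        for label, fp in self.ground_truth_fingerprints.items():
            fp = np.asarray(fp, dtype=float)
            if fp.shape != (8,):
                raise ValueError(f"fingerprint for seed {label!r} must have length 8")
            if np.any(np.abs(fp) >= 1):
                raise ValueError(f"fingerprint for seed {label!r}: correlations must lie in (-1, 1)")

        # grid containment for every ROI
        affine = self.affine
        for roi in [*self.seed_rois, *self.target_rois]:
            roi.voxel_indices(self.grid_shape, affine)  # raises if outside / empty

        self.correlation_matrix = self._build_correlation()

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_mm] * 3 + [1.0])
        return aff

    @property
    def region_labels(self) -> list[str]:
        return [r.label for r in self.seed_rois] + [r.label for r in self.target_rois]

    @property
    def n_scans(self) -> int:
        return self.n_animals * self.runs_per_animal

    def _build_correlation(self) -> np.ndarray:
        n_seeds = len(self.seed_rois)
        n = n_seeds + 8
        corr = np.full((n, n), np.nan)
        corr[np.diag_indices(n)] = 1.0
        for i in range(n_seeds):
            for j in range(i + 1, n_seeds):
                corr[i, j] = corr[j, i] = self.seed_seed_corr
        for i in range(n_seeds, n):
            for j in range(i + 1, n):
                corr[i, j] = corr[j, i] = self.target_target_corr
        for i, roi in enumerate(self.seed_rois):
            fp = np.asarray(self.ground_truth_fingerprints[roi.label], dtype=float)
            corr[i, n_seeds:] = fp
            corr[n_seeds:, i] = fp

        # Per-seed PSD check so a rejection can name the offending fingerprint.
        for i, roi in enumerate(self.seed_rois):
            idx = [i] + list(range(n_seeds, n))
            sub = corr[np.ix_(idx, idx)]
            if np.linalg.eigvalsh(sub).min() < -1e-10:
                raise ValueError(
                    f"fingerprint for seed {roi.label!r} implies a non-positive-semi-definite "
                    f"signal covariance; adjust the planted correlations"
                )
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            raise ValueError(
                "combined seed/target correlation matrix is not positive semi-definite; "
                "adjust seed_seed_corr/target_target_corr or the planted fingerprints"
            )
        return corr


@dataclass
class ScanTimeseries:
    """ROI-level time courses and confounds for one scan (run)."""

    species_label: str
    animal: int
    run: int
    table: pd.DataFrame       # T rows x (seeds + targets) columns
    confounds: pd.DataFrame   # T rows x 7 columns (drift + 6 motion-like)


def _ar1(rng: np.random.Generator, n_samples: int, n_series: int, phi: float,
         chol: np.ndarray | None = None) -> np.ndarray:
    """Unit-variance stationary AR(1) series, optionally cross-correlated.

    With identical ``phi`` across series, filtering innovations of correlation
    C leaves the lag-0 cross-correlation exactly C.
    """
    total = n_samples + _AR1_BURN_IN
    e = rng.standard_normal((total, n_series))
    if chol is not None:
        e = e @ chol.T
    if phi > 0:
        x = sp_signal.lfilter([1.0], [1.0, -phi], e, axis=0)
        x = x * np.sqrt(1.0 - phi ** 2)
    else:
        x = e
    return x[_AR1_BURN_IN:]


def _confound_table(rng: np.random.Generator, n_volumes: int, tr_seconds: float) -> pd.DataFrame:
    """One slow sinusoidal drift plus six smooth motion-like regressors.

    Mirrors the six rigid-body motion parameters a volume-registration step
    would store.  Motion-like columns are heavily smoothed white noise,
    standardized; the drift completes half a cycle over the scan.
    """
    t = np.arange(n_volumes) * tr_seconds
    drift = np.sin(np.pi * t / t[-1]) if n_volumes > 1 else np.zeros(1)
    cols = {"drift": drift}
    for k in range(6):
        raw = gaussian_filter1d(rng.standard_normal(n_volumes), sigma=15.0, mode="reflect")
        sd = raw.std()
        cols[f"motion_{k}"] = raw / sd if sd > 0 else raw
    return pd.DataFrame(cols)


def _scan_rngs(spec: SyntheticSpec) -> list[np.random.Generator]:
    root = np.random.SeedSequence(spec.rng_seed)
    return [np.random.default_rng(child) for child in root.spawn(spec.n_scans)]


def _scan_signals(spec: SyntheticSpec, rng: np.random.Generator) -> tuple[np.ndarray, pd.DataFrame]:
    """Observed ROI series (T x regions) and the confound table for one scan."""
    n_regions = len(spec.region_labels)
    # Cholesky with a tiny jitter so exactly-singular planted matrices
    # (e.g. |r| -> 1) still factor; jitter is below recoverable precision.
    corr = spec.correlation_matrix + 1e-12 * np.eye(n_regions)
    chol = np.linalg.cholesky(corr)
    latent = spec.signal_sd * _ar1(rng, spec.n_volumes, n_regions, spec.ar1_phi, chol=chol)
    noise = spec.noise_sd * _ar1(rng, spec.n_volumes, n_regions, spec.ar1_phi)
    observed = latent + noise
    confounds = _confound_table(rng, spec.n_volumes, spec.tr_seconds)
    if spec.confound_amplitude > 0:
        loadings = rng.standard_normal((confounds.shape[1], n_regions))
        observed = observed + spec.confound_amplitude * (confounds.to_numpy() @ loadings)
    return observed, confounds


def generate_roi_timeseries(spec: SyntheticSpec) -> list[ScanTimeseries]:
    """Generate per-scan ROI time-course tables for one species.

    Returns one :class:`ScanTimeseries` per (animal, run), each with a
    T x (n_seeds + 8) table in region order and the scan's confound table.
    Identical spec + rng_seed reproduces identical output.
    """
    scans = []
    rngs = _scan_rngs(spec)
    i = 0
    for animal in range(spec.n_animals):
        for run in range(spec.runs_per_animal):
            observed, confounds = _scan_signals(spec, rngs[i])
            table = pd.DataFrame(observed, columns=spec.region_labels)
            scans.append(ScanTimeseries(spec.species_label, animal, run, table, confounds))
            i += 1
    return scans


def generate_volumes(spec: SyntheticSpec) -> Iterator[tuple[VolumeSeries, ScanTimeseries]]:
    """Generate full 4D volumes, one scan at a time.

    Voxels inside an ROI cube carry that ROI's observed time course plus
    independent white voxel noise (``voxel_noise_sd``); voxels outside all
    ROIs carry pure voxel noise.  Yields ``(VolumeSeries, ScanTimeseries)``
    pairs lazily to bound memory.
    """
    affine = spec.affine
    memberships = [
        (roi, roi.voxel_indices(spec.grid_shape, affine))
        for roi in [*spec.seed_rois, *spec.target_rois]
    ]
    rngs = _scan_rngs(spec)
    i = 0
    for animal in range(spec.n_animals):
        for run in range(spec.runs_per_animal):
            rng = rngs[i]
            observed, confounds = _scan_signals(spec, rng)
            scan = ScanTimeseries(spec.species_label, animal, run,
                                  pd.DataFrame(observed, columns=spec.region_labels),
                                  confounds)
            shape4 = (*spec.grid_shape, spec.n_volumes)
            if spec.voxel_noise_sd > 0:
                data = spec.voxel_noise_sd * rng.standard_normal(shape4)
            else:
                data = np.zeros(shape4)
            for k, (roi, vox) in enumerate(memberships):
                data[vox[:, 0], vox[:, 1], vox[:, 2], :] += observed[:, k]
            vol = VolumeSeries(data=data, affine=affine, tr_seconds=spec.tr_seconds,
                               space_label=spec.seed_rois[0].space_label if spec.seed_rois else "")
            yield vol, scan
            i += 1


def make_species_spec(species_label: str,
                      fingerprints: Mapping[str, Sequence[float]],
                      *,
                      target_labels: Sequence[str] = ("M1", "Ins", "S1", "PCC", "PPC",
                                                      "Str", "Pul", "SC"),
                      voxel_mm: float = 0.5,
                      grid_shape: tuple[int, int, int] = (24, 24, 24),
                      edge_mm: float = 1.5,
                      **kwargs) -> SyntheticSpec:
    """Convenience constructor: lay seed + target cubes on a regular lattice.

    Cubes are spaced so they never overlap; the caller supplies only the
    planted fingerprints (seed label -> 8 correlations in canonical target
    order) and any :class:`SyntheticSpec` overrides.
    """
    seed_labels = list(fingerprints)
    n_rois = len(seed_labels) + len(target_labels)
    # lattice pitch: cube edge plus one voxel of clearance
    pitch_vox = int(np.ceil(edge_mm / voxel_mm)) + 1
    per_axis = min(grid_shape) // pitch_vox
    if per_axis < 1 or per_axis ** 3 < n_rois:
        raise ValueError(
            f"grid {grid_shape} too small for {n_rois} non-overlapping cubes of {edge_mm} mm"
        )
    centers = []
    for idx in range(n_rois):
        i, rem = divmod(idx, per_axis * per_axis)
        j, k = divmod(rem, per_axis)
        vox_center = (np.array([i, j, k]) * pitch_vox) + pitch_vox / 2.0
        centers.append(tuple(vox_center * voxel_mm))
    space = f"{species_label}_space"
    seeds = [ROISpec(lbl, "seed", space, centers[n], edge_mm)
             for n, lbl in enumerate(seed_labels)]
    targets = [ROISpec(lbl, "target", space, centers[len(seed_labels) + n], edge_mm)
               for n, lbl in enumerate(target_labels)]
    return SyntheticSpec(species_label=species_label, seed_rois=seeds, target_rois=targets,
                         ground_truth_fingerprints=dict(fingerprints),
                         voxel_mm=voxel_mm, grid_shape=tuple(grid_shape), **kwargs)
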