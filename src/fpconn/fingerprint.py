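"""Interareal connectivity fingerprints and their cosine comparison.

A fingerprint is the ordered vector of a seed's FC values with eight canonical
target regions — five cortical (primary motor M1, insula Ins, primary
somatosensory S1, posterior cingulate PCC, posterior parietal PPC) and three
subcortical (striatum Str, pulvinar Pul, superior colliculus SC).  Fingerprints
are min-max normalized to [0, 1] per seed (0 = weakest, 1 = strongest
connection among the eight targets), making the *pattern* comparable across
species whose absolute FC levels differ.  Pattern similarity is the cosine of
the angle between two normalized fingerprints; with nonnegative normalized
entries it lies in [0, 1].

The target order is pinned package-wide (:data:`CANONICAL_TARGETS`) and stored
in every fingerprint file: cosine comparability requires applying one fixed
order to both vectors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

from .connectivity import FCMap
from .rois import ROISpec

if TYPE_CHECKING:  # pragma: no cover
    from .permutation import PermutationResult

__all__ = [
    "CANONICAL_TARGETS",
    "Fingerprint",
    "SimilarityMatrix",
    "extract_fingerprint",
    "normalize_fingerprint",
    "cosine_similarity",
    "build_similarity_matrix",
    "translation_sweep",
    "write_fingerprints",
    "read_fingerprints",
]

logger = logging.getLogger(__name__)

#: Canonical target order used for every fingerprint in the package.
CANONICAL_TARGETS = ("M1", "Ins", "S1", "PCC", "PPC", "Str", "Pul", "SC")


@dataclass(frozen=True)
class Fingerprint:
    seed_label: str
    species_label: str
    values: np.ndarray                # length 8, canonical order
    level: str = "group"              # 'scan' | 'group'
    normalized: bool = False
    target_labels: tuple[str, ...] = CANONICAL_TARGETS

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.target_labels),):
            raise ValueError(
                f"fingerprint for {self.seed_label!r} must have {len(self.target_labels)} "
                f"entries, got shape {v.shape}"
            )
        if self.normalized:
            finite = v[np.isfinite(v)]
            if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
                raise ValueError("normalized fingerprint entries must lie in [0, 1]")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=list(self.target_labels))


def extract_fingerprint(fc: FCMap, targets: Sequence[ROISpec] | None = None) -> Fingerprint:
    """Build a raw fingerprint from an FC map.

    ROI-mode maps (a value per target) are reordered into canonical target
    order.  Voxel-mode maps require the eight target ROI definitions; each
    entry is the mean z over the target's member voxels, with missing voxels
    averaged over and logged.
    """
    if fc.is_map:
        if targets is None or len(targets) != 8:
            raise ValueError("voxel-mode extraction requires the 8 target ROIs")
        by_label = {t.label: t for t in targets}
        unknown = set(by_label) - set(CANONICAL_TARGETS)
        if unknown:
            raise ValueError(f"unknown target labels {sorted(unknown)}; "
                             f"expected {list(CANONICAL_TARGETS)}")
        vals = []
        grid = np.asarray(fc.values, dtype=float)
        for label in CANONICAL_TARGETS:
            if label not in by_label:
                raise ValueError(f"target {label!r} missing from supplied ROI set")
            vox = by_label[label].voxel_indices(grid.shape, fc.affine)
            v = grid[vox[:, 0], vox[:, 1], vox[:, 2]]
            n_missing = int(np.count_nonzero(~np.isfinite(v)))
            if n_missing == v.size:
                raise ValueError(f"target {label!r}: no finite FC values among its voxels")
            if n_missing:
                logger.info("target %s: %d/%d voxels missing from FC map", label,
                            n_missing, v.size)
            vals.append(float(np.nanmean(v)))
        values = np.array(vals)
    else:
        series = pd.Series(fc.values)
        missing = [t for t in CANONICAL_TARGETS if t not in series.index]
        if missing:
            raise ValueError(f"FC map lacks target(s) {missing}")
        values = series.reindex(list(CANONICAL_TARGETS)).to_numpy(dtype=float)
    return Fingerprint(seed_label=fc.seed_label, species_label=fc.species_label,
                       values=values, level=fc.level, normalized=False)


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(v)), float(np.max(v))
    if hi == lo:
        raise ValueError("constant fingerprint cannot be min-max normalized "
                         "(no direction information)")
    return (v - lo) / (hi - lo)


def normalize_fingerprint(fp: Fingerprint) -> Fingerprint:
    """Min-max normalize: weakest target -> 0, strongest -> 1.

    Idempotent on already-normalized vectors; ties at the extremes are kept
    (several 0s or 1s are allowed).  Constant fingerprints are rejected.
    """
    if not np.all(np.isfinite(fp.values)):
        raise ValueError(f"fingerprint for {fp.seed_label!r} has non-finite entries")
    return replace(fp, values=_minmax(fp.values), normalized=True)


def cosine_similarity(a: np.ndarray | Fingerprint, b: np.ndarray | Fingerprint) -> float:
    """Cosine of the angle between two fingerprint vectors.

    Symmetric and invariant to positive rescaling of either argument;
    equals 1 iff the vectors are positive multiples of each other.
    """
    va = a.values if isinstance(a, Fingerprint) else np.asarray(a, dtype=float)
    vb = b.values if isinstance(b, Fingerprint) else np.asarray(b, dtype=float)
    if va.shape != vb.shape:
        raise ValueError(f"shape mismatch: {va.shape} vs {vb.shape}")
    na = float(np.linalg.norm(va))
    nb = float(np.linalg.norm(vb))
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(va @ vb / (na * nb))


@dataclass
class SimilarityMatrix:
    """All-pairs cosine similarities between two species' seed fingerprints."""

    species_a: str
    species_b: str
    cosine: pd.DataFrame                       # rows = seeds of A, cols = seeds of B
    significant: pd.DataFrame | None = None    # boolean, same shape
    permutation_results: dict[tuple[str, str], "PermutationResult"] = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return int(self.cosine.size)

    def threshold_counts(self, threshold: float = 0.75) -> dict[str, int]:
        """Cells strictly below / at-or-above a similarity threshold, and
        significant cells (when permutation results are attached)."""
        vals = self.cosine.to_numpy()
        below = int((vals < threshold).sum())
        counts = {"below": below, "above_or_equal": int(vals.size) - below,
                  "total": int(vals.size)}
        if self.significant is not None:
            counts["significant"] = int(self.significant.to_numpy().sum())
        return counts


def build_similarity_matrix(fps_a: Sequence[Fingerprint],
                            fps_b: Sequence[Fingerprint]) -> SimilarityMatrix:
    """Cosine similarity of every seed of species A with every seed of B.

    All fingerprints must be normalized group-level vectors in the canonical
    target order.
    """
    for fp in [*fps_a, *fps_b]:
        if not fp.normalized:
            raise ValueError(f"fingerprint {fp.species_label}/{fp.seed_label} is not normalized")
        if fp.target_labels != CANONICAL_TARGETS:
            raise ValueError(f"fingerprint {fp.seed_label!r} uses a non-canonical target order")
    if not fps_a or not fps_b:
        raise ValueError("both species need at least one fingerprint")
    rows = [fp.seed_label for fp in fps_a]
    cols = [fp.seed_label for fp in fps_b]
    mat = np.array([[cosine_similarity(a, b) for b in fps_b] for a in fps_a])
    return SimilarityMatrix(
        species_a=fps_a[0].species_label,
        species_b=fps_b[0].species_label,
        cosine=pd.DataFrame(mat, index=rows, columns=cols),
    )


def translation_sweep(vols: Sequence, seed: ROISpec, targets: Sequence[ROISpec],
                      offsets_mm: Sequence[Sequence[float]]) -> pd.DataFrame:
    """Seed-placement robustness sweep.

    Recomputes the group fingerprint with the seed translated by each offset
    (mm) and reports the cosine similarity of each offset fingerprint with the
    fingerprint at the anatomical centroid (zero offset).  Offsets that push
    the seed outside the grid are skipped with a log entry.

    ``vols`` are preprocessed :class:`~fpconn.volumes.VolumeSeries` scans of
    one species.  Returns a long-format table with one row per retained
    offset: offset coordinates, cosine vs. centroid, and the 8 normalized
    fingerprint entries.
    """
    from .connectivity import group_fc, seed_fc_map

    def fingerprint_at(roi: ROISpec) -> Fingerprint:
        maps = [seed_fc_map(v, roi, species_label=v.space_label) for v in vols]
        return normalize_fingerprint(extract_fingerprint(group_fc(maps), targets))

    center_fp = fingerprint_at(seed)
    rows = []
    for off in offsets_mm:
        roi = seed.translated(off)
        try:
            fp = fingerprint_at(roi)
        except ValueError as exc:
            logger.warning("translation sweep: offset %s skipped (%s)", tuple(off), exc)
            continue
        row = {"offset_x_mm": off[0], "offset_y_mm": off[1], "offset_z_mm": off[2],
               "cosine_vs_centroid": cosine_similarity(fp, center_fp)}
        row.update(dict(zip(CANONICAL_TARGETS, fp.values)))
        rows.append(row)
    return pd.DataFrame(rows)


def write_fingerprints(fps: Sequence[Fingerprint], path: str | Path) -> None:
    """Write fingerprints as TSV: species, seed, level, normalized, then the
    8 canonical target columns."""
    rows = []
    for fp in fps:
        row = {"species": fp.species_label, "seed": fp.seed_label, "level": fp.level,
               "normalized": fp.normalized}
        row.update(dict(zip(fp.target_labels, fp.values)))
        rows.append(row)
    cols = ["species", "seed", "level", "normalized", *CANONICAL_TARGETS]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_fingerprints(path: str | Path) -> list[Fingerprint]:
    df = pd.read_csv(path, sep="\t")
    fps = []
    for row in df.itertuples():
        values = np.array([getattr(row, t) for t in CANONICAL_TARGETS], dtype=float)
        fps.append(Fingerprint(seed_label=str(row.seed), species_label=str(row.species),
                               values=values, level=str(row.level),
                               normalized=bool(row.normalized)))
    return fps
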