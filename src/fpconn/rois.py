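"""Region-of-interest definitions and voxel resolution.

ROIs are either isotropic cubes (center in mm plus edge length) or single
voxels, placed in a named species space.  Cube-to-voxel conversion follows a
pinned rule: a voxel belongs to a cube iff its *center* (in mm, via the image
affine) lies inside the closed cube.  All voxel indices are 0-based.

ROI sets are exchanged as a TSV sidecar with columns
``label, role, space, center_x_mm, center_y_mm, center_z_mm, edge_mm``.
A single-voxel ROI is stored with ``edge_mm = 0``; on resolution it maps to
the voxel whose center is nearest to the stored coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["ROISpec", "read_roi_sidecar", "write_roi_sidecar"]

SIDECAR_COLUMNS = [
    "label",
    "role",
    "space",
    "center_x_mm",
    "center_y_mm",
    "center_z_mm",
    "edge_mm",
]


@dataclass(frozen=True)
class ROISpec:
    """A named seed or target region.

    Parameters
    ----------
    label : str
        Region name (e.g. ``"PPC"`` or ``"Fr3"``).
    role : str
        Either ``"seed"`` or ``"target"``.
    space_label : str
        Name of the species space the mm coordinates live in.
    center_mm : tuple of 3 floats
        Cube center (or single-voxel location) in world mm.
    edge_mm : float
        Cube edge length in mm; ``0`` denotes a single-voxel ROI.
    """

    label: str
    role: str
    space_label: str
    center_mm: tuple[float, float, float]
    edge_mm: float

    def __post_init__(self) -> None:
        if self.role not in ("seed", "target"):
            raise ValueError(f"ROI {self.label!r}: role must be 'seed' or 'target', got {self.role!r}")
        if self.edge_mm < 0:
            raise ValueError(f"ROI {self.label!r}: edge_mm must be >= 0, got {self.edge_mm}")
        if len(self.center_mm) != 3:
            raise ValueError(f"ROI {self.label!r}: center_mm must have 3 coordinates")

    @property
    def is_single_voxel(self) -> bool:
        return self.edge_mm == 0

    def translated(self, offset_mm: Sequence[float]) -> "ROISpec":
        """Return a copy shifted by ``offset_mm`` (3-vector, mm)."""
        cx, cy, cz = self.center_mm
        ox, oy, oz = offset_mm
        return ROISpec(self.label, self.role, self.space_label,
                       (cx + ox, cy + oy, cz + oz), self.edge_mm)

    def voxel_indices(self, shape: Sequence[int], affine: np.ndarray) -> np.ndarray:
        """Resolve to member voxel indices on a grid.

        Parameters
        ----------
        shape : (3,) ints
            Spatial grid shape.
        affine : (4, 4) array
            Voxel-index-to-mm affine of the image.

        Returns
        -------
        (n, 3) int array of 0-based voxel indices.

        Raises
        ------
        ValueError
            If the ROI resolves to zero voxels or extends beyond the grid.
        """
        inv = np.linalg.inv(affine)
        center_vox = (inv @ np.array([*self.center_mm, 1.0]))[:3]
        if self.is_single_voxel:
            idx = np.round(center_vox).astype(int)
            if np.any(idx < 0) or np.any(idx >= np.asarray(shape)):
                raise ValueError(
                    f"ROI {self.label!r}: single voxel {tuple(idx)} outside grid {tuple(shape)}"
                )
            return idx[None, :]

        # Candidate bounding box in voxel space, then exact center-in-cube test
        # in mm.  Assumes an axis-aligned affine for the bounding box; the
        # membership test itself is affine-exact.
        half = self.edge_mm / 2.0
        scales = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
        lo = np.floor(center_vox - half / scales - 1).astype(int)
        hi = np.ceil(center_vox + half / scales + 1).astype(int)
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, np.asarray(shape) - 1)
        if np.any(lo > hi):
            raise ValueError(f"ROI {self.label!r}: cube lies entirely outside grid {tuple(shape)}")
        ii, jj, kk = np.meshgrid(*(np.arange(l, h + 1) for l, h in zip(lo, hi)), indexing="ij")
        vox = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
        centers = vox @ affine[:3, :3].T + affine[:3, 3]
        inside = np.all(np.abs(centers - np.asarray(self.center_mm)) <= half + 1e-9, axis=1)
        members = vox[inside]
        if members.shape[0] == 0:
            raise ValueError(
                f"ROI {self.label!r}: cube (edge {self.edge_mm} mm) resolves to 0 voxels "
                f"at this resolution"
            )
        # Reject cubes that straddle the grid edge: the exact membership set
        # must not touch the clipped bounding box walls when clipping occurred.
        full_lo = np.floor(center_vox - half / scales - 1).astype(int)
        full_hi = np.ceil(center_vox + half / scales + 1).astype(int)
        if np.any(full_lo < -1) or np.any(full_hi > np.asarray(shape)):
            # Recompute membership on the unclipped box to detect truncation.
            n_expected = self._count_unclipped(affine, full_lo, full_hi, half)
            if n_expected != members.shape[0]:
                raise ValueError(
                    f"ROI {self.label!r}: cube extends beyond the grid "
                    f"({members.shape[0]} of {n_expected} member voxels inside)"
                )
        return members

    def _count_unclipped(self, affine: np.ndarray, lo: np.ndarray, hi: np.ndarray,
                         half: float) -> int:
        ii, jj, kk = np.meshgrid(*(np.arange(l, h + 1) for l, h in zip(lo, hi)), indexing="ij")
        vox = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
        centers = vox @ affine[:3, :3].T + affine[:3, 3]
        inside = np.all(np.abs(centers - np.asarray(self.center_mm)) <= half + 1e-9, axis=1)
        return int(inside.sum())


def write_roi_sidecar(rois: Sequence[ROISpec], path: str | Path) -> None:
    """Write an ROI set to the sidecar TSV format."""
    rows = [
        {
            "label": r.label,
            "role": r.role,
            "space": r.space_label,
            "center_x_mm": r.center_mm[0],
            "center_y_mm": r.center_mm[1],
            "center_z_mm": r.center_mm[2],
            "edge_mm": r.edge_mm,
        }
        for r in rois
    ]
    pd.DataFrame(rows, columns=SIDECAR_COLUMNS).to_csv(path, sep="\t", index=False,
                                                       float_format="%.6g")


def read_roi_sidecar(path: str | Path) -> list[ROISpec]:
    """Read an ROI set from the sidecar TSV format."""
    df = pd.read_csv(path, sep="\t")
    missing = set(SIDECAR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"ROI sidecar {path}: missing columns {sorted(missing)}")
    return [
        ROISpec(
            label=str(row.label),
            role=str(row.role),
            space_label=str(row.space),
            center_mm=(float(row.center_x_mm), float(row.center_y_mm), float(row.center_z_mm)),
            edge_mm=float(row.edge_mm),
        )
        for row in df.itertuples()
    ]
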