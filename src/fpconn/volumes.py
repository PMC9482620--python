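"""4D resting-state volume container and NIfTI-1 I/O.

A :class:`VolumeSeries` is the post-registration contract of the pipeline: a
4D scalar array (X, Y, Z, T) with a voxel-to-mm affine, the repetition time
(TR) stored in seconds, a species-space label, and an optional 3D brain mask.
TR round-trips through the NIfTI header (``pixdim[4]``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["VolumeSeries", "load_nifti", "save_nifti"]


@dataclass
class VolumeSeries:
    data: np.ndarray
    affine: np.ndarray
    tr_seconds: float
    space_label: str = ""
    brain_mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"data must be 4D (X,Y,Z,T), got shape {self.data.shape}")
        if self.data.shape[3] < 2:
            raise ValueError(f"need at least 2 time points, got {self.data.shape[3]}")
        if self.tr_seconds <= 0:
            raise ValueError(f"tr_seconds must be positive, got {self.tr_seconds}")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if np.any(self.voxel_mm <= 0):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_mm}")
        if self.brain_mask is not None:
            self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
            if self.brain_mask.shape != self.data.shape[:3]:
                raise ValueError(
                    f"brain_mask shape {self.brain_mask.shape} does not match "
                    f"spatial shape {self.data.shape[:3]}"
                )

    @property
    def voxel_mm(self) -> np.ndarray:
        """Voxel edge lengths in mm (column norms of the affine)."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]


def save_nifti(vol: VolumeSeries, path: str | Path) -> None:
    """Write a VolumeSeries as NIfTI-1 with TR in pixdim[4]."""
    img = nib.Nifti1Image(vol.data.astype(np.float32), vol.affine)
    img.header.set_zooms((*vol.voxel_mm, vol.tr_seconds))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def load_nifti(path: str | Path, space_label: str = "",
               brain_mask: np.ndarray | None = None) -> VolumeSeries:
    """Read a 4D NIfTI-1 file into a VolumeSeries (TR from pixdim[4])."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D image, got shape {data.shape}")
    zooms = img.header.get_zooms()
    tr = float(zooms[3]) if len(zooms) > 3 else 0.0
    if tr <= 0:
        raise ValueError(f"{path}: no repetition time in header (pixdim[4] = {tr})")
    return VolumeSeries(data=data, affine=img.affine, tr_seconds=tr,
                        space_label=space_label, brain_mask=brain_mask)
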