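"""In-scope tail of resting-state preprocessing.

Consumes already-registered 4D volumes and applies, in the pinned canonical
order: isotropic Gaussian spatial smoothing, ordinary-least-squares nuisance
regression, and zero-phase Butterworth band-pass filtering (0.01-0.1 Hz by
default), followed by ROI time-course extraction.  Despiking, motion
correction, skull-stripping and registration are upstream and out of scope.

Filtering and regression operate on T x N matrices, so they apply identically
to voxelwise data (N = voxels) and ROI-level tables (N = regions); ROI-mean
extraction commutes with both by linearity.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import signal as sp_signal

from .rois import ROISpec
from .volumes import VolumeSeries

__all__ = [
    "smooth_gaussian",
    "regress_confounds",
    "bandpass",
    "extract_roi_timeseries",
    "preprocess_series",
    "FWHM_TO_SIGMA",
]

logger = logging.getLogger(__name__)

#: FWHM = 2 sqrt(2 ln 2) sigma for a Gaussian kernel.
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def smooth_gaussian(vol: VolumeSeries, fwhm_mm: float) -> VolumeSeries:
    """Smooth each volume with an isotropic Gaussian of the given FWHM (mm).

    The kernel standard deviation per axis is ``fwhm * FWHM_TO_SIGMA`` in mm,
    converted to voxel units; boundaries are handled by reflection, which
    preserves total image mass.
    """
    if fwhm_mm <= 0:
        raise ValueError(f"fwhm_mm must be positive, got {fwhm_mm}")
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / vol.voxel_mm
    smoothed = ndimage.gaussian_filter(vol.data, sigma=(*sigma_vox, 0.0), mode="reflect")
    return VolumeSeries(data=smoothed, affine=vol.affine, tr_seconds=vol.tr_seconds,
                        space_label=vol.space_label, brain_mask=vol.brain_mask)


def _design_matrix(confounds: pd.DataFrame, add_trend: bool) -> tuple[np.ndarray, list[str]]:
    T = len(confounds)
    cols: list[np.ndarray] = [np.ones(T)]
    names = ["intercept"]
    if add_trend:
        cols.append(np.linspace(-1.0, 1.0, T))
        names.append("linear_trend")
    for name in confounds.columns:
        cols.append(confounds[name].to_numpy(dtype=float))
        names.append(str(name))
    return np.column_stack(cols), names


def regress_confounds(series: np.ndarray, confounds: pd.DataFrame,
                      add_trend: bool = True) -> np.ndarray:
    """OLS residuals of each column of ``series`` on [intercept | trend | confounds].

    Residuals are orthogonal to every regressor.  A rank-deficient design is
    rejected, naming the columns that add no rank.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim == 1:
        series = series[:, None]
    T = series.shape[0]
    if len(confounds) != T:
        raise ValueError(
            f"confound table has {len(confounds)} rows but series has {T} time points"
        )
    if not np.all(np.isfinite(confounds.to_numpy(dtype=float))):
        raise ValueError("confound table contains non-finite entries")
    X, names = _design_matrix(confounds, add_trend)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # greedy scan: columns that do not increase rank are collinear
        bad = []
        kept = np.empty((T, 0))
        for j, name in enumerate(names):
            cand = np.column_stack([kept, X[:, j]])
            if np.linalg.matrix_rank(cand) == kept.shape[1]:
                bad.append(name)
            else:
                kept = cand
        raise ValueError(f"confound design is rank-deficient; collinear columns: {bad}")
    beta, *_ = np.linalg.lstsq(X, series, rcond=None)
    return series - X @ beta


def bandpass(series: np.ndarray, tr_seconds: float,
             low_hz: float = 0.01, high_hz: float = 0.1) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the time axis (axis 0).

    A 4th-order Butterworth design applied forward and backward
    (``sosfiltfilt``) so the filter introduces no phase lag that would distort
    correlations.  ``low_hz = 0`` degrades gracefully to a low-pass.
    """
    if tr_seconds <= 0:
        raise ValueError(f"tr_seconds must be positive, got {tr_seconds}")
    nyquist = 0.5 / tr_seconds
    if not (0 <= low_hz < high_hz):
        raise ValueError(f"need 0 <= low_hz < high_hz, got [{low_hz}, {high_hz}]")
    if high_hz >= nyquist:
        raise ValueError(
            f"high_hz = {high_hz} Hz is at or above the Nyquist frequency "
            f"{nyquist:.6g} Hz for TR = {tr_seconds} s"
        )
    series = np.asarray(series, dtype=float)
    if low_hz > 0:
        sos = sp_signal.butter(4, [low_hz, high_hz], btype="bandpass", fs=1.0 / tr_seconds,
                               output="sos")
    else:
        sos = sp_signal.butter(4, high_hz, btype="lowpass", fs=1.0 / tr_seconds, output="sos")
    out = sp_signal.sosfiltfilt(sos, series, axis=0)
    if low_hz == 0:
        out = out - out.mean(axis=0, keepdims=True)  # DC removal for the low-pass case
    return out


def extract_roi_timeseries(vol: VolumeSeries, roi: ROISpec) -> np.ndarray:
    """Mean time course across the ROI's member voxels (T-vector).

    Single-voxel ROIs return that voxel's series exactly; cubes average their
    member voxels with equal weight.  ROIs outside the grid or resolving to
    zero voxels are rejected (never silently clipped).
    """
    vox = roi.voxel_indices(vol.shape[:3], vol.affine)
    if vol.brain_mask is not None:
        inside = vol.brain_mask[vox[:, 0], vox[:, 1], vox[:, 2]]
        n_dropped = int((~inside).sum())
        if n_dropped:
            logger.info("ROI %s: %d of %d voxels outside brain mask", roi.label,
                        n_dropped, len(vox))
        vox = vox[inside]
        if vox.shape[0] == 0:
            raise ValueError(f"ROI {roi.label!r}: all member voxels fall outside the brain mask")
    return vol.data[vox[:, 0], vox[:, 1], vox[:, 2], :].mean(axis=0)


def preprocess_series(series: np.ndarray, tr_seconds: float,
                      confounds: pd.DataFrame | None = None,
                      low_hz: float = 0.01, high_hz: float = 0.1,
                      add_trend: bool = True) -> np.ndarray:
    """Canonical ROI-mode preprocessing: confound regression then band-pass."""
    series = np.asarray(series, dtype=float)
    if confounds is not None:
        series = regress_confounds(series, confounds, add_trend=add_trend)
    return bandpass(series, tr_seconds, low_hz=low_hz, high_hz=high_hz)
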