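"""Seed-based functional connectivity.

Functional connectivity between a seed and a target is the Pearson
product-moment correlation of their time courses, mapped through the Fisher
r-to-z transform (arctanh) so that values can be averaged across scans.
Group-level maps are the unweighted across-scan mean of scan-level z values
(fixed effects over scans); a one-sample t-based alternative and a two-stage
run->animal->group aggregation are available as options.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import extract_roi_timeseries
from .rois import ROISpec
from .volumes import VolumeSeries

__all__ = ["FCMap", "pearson_r", "fisher_z", "seed_fc_table", "seed_fc_map", "group_fc"]

logger = logging.getLogger(__name__)

#: |r| is clamped to this bound before arctanh so z stays finite.
R_CLAMP = 1.0 - 1e-7


@dataclass
class FCMap:
    """Fisher-z connectivity of one seed: an ROI-level vector or a 3D map."""

    values: pd.Series | np.ndarray
    seed_label: str
    species_label: str
    level: str = "scan"            # 'scan' | 'group'
    n_scans_aggregated: int = 1
    affine: np.ndarray | None = None   # set for 3D map mode

    @property
    def is_map(self) -> bool:
        return isinstance(self.values, np.ndarray) and self.values.ndim == 3


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation of two time series.

    Rejects series shorter than 3 points and zero-variance inputs, naming the
    constant series.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be 1-D of equal length, got {x.shape} and {y.shape}")
    if x.size < 3:
        raise ValueError(f"need at least 3 time points, got {x.size}")
    xd = x - x.mean()
    yd = y - y.mean()
    ssx = xd @ xd
    ssy = yd @ yd
    if ssx == 0 or ssy == 0:
        which = "first" if ssx == 0 else "second"
        raise ValueError(f"the {which} series is constant (zero variance)")
    # single sqrt of the product keeps r exactly +/-1 for (anti)identical series
    return float(np.clip((xd @ yd) / np.sqrt(ssx * ssy), -1.0, 1.0))


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """Fisher r-to-z transform, arctanh(r), clamping |r| to 1 - 1e-7.

    Clamps are logged; the transform is odd and strictly increasing.
    """
    r = np.asarray(r, dtype=float)
    n_clamped = int(np.count_nonzero(np.abs(r) > R_CLAMP))
    if n_clamped:
        logger.warning("fisher_z: clamped %d correlation(s) with |r| > %.7f", n_clamped, R_CLAMP)
    z = np.arctanh(np.clip(r, -R_CLAMP, R_CLAMP))
    return float(z) if z.ndim == 0 else z


def seed_fc_table(roi_table: pd.DataFrame, seed_label: str,
                  target_labels: Sequence[str], species_label: str = "") -> FCMap:
    """Scan-level seed FC against named target columns of an ROI table.

    The table holds preprocessed time courses (one column per region).  Each
    target's value is the Fisher z of its Pearson correlation with the seed
    column; a constant target yields a missing value with a logged count.
    """
    if seed_label not in roi_table.columns:
        raise ValueError(f"seed column {seed_label!r} not present in ROI table")
    seed = roi_table[seed_label].to_numpy(dtype=float)
    values = {}
    n_missing = 0
    for t in target_labels:
        if t not in roi_table.columns:
            raise ValueError(f"target column {t!r} not present in ROI table")
        y = roi_table[t].to_numpy(dtype=float)
        if np.ptp(y) == 0 or np.ptp(seed) == 0:
            values[t] = np.nan
            n_missing += 1
            continue
        values[t] = fisher_z(pearson_r(seed, y))
    if n_missing:
        logger.warning("seed %s: %d constant target series set to missing", seed_label, n_missing)
    return FCMap(values=pd.Series(values, index=list(target_labels)),
                 seed_label=seed_label, species_label=species_label, level="scan")


def seed_fc_map(vol: VolumeSeries, seed: ROISpec, species_label: str = "") -> FCMap:
    """Scan-level voxelwise seed FC map (Fisher z) from a preprocessed volume.

    Voxels outside the brain mask (when present) are NaN; constant voxels are
    set to missing with a logged count.
    """
    seed_series = extract_roi_timeseries(vol, seed)
    if np.ptp(seed_series) == 0:
        raise ValueError(f"seed {seed.label!r}: mean time course is constant")
    X, Y, Z, T = vol.shape
    flat = vol.data.reshape(-1, T)
    if vol.brain_mask is not None:
        in_mask = vol.brain_mask.reshape(-1)
    else:
        in_mask = np.ones(flat.shape[0], dtype=bool)
    sd = seed_series - seed_series.mean()
    sd_norm = np.sqrt(sd @ sd)
    vd = flat - flat.mean(axis=1, keepdims=True)
    v_norm = np.sqrt((vd ** 2).sum(axis=1))
    valid = in_mask & (v_norm > 0)
    n_const = int(np.count_nonzero(in_mask & (v_norm == 0)))
    if n_const:
        logger.warning("seed %s: %d constant voxel series set to missing", seed.label, n_const)
    r = np.full(flat.shape[0], np.nan)
    r[valid] = (vd[valid] @ sd) / (v_norm[valid] * sd_norm)
    z = np.full(flat.shape[0], np.nan)
    z[valid] = fisher_z(np.clip(r[valid], -1.0, 1.0))
    return FCMap(values=z.reshape(X, Y, Z), seed_label=seed.label,
                 species_label=species_label, level="scan", affine=vol.affine.copy())


def _aggregate(stack: np.ndarray, stat: str) -> np.ndarray:
    """Across-scan aggregation on axis 0, NaN-aware.

    ``mean_z``: plain mean over present values.  ``t_z``: one-sample t across
    scans mapped through the t CDF to a standard normal deviate.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        if stat == "mean_z":
            return np.nanmean(stack, axis=0)
        n = np.sum(np.isfinite(stack), axis=0)
        if np.any(n[np.any(np.isfinite(stack), axis=0)] < 2):
            raise ValueError("t_z aggregation needs >= 2 scans per target/voxel")
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1)
        t = mean / (sd / np.sqrt(n))
        from scipy import stats as sp_stats
        z = sp_stats.norm.ppf(sp_stats.t.cdf(t, df=n - 1))
        return np.clip(z, -8.2, 8.2)  # keep the deviate finite at extreme t


def group_fc(scan_maps: Sequence[FCMap], stat: str = "mean_z",
             animal_ids: Sequence | None = None) -> FCMap:
    """Aggregate scan-level Fisher-z maps to a group map.

    The default statistic (``stat="mean_z"``) is the unweighted across-scan
    mean of Fisher-z values (scan-level fixed effects).  ``stat="t_z"``
    instead converts the one-sample t statistic across scans to a standard
    normal deviate (the "t-to-z" group map reading); it requires >= 2 scans.
    With ``animal_ids`` (one id per scan) aggregation is two-stage: scans are
    first averaged within animal, then the chosen statistic is applied across
    animal means.

    All inputs must share seed, species, and grid/target layout.  Targets or
    voxels missing in some scans are averaged over the scans where they are
    present, with a logged count.
    """
    if stat not in ("mean_z", "t_z"):
        raise ValueError(f"stat must be 'mean_z' or 't_z', got {stat!r}")
    if len(scan_maps) == 0:
        raise ValueError("need at least one scan-level FC map")
    if animal_ids is not None:
        if len(animal_ids) != len(scan_maps):
            raise ValueError("animal_ids must give one id per scan map")
        n_total = len(scan_maps)
        by_animal: dict = {}
        for aid, m in zip(animal_ids, scan_maps):
            by_animal.setdefault(aid, []).append(m)
        scan_maps = [group_fc(maps, stat="mean_z") for maps in by_animal.values()]
        out = group_fc(scan_maps, stat=stat)
        out.n_scans_aggregated = n_total
        return out
    first = scan_maps[0]
    for m in scan_maps[1:]:
        if m.seed_label != first.seed_label or m.species_label != first.species_label:
            raise ValueError(
                f"cannot aggregate maps of different seeds/species: "
                f"({first.species_label}, {first.seed_label}) vs ({m.species_label}, {m.seed_label})"
            )
        if m.is_map != first.is_map:
            raise ValueError("cannot mix ROI-level and voxel-level FC maps")
    if first.is_map:
        stack = np.stack([np.asarray(m.values, dtype=float) for m in scan_maps])
        if any(np.asarray(m.values).shape != stack.shape[1:] for m in scan_maps):
            raise ValueError("cannot aggregate maps on different grids")
        values: pd.Series | np.ndarray = _aggregate(stack, stat)
    else:
        frame = pd.concat([pd.Series(m.values) for m in scan_maps], axis=1)
        if any(not pd.Series(m.values).index.equals(frame.index) for m in scan_maps):
            raise ValueError("cannot aggregate ROI-level maps with different target sets")
        n_partial = int((frame.isna().any(axis=1) & frame.notna().any(axis=1)).sum())
        if n_partial:
            logger.info("group_fc %s: %d targets missing in some scans", first.seed_label,
                        n_partial)
        values = pd.Series(_aggregate(frame.to_numpy(dtype=float).T, stat),
                           index=frame.index)
    return FCMap(values=values, seed_label=first.seed_label, species_label=first.species_label,
                 level="group", n_scans_aggregated=len(scan_maps),
                 affine=first.affine)
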