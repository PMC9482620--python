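"""End-to-end study orchestration.

Drives the full analysis from a single YAML/JSON config: load scans (ROI-level
tables or 4D volumes), preprocess, compute scan-level seed FC, aggregate to
group fingerprints, normalize, compare every species pair by cosine
similarity, and attach per-cell permutation decisions.  All outputs are plain
text (TSV/JSON); a manifest records every file with a SHA-256 hash and a run
log records every pinned analysis decision, so a rerun with the same config
and seed reproduces byte-identical outputs.

Seed derivation: one top-level ``rng_seed`` in the config; the per-cell
permutation seed is drawn from ``numpy.random.SeedSequence(rng_seed,
spawn_key=(pair_index, row, col))``, reduced below 2**31.  This makes every
cell's null reproducible in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from .connectivity import group_fc, seed_fc_table
from .fingerprint import (
    CANONICAL_TARGETS,
    Fingerprint,
    SimilarityMatrix,
    build_similarity_matrix,
    extract_fingerprint,
    normalize_fingerprint,
    write_fingerprints,
)
from .permutation import permutation_test
from .preprocess import bandpass, extract_roi_timeseries, regress_confounds, smooth_gaussian
from .rois import read_roi_sidecar
from .volumes import load_nifti

__all__ = ["StudyConfig", "SpeciesConfig", "ScanInput", "run_pipeline",
           "report_threshold_counts", "derive_cell_seed"]

logger = logging.getLogger(__name__)


@dataclass
class ScanInput:
    """One scan: either an ROI-level time-series table or a 4D volume."""

    roi_table: Path | None = None
    volume: Path | None = None
    confounds: Path | None = None
    animal: str | None = None   # used by two-stage aggregation / animal-block shuffling

    def validate(self, label: str) -> None:
        if (self.roi_table is None) == (self.volume is None):
            raise ValueError(f"scan in species {label!r}: give exactly one of roi_table/volume")
        for p in (self.roi_table, self.volume, self.confounds):
            if p is not None and not Path(p).exists():
                raise ValueError(f"scan in species {label!r}: path {p} does not exist")


@dataclass
class SpeciesConfig:
    label: str
    seeds: list[str]
    scans: list[ScanInput]
    roi_sidecar: Path | None = None   # required for volume-mode scans

    def validate(self) -> None:
        if not self.seeds:
            raise ValueError(f"species {self.label!r}: no seed labels")
        if not self.scans:
            raise ValueError(f"species {self.label!r}: no scans")
        for scan in self.scans:
            scan.validate(self.label)
        if any(s.volume is not None for s in self.scans):
            if self.roi_sidecar is None or not Path(self.roi_sidecar).exists():
                raise ValueError(f"species {self.label!r}: volume-mode scans need an roi_sidecar")


@dataclass
class StudyConfig:
    species: list[SpeciesConfig]
    output_dir: Path
    rng_seed: int = 0
    fwhm_mm: float = 1.0
    low_hz: float = 0.01
    high_hz: float = 0.1
    detrend: bool = True
    tr_seconds: float = 1.5   # used for ROI-table scans; volumes carry TR in the header
    n_iterations: int = 10_000
    similarity_threshold: float = 0.75
    target_order: tuple[str, ...] = CANONICAL_TARGETS
    save_null: bool = False
    group_stat: str = "mean_z"        # 'mean_z' (default) | 't_z'
    two_stage: bool = False           # run -> animal -> group aggregation
    fdr: bool = False                 # Benjamini-Hochberg across matrix cells
    exchange_block: str | None = None  # None | 'animal'

    def validate(self) -> None:
        labels = [s.label for s in self.species]
        if len(set(labels)) != len(labels):
            raise ValueError(f"species labels are not unique: {labels}")
        if len(self.target_order) != 8:
            raise ValueError(f"target order must list exactly 8 labels, got {self.target_order}")
        if self.group_stat not in ("mean_z", "t_z"):
            raise ValueError(f"group_stat must be 'mean_z' or 't_z', got {self.group_stat!r}")
        if self.exchange_block not in (None, "animal"):
            raise ValueError(f"exchange_block must be None or 'animal', got {self.exchange_block!r}")
        for sp in self.species:
            sp.validate()

    @classmethod
    def from_file(cls, path: str | Path) -> "StudyConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) if path.suffix in (".yaml", ".yml") else json.load(fh)
        return cls.from_dict(raw, base_dir=path.parent)

    @classmethod
    def from_dict(cls, raw: dict[str, Any], base_dir: Path = Path(".")) -> "StudyConfig":
        def _p(v: Any) -> Path | None:
            if v is None:
                return None
            p = Path(v)
            return p if p.is_absolute() else base_dir / p

        species = []
        for sp in raw.get("species", []):
            scans = [
                ScanInput(roi_table=_p(s.get("roi_table")), volume=_p(s.get("volume")),
                          confounds=_p(s.get("confounds")),
                          animal=s.get("animal"))
                for s in sp.get("scans", [])
            ]
            species.append(SpeciesConfig(label=str(sp["label"]), seeds=list(sp["seeds"]),
                                         scans=scans, roi_sidecar=_p(sp.get("roi_sidecar"))))
        pre = raw.get("preprocessing", {})
        perm = raw.get("permutation", {})
        cfg = cls(
            species=species,
            output_dir=_p(raw["output_dir"]),
            rng_seed=int(raw.get("rng_seed", 0)),
            fwhm_mm=float(pre.get("fwhm_mm", 1.0)),
            low_hz=float(pre.get("low_hz", 0.01)),
            high_hz=float(pre.get("high_hz", 0.1)),
            detrend=bool(pre.get("detrend", True)),
            tr_seconds=float(pre.get("tr_seconds", 1.5)),
            n_iterations=int(perm.get("n_iterations", 10_000)),
            save_null=bool(perm.get("save_null", False)),
            exchange_block=perm.get("exchange_block"),
            similarity_threshold=float(raw.get("similarity_threshold", 0.75)),
            target_order=tuple(raw.get("target_order", CANONICAL_TARGETS)),
            group_stat=str(raw.get("group_stat", "mean_z")),
            two_stage=bool(raw.get("two_stage", False)),
            fdr=bool(raw.get("fdr", False)),
        )
        cfg.validate()
        return cfg


def derive_cell_seed(root_seed: int, pair_index: int, row: int, col: int) -> int:
    """Per-cell permutation seed from the study seed (documented counter scheme)."""
    ss = np.random.SeedSequence(root_seed, spawn_key=(pair_index, row, col))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _round6(x: float) -> float:
    return float(f"{x:.6g}")


def _json_dump(obj: Any, path: Path) -> None:
    def _default(v: Any) -> Any:
        if isinstance(v, (np.integer,)):
            return int(v)
        if isinstance(v, (np.floating,)):
            return _round6(float(v))
        if isinstance(v, np.ndarray):
            return [_default(x) for x in v]
        raise TypeError(f"not JSON-serializable: {type(v)}")

    def _walk(v: Any) -> Any:
        if isinstance(v, float):
            return _round6(v)
        if isinstance(v, dict):
            return {k: _walk(w) for k, w in v.items()}
        if isinstance(v, (list, tuple)):
            return [_walk(w) for w in v]
        return v

    with open(path, "w") as fh:
        json.dump(_walk(obj), fh, indent=1, default=_default, sort_keys=True)
        fh.write("\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_scan_table(scan: ScanInput, config: StudyConfig,
                     species: SpeciesConfig) -> pd.DataFrame:
    """Load one scan and return the preprocessed ROI time-series table."""
    confounds = None
    if scan.confounds is not None:
        confounds = pd.read_csv(scan.confounds, sep="\t")
    if scan.roi_table is not None:
        table = pd.read_csv(scan.roi_table, sep="\t")
        series = table.to_numpy(dtype=float)
        columns = list(table.columns)
        tr = config.tr_seconds  # ROI tables carry no header; TR comes from the config
    else:
        vol = load_nifti(scan.volume, space_label=species.label)
        vol = smooth_gaussian(vol, config.fwhm_mm)
        X, Y, Z, T = vol.shape
        series = vol.data.reshape(-1, T).T  # T x voxels
        tr = vol.tr_seconds
        if confounds is not None:
            series = regress_confounds(series, confounds, add_trend=config.detrend)
            confounds = None  # already removed voxelwise
        series = bandpass(series, tr, config.low_hz, config.high_hz)
        vol.data = series.T.reshape(X, Y, Z, T)
        rois = read_roi_sidecar(species.roi_sidecar)
        columns = [r.label for r in rois]
        series = np.column_stack([extract_roi_timeseries(vol, r) for r in rois])
        return pd.DataFrame(series, columns=columns)
    if confounds is not None:
        series = regress_confounds(series, confounds, add_trend=config.detrend)
    elif config.detrend:
        series = regress_confounds(series, pd.DataFrame(index=range(series.shape[0])),
                                   add_trend=True)
    series = bandpass(series, tr, config.low_hz, config.high_hz)
    return pd.DataFrame(series, columns=columns)


def _scan_animals(species: SpeciesConfig) -> list[str]:
    """Animal label per scan; scans without one are their own singleton."""
    return [s.animal if s.animal is not None else f"scan{k}"
            for k, s in enumerate(species.scans)]


def _species_fingerprints(species: SpeciesConfig, config: StudyConfig
                          ) -> tuple[list[Fingerprint], dict[str, list[Fingerprint]]]:
    """Group (normalized) and scan-level (raw) fingerprints for one species."""
    tables = [_load_scan_table(scan, config, species) for scan in species.scans]
    animal_ids = _scan_animals(species) if config.two_stage else None
    group_fps: list[Fingerprint] = []
    scan_fps: dict[str, list[Fingerprint]] = {}
    for seed in species.seeds:
        maps = [seed_fc_table(t, seed, config.target_order, species_label=species.label)
                for t in tables]
        scan_fps[seed] = [extract_fingerprint(m) for m in maps]
        agg = group_fc(maps, stat=config.group_stat, animal_ids=animal_ids)
        group_fps.append(normalize_fingerprint(extract_fingerprint(agg)))
    return group_fps, scan_fps


def report_threshold_counts(matrix: SimilarityMatrix, threshold: float = 0.75) -> dict[str, int]:
    """Counts of cells below / at-or-above a cosine threshold (ties count as
    above) plus the number of significant cells when decisions are attached."""
    return matrix.threshold_counts(threshold)


def run_pipeline(config: StudyConfig) -> dict[str, Any]:
    """Run the full study described by ``config``.

    Writes, under ``config.output_dir``: per-species fingerprint TSVs (scan
    level raw + group level normalized), a long-format spider-plot table, one
    similarity TSV + JSON per species pair with per-cell permutation
    decisions, a run log of pinned decisions, and ``manifest.json`` with a
    SHA-256 hash per file.  Returns a summary dict with the similarity
    matrices and threshold counts.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    all_group: dict[str, list[Fingerprint]] = {}
    all_scan: dict[str, dict[str, list[Fingerprint]]] = {}
    long_rows = []
    for sp in config.species:
        group_fps, scan_fps = _species_fingerprints(sp, config)
        all_group[sp.label] = group_fps
        all_scan[sp.label] = scan_fps
        fp_path = out / f"fingerprints_{sp.label}.tsv"
        flat_scans = [fp for fps in scan_fps.values() for fp in fps]
        write_fingerprints([*group_fps, *flat_scans], fp_path)
        written.append(fp_path)
        for fp in group_fps:
            for target, value in zip(fp.target_labels, fp.values):
                long_rows.append({"species": sp.label, "seed": fp.seed_label,
                                  "target": target, "value": value})
    long_path = out / "fingerprints_long.tsv"
    pd.DataFrame(long_rows).to_csv(long_path, sep="\t", index=False, float_format="%.6g")
    written.append(long_path)

    matrices: dict[tuple[str, str], SimilarityMatrix] = {}
    summary: dict[str, Any] = {"pairs": {}}
    pair_index = 0
    labels = [sp.label for sp in config.species]
    sp_by_label = {sp.label: sp for sp in config.species}
    for a_idx in range(len(labels)):
        for b_idx in range(a_idx + 1, len(labels)):
            la, lb = labels[a_idx], labels[b_idx]
            blocks = None
            if config.exchange_block == "animal":
                blocks = ([f"{la}/{a}" for a in _scan_animals(sp_by_label[la])]
                          + [f"{lb}/{a}" for a in _scan_animals(sp_by_label[lb])])
            matrix = build_similarity_matrix(all_group[la], all_group[lb])
            sig = pd.DataFrame(False, index=matrix.cosine.index, columns=matrix.cosine.columns)
            cells = {}
            for i, seed_a in enumerate(matrix.cosine.index):
                for j, seed_b in enumerate(matrix.cosine.columns):
                    cell_seed = derive_cell_seed(config.rng_seed, pair_index, i, j)
                    res = permutation_test(all_scan[la][seed_a], all_scan[lb][seed_b],
                                           n_iterations=config.n_iterations,
                                           rng_seed=cell_seed,
                                           seed_pair=(seed_a, seed_b),
                                           exchange_blocks=blocks)
                    sig.loc[seed_a, seed_b] = res.significant
                    matrix.permutation_results[(seed_a, seed_b)] = res
                    cells[f"{seed_a}|{seed_b}"] = res.to_dict(include_null=config.save_null)
            if config.fdr:
                from statsmodels.stats.multitest import multipletests
                keys = list(cells)
                pvals = [cells[k]["empirical_p"] for k in keys]
                reject, p_adj, *_ = multipletests(pvals, alpha=0.05, method="fdr_bh")
                for k, r, p in zip(keys, reject, p_adj):
                    cells[k]["p_fdr"] = float(p)
                    cells[k]["significant_fdr"] = bool(r)
            matrix.significant = sig
            matrices[(la, lb)] = matrix

            stem = f"similarity_{la}_vs_{lb}"
            tsv_path = out / f"{stem}.tsv"
            matrix.cosine.to_csv(tsv_path, sep="\t", float_format="%.6g")
            written.append(tsv_path)
            counts = report_threshold_counts(matrix, config.similarity_threshold)
            json_path = out / f"{stem}.json"
            _json_dump({
                "species_a": la, "species_b": lb,
                "n_cells": matrix.n_cells,
                "similarity_threshold": config.similarity_threshold,
                "threshold_counts": counts,
                "cells": cells,
            }, json_path)
            written.append(json_path)
            summary["pairs"][f"{la}_vs_{lb}"] = {"n_cells": matrix.n_cells,
                                                 "threshold_counts": counts}
            pair_index += 1

    log_path = out / "run_log.json"
    _json_dump({
        "pinned_decisions": {
            "preprocessing_order": "smooth -> confound regression -> band-pass",
            "bandpass_filter": "Butterworth order 4, zero-phase forward-backward (sosfiltfilt)",
            "bandpass_hz": [config.low_hz, config.high_hz],
            "fwhm_mm": config.fwhm_mm,
            "detrend": config.detrend,
            "smoothing_boundary": "reflect",
            "cube_membership": "voxel center in closed cube, 0-based indices",
            "correlation": "Pearson product-moment",
            "z_transform": "Fisher arctanh, |r| clamped at 1 - 1e-7",
            "aggregation": ("two-stage run->animal->group" if config.two_stage
                            else "unweighted scan-level fixed-effects"),
            "group_stat": config.group_stat,
            "fdr": config.fdr,
            "exchange_block": config.exchange_block,
            "normalization": "min-max per fingerprint, after group averaging",
            "target_order": list(config.target_order),
            "percentile_definition": "lower empirical quantile, 1-based index ceil(q/100*n)",
            "decision_rule": "significant iff observed cosine < null 1st percentile (strict)",
            "n_iterations": config.n_iterations,
            "rng_seed": config.rng_seed,
            "cell_seed_scheme": "SeedSequence(rng_seed, spawn_key=(pair_index, row, col)) % 2^31",
        },
    }, log_path)
    written.append(log_path)

    manifest_path = out / "manifest.json"
    _json_dump({
        "files": {p.name: _sha256(p) for p in sorted(written)},
        "rng_seed": config.rng_seed,
    }, manifest_path)

    summary["matrices"] = matrices
    summary["manifest"] = manifest_path
    summary["output_dir"] = out
    return summary


def simulate_study(specs: Sequence, out_dir: str | Path, *, volumes: bool = False,
                   rng_seed: int = 0, n_iterations: int = 10_000) -> Path:
    """Materialize synthetic species data on disk and write a ready study config.

    ``specs`` are :class:`~fpconn.synthetic.SyntheticSpec` objects, one per
    species.  In ROI mode (default) each scan is written as a time-series TSV
    plus a confound TSV; with ``volumes=True`` each scan is written as a
    NIfTI-1 volume and the species gets an ROI sidecar.  Returns the path of
    the written ``study.yaml``.
    """
    from .rois import write_roi_sidecar
    from .synthetic import generate_roi_timeseries, generate_volumes
    from .volumes import save_nifti

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    species_cfg = []
    for spec in specs:
        sp_dir = out_dir / spec.species_label
        sp_dir.mkdir(exist_ok=True)
        scans_cfg = []
        if volumes:
            sidecar = sp_dir / "rois.tsv"
            write_roi_sidecar([*spec.seed_rois, *spec.target_rois], sidecar)
            for k, (vol, scan) in enumerate(generate_volumes(spec)):
                vol_path = sp_dir / f"scan_{k:02d}.nii.gz"
                conf_path = sp_dir / f"scan_{k:02d}_confounds.tsv"
                save_nifti(vol, vol_path)
                scan.confounds.to_csv(conf_path, sep="\t", index=False, float_format="%.6g")
                scans_cfg.append({"volume": str(vol_path.relative_to(out_dir)),
                                  "confounds": str(conf_path.relative_to(out_dir)),
                                  "animal": f"animal{scan.animal}"})
            entry = {"label": spec.species_label,
                     "seeds": [r.label for r in spec.seed_rois],
                     "roi_sidecar": str(sidecar.relative_to(out_dir)),
                     "scans": scans_cfg}
        else:
            for k, scan in enumerate(generate_roi_timeseries(spec)):
                ts_path = sp_dir / f"scan_{k:02d}_roi.tsv"
                conf_path = sp_dir / f"scan_{k:02d}_confounds.tsv"
                scan.table.to_csv(ts_path, sep="\t", index=False, float_format="%.10g")
                scan.confounds.to_csv(conf_path, sep="\t", index=False, float_format="%.10g")
                scans_cfg.append({"roi_table": str(ts_path.relative_to(out_dir)),
                                  "confounds": str(conf_path.relative_to(out_dir)),
                                  "animal": f"animal{scan.animal}"})
            entry = {"label": spec.species_label,
                     "seeds": [r.label for r in spec.seed_rois],
                     "scans": scans_cfg}
        species_cfg.append(entry)
    config = {
        "output_dir": "results",
        "rng_seed": rng_seed,
        "preprocessing": {"fwhm_mm": 1.0, "low_hz": 0.01, "high_hz": 0.1,
                          "detrend": True, "tr_seconds": float(specs[0].tr_seconds)},
        "permutation": {"n_iterations": n_iterations},
        "species": species_cfg,
    }
    cfg_path = out_dir / "study.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return cfg_path
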