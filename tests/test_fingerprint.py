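"""Fingerprint construction, normalization, cosine comparison, sweeps."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fpconn.connectivity import FCMap, group_fc, seed_fc_table
from fpconn.fingerprint import (CANONICAL_TARGETS, Fingerprint, build_similarity_matrix,
                                cosine_similarity, extract_fingerprint, normalize_fingerprint,
                                read_fingerprints, translation_sweep, write_fingerprints)
from fpconn.rois import ROISpec
from fpconn.synthetic import generate_roi_timeseries, generate_volumes, make_species_spec

RAT_SEEDS = ["FrA", "LO", "MO", "Fr3", "M2"]
SQUIRREL_SEEDS = ["F1", "F2", "F3", "F4", "F5", "F6"]
MARMOSET_SEEDS = ["6VA", "6DR", "8AD", "8AV", "45", "47L", "46D", "46V"]


def _fp(values, seed="s", species="sp", normalized=False, level="group"):
    return Fingerprint(seed_label=seed, species_label=species, values=np.asarray(values),
                       normalized=normalized, level=level)


def _norm_fp(rng, seed="s", species="sp"):
    return normalize_fingerprint(_fp(rng.random(8), seed=seed, species=species))


class TestNormalization:
    def test_affine_map_example(self):
        raw = _fp([2, 4, 6, 3, 5, 2.5, 3.5, 4.5])
        out = normalize_fingerprint(raw)
        np.testing.assert_array_equal(out.values,
                                      [0, 0.5, 1, 0.25, 0.75, 0.125, 0.375, 0.625])
        assert out.normalized

    def test_idempotent_on_normalized_vector(self):
        once = normalize_fingerprint(_fp([0.1, 0.9, 0.4, 1.0, 0.0, 0.3, 0.6, 0.2]))
        twice = normalize_fingerprint(once)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_constant_fingerprint_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normalize_fingerprint(_fp([3.0] * 8))

    def test_ties_at_extremes_are_kept(self):
        out = normalize_fingerprint(_fp([1, 1, 2, 3, 3, 2, 1, 3]))
        assert (out.values == 0).sum() == 3 and (out.values == 1).sum() == 3


class TestCosine:
    def test_identical_vectors_give_one(self):
        v = np.array([0.2, 0.5, 1, 0, 0.3, 0.8, 0.1, 0.9])
        assert cosine_similarity(v, v) == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_unit_vectors_give_zero(self):
        a = np.zeros(8); a[0] = 1
        b = np.zeros(8); b[1] = 1
        assert cosine_similarity(a, b) == 0.0

    def test_matches_explicit_formula(self):
        a = np.zeros(8); a[:2] = 1
        b = np.zeros(8); b[0] = 1
        assert abs(cosine_similarity(a, b) - 1 / np.sqrt(2)) < 1e-12

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            cosine_similarity(np.zeros(8), np.ones(8))

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.0, 1.0), min_size=8, max_size=8),
           st.floats(0.01, 100.0))
    def test_scale_invariance(self, vals, alpha):
        v = np.asarray(vals)
        if v.max() == 0:
            return
        w = np.linspace(0.1, 1.0, 8)
        assert cosine_similarity(alpha * v, w) == pytest.approx(cosine_similarity(v, w),
                                                               abs=1e-9)

    def test_normalized_fingerprints_stay_in_unit_interval(self, rng):
        for _ in range(100):
            c = cosine_similarity(_norm_fp(rng), _norm_fp(rng))
            assert 0.0 <= c <= 1.0

    def test_consistent_reordering_invariant_inconsistent_not(self, rng):
        a, b = rng.random(8) + 0.1, rng.random(8) + 0.1
        perm = rng.permutation(8)
        both = cosine_similarity(a[perm], b[perm])
        assert both == pytest.approx(cosine_similarity(a, b), abs=1e-12)
        one = cosine_similarity(a[perm], b)
        assert abs(one - cosine_similarity(a, b)) > 1e-6  # shuffling one side breaks it


class TestExtraction:
    def test_roi_mode_reorders_into_canonical_order(self):
        scrambled = pd.Series({t: i for i, t in enumerate(reversed(CANONICAL_TARGETS))})
        fc = FCMap(values=scrambled, seed_label="s", species_label="sp")
        fp = extract_fingerprint(fc)
        np.testing.assert_array_equal(fp.values, [7, 6, 5, 4, 3, 2, 1, 0])

    def test_missing_target_rejected_by_name(self):
        fc = FCMap(values=pd.Series({"M1": 0.1}), seed_label="s", species_label="sp")
        with pytest.raises(ValueError, match="Ins"):
            extract_fingerprint(fc)

    def test_map_mode_matches_bruteforce_voxel_means(self, rng, base_fingerprint):
        spec = make_species_spec("sp", {"SEED": base_fingerprint}, rng_seed=4)
        grid = rng.standard_normal(spec.grid_shape)
        fc = FCMap(values=grid, seed_label="SEED", species_label="sp", affine=spec.affine)
        fp = extract_fingerprint(fc, targets=spec.target_rois)
        for i, roi in enumerate(spec.target_rois):
            vox = roi.voxel_indices(spec.grid_shape, spec.affine)
            oracle = np.mean([grid[tuple(v)] for v in vox])
            assert abs(fp.values[i] - oracle) < 1e-12

    def test_constant_map_gives_constant_fingerprint(self, base_fingerprint):
        spec = make_species_spec("sp", {"SEED": base_fingerprint}, rng_seed=4)
        fc = FCMap(values=np.full(spec.grid_shape, 0.7), seed_label="SEED",
                   species_label="sp", affine=spec.affine)
        fp = extract_fingerprint(fc, targets=spec.target_rois)
        np.testing.assert_allclose(fp.values, 0.7)

    def test_partially_missing_target_uses_present_voxels(self, base_fingerprint):
        spec = make_species_spec("sp", {"SEED": base_fingerprint}, rng_seed=4)
        grid = np.full(spec.grid_shape, 0.5)
        vox = spec.target_rois[0].voxel_indices(spec.grid_shape, spec.affine)
        grid[tuple(vox[0])] = np.nan
        fc = FCMap(values=grid, seed_label="SEED", species_label="sp", affine=spec.affine)
        fp = extract_fingerprint(fc, targets=spec.target_rois)
        assert fp.values[0] == pytest.approx(0.5)


class TestSimilarityMatrix:
    def test_species_vs_itself_has_unit_diagonal(self, rng):
        fps = [_norm_fp(rng, seed=f"s{i}") for i in range(4)]
        m = build_similarity_matrix(fps, fps)
        np.testing.assert_allclose(np.diag(m.cosine.to_numpy()), 1.0, atol=1e-12)

    @pytest.mark.parametrize("seeds_a,seeds_b,expected", [
        (RAT_SEEDS, MARMOSET_SEEDS, 40),
        (SQUIRREL_SEEDS, MARMOSET_SEEDS, 48),
        (RAT_SEEDS, SQUIRREL_SEEDS, 30),
    ])
    def test_cell_counts_for_study_seed_sets(self, rng, seeds_a, seeds_b, expected):
        fps_a = [_norm_fp(rng, seed=s, species="A") for s in seeds_a]
        fps_b = [_norm_fp(rng, seed=s, species="B") for s in seeds_b]
        m = build_similarity_matrix(fps_a, fps_b)
        assert m.n_cells == expected
        assert m.cosine.shape == (len(seeds_a), len(seeds_b))

    def test_raw_fingerprints_rejected(self, rng):
        raw = _fp(rng.random(8))
        with pytest.raises(ValueError, match="not normalized"):
            build_similarity_matrix([raw], [_norm_fp(rng)])

    def test_tsv_roundtrip(self, rng, tmp_path):
        fps = [_norm_fp(rng, seed=s, species="X") for s in ("a", "b")]
        path = tmp_path / "fps.tsv"
        write_fingerprints(fps, path)
        back = read_fingerprints(path)
        assert [f.seed_label for f in back] == ["a", "b"]
        for orig, rt in zip(fps, back):
            np.testing.assert_allclose(rt.values, orig.values, atol=5e-7)  # 6 sig digits
            assert rt.normalized


@pytest.fixture(scope="module")
def sweep_material():
    fp = {"SEED": [0.5, 0.2, 0.4, 0.1, 0.3, 0.25, 0.15, 0.35]}
    spec = make_species_spec("sp", fp, n_volumes=250, runs_per_animal=2,
                             noise_sd=0.2, voxel_noise_sd=0.1, rng_seed=21)
    vols = [vol for vol, _ in generate_volumes(spec)]
    return spec, vols


class TestTranslationSweep:
    def test_zero_offset_gives_cosine_one(self, sweep_material):
        spec, vols = sweep_material
        table = translation_sweep(vols, spec.seed_rois[0], spec.target_rois,
                                  [(0.0, 0.0, 0.0)])
        assert table["cosine_vs_centroid"].iloc[0] == pytest.approx(1.0, abs=1e-12)

    def test_within_cube_offsets_barely_move_the_fingerprint(self, sweep_material):
        # the planted signal is constant inside the seed cube, so sub-cube
        # shifts keep most member voxels and the pattern
        spec, vols = sweep_material
        offsets = [(0.5, 0.0, 0.0), (0.0, -0.5, 0.0), (0.0, 0.0, 0.5)]
        table = translation_sweep(vols, spec.seed_rois[0], spec.target_rois, offsets)
        assert len(table) == 3
        assert (table["cosine_vs_centroid"] >= 0.99).all()

    def test_out_of_grid_offsets_are_skipped(self, sweep_material):
        spec, vols = sweep_material
        table = translation_sweep(vols, spec.seed_rois[0], spec.target_rois,
                                  [(0.0, 0.0, 0.0), (100.0, 0.0, 0.0)])
        assert len(table) == 1


class TestMonotoneDegradation:
    def test_estimated_cosine_decreases_with_planted_angle(self, base_fingerprint):
        """As the angle between two species' ground-truth fingerprints grows,
        the mean estimated cosine falls monotonically (Spearman over grid)."""
        from scipy.stats import spearmanr

        base = np.asarray(base_fingerprint)
        # blend toward the pattern with reversed target order: angle grows
        other = base[::-1].copy()
        mixes = [0.0, 0.25, 0.5, 0.75, 1.0]
        mean_cos = []
        for m_idx, w in enumerate(mixes):
            planted_b = (1 - w) * base + w * other
            reps = []
            for rep in range(20):
                cos = _estimated_cosine(base, planted_b, rng_seed=3000 + 100 * m_idx + rep)
                reps.append(cos)
            mean_cos.append(np.mean(reps))
        rho, _ = spearmanr(np.arange(len(mixes)), mean_cos)
        assert rho < 0


def _estimated_cosine(fp_a, fp_b, rng_seed):
    fps = []
    for label, fp, offset in (("A", fp_a, 0), ("B", fp_b, 1)):
        spec = make_species_spec(label, {"SEED": fp}, n_volumes=300, runs_per_animal=3,
                                 noise_sd=0.5, rng_seed=rng_seed + offset)
        scans = generate_roi_timeseries(spec)
        maps = [seed_fc_table(s.table, "SEED", CANONICAL_TARGETS, label) for s in scans]
        fps.append(normalize_fingerprint(extract_fingerprint(group_fc(maps))))
    return cosine_similarity(fps[0], fps[1])
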