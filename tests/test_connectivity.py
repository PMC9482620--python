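"""Pearson r, Fisher z, seed FC, and group aggregation contracts."""

import numpy as np
import pandas as pd
import pytest

from fpconn.connectivity import FCMap, fisher_z, group_fc, pearson_r, seed_fc_map, seed_fc_table
from fpconn.rois import ROISpec
from fpconn.volumes import VolumeSeries


class TestPearson:
    def test_identical_series_gives_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(x, x) == 1.0

    def test_negated_series_gives_minus_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_r(x, -x) == -1.0

    def test_matches_two_pass_definition(self):
        """Oracle: explicit covariance / SD formula."""
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 3.0, 5.0])
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        oracle = cov / (x.std() * y.std())
        assert abs(pearson_r(x, y) - oracle) < 1e-12

    def test_symmetric_in_arguments(self, rng):
        x, y = rng.standard_normal(20), rng.standard_normal(20)
        assert pearson_r(x, y) == pearson_r(y, x)

    @pytest.mark.parametrize("const_first,pattern", [(True, "first"), (False, "second")])
    def test_constant_series_rejected_by_position(self, const_first, pattern):
        c = np.full(10, 3.0)
        v = np.arange(10.0)
        args = (c, v) if const_first else (v, c)
        with pytest.raises(ValueError, match=pattern):
            pearson_r(*args)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="3"):
            pearson_r(np.array([1.0, 2.0]), np.array([2.0, 1.0]))


class TestFisherZ:
    def test_zero_maps_to_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_matches_log_identity(self):
        # arctanh(r) = 0.5 * ln((1+r)/(1-r))
        assert abs(fisher_z(0.5) - 0.5 * np.log(1.5 / 0.5)) < 1e-12

    def test_odd_function(self):
        for r in (0.1, 0.5, 0.9, 0.99):
            assert fisher_z(-r) == -fisher_z(r)

    def test_strictly_increasing(self):
        rs = np.linspace(-0.999, 0.999, 101)
        zs = np.array([fisher_z(r) for r in rs])
        assert np.all(np.diff(zs) > 0)

    def test_clamps_at_unity_and_logs(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            z = fisher_z(1.0)
        assert np.isfinite(z)
        assert z == np.arctanh(1 - 1e-7)
        assert "clamped" in caplog.text


class TestSeedFC:
    def test_self_correlation_yields_clamped_maximum_z(self, rng):
        x = rng.standard_normal(100)
        table = pd.DataFrame({"seed": x, "t1": x})
        fc = seed_fc_table(table, "seed", ["t1"])
        assert fc.values["t1"] == np.arctanh(1 - 1e-7)

    def test_independent_white_noise_near_zero(self, rng):
        # oracle: Fisher-z null SE is 1/sqrt(T-3)
        T = 600
        table = pd.DataFrame({"seed": rng.standard_normal(T),
                              "t1": rng.standard_normal(T)})
        fc = seed_fc_table(table, "seed", ["t1"])
        assert abs(fc.values["t1"]) < 3 / np.sqrt(T - 3)

    def test_planted_correlation_recovered_in_z(self, rng):
        """Mean recovered z across 50 scans within 2 SE of arctanh(0.6)."""
        T, r, n_scans = 600, 0.6, 50
        zs = []
        for _ in range(n_scans):
            x = rng.standard_normal(T)
            y = r * x + np.sqrt(1 - r ** 2) * rng.standard_normal(T)
            fc = seed_fc_table(pd.DataFrame({"s": x, "t": y}), "s", ["t"])
            zs.append(fc.values["t"])
        se = 1 / np.sqrt(T - 3) / np.sqrt(n_scans)
        assert abs(np.mean(zs) - np.arctanh(r)) < 2 * se

    def test_constant_target_becomes_missing(self, rng):
        table = pd.DataFrame({"seed": rng.standard_normal(50),
                              "flat": np.zeros(50),
                              "ok": rng.standard_normal(50)})
        fc = seed_fc_table(table, "seed", ["flat", "ok"])
        assert np.isnan(fc.values["flat"]) and np.isfinite(fc.values["ok"])

    def test_invariant_to_affine_rescaling_of_inputs(self, rng):
        T = 200
        x, y = rng.standard_normal(T), rng.standard_normal(T)
        t1 = pd.DataFrame({"s": x, "t": y})
        t2 = pd.DataFrame({"s": 3.0 * x + 5.0, "t": 0.5 * y - 2.0})
        a = seed_fc_table(t1, "s", ["t"]).values["t"]
        b = seed_fc_table(t2, "s", ["t"]).values["t"]
        assert abs(a - b) < 1e-12

    def test_voxelwise_map_agrees_with_direct_correlation(self, rng):
        data = rng.standard_normal((6, 6, 6, 80))
        vol = VolumeSeries(data=data, affine=np.diag([0.5] * 3 + [1.0]), tr_seconds=1.5)
        seed = ROISpec("s", "seed", "", (1.25, 1.25, 1.25), 1.0)
        fc = seed_fc_map(vol, seed)
        from fpconn.preprocess import extract_roi_timeseries
        seed_series = extract_roi_timeseries(vol, seed)
        expected = np.arctanh(np.corrcoef(seed_series, data[4, 4, 4])[0, 1])
        assert abs(fc.values[4, 4, 4] - expected) < 1e-10


class TestGroupFC:
    def _map(self, values, seed="s", species="sp"):
        return FCMap(values=pd.Series(values), seed_label=seed, species_label=species)

    def test_single_scan_is_identity(self):
        m = self._map({"t1": 0.3, "t2": -0.2})
        g = group_fc([m])
        pd.testing.assert_series_equal(pd.Series(g.values), pd.Series(m.values))
        assert g.level == "group" and g.n_scans_aggregated == 1

    def test_opposite_maps_average_to_zero(self):
        g = group_fc([self._map({"t": 0.4}), self._map({"t": -0.4})])
        assert g.values["t"] == 0.0

    def test_matches_explicit_loop_mean(self, rng):
        """Oracle: elementwise arithmetic mean by direct loop."""
        targets = [f"t{i}" for i in range(8)]
        maps = [self._map({t: rng.standard_normal() for t in targets}) for _ in range(10)]
        g = group_fc(maps)
        for t in targets:
            oracle = sum(m.values[t] for m in maps) / 10
            assert abs(g.values[t] - oracle) < 1e-12

    def test_mixed_seeds_rejected(self):
        with pytest.raises(ValueError, match="different seeds"):
            group_fc([self._map({"t": 0.1}, seed="a"), self._map({"t": 0.2}, seed="b")])

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            group_fc([])

    def test_group_standard_error_shrinks_like_inverse_sqrt_scans(self, rng):
        """Empirical SE of the group mean scales as 1/sqrt(S)."""
        sds = {}
        for S in (2, 5, 10):
            means = [np.mean(rng.standard_normal(S)) for _ in range(2000)]
            sds[S] = np.std(means)
        assert abs(sds[2] / sds[10] - np.sqrt(10 / 2)) < 0.3
        assert abs(sds[5] / sds[10] - np.sqrt(10 / 5)) < 0.2


class TestGroupVariants:
    def _map(self, values, seed="s", species="sp"):
        return FCMap(values=pd.Series(values), seed_label=seed, species_label=species)

    def test_t_z_aggregation_sign_and_magnitude(self, rng):
        # consistent positive z values across scans -> strongly positive group z
        maps = [self._map({"t": 0.5 + 0.01 * rng.standard_normal()}) for _ in range(10)]
        g = group_fc(maps, stat="t_z")
        assert g.values["t"] > 3.0
        # values symmetric around zero -> group z near zero
        maps = [self._map({"t": v}) for v in (-0.2, -0.1, 0.1, 0.2)]
        assert abs(group_fc(maps, stat="t_z").values["t"]) < 1e-10

    def test_t_z_needs_at_least_two_scans(self):
        with pytest.raises(ValueError, match="2 scans"):
            group_fc([self._map({"t": 0.5})], stat="t_z")

    def test_two_stage_weights_animals_equally(self):
        # animal A contributes 3 runs of 0.9, animal B one run of 0.1:
        # pooled mean is 0.7, two-stage mean is 0.5
        maps = [self._map({"t": 0.9})] * 3 + [self._map({"t": 0.1})]
        pooled = group_fc(maps)
        staged = group_fc(maps, animal_ids=["A", "A", "A", "B"])
        assert pooled.values["t"] == pytest.approx(0.7)
        assert staged.values["t"] == pytest.approx(0.5)
        assert staged.n_scans_aggregated == 4

    def test_two_stage_reduces_to_pooled_with_one_run_per_animal(self, rng):
        maps = [self._map({"t": rng.standard_normal()}) for _ in range(5)]
        pooled = group_fc(maps)
        staged = group_fc(maps, animal_ids=list("abcde"))
        assert staged.values["t"] == pytest.approx(pooled.values["t"], abs=1e-12)
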