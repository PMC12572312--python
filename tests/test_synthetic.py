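import numpy as np
import pandas as pd
import pytest

from growthchart import quantify as q
from growthchart import synthetic as syn


def _spec(regions, grid=(32, 32, 32), cortical=(), ages=("P4", "P6", "P8")):
    return syn.AtlasSpec(
        grid_shape=grid, voxel_size_um=(20.0, 20.0, 20.0),
        regions=tuple(regions), cortical_ids=tuple(cortical), ages=tuple(ages),
    )


class TestLabelVolumeGeneration:
    def test_single_region_fills_grid(self):
        spec = _spec([syn.RegionDef(5, 1, (0, 0, 0), (32, 32, 32))])
        vol = syn.generate_label_volume(spec)
        assert (vol.grid == 5).all()

    def test_two_regions_have_exact_voxel_counts(self):
        spec = _spec([
            syn.RegionDef(1, 0, (0, 0, 0), (10, 10, 10)),
            syn.RegionDef(2, 0, (20, 20, 20), (30, 30, 30)),
        ])
        vol = syn.generate_label_volume(spec)
        # brute-force scan, independent of voxel_counts()
        flat = vol.grid.ravel()
        assert sum(1 for v in flat if v == 1) == 1000
        assert sum(1 for v in flat if v == 2) == 1000
        assert sum(1 for v in flat if v == 0) == 32**3 - 2000

    def test_out_of_bounds_extent_rejected(self):
        spec = _spec([syn.RegionDef(1, 0, (0, 0, 0), (40, 10, 10))])
        with pytest.raises(ValueError, match="outside grid"):
            syn.generate_label_volume(spec)

    def test_overlapping_extents_name_colliding_ids(self):
        spec = _spec([
            syn.RegionDef(1, 0, (0, 0, 0), (10, 10, 10)),
            syn.RegionDef(2, 0, (5, 5, 5), (15, 15, 15)),
        ])
        with pytest.raises(ValueError, match=r"2 collides with \[1\]"):
            syn.generate_label_volume(spec)

    def test_conservation_of_voxels(self, atlas_spec, volume):
        total_region = sum(r.n_voxels() for r in atlas_spec.regions)
        assert int((volume.grid > 0).sum()) == total_region
        assert int((volume.grid == 0).sum()) == np.prod(atlas_spec.grid_shape) - total_region


class TestDensityTable:
    AGES = ("P4", "P6", "P8", "P10", "P12", "P14")

    def test_stable_pattern_is_constant(self):
        t = syn.TrajectorySpec(1, "x", "stable", 5000.0)
        tab = syn.make_density_table([t], self.AGES)
        assert (tab["density"] == 5000.0).all()

    def test_decline_reaches_plateau_at_stabilization_age(self):
        t = syn.TrajectorySpec(1, "x", "decline_then_stable", 8000.0, 0.5, "P12")
        tab = syn.make_density_table([t], self.AGES).set_index("age")["density"]
        assert tab["P12"] == pytest.approx(4000.0)
        assert tab["P14"] == pytest.approx(4000.0)
        diffs = np.diff(tab[list(self.AGES)].to_numpy())
        assert (diffs <= 1e-9).all()

    def test_increase_reaches_effect_magnitude(self):
        t = syn.TrajectorySpec(1, "x", "increase", 3000.0, 2.0)
        tab = syn.make_density_table([t], self.AGES).set_index("age")["density"]
        assert tab["P14"] == pytest.approx(6000.0)
        assert (np.diff(tab[list(self.AGES)].to_numpy()) >= 0).all()

    def test_unknown_pattern_rejected(self):
        with pytest.raises(ValueError, match="unknown pattern"):
            syn.TrajectorySpec(1, "x", "wiggle", 100.0)

    def test_bad_stabilization_age_rejected(self):
        t = syn.TrajectorySpec(1, "x", "decline_then_stable", 100.0, 0.5, "P99")
        with pytest.raises(ValueError, match="P99"):
            syn.make_density_table([t], self.AGES)


class TestCellSampling:
    def test_zero_density_gives_empty_table(self, volume):
        dens = pd.DataFrame({"region_id": [100], "cell_type": ["gabaergic"], "density": [0.0]})
        cells = syn.sample_cells(volume, dens, "s1", "P4", seed=0)
        assert len(cells) == 0

    def test_negative_density_rejected(self, volume):
        dens = pd.DataFrame({"region_id": [100], "cell_type": ["gabaergic"], "density": [-1.0]})
        with pytest.raises(ValueError, match="negative"):
            syn.sample_cells(volume, dens, "s1", "P4", seed=0)

    def test_poisson_mean_recovered_over_seeds(self):
        # 0.2 mm^3 region: 25,000 voxels at 20 um; density 5000 -> lambda 1000
        spec = _spec([syn.RegionDef(1, 0, (0, 0, 0), (50, 50, 10))], grid=(50, 50, 10))
        vol = syn.generate_label_volume(spec)
        dens = pd.DataFrame({"region_id": [1], "cell_type": ["gabaergic"], "density": [5000.0]})
        counts = [
            len(syn.sample_cells(vol, dens, "s", "P4", seed=s, sample_cv=0.0))
            for s in range(200)
        ]
        assert abs(np.mean(counts) - 1000) < 3 * np.sqrt(1000 / 200)

    def test_positions_map_back_to_generating_region(self, volume):
        for rid in (100, 135, 203):
            dens = pd.DataFrame({"region_id": [rid], "cell_type": ["gabaergic"], "density": [20000.0]})
            cells = syn.sample_cells(volume, dens, "s", "P4", seed=rid)
            assigned, n_out = q.assign_cells_to_regions(cells, volume)
            assert n_out == 0
            assert (assigned["region_id"] == rid).all()


class TestDetectionSimulation:
    def _one_region_cells(self, n, compartment="cytoplasmic"):
        spec = _spec([syn.RegionDef(1, 0, (0, 0, 0), (32, 32, 32))])
        vol = syn.generate_label_volume(spec)
        rng = np.random.default_rng(0)
        pos = rng.random((n, 3)) * 32 * 20.0
        cells = pd.DataFrame({
            "sample_id": "s", "age": "P4",
            "x_um": pos[:, 0], "y_um": pos[:, 1], "z_um": pos[:, 2],
            "cell_type": "t", "compartment": compartment, "truth_flag": True,
        })
        return cells, vol

    def test_ideal_mode_applies_cytoplasmic_factor(self):
        cells, vol = self._one_region_cells(140)
        res = syn.simulate_detection(cells, vol, syn.DetectionSimSpec(mode="ideal"), seed=0)
        assert len(res.detected) == 100  # 140 / 1.4
        assert res.fp == 0

    def test_ideal_mode_applies_nuclear_factor(self):
        cells, vol = self._one_region_cells(150, compartment="nuclear")
        res = syn.simulate_detection(cells, vol, syn.DetectionSimSpec(mode="ideal"), seed=0)
        assert len(res.detected) == 100  # 150 / 1.5

    def test_stochastic_with_no_false_positive_rate_has_zero_fp(self):
        cells, vol = self._one_region_cells(500)
        spec = syn.DetectionSimSpec(mode="stochastic", detection_probability=1.0,
                                    false_positive_rate=0.0)
        res = syn.simulate_detection(cells, vol, spec, seed=3)
        assert res.fp == 0
        assert res.tp == len(res.detected)

    def test_stochastic_thinning_matches_binomial_oracle(self):
        cells, vol = self._one_region_cells(400)
        p_det = 0.8
        spec = syn.DetectionSimSpec(mode="stochastic", detection_probability=p_det,
                                    false_positive_rate=0.0)
        ratios = [
            len(syn.simulate_detection(cells, vol, spec, seed=s).detected) / 400
            for s in range(200)
        ]
        p = p_det / 1.4
        se = np.sqrt(p * (1 - p) / 400 / 200)
        assert abs(np.mean(ratios) - p) < 3 * se

    def test_matching_labels_thinned_cells_as_tp(self):
        cells, vol = self._one_region_cells(300)
        spec = syn.DetectionSimSpec(mode="stochastic", false_positive_rate=200.0)
        res = syn.simulate_detection(cells, vol, spec, seed=5)
        tp_rows = res.detected[res.detected["status"] == "TP"]
        assert (tp_rows["truth_index"] >= 0).all()
        # each truth cell matched at most once
        assert tp_rows["truth_index"].is_unique
        assert res.tp + res.fn == res.n_truth


class TestFlatmapLookup:
    def test_covers_exactly_the_cortical_voxels(self, volume, atlas_spec):
        lookup = syn.make_flatmap_lookup(volume, atlas_spec.cortical_ids)
        n_cortical = int(np.isin(volume.grid, atlas_spec.cortical_ids).sum())
        assert len(lookup.table) == n_cortical

    def test_column_voxels_share_a_bin(self, volume, atlas_spec):
        lookup = syn.make_flatmap_lookup(volume, atlas_spec.cortical_ids)
        col = lookup.table.query("i == 5 and j == 5")
        assert len(col) > 1
        assert col[["ap_bin", "az_bin"]].drop_duplicates().shape[0] == 1

    def test_non_cortical_voxels_absent(self, volume, atlas_spec):
        lookup = syn.make_flatmap_lookup(volume, atlas_spec.cortical_ids)
        keys = set(zip(lookup.table["i"], lookup.table["j"], lookup.table["k"]))
        sub_voxel = tuple(np.argwhere(volume.grid == 200)[0])
        assert tuple(int(x) for x in sub_voxel) not in keys

    def test_empty_cortical_set_rejected(self, volume):
        with pytest.raises(ValueError, match="empty"):
            syn.make_flatmap_lookup(volume, ())


class TestStudyBundle:
    def test_same_seed_reproduces_tables_exactly(self):
        a = syn.generate_study(n_per_age=1, seed=42)
        b = syn.generate_study(n_per_age=1, seed=42)
        pd.testing.assert_frame_equal(a.truth_cells, b.truth_cells)
        pd.testing.assert_frame_equal(a.detected_cells, b.detected_cells)

    def test_sample_count_follows_n_per_age(self):
        study = syn.generate_study(
            atlas=_mini_atlas(),
            trajectories=[syn.TrajectorySpec(100, "x", "stable", 1000.0)],
            n_per_age={"P4": 2, "P6": 3}, seed=0,
            compartments={"x": "cytoplasmic"},
        )
        assert len(study.sample_ids()) == 5

    def test_manifest_densities_match_density_table(self, small_bundle):
        m = pd.DataFrame(small_bundle.manifest["densities"])
        pd.testing.assert_frame_equal(
            m.sort_values(["cell_type", "region_id", "age"]).reset_index(drop=True),
            small_bundle.density_table.sort_values(
                ["cell_type", "region_id", "age"]
            ).reset_index(drop=True),
            check_like=True,
        )

    def test_written_study_loads_back(self, tmp_path, ideal_bundle):
        paths = syn.write_study(ideal_bundle, tmp_path)
        assert pd.read_csv(paths["truth_cells"]).shape[0] == len(ideal_bundle.truth_cells)
        assert pd.read_csv(paths["ontology"])["id"].nunique() == len(ideal_bundle.ontology.ids())


def _mini_atlas():
    return syn.AtlasSpec(
        grid_shape=(16, 16, 8), voxel_size_um=(20.0, 20.0, 20.0),
        regions=(syn.RegionDef(100, syn.CORTEX_ID, (0, 0, 0), (16, 16, 4)),),
        cortical_ids=(100,), ages=("P4", "P6"),
    )
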