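"""Phantom generator: determinism, ground-truth consistency, placement modes."""

import numpy as np
import pytest

from conftest import lattice_sphere_count, quick_params
from sxtcell import (
    PlacementError,
    distance_field_from_pm,
    generate_cell_phantom,
    place_points,
    rasterize_sphere,
)
from sxtcell.volumes import CYTOSOL, INSULIN_VESICLE, NUCLEUS


class TestRasterizeSphere:
    def test_subvoxel_sphere_claims_containing_voxel(self):
        grid = np.zeros((8, 8, 8), dtype=np.float32)
        n = rasterize_sphere(grid, (4 * 35.0,) * 3, diameter_nm=10.0, lac_value=1.0,
                             voxel_edge_nm=35.0)
        assert n == 1
        assert grid[4, 4, 4] == 1.0
        assert grid.sum() == 1.0

    def test_voxel_count_matches_lattice_enumeration(self):
        grid = np.zeros((16, 16, 16), dtype=np.float32)
        center = (8 * 35.0, 8 * 35.0, 8 * 35.0)
        n = rasterize_sphere(grid, center, diameter_nm=8 * 35.0, lac_value=1.0,
                             voxel_edge_nm=35.0)
        expected = lattice_sphere_count(np.array([8.0, 8.0, 8.0]), 4.0, (16, 16, 16))
        assert n == expected == int(grid.sum())

    def test_boundary_sphere_clip_flag(self):
        grid = np.zeros((10, 10, 10), dtype=np.float32)
        center = (0.0, 5 * 35.0, 5 * 35.0)  # on the grid face
        n = rasterize_sphere(grid, center, 4 * 35.0, 1.0, 35.0, clip=True)
        full = lattice_sphere_count(np.array([15, 15, 15.0]), 2.0, (30, 30, 30))
        assert 0 < n < full
        with pytest.raises(ValueError, match="clip"):
            rasterize_sphere(np.zeros((10, 10, 10), np.float32), center, 4 * 35.0,
                             1.0, 35.0, clip=False)

    def test_fully_outside_raises(self):
        grid = np.zeros((8, 8, 8), dtype=np.float32)
        with pytest.raises(ValueError, match="outside"):
            rasterize_sphere(grid, (-2000.0, -2000.0, -2000.0), 100.0, 1.0, 35.0)


class TestGenerateCellPhantom:
    def test_same_seed_reproduces_bitwise_different_seed_differs(self):
        params = quick_params(n_vesicles=15, seed=5)
        va, gta = generate_cell_phantom(params)
        vb, gtb = generate_cell_phantom(quick_params(n_vesicles=15, seed=5))
        assert np.array_equal(va.values, vb.values)
        assert gta.table.equals(gtb.table)
        vc, gtc = generate_cell_phantom(quick_params(n_vesicles=15, seed=6))
        assert not np.array_equal(va.values, vc.values)
        assert not np.allclose(
            gta.table[["cz_nm", "cy_nm", "cx_nm"]], gtc.table[["cz_nm", "cy_nm", "cx_nm"]]
        )

    def test_zero_vesicles_gives_zero_vesicle_voxels(self):
        _, gt = generate_cell_phantom(quick_params(n_vesicles=0, seed=2))
        assert not np.any(gt.labels == INSULIN_VESICLE)
        assert (gt.table["class"] == "insulin_vesicle").sum() == 0

    def test_every_object_has_one_record_and_labels_partition(self, small_cell):
        _, _, gt = small_cell
        ids_in_map = set(np.unique(gt.object_ids)) - {0}
        assert ids_in_map == set(gt.table["object_id"])
        # compartment labels are a partition by construction (one array);
        # check every object voxel carries its object's class label
        legend_inv = {v: k for k, v in gt.label_map.legend.items()}
        for _, row in gt.table.iterrows():
            voxels = gt.object_ids == row["object_id"]
            assert np.all(gt.labels[voxels] == legend_inv[row["class"]])

    def test_noiseless_volume_is_piecewise_constant(self):
        params = quick_params(noise_sd=0.0, n_vesicles=10, n_lipid_droplets=0, seed=7)
        volume, gt = generate_cell_phantom(params)
        for label, column in ((CYTOSOL, None), (NUCLEUS, None)):
            vals = volume.values[gt.labels == label]
            assert np.allclose(vals, vals[0])
        for _, row in gt.table.iterrows():
            vals = volume.values[gt.object_ids == row["object_id"]]
            assert np.allclose(vals, row["lac"], atol=1e-6)

    def test_generated_vesicle_stats_converge_to_presets(self):
        # law-of-large-numbers check on the ground-truth draws at n = 500
        params = quick_params(
            grid_shape=(128, 128, 128), cell_radius_nm=1900.0, nucleus_radius_nm=700.0,
            n_vesicles=500, vesicle_diameter_mean_nm=140.0, vesicle_diameter_sd_nm=20.0,
            placement_mode="diffuse", n_mitochondria=0, n_lipid_droplets=0, seed=3,
        )
        _, gt = generate_cell_phantom(params)
        ves = gt.table[gt.table["class"] == "insulin_vesicle"]
        assert len(ves) == 500
        se_d = params.vesicle_diameter_sd_nm / np.sqrt(500)
        assert abs(ves["diameter_nm"].mean() - 140.0) < 3 * se_d
        se_l = params.vesicle_lac_sd / np.sqrt(500)
        # truncation pulls the mean in by < 1 SE at these settings
        assert abs(ves["lac"].mean() - params.vesicle_lac_mean) < 3 * se_l + 0.002

    def test_unstimulated_truth_mean_lac_near_preset(self, small_cell):
        params, _, gt = small_cell
        ves = gt.table[gt.table["class"] == "insulin_vesicle"]
        se = params.vesicle_lac_sd / np.sqrt(len(ves))
        assert abs(ves["lac"].mean() - 0.39) < 4 * se

    def test_infeasible_count_raises_placement_error_naming_class(self):
        params = quick_params(n_vesicles=2000, n_mitochondria=0, n_lipid_droplets=0,
                              seed=1, max_attempts_factor=30)
        with pytest.raises(PlacementError, match="insulin_vesicle"):
            generate_cell_phantom(params)


class TestPlacePoints:
    @pytest.fixture(scope="class")
    def masks(self):
        params = quick_params(n_vesicles=0, n_mitochondria=0, n_lipid_droplets=0, seed=4)
        _, gt = generate_cell_phantom(params)
        return gt.label_map.cell_mask(), gt.label_map.mask("nucleus")

    def test_docked_points_lie_within_band(self, masks):
        cell, nucleus = masks
        pts = place_points("docked", cell, nucleus, n=40, min_sep_nm=100.0,
                           band_fraction=0.2, seed=0)
        df = distance_field_from_pm(cell, 35.0)
        idx = np.floor(pts / 35.0).astype(int)
        d = df[idx[:, 0], idx[:, 1], idx[:, 2]]
        assert np.all(d <= 0.2 * df.max())
        assert np.all(d > 0)

    def test_single_point_inside_allowed_region(self, masks):
        cell, nucleus = masks
        pts = place_points("diffuse", cell, nucleus, n=1, min_sep_nm=0.0, seed=1)
        idx = tuple(np.floor(pts[0] / 35.0).astype(int))
        assert cell[idx] and not nucleus[idx]

    def test_pairwise_separation_enforced(self, masks):
        cell, nucleus = masks
        pts = place_points("diffuse", cell, nucleus, n=30, min_sep_nm=200.0, seed=2)
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() >= 200.0

    def test_clustered_mode_adds_interior_peak(self, masks):
        # verify against brute-force per-point distances: the interior
        # (beyond the docked band) holds roughly the configured fraction
        cell, nucleus = masks
        pts = place_points("clustered", cell, nucleus, n=60, min_sep_nm=80.0,
                           seed=3, cluster_interior_fraction=0.5, n_clusters=4)
        df = distance_field_from_pm(cell, 35.0)
        idx = np.floor(pts / 35.0).astype(int)
        d = df[idx[:, 0], idx[:, 1], idx[:, 2]] / df.max()
        interior = (d > 0.2).mean()
        assert 0.25 <= interior <= 0.75
        # docked component present too
        assert (d <= 0.2).mean() >= 0.25

    def test_chains_mode_places_collinear_runs(self, masks):
        cell, nucleus = masks
        pts = place_points("chains", cell, nucleus, n=12, min_sep_nm=100.0,
                           seed=5, chain_spacing_nm=180.0)
        assert pts.shape == (12, 3)
        # first run: consecutive gaps equal the chain spacing
        gaps = np.linalg.norm(np.diff(pts[:4], axis=0), axis=1)
        assert np.allclose(gaps, 180.0, atol=1e-6)

    def test_docked_closer_to_pm_than_diffuse_on_average(self, masks):
        cell, nucleus = masks
        df = distance_field_from_pm(cell, 35.0)

        def mean_d(mode, seed):
            pts = place_points(mode, cell, nucleus, n=25, min_sep_nm=100.0, seed=seed)
            idx = np.floor(pts / 35.0).astype(int)
            return df[idx[:, 0], idx[:, 1], idx[:, 2]].mean()

        docked = np.mean([mean_d("docked", s) for s in range(10)])
        diffuse = np.mean([mean_d("diffuse", s) for s in range(10)])
        assert docked < diffuse

    def test_infeasible_separation_raises(self, masks):
        cell, nucleus = masks
        with pytest.raises(PlacementError):
            place_points("diffuse", cell, nucleus, n=500, min_sep_nm=2000.0,
                         seed=0, max_attempts=2000)
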