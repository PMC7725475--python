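"""Region growing, component labeling, classification rules, normalization."""

import numpy as np
import pandas as pd
import pytest

from conftest import bfs_flood_fill, quick_params, union_find_components
from sxtcell import (
    ClassificationRules,
    TomogramVolume,
    classify_object,
    generate_cell_phantom,
    label_components,
    normalize_lac,
    region_grow,
    segment_cell,
)


def _volume(values):
    return TomogramVolume(np.asarray(values, dtype=np.float32), 35.0)


class TestRegionGrow:
    def test_uniform_blob_fully_selected(self):
        vals = np.full((9, 9, 9), 0.1, np.float32)
        vals[2:6, 2:6, 2:6] = 0.5
        mask = region_grow(_volume(vals), (3, 3, 3), (0.4, 0.6))
        assert mask.sum() == 4**3
        assert mask[2:6, 2:6, 2:6].all()

    def test_disconnected_blob_not_selected(self):
        vals = np.full((11, 9, 9), 0.1, np.float32)
        vals[1:3, 2:5, 2:5] = 0.5
        vals[7:9, 2:5, 2:5] = 0.5  # separated by below-window voxels
        mask = region_grow(_volume(vals), (1, 3, 3), (0.4, 0.6))
        assert mask[1:3, 2:5, 2:5].all()
        assert not mask[7:9].any()

    def test_seed_outside_window_rejected(self):
        vals = np.full((5, 5, 5), 0.1, np.float32)
        with pytest.raises(ValueError, match="outside window"):
            region_grow(_volume(vals), (2, 2, 2), (0.4, 0.6))

    def test_matches_bfs_flood_fill_oracle(self):
        rng = np.random.default_rng(42)
        vals = rng.uniform(0.0, 1.0, size=(20, 20, 20)).astype(np.float32)
        window = (0.3, 0.8)
        in_window = (vals >= window[0]) & (vals <= window[1])
        seed = tuple(np.argwhere(in_window)[0])
        got = region_grow(_volume(vals), seed, window)
        expected = bfs_flood_fill(in_window, seed)
        assert np.array_equal(got, expected)


class TestLabelComponents:
    def test_empty_mask_zero_objects(self):
        _, n = label_components(np.zeros((4, 4, 4), bool))
        assert n == 0

    def test_corner_touching_voxels_depend_on_connectivity(self):
        mask = np.zeros((3, 3, 3), bool)
        mask[0, 0, 0] = mask[1, 1, 1] = True
        assert label_components(mask, connectivity=26)[1] == 1
        assert label_components(mask, connectivity=6)[1] == 2

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_union_find_oracle(self, connectivity):
        rng = np.random.default_rng(7)
        mask = rng.uniform(size=(15, 15, 15)) < 0.25
        _, n = label_components(mask, connectivity=connectivity)
        assert n == union_find_components(mask, connectivity)


class TestClassifyObject:
    RULES = ClassificationRules()

    @pytest.mark.parametrize(
        "metrics,expected",
        [
            # bright spherical object -> lipid droplet
            (dict(mean_lac=0.60, max_lac=0.70, equivalent_diameter_nm=320, axis_ratio=1.2),
             "lipid_droplet"),
            # max LAC exactly at the threshold is inclusive
            (dict(mean_lac=0.60, max_lac=0.68, equivalent_diameter_nm=320, axis_ratio=1.2),
             "lipid_droplet"),
            # spherical, vesicle window, large enough -> insulin vesicle
            (dict(mean_lac=0.45, max_lac=0.50, equivalent_diameter_nm=250, axis_ratio=1.3),
             "insulin_vesicle"),
            # window edges inclusive
            (dict(mean_lac=0.35, max_lac=0.40, equivalent_diameter_nm=250, axis_ratio=1.3),
             "insulin_vesicle"),
            (dict(mean_lac=0.67, max_lac=0.675, equivalent_diameter_nm=250, axis_ratio=1.3),
             "insulin_vesicle"),
            # elongated in the mitochondria window
            (dict(mean_lac=0.34, max_lac=0.40, equivalent_diameter_nm=600, axis_ratio=4.0),
             "mitochondria"),
        ],
    )
    def test_accepted_classes(self, metrics, expected):
        cls, reason = classify_object(metrics, self.RULES)
        assert cls == expected and reason == ""

    @pytest.mark.parametrize(
        "metrics,reason",
        [
            # small spherical object in the vesicle window -> microvesicle cut
            (dict(mean_lac=0.45, max_lac=0.50, equivalent_diameter_nm=80, axis_ratio=1.3),
             "microvesicle"),
            # intermediate shape neither spherical nor elongated
            (dict(mean_lac=0.45, max_lac=0.50, equivalent_diameter_nm=250, axis_ratio=2.5),
             "ambiguous_shape"),
            # spherical but below every LAC window
            (dict(mean_lac=0.10, max_lac=0.15, equivalent_diameter_nm=250, axis_ratio=1.2),
             "lac_outside_windows"),
        ],
    )
    def test_rejections_carry_reason(self, metrics, reason):
        cls, got = classify_object(metrics, self.RULES)
        assert cls == "rejected" and got == reason

    def test_droplet_precedence_over_vesicle(self):
        # mean in the vesicle window but max above the droplet threshold
        metrics = dict(mean_lac=0.55, max_lac=0.70, equivalent_diameter_nm=300,
                       axis_ratio=1.1)
        assert classify_object(metrics, self.RULES)[0] == "lipid_droplet"

    def test_missing_metric_raises(self):
        with pytest.raises(ValueError, match="missing"):
            classify_object(dict(mean_lac=0.45), self.RULES)

    def test_classification_is_per_object(self):
        # permuting records permutes outputs identically
        rng = np.random.default_rng(0)
        records = [
            dict(mean_lac=float(rng.uniform(0.1, 0.8)),
                 max_lac=float(rng.uniform(0.5, 0.9)),
                 equivalent_diameter_nm=float(rng.uniform(50, 500)),
                 axis_ratio=float(rng.uniform(1.0, 5.0)))
            for _ in range(30)
        ]
        out = [classify_object(m, self.RULES) for m in records]
        perm = rng.permutation(30)
        out_perm = [classify_object(records[i], self.RULES) for i in perm]
        assert out_perm == [out[i] for i in perm]


class TestNormalizeLac:
    TABLE = pd.DataFrame(dict(mean_lac=[0.39, 0.60], max_lac=[0.45, 0.72]))

    def test_identity_when_capillary_equals_reference(self):
        out = normalize_lac(self.TABLE, 0.30, 0.30)
        assert np.allclose(out["mean_lac_norm"], self.TABLE["mean_lac"])

    def test_linearity(self):
        out = normalize_lac(self.TABLE, 0.60, 0.30)
        assert np.allclose(out["mean_lac_norm"], self.TABLE["mean_lac"] / 2)
        assert np.allclose(out["max_lac_norm"], self.TABLE["max_lac"] / 2)

    def test_idempotent_and_keeps_raw(self):
        once = normalize_lac(self.TABLE, 0.45, 0.30)
        twice = normalize_lac(once, 0.45, 0.30)
        assert np.allclose(once["mean_lac_norm"], twice["mean_lac_norm"])
        assert np.allclose(once["mean_lac"], self.TABLE["mean_lac"])

    def test_nonpositive_capillary_rejected(self):
        with pytest.raises(ValueError):
            normalize_lac(self.TABLE, 0.0, 0.30)


class TestSegmentCell:
    def test_noiseless_phantom_recovered_exactly(self):
        params = quick_params(noise_sd=0.0, seed=21)
        volume, gt = generate_cell_phantom(params)
        _, table = segment_cell(volume, gt.label_map.cell_mask(),
                                gt.label_map.mask("nucleus"))
        got = table["class"].value_counts().to_dict()
        want = gt.table["class"].value_counts().to_dict()
        assert got == want

    def test_noisy_phantom_class_agreement_at_least_95pct(self, small_segmented):
        params, volume, gt, label_map, table = small_segmented
        # match each recovered object to the ground-truth object at its centroid
        agree = total = 0
        for _, row in table.iterrows():
            idx = tuple(
                int(c // volume.voxel_edge_nm)
                for c in (row["cz_nm"], row["cy_nm"], row["cx_nm"])
            )
            oid = gt.object_ids[idx]
            if oid == 0:
                continue
            truth = gt.table.loc[gt.table["object_id"] == oid, "class"].iloc[0]
            total += 1
            agree += truth == row["class"]
        assert total >= 0.95 * len(gt.table)
        assert agree / total >= 0.95

    def test_negative_control_has_almost_no_vesicles(self):
        params = quick_params(preset="negative_control", n_vesicles=0, seed=9)
        volume, gt = generate_cell_phantom(params)
        _, table = segment_cell(volume, gt.label_map.cell_mask(),
                                gt.label_map.mask("nucleus"))
        n_ves = (table["class"] == "insulin_vesicle").sum()
        assert n_ves <= 0.09 * 319  # at most the HEK false-positive rate

    def test_in_cell_voxels_fully_labeled(self, small_segmented):
        _, volume, gt, label_map, _ = small_segmented
        cell = gt.label_map.cell_mask()
        assert np.all(label_map.labels[cell] > 0)
        assert np.all(label_map.labels[~cell] == 0)

    def test_nucleus_outside_pm_rejected(self, small_cell):
        _, volume, gt = small_cell
        pm = gt.label_map.cell_mask()
        bad_nucleus = np.zeros_like(pm)
        bad_nucleus[0, 0, 0] = True
        with pytest.raises(ValueError, match="nucleus"):
            segment_cell(volume, pm, bad_nucleus)
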