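import numpy as np
import pytest
from scipy import ndimage
from skimage.draw import disk as draw_disk

from cytoquant.config import PrimarySegmentationParams
from cytoquant.measure import measure_shape
from cytoquant.primary import (declump_by_shape, filter_real_nuclei,
                               gate_primary_objects, otsu_threshold,
                               threshold_mask)

from oracles import otsu_bruteforce


def _disks(shape, centers, radius):
    mask = np.zeros(shape, dtype=bool)
    for c in centers:
        rr, cc = draw_disk(c, radius, shape=shape)
        mask[rr, cc] = True
    return mask


class TestOtsu:
    def test_two_delta_histogram_splits_between_modes(self):
        img = np.concatenate([np.full(500, 0.2), np.full(500, 0.8)]).reshape(20, 50)
        t = otsu_threshold(img)
        assert 0.2 < t < 0.8

    def test_constant_image_yields_empty_foreground(self):
        img = np.full((10, 10), 0.37)
        t = otsu_threshold(img)
        assert t == 0.37
        assert not (img > t).any()

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_scan_on_random_images(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.uniform(0, 1, size=(25, 40))
        assert otsu_threshold(img) == otsu_bruteforce(img)

    def test_bimodal_random_image(self, rng):
        img = np.concatenate([rng.normal(0.25, 0.04, 600),
                              rng.normal(0.75, 0.04, 400)]).clip(0, 1).reshape(25, 40)
        assert otsu_threshold(img) == otsu_bruteforce(img)


class TestThresholdMask:
    def test_identity_correction_equals_plain_otsu_of_smoothed(self, rng):
        img = rng.uniform(0, 1, size=(40, 40))
        params = PrimarySegmentationParams(threshold_correction=1.0)
        mask, t = threshold_mask(img, params, return_threshold=True)
        smoothed = ndimage.gaussian_filter(img, params.sigma, mode="nearest")
        assert t == otsu_threshold(smoothed)
        np.testing.assert_array_equal(mask, smoothed > t)

    def test_correction_scales_threshold(self, rng):
        img = rng.uniform(0, 1, size=(40, 40))
        p1 = PrimarySegmentationParams(threshold_correction=1.0)
        p7 = PrimarySegmentationParams(threshold_correction=0.7)
        _, t1 = threshold_mask(img, p1, return_threshold=True)
        _, t7 = threshold_mask(img, p7, return_threshold=True)
        assert t7 == pytest.approx(0.7 * t1)

    def test_bounds_clamp_threshold(self, rng):
        img = rng.uniform(0, 1, size=(30, 30))
        p = PrimarySegmentationParams(threshold_bounds=(0.5, 0.5))
        _, t = threshold_mask(img, p, return_threshold=True)
        assert t == 0.5

    def test_raising_correction_never_grows_foreground(self, rng):
        img = rng.uniform(0, 1, size=(50, 50))
        areas = []
        for corr in (0.5, 0.7, 1.0, 1.3):
            p = PrimarySegmentationParams(threshold_correction=corr)
            areas.append(int(threshold_mask(img, p).sum()))
        assert areas == sorted(areas, reverse=True)


class TestDeclump:
    params = PrimarySegmentationParams()

    def test_single_disk_single_label(self):
        mask = _disks((80, 80), [(40, 40)], 15)
        labels = declump_by_shape(mask, self.params)
        assert labels.max() == 1
        np.testing.assert_array_equal(labels > 0, mask)

    def test_disjoint_disks_keep_connected_components(self):
        mask = _disks((100, 100), [(25, 25), (70, 70)], 12)
        labels = declump_by_shape(mask, self.params)
        assert labels.max() == 2
        n_cc, _ = ndimage.label(mask), None
        assert len(np.unique(labels)) - 1 == ndimage.label(mask)[1]

    def test_overlapping_pair_is_split_in_two(self):
        # centers 22 px apart, radius 12: a clumped pair with an indentation
        mask = _disks((100, 100), [(50, 39), (50, 61)], 12)
        labels = declump_by_shape(mask, self.params)
        assert labels.max() == 2
        # every foreground pixel assigned exactly once
        np.testing.assert_array_equal(labels > 0, mask)
        # seed count oracle: brute-force scan for smoothed-distance maxima
        edt = ndimage.distance_transform_edt(mask)
        sd = ndimage.gaussian_filter(edt, self.params.distance_sigma, mode="constant")
        peaks = []
        for i in range(1, 99):
            for j in range(1, 99):
                if mask[i, j] and sd[i, j] >= sd[i - 1:i + 2, j - 1:j + 2].max():
                    peaks.append((i, j))
        survivors = []
        for p in sorted(peaks, key=lambda q: (-sd[q], q)):
            if all((p[0] - s[0]) ** 2 + (p[1] - s[1]) ** 2 >= 16**2 for s in survivors):
                survivors.append(p)
        assert len(survivors) == 2

    def test_empty_mask(self):
        labels = declump_by_shape(np.zeros((20, 20), dtype=bool), self.params)
        assert labels.max() == 0

    def test_holes_filled_within_objects(self):
        mask = _disks((60, 60), [(30, 30)], 15)
        mask[28:32, 28:32] = False  # punch a hole
        labels = declump_by_shape(mask, self.params)
        assert labels[30, 30] == 1


class TestGate:
    params = PrimarySegmentationParams()

    def test_small_object_removed(self):
        labels = _disks((80, 80), [(40, 40)], 5).astype(np.int32)  # equiv diam ~10
        assert gate_primary_objects(labels, self.params).max() == 0

    def test_in_gate_object_kept(self):
        labels = _disks((90, 90), [(45, 45)], 20).astype(np.int32)
        assert gate_primary_objects(labels, self.params).max() == 1

    def test_border_touching_removed(self):
        labels = _disks((80, 80), [(2, 40)], 12).astype(np.int32)
        assert gate_primary_objects(labels, self.params).max() == 0
        keep = PrimarySegmentationParams(exclude_border=False)
        assert gate_primary_objects(labels, keep).max() == 1

    def test_relabelling_is_sequential_and_order_preserving(self):
        labels = np.zeros((120, 220), dtype=np.int32)
        for i, col in enumerate([30, 90, 150], start=1):
            rr, cc = draw_disk((60, col), 18, shape=labels.shape)
            labels[rr, cc] = i * 3  # labels 3, 6, 9
        gated = gate_primary_objects(labels, self.params)
        assert sorted(np.unique(gated).tolist()) == [0, 1, 2, 3]
        assert gated[60, 30] == 1 and gated[60, 90] == 2 and gated[60, 150] == 3


class TestRealNucleiFilter:
    def test_form_factor_cutoff_straddle(self):
        labels = np.zeros((40, 80), dtype=np.int32)
        labels[5:15, 5:15] = 1
        labels[20:30, 40:50] = 2
        table = measure_shape(labels)
        table.loc[1, "form_factor"] = 0.600
        table.loc[2, "form_factor"] = 0.598
        out_labels, out_table = filter_real_nuclei(labels, table, 0.599)
        assert list(out_table.index) == [1]
        assert set(np.unique(out_labels).tolist()) == {0, 1}

    def test_empty_input(self):
        labels = np.zeros((10, 10), dtype=np.int32)
        out_labels, out_table = filter_real_nuclei(labels, measure_shape(labels), 0.599)
        assert out_labels.max() == 0 and len(out_table) == 0

    def test_missing_measurement_rejected(self):
        labels = np.zeros((10, 10), dtype=np.int32)
        labels[2:6, 2:6] = 1
        import pandas as pd
        with pytest.raises(ValueError):
            filter_real_nuclei(labels, pd.DataFrame({"form_factor": []}), 0.599)

    def test_synthetic_burst_star_removed(self, small_case, study_config):
        """Burst star shapes measured below 0.599 must be dropped."""
        from cytoquant.synthetic import SyntheticSpec, generate
        spec = SyntheticSpec(n_cells=6, frac_burst_nuclei=0.5,
                             image_size=(360, 360), rng_seed=9)
        _, truth = generate(spec)
        labels = truth.nucleus_label_map
        table = measure_shape(labels)
        _, kept = filter_real_nuclei(labels, table, 0.599)
        burst_ids = set(truth.cells.cell_id[truth.cells.is_burst_nucleus] + 1)
        # relabelled table: map survivors back via count
        assert len(kept) == len(table) - len(burst_ids)
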