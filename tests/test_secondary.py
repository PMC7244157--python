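import numpy as np
import pandas as pd
import pytest

from cytoquant.config import SecondarySegmentationParams
from cytoquant.measure import measure_intensity, measure_shape
from cytoquant.secondary import (filter_intact_cells, propagate_labels,
                                 propagate_secondary, secondary_foreground_mask)

from oracles import propagation_bruteforce


def _random_case(seed, shape=(32, 32), n_seeds=3):
    rng = np.random.default_rng(seed)
    image = rng.uniform(0, 1, size=shape)
    seeds = np.zeros(shape, dtype=np.int32)
    coords = rng.choice(shape[0] * shape[1], size=n_seeds, replace=False)
    for lab, idx in enumerate(coords, start=1):
        seeds[idx // shape[1], idx % shape[1]] = lab
    mask = rng.uniform(size=shape) < 0.7
    return seeds, image, mask


class TestPropagateLabels:
    def test_single_seed_floods_reachable_foreground(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 5:15] = True
        seeds = np.zeros((20, 20), dtype=np.int32)
        seeds[10, 10] = 1
        out = propagate_labels(seeds, np.full((20, 20), 0.5), mask, 0.1)
        np.testing.assert_array_equal(out > 0, mask)
        assert set(np.unique(out)) == {0, 1}

    def test_uniform_image_partitions_by_distance(self):
        """With uniform intensity and lambda > 0 the partition is the
        nearest-seed 8-connected geodesic partition."""
        seeds = np.zeros((21, 41), dtype=np.int32)
        seeds[10, 5] = 1
        seeds[10, 35] = 2
        mask = np.ones((21, 41), dtype=bool)
        out = propagate_labels(seeds, np.full(mask.shape, 0.3), mask, 0.5)
        assert out[10, 8] == 1 and out[10, 32] == 2
        oracle = propagation_bruteforce(seeds, np.full(mask.shape, 0.3), mask, 0.5)
        np.testing.assert_array_equal(out, oracle)

    def test_dark_ridge_divides_at_lambda_zero(self):
        """With lambda = 0 the boundary follows the intensity ridge even
        when that is far from the halfway line."""
        img = np.full((15, 40), 0.8)
        img[:, 30] = 0.1  # dark ridge at column 30, off-center
        seeds = np.zeros(img.shape, dtype=np.int32)
        seeds[7, 2] = 1
        seeds[7, 37] = 2
        out = propagate_labels(seeds, img, np.ones(img.shape, bool), 0.0)
        # everything left of the ridge is label 1 despite being > halfway
        assert (out[:, :30] == 1).all()
        oracle = propagation_bruteforce(seeds, img, np.ones(img.shape, bool), 0.0)
        np.testing.assert_array_equal(out, oracle)

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("lam", [0.0, 0.1, 1.0])
    def test_matches_dijkstra_oracle_exactly(self, seed, lam):
        seeds, image, mask = _random_case(seed)
        out = propagate_labels(seeds, image, mask, lam)
        oracle = propagation_bruteforce(seeds, image, mask, lam)
        np.testing.assert_array_equal(out, oracle)

    def test_large_lambda_converges_to_geodesic_partition(self):
        seeds, image, _ = _random_case(99, n_seeds=2)
        mask = np.ones(image.shape, dtype=bool)
        big = propagate_labels(seeds, image, mask, 1e6)
        geo = propagate_labels(seeds, np.zeros(image.shape), mask, 1.0)
        assert (big == geo).mean() > 0.98

    def test_seed_pixels_keep_their_label_below_threshold(self):
        seeds = np.zeros((10, 10), dtype=np.int32)
        seeds[4, 4] = 1
        mask = np.zeros((10, 10), dtype=bool)  # nothing above threshold
        out = propagate_labels(seeds, np.zeros((10, 10)), mask, 0.1)
        assert out[4, 4] == 1 and out.sum() == 1


class TestPropagateSecondary:
    def test_empty_seed_map_warns_and_returns_empty(self):
        params = SecondarySegmentationParams()
        with pytest.warns(UserWarning):
            out = propagate_secondary(np.zeros((12, 12), dtype=np.int32),
                                      np.random.default_rng(0).uniform(size=(12, 12)),
                                      params)
        assert out.max() == 0

    def test_bodies_carry_seed_labels_and_contain_seeds(self, small_case, study_config):
        _, image, truth = small_case
        from cytoquant import primary
        p = study_config.primary
        labels = primary.gate_primary_objects(
            primary.declump_by_shape(primary.threshold_mask(image["DAPI"], p), p), p)
        bodies = propagate_secondary(labels, image["VIME"], study_config.secondary)
        for lab in np.unique(labels)[1:]:
            body_ids = set(np.unique(bodies[labels == lab]).tolist())
            assert body_ids == {int(lab)}


class TestFilterIntactCells:
    params = SecondarySegmentationParams()

    def _body_table(self, rows):
        df = pd.DataFrame(rows, columns=["area", "form_factor", "mean_intensity_VIME"])
        df.index = pd.Index(range(1, len(df) + 1), name="label")
        return df

    def test_area_straddle_27_vs_28(self):
        table = self._body_table([[27, 0.9, 0.5], [28, 0.9, 0.5]])
        bodies = np.zeros((10, 10), dtype=np.int32)
        bodies[0, :5] = 1
        bodies[5, :5] = 2
        _, out = filter_intact_cells(bodies, table, self.params)
        assert not out.at[1, "has_intact_body"]
        assert out.at[2, "has_intact_body"]

    def test_zero_vime_intensity_removed_regardless_of_shape(self):
        table = self._body_table([[100, 1.0, 0.0]])
        bodies = np.ones((5, 5), dtype=np.int32)
        filtered, out = filter_intact_cells(bodies, table, self.params)
        assert not out.at[1, "has_intact_body"] and filtered.max() == 0

    def test_form_factor_straddle(self):
        table = self._body_table([[50, 0.349, 0.5], [50, 0.35, 0.5]])
        bodies = np.zeros((10, 10), dtype=np.int32)
        bodies[0, :5] = 1
        bodies[5, :5] = 2
        _, out = filter_intact_cells(bodies, table, self.params)
        assert list(out[out.has_intact_body].index) == [2]

    def test_orphan_body_rejected(self):
        table = self._body_table([[50, 0.9, 0.5]])
        bodies = np.ones((4, 4), dtype=np.int32)
        with pytest.raises(ValueError, match="parent"):
            filter_intact_cells(bodies, table, self.params,
                                nuclei_labels=np.zeros((4, 4), dtype=np.int32))

    def test_burst_body_cells_lose_intact_flag(self, study_config):
        """Cells whose body burst (spiky VIME splash) end without an
        intact body; normal cells keep theirs."""
        from cytoquant import primary
        from cytoquant.synthetic import SyntheticSpec, generate, match_to_truth
        spec = SyntheticSpec(n_cells=8, frac_burst_bodies=0.5,
                             image_size=(420, 420), rng_seed=21)
        image, truth = generate(spec)
        p = study_config.primary
        labels = primary.gate_primary_objects(
            primary.declump_by_shape(primary.threshold_mask(image["DAPI"], p), p), p)
        bodies = propagate_secondary(labels, image["VIME"], study_config.secondary)
        table = measure_shape(bodies).join(
            measure_intensity(bodies, image["VIME"], "VIME"))
        _, out = filter_intact_cells(bodies, table, study_config.secondary)
        mapping = match_to_truth(labels, truth.nucleus_label_map)
        burst = set(truth.cells.cell_id[truth.cells.is_burst_body] + 1)
        for label, gt in mapping.items():
            assert out.at[label, "has_intact_body"] == (gt not in burst)
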