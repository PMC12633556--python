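"""3-D flood-fill wave segmentation against a brute-force oracle."""

import numpy as np
import pytest

from waveminer import Connectivity, extract_waves, segment_waves

from _oracles import brute_force_components, partition_of_labels


class TestSegmentWaves:
    def test_two_separated_blobs_are_two_waves(self):
        data = np.zeros((10, 10, 10), dtype=bool)
        data[1:3, 1:3, 1:3] = True
        data[6:8, 6:8, 6:8] = True
        wlm = segment_waves(data)
        assert wlm.n_waves == 2

    def test_isolated_pixel_discarded(self):
        data = np.zeros((5, 5, 5), dtype=bool)
        data[2, 2, 2] = True
        wlm = segment_waves(data)
        assert wlm.n_waves == 0
        assert wlm.labels.sum() == 0

    def test_labels_dense_and_disjoint(self, rng):
        data = rng.random((15, 15, 20)) < 0.1
        wlm = segment_waves(data)
        present = np.unique(wlm.labels)
        np.testing.assert_array_equal(present, np.arange(wlm.n_waves + 1))
        assert np.all(data[wlm.labels > 0])  # labeled only where active

    @pytest.mark.parametrize("conn", [Connectivity(8, True), Connectivity(4, False)])
    def test_matches_brute_force_union_find(self, conn, rng):
        """Partition identity with an independent union-find oracle."""
        for _ in range(15):
            data = rng.random((12, 12, 15)) < 0.08
            wlm = segment_waves(data, connectivity=conn, min_pixels=2)
            expected = set(
                brute_force_components(
                    data, conn.spatial, conn.temporal_diagonal, min_pixels=2
                )
            )
            assert partition_of_labels(wlm.labels) == expected

    def test_ids_follow_t_major_scan_order(self):
        data = np.zeros((6, 6, 6), dtype=bool)
        data[4:6, 4:6, 3] = True   # later in time -> higher ID
        data[0:2, 0:2, 0] = True   # earliest voxel -> ID 1
        wlm = segment_waves(data)
        assert wlm.labels[0, 0, 0] == 1
        assert wlm.labels[4, 4, 3] == 2

    def test_deterministic_rerun(self, rng):
        data = rng.random((10, 10, 12)) < 0.1
        a = segment_waves(data)
        b = segment_waves(data)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_temporal_gap_splits_merged_frames_join(self):
        # same footprint in frames 0 and 3 (gap > 1) -> two waves
        data = np.zeros((4, 4, 6), dtype=bool)
        data[1:3, 1:3, 0] = True
        data[1:3, 1:3, 3] = True
        assert segment_waves(data).n_waves == 2
        # touching in adjacent frames -> one wave
        data[1:3, 1:3, 1:3] = True
        assert segment_waves(data).n_waves == 1

    def test_min_pixels_filter(self):
        data = np.zeros((6, 6, 4), dtype=bool)
        data[0:2, 0, 0] = True           # size-2 cluster
        data[4, 4, 0] = data[4, 4, 1] = True  # size-2 cluster in time
        wlm = segment_waves(data, min_pixels=3)
        assert wlm.n_waves == 0


class TestConnectivity:
    def test_structure_symmetric(self):
        for conn in (Connectivity(8, True), Connectivity(4, False), Connectivity(4, True)):
            st = conn.structure()
            np.testing.assert_array_equal(st, st[::-1, ::-1, ::-1])

    def test_spatial_4_excludes_diagonals(self):
        data = np.zeros((4, 4, 3), dtype=bool)
        data[0, 0, 1] = True
        data[1, 1, 1] = True
        assert segment_waves(data, Connectivity(4, False), min_pixels=1).n_waves == 2
        assert segment_waves(data, Connectivity(8, True), min_pixels=1).n_waves == 1

    def test_invalid_spatial_rejected(self):
        with pytest.raises(ValueError):
            Connectivity(spatial=6)


class TestExtractWaves:
    def test_frame_bounds(self):
        data = np.zeros((5, 5, 10), dtype=bool)
        data[2, 2, 3:8] = True
        records = extract_waves(segment_waves(data))
        assert len(records) == 1
        assert (records[0].t_start, records[0].t_end) == (3, 7)

    def test_empty_matrix_gives_empty_list(self):
        wlm = segment_waves(np.zeros((4, 4, 4), dtype=bool))
        assert extract_waves(wlm) == []

    def test_pixel_lists_tile_labeled_support(self, rng):
        data = rng.random((12, 12, 10)) < 0.12
        wlm = segment_waves(data)
        records = extract_waves(wlm)
        total = sum(r.n_pixels for r in records)
        assert total == np.count_nonzero(wlm.labels)
        # voxels agree label by label
        for r in records:
            got = {tuple(p) for p in r.pixels}
            exp = set(zip(*np.nonzero(wlm.labels == r.wave_id)))
            assert got == exp
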