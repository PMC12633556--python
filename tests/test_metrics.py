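"""Per-wave and population spatiotemporal metrics."""

import numpy as np
import pytest

from waveminer import (
    ActivityMovie,
    Connectivity,
    UndefinedResultError,
    WaveLabelMatrix,
    WaveRecord,
    classify_direction,
    flow_field,
    initiation_bias,
    initiation_site,
    inter_wave_intervals,
    local_synchrony,
    nasal_bias,
    propagation_direction,
    wave_area,
    wave_duration,
    wave_frequency,
    wave_speed,
)

from _oracles import brute_force_edge_distances

PITCH = 87.5


def record(frame_masks, shape):
    """WaveRecord from {t: bool (nx, ny) mask}."""
    pix = []
    for t, mask in frame_masks.items():
        for x, y in np.argwhere(mask):
            pix.append((x, y, t))
    return WaveRecord(wave_id=1, pixels=np.array(pix), shape=shape)


def column_mask(shape, x):
    m = np.zeros(shape[:2], dtype=bool)
    if 0 <= x < shape[0]:
        m[x, :] = True
    return m


def label_matrix(labels, frame_s=1.0, valid_mask=None):
    labels = np.asarray(labels, dtype=np.int32)
    return WaveLabelMatrix(
        labels=labels, n_waves=int(labels.max()), connectivity=Connectivity(),
        min_pixels=2, pixel_pitch_um=PITCH, frame_s=frame_s, valid_mask=valid_mask,
    )


class TestAreaAndDuration:
    def test_area_counts_distinct_xy_once(self):
        shape = (5, 5, 4)
        masks = {}
        for t in range(3):  # 4 distinct pixels, repeated across frames
            m = np.zeros(shape[:2], dtype=bool)
            m[1, 1] = m[1, 2] = m[2, 1] = m[2, 2] = True
            masks[t] = m
        assert wave_area(record(masks, shape), PITCH) == pytest.approx(4 * 87.5**2)
        assert wave_area(record(masks, shape), PITCH) == pytest.approx(30625.0)

    def test_single_pixel_footprint_area(self):
        shape = (3, 3, 3)
        m = np.zeros((3, 3), dtype=bool)
        m[1, 1] = True
        assert wave_area(record({0: m, 1: m}, shape), PITCH) == pytest.approx(7656.25)

    def test_area_equals_unique_xy_count(self, rng):
        shape = (10, 10, 6)
        masks = {t: rng.random((10, 10)) < 0.2 for t in range(6)}
        w = record(masks, shape)
        expected = len({(x, y) for x, y, _ in map(tuple, w.pixels)})
        assert wave_area(w, PITCH) == pytest.approx(expected * PITCH**2)

    def test_duration_formula(self):
        shape = (3, 3, 30)
        m = np.zeros((3, 3), dtype=bool)
        m[0, 0] = m[0, 1] = True
        w = record({10: m, 25: m}, shape)  # tests bounds, not connectivity
        assert wave_duration(w, 1.0) == 15.0
        assert wave_duration(record({4: m}, shape), 1.0) == 0.0

    def test_duration_scales_with_frame_interval(self):
        shape = (3, 3, 10)
        m = np.ones((3, 3), dtype=bool)
        w = record({2: m, 5: m}, shape)
        assert wave_duration(w, 2.0) == 2 * wave_duration(w, 1.0)


class TestSpeed:
    def test_planar_wave_one_pixel_per_frame(self):
        shape = (10, 6, 5)
        masks = {t: column_mask(shape, 2 + t) for t in range(4)}
        assert wave_speed(record(masks, shape), PITCH, 1.0) == pytest.approx(87.5)

    def test_stationary_wave_speed_zero(self):
        shape = (6, 6, 4)
        m = np.zeros((6, 6), dtype=bool)
        m[2:4, 2:4] = True
        assert wave_speed(record({0: m, 1: m, 2: m}, shape), PITCH, 1.0) == 0.0

    def test_point_advancing_two_pixels_per_frame(self):
        shape = (12, 3, 4)
        masks = {}
        for t in range(4):
            m = np.zeros(shape[:2], dtype=bool)
            m[2 + 2 * t, 1] = True
            masks[t] = m
        assert wave_speed(record(masks, shape), PITCH, 1.0) == pytest.approx(2 * 87.5)

    def test_single_frame_wave_is_nan(self):
        shape = (4, 4, 3)
        m = np.zeros((4, 4), dtype=bool)
        m[1, 1] = m[1, 2] = True
        assert np.isnan(wave_speed(record({1: m}, shape), PITCH, 1.0))

    def test_matches_brute_force_nearest_neighbor(self, rng):
        """EDT leading-edge distances equal an exhaustive nearest-neighbor scan."""
        shape = (15, 15, 3)
        for _ in range(10):
            prev = rng.random((15, 15)) < 0.2
            nxt = prev | (rng.random((15, 15)) < 0.15)
            if not (prev.any() and (nxt & ~prev).any()):
                continue
            w = record({0: prev, 1: nxt}, shape)
            expected = np.mean(brute_force_edge_distances(prev, nxt)) * PITCH
            assert wave_speed(w, PITCH, 1.0) == pytest.approx(expected)

    def test_speed_scales_with_pitch(self):
        shape = (10, 4, 4)
        masks = {t: column_mask(shape, 1 + t) for t in range(3)}
        w = record(masks, shape)
        assert wave_speed(w, 2 * PITCH, 1.0) == pytest.approx(2 * wave_speed(w, PITCH, 1.0))


class TestInitiation:
    def test_single_pixel_first_frame(self):
        shape = (8, 8, 3)
        m0 = np.zeros((8, 8), dtype=bool)
        m0[3, 7] = True
        m1 = np.zeros((8, 8), dtype=bool)
        m1[4, 7] = m1[4, 6] = True
        assert initiation_site(record({0: m0, 1: m1}, shape)) == (3.0, 7.0)

    def test_centroid_of_two_pixels(self):
        shape = (4, 4, 2)
        m = np.zeros((4, 4), dtype=bool)
        m[0, 0] = m[2, 0] = True
        assert initiation_site(record({0: m}, shape)) == (1.0, 0.0)

    def test_centroid_equals_coordinate_mean(self, rng):
        shape = (12, 12, 2)
        m = rng.random((12, 12)) < 0.3
        m[0, 0] = True
        w = record({0: m}, shape)
        coords = np.argwhere(m)
        assert initiation_site(w) == (
            pytest.approx(coords[:, 0].mean()), pytest.approx(coords[:, 1].mean())
        )

    def test_initiation_bias_boundaries(self):
        assert initiation_bias(np.array([20.0, 25.0, 30.0]), 15.5) == 1.0
        assert initiation_bias(np.array([20.0] * 5 + [10.0] * 5), 15.5) == 0.5
        # sites exactly on the split count as nasal
        assert initiation_bias(np.array([15.5]), 15.5) == 1.0

    def test_initiation_bias_empty_raises(self):
        with pytest.raises(UndefinedResultError):
            initiation_bias(np.array([]), 15.5)

    def test_mirror_maps_ibi_to_complement(self, rng):
        nx = 32
        sites = rng.uniform(0, nx - 1, size=50)
        split = (nx - 1) / 2
        ibi = initiation_bias(sites, split)
        flipped = (nx - 1) - sites
        # no site may sit exactly on the split for exact complement
        assert not np.any(sites == split)
        assert initiation_bias(flipped, split) == pytest.approx(1 - ibi)


class TestFlowField:
    def test_rightward_planar_wave_flows_nasally(self):
        shape = (12, 6, 5)
        masks = {t: column_mask(shape, 3 + t) for t in range(4)}
        xy, vec = flow_field(record(masks, shape))
        assert np.all(vec[:, 0] > 0)
        np.testing.assert_allclose(vec[:, 1], 0.0, atol=1e-12)

    def test_stationary_wave_zero_field(self):
        shape = (6, 6, 4)
        m = np.zeros((6, 6), dtype=bool)
        m[2:4, 2:4] = True
        _, vec = flow_field(record({0: m, 1: m, 2: m}, shape))
        np.testing.assert_allclose(vec, 0.0, atol=1e-12)

    def test_mirrored_wave_has_mirrored_field(self, rng):
        shape = (14, 10, 4)
        masks = {}
        blob = rng.random((5, 5)) < 0.6
        blob[2, 2] = True
        for t in range(3):
            m = np.zeros(shape[:2], dtype=bool)
            m[3 + t : 8 + t, 2:7] |= blob
            masks[t] = m
        w = record(masks, shape)
        wm = record({t: m[::-1, :] for t, m in masks.items()}, shape)
        xy, v = flow_field(w)
        xym, vm = flow_field(wm)
        # match pixels through the mirror map x -> nx-1-x
        lut = {(shape[0] - 1 - x, y): tuple(vv) for (x, y), vv in zip(map(tuple, xy), v)}
        for (x, y), (vx, vy) in zip(map(tuple, xym), vm):
            evx, evy = lut[(x, y)]
            assert vx == pytest.approx(-evx)
            assert vy == pytest.approx(evy)


class TestDirection:
    def test_cardinal_classification(self):
        assert classify_direction(1.0, 0.0) == "nasal"
        assert classify_direction(-1.0, 0.0) == "temporal"
        assert classify_direction(0.0, 1.0) == "dorsal"
        assert classify_direction(0.0, -1.0) == "ventral"

    def test_bin_boundaries(self):
        v44 = (np.cos(np.radians(44)), np.sin(np.radians(44)))
        v46 = (np.cos(np.radians(46)), np.sin(np.radians(46)))
        assert classify_direction(*v44) == "nasal"
        assert classify_direction(*v46) == "dorsal"
        # exact 45-degree tie falls counterclockwise into the next bin
        assert classify_direction(1.0, 1.0) == "dorsal"
        assert classify_direction(-1.0, 1.0) == "temporal"

    def test_zero_vector_unclassified(self):
        assert classify_direction(0.0, 0.0) is None

    def test_propagation_direction_of_planar_wave(self):
        shape = (12, 6, 5)
        masks = {t: column_mask(shape, 3 + t) for t in range(4)}
        vec, cls = propagation_direction(record(masks, shape))
        assert cls == "nasal"
        assert vec[0] > 0

    def test_nbi_values(self):
        classes = ["nasal"] * 10 + ["temporal"] * 10 + ["dorsal"] * 10 + ["ventral"] * 10
        assert nasal_bias(classes) == 0.25
        assert nasal_bias(["nasal"] * 7) == 1.0
        with pytest.raises(UndefinedResultError):
            nasal_bias([None, None])


class TestLocalSynchrony:
    def _setup(self, ahead_counts):
        shape = (10, 4, 3)
        masks = {0: column_mask(shape, 2), 1: column_mask(shape, 2) | column_mask(shape, 3)}
        w = record(masks, shape)
        data = np.zeros(shape, dtype=np.int32)
        data[2, :, 0] = 5          # wave body at t=0
        data[3, :, 1] = 5          # wavefront at t=1
        data[2, :, 1] = 5          # persisting wave activity
        data[6, :, 1] = ahead_counts  # activity ahead of the front at t=1
        return w, ActivityMovie(data=data)

    def test_no_activity_ahead_gives_one(self):
        w, movie = self._setup(0)
        assert local_synchrony(w, movie) == 1.0

    def test_equal_activity_ahead_gives_half(self):
        w, movie = self._setup(5)
        assert local_synchrony(w, movie) == 0.5

    def test_single_frame_wave_undefined(self):
        shape = (4, 4, 2)
        m = np.zeros((4, 4), dtype=bool)
        m[1, 1] = m[1, 2] = True
        with pytest.raises(UndefinedResultError):
            local_synchrony(record({0: m}, shape), ActivityMovie(data=np.ones(shape)))

    def test_recovers_known_ahead_mass_ratio(self):
        """LSI on simulated waves with ahead/front mass ratio r -> 1/(1+r)."""
        from waveminer import extract_waves
        from waveminer.synthetic import SimulationParams, simulate
        from waveminer import rasterize

        r = 0.5
        # temporal-half origins moving nasally keep every wavefront (and the
        # injected ahead band) inside the grid, so the full ahead mass lands
        p = SimulationParams(
            duration_s=1200, wave_rate_per_min=2.0, tonic_rate_hz=0.0,
            ahead_noise_ratio=r, direction_distribution=(1.0, 0, 0, 0),
            initiation_p_nasal=0.0, rng_seed=7,
        )
        spikes, truth = simulate(p)
        movie = rasterize(spikes)
        waves = extract_waves(truth.label_matrix())
        lsis = [local_synchrony(w, movie) for w in waves if w.n_frames >= 2]
        assert len(lsis) >= 30
        assert np.mean(lsis) == pytest.approx(1 / (1 + r), abs=0.05)


class TestOccurrence:
    def test_frequency_formula_single_pixel(self):
        labels = np.zeros((1, 1, 600), dtype=np.int32)
        labels[0, 0, 10:13] = 1
        labels[0, 0, 300:303] = 2
        wlm = label_matrix(labels)
        assert wave_frequency(wlm, recording_s=600.0) == pytest.approx(0.2)

    def test_no_waves_zero_frequency(self):
        wlm = label_matrix(np.zeros((4, 4, 100), dtype=np.int32))
        assert wave_frequency(wlm, recording_s=100.0) == 0.0

    def test_frequency_halves_when_frame_interval_doubles(self):
        labels = np.zeros((2, 2, 300), dtype=np.int32)
        labels[0, 0, 10:12] = 1
        a = wave_frequency(label_matrix(labels, frame_s=1.0))
        b = wave_frequency(label_matrix(labels, frame_s=2.0))
        assert b == pytest.approx(a / 2)

    def test_iwi_between_two_waves(self):
        labels = np.zeros((1, 1, 400), dtype=np.int32)
        labels[0, 0, 60:63] = 1
        labels[0, 0, 180:184] = 2
        iwi = inter_wave_intervals(label_matrix(labels))
        np.testing.assert_allclose(iwi, [2.0])

    def test_single_wave_pixel_contributes_nothing(self):
        labels = np.zeros((2, 1, 200), dtype=np.int32)
        labels[0, 0, 50:53] = 1
        assert inter_wave_intervals(label_matrix(labels)).size == 0

    def test_per_pixel_onsets_used_not_wave_onsets(self):
        # wave 1 reaches pixel 1 later than pixel 0: per-pixel intervals differ
        labels = np.zeros((2, 1, 400), dtype=np.int32)
        labels[0, 0, 0] = labels[1, 0, 60] = 1
        labels[0, 0, 120] = labels[1, 0, 120] = 2
        iwi = np.sort(inter_wave_intervals(label_matrix(labels)))
        np.testing.assert_allclose(iwi, [1.0, 2.0])
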