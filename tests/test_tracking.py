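"""The imaging chain: trimming, background, segmentation, linking."""

import numpy as np
import pytest

from chemokin.rendering import render_frames
from chemokin.tracking import (
    FrameSeries,
    assign_population,
    exclude_tracks,
    filter_min_length,
    link_tracks,
    segment_frame,
    subtract_background,
    trim_and_downsample,
)

from conftest import make_track


def series_of(images, interval, px=1.3, t0=0.0):
    return FrameSeries(np.asarray(images, dtype=float), interval, px, t0_offset=t0)


class TestTrimAndDownsample:
    def test_stride_for_camera_rate(self):
        # 0.3 fps (3.333 s/frame) thinned to >= 15 s -> stride 5, 16.67 s
        n = 300
        s = series_of(np.zeros((n, 4, 4)), 10.0 / 3.0)
        out = trim_and_downsample(s, start_after_release=60.0, window=600.0)
        assert out.frame_interval == pytest.approx(50.0 / 3.0)

    def test_identity_when_target_equals_interval(self):
        imgs = np.arange(45 * 4).reshape(45, 2, 2).astype(float)
        s = series_of(imgs, 15.0)
        out = trim_and_downsample(s, start_after_release=0.0, window=660.0,
                                  target_interval=15.0)
        np.testing.assert_array_equal(out.images, imgs)

    def test_at_most_41_frames_in_10_min_window(self):
        s = series_of(np.zeros((400, 2, 2)), 10.0 / 3.0)
        out = trim_and_downsample(s, 60.0, 600.0, 15.0)
        assert len(out) <= 41

    def test_truncation_warns(self):
        s = series_of(np.zeros((10, 2, 2)), 15.0)
        with pytest.warns(UserWarning):
            trim_and_downsample(s, 0.0, 600.0, 15.0)

    def test_target_below_interval_rejected(self):
        s = series_of(np.zeros((5, 2, 2)), 15.0)
        with pytest.raises(ValueError):
            trim_and_downsample(s, 0.0, 60.0, target_interval=5.0)

    def test_release_offset_respected(self):
        # release 120 s into the recording; analysis starts 60 s later
        s = series_of(np.arange(100)[:, None, None] * np.ones((1, 2, 2)), 15.0,
                      t0=120.0)
        out = trim_and_downsample(s, 60.0, 120.0, 15.0)
        assert out.images[0, 0, 0] == 12  # frame at t = 180 s
        assert out.t0_offset == pytest.approx(-60.0)


class TestBackgroundSubtraction:
    def test_constant_frame_goes_to_zero(self):
        s = series_of(np.full((3, 8, 8), 42.0), 15.0)
        np.testing.assert_array_equal(subtract_background(s).images, 0.0)

    def test_blob_peak_reduced_by_background(self):
        img = np.full((64, 64), 10.0)
        img[30, 30] = 210.0
        out = subtract_background(series_of(img[None], 15.0))
        assert out.images[0, 30, 30] == pytest.approx(200.0)

    def test_noisy_background_residual_small(self, rng):
        bg = 500.0
        imgs = rng.normal(bg, 3.0, size=(5, 128, 128))
        out = subtract_background(series_of(np.clip(imgs, 0, None), 15.0))
        # 5th-percentile estimator under-subtracts by ~1.6 sigma
        assert abs(out.images.mean()) < 0.02 * bg


class TestSegmentation:
    def test_blank_frame_empty(self):
        c, a = segment_frame(np.zeros((32, 32)))
        assert c.shape == (0, 2)

    def test_two_blobs_recovered_subpixel(self):
        t1 = make_track([(40 * 1.3, 40 * 1.3)])
        t2 = make_track([(90 * 1.3, 40 * 1.3)], cell_id=1)  # 50 px apart
        stack, _ = render_frames([t1, t2], image_shape=(128, 128), noise=False)
        sub = subtract_background(series_of(stack, 15.0))
        cents, areas = segment_frame(sub.images[0])
        assert len(cents) == 2
        for truth in ((40.0, 40.0), (90.0, 40.0)):
            err = np.linalg.norm(cents - truth, axis=1).min()
            assert err < 0.1

    def test_min_area_filter(self):
        img = np.zeros((32, 32))
        img[10, 10] = 100.0  # single-pixel speck
        c, _ = segment_frame(img, min_area=9)
        assert len(c) == 0

    def test_invalid_input(self):
        with pytest.raises(ValueError):
            segment_frame(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError):
            segment_frame(-np.ones((4, 4)))


class TestLinking:
    def test_two_separated_cells_two_tracks(self):
        a = np.array([10.0, 10.0])
        b = np.array([200.0, 200.0])
        frames = [np.vstack([a + i, b - i]) for i in range(25)]
        ts = link_tracks(frames, 15.0, max_disp=5.0, min_length=20)
        assert len(ts) == 2
        for tr in ts:
            assert len(tr) == 25
            steps = np.linalg.norm(np.diff(tr.positions, axis=0), axis=1)
            assert np.all(steps < 5.0)  # no identity switches

    def test_min_length_threshold_is_inclusive(self):
        # tracks of lengths 10, 19, 20, 25, 40 -> exactly 3 survive
        lengths = [10, 19, 20, 25, 40]
        frames = []
        for f in range(max(lengths)):
            dets = [
                (100.0 * i, 0.0) for i, L in enumerate(lengths) if f < L
            ]
            frames.append(np.array(dets))
        ts = link_tracks(frames, 15.0, max_disp=5.0, min_length=20)
        assert sorted(len(tr) for tr in ts) == [20, 25, 40]

    def test_permutation_invariance(self, rng):
        base = [rng.uniform(0, 500, size=(8, 2)) + f for f in range(22)]
        shuffled = [d[rng.permutation(len(d))] for d in base]
        a = link_tracks(base, 15.0, max_disp=10.0, min_length=20)
        b = link_tracks(shuffled, 15.0, max_disp=10.0, min_length=20)
        pos_a = sorted(tuple(map(tuple, tr.positions)) for tr in a)
        pos_b = sorted(tuple(map(tuple, tr.positions)) for tr in b)
        assert pos_a == pos_b

    def test_gap_ends_track(self):
        # a missed detection terminates the track (no gap closing)
        frames = [np.array([[0.0, 0.0]])] * 21 + [np.empty((0, 2))] + [
            np.array([[0.0, 0.0]])
        ] * 21
        ts = link_tracks(frames, 15.0, max_disp=5.0, min_length=20)
        assert len(ts) == 2
        assert all(len(tr) == 21 for tr in ts)

    def test_empty_input(self):
        ts = link_tracks([], 15.0, max_disp=5.0)
        assert len(ts) == 0

    def test_filter_idempotent(self):
        frames = [np.array([[float(f), 0.0]]) for f in range(30)]
        ts = link_tracks(frames, 15.0, max_disp=5.0, min_length=20)
        once = filter_min_length(ts, 20)
        twice = filter_min_length(once, 20)
        assert [len(t) for t in once] == [len(t) for t in twice]

    def test_curation_hook_logged(self):
        frames = [np.array([[0.0, 0.0], [300.0, 300.0]])] * 25
        ts = link_tracks(frames, 15.0, max_disp=5.0, min_length=20)
        curated = exclude_tracks(ts, [0])
        assert len(curated) == len(ts) - 1
        assert curated.provenance["curation"][0]["excluded_ids"] == [0]
        untouched = exclude_tracks(ts)
        assert len(untouched) == len(ts)


class TestPopulationAssignment:
    def test_single_dye_cell(self):
        assert assign_population([900.0] * 5, [10.0] * 5) == "population_A"
        assert assign_population([10.0] * 5, [900.0] * 5) == "population_B"

    def test_equal_intensities_unassigned(self):
        assert assign_population([100.0] * 5, [100.0] * 5) == "unassigned"

    def test_mixed_dish_recovery(self, rng):
        # 1:1 mix with realistic intensity scatter: recovered split is
        # within binomial noise of 50/50
        n = 200
        truth = rng.integers(0, 2, n)
        labels = []
        for t in truth:
            bright = rng.normal(800, 80, size=10)
            dim = rng.normal(60, 15, size=10)
            g, o = (bright, dim) if t == 0 else (dim, bright)
            labels.append(assign_population(g, o))
        n_a = labels.count("population_A")
        assert labels.count("unassigned") == 0
        assert abs(n_a - (truth == 0).sum()) == 0
        assert abs(n_a - n / 2) < 3 * np.sqrt(n * 0.25)

    def test_missing_channel_rejected(self):
        with pytest.raises(ValueError):
            assign_population([1.0, 2.0], [])
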