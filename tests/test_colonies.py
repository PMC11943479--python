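import numpy as np
import pytest
from skimage.measure import regionprops

from mentholtox import colonies as co
from mentholtox import synthetic as syn
from mentholtox.synthetic import _raster_ellipse


def frame_from_mask(mask, phase=None, t=0.0):
    label = mask.astype(np.int32)
    if phase is None:
        phase = np.full(mask.shape, 100.0)
    return co.MaskFrame(label, phase, timestamp_h=t)


def ellipse_frame(semi_major, semi_minor, angle_deg=0.0, shape=(301, 301)):
    mask = _raster_ellipse(shape, (shape[0] / 2, shape[1] / 2),
                           semi_major, semi_minor, np.deg2rad(angle_deg))
    return frame_from_mask(mask)


class TestArea:
    def test_disk_matches_pi_r_squared(self):
        frame = ellipse_frame(50, 50)
        assert co.colony_area(frame, 1) == pytest.approx(np.pi * 50**2, rel=0.02)

    def test_absent_label_errors_with_id(self):
        frame = ellipse_frame(20, 20)
        with pytest.raises(ValueError, match="colony 7"):
            co.colony_area(frame, 7)

    def test_disjoint_labels_sum_to_foreground(self):
        label = np.zeros((100, 100), dtype=np.int32)
        label[10:30, 10:30] = 1
        label[60:90, 60:80] = 2
        frame = co.MaskFrame(label, np.zeros((100, 100)), 0.0)
        total = co.colony_area(frame, 1) + co.colony_area(frame, 2)
        assert total == np.count_nonzero(label)

    def test_physical_units(self):
        label = np.zeros((10, 10), dtype=np.int32)
        label[0:2, 0:2] = 1
        frame = co.MaskFrame(label, np.zeros((10, 10)), 0.0, pixel_size_um=2.0)
        assert co.colony_area(frame, 1, physical=True) == pytest.approx(16.0)


class TestBrightnessRatio:
    def test_uniform_colony_is_zero_with_warning(self):
        frame = ellipse_frame(30, 30)
        with pytest.warns(UserWarning, match="constant intensity"):
            assert co.brightness_area_ratio(frame, 1) == 0.0

    def test_programmed_speckle_fraction_recovered(self):
        spec = syn.ColonyMovieSpec(seed=21, n_colonies=4, n_frames=2,
                                   image_shape=(256, 256), initial_radius_px=25,
                                   speckle_fraction=0.10, walk_sd_px=0.0)
        frames, corr, truth = syn.gen_colony_movie(spec)
        ratios = [co.brightness_area_ratio(frames[0], lab)
                  for lab in frames[0].labels()]
        assert np.mean(ratios) == pytest.approx(0.10, abs=0.01)

    def test_absolute_threshold_all_above_gives_one(self):
        mask = _raster_ellipse((64, 64), (32, 32), 10, 10, 0.0)
        frame = frame_from_mask(mask, phase=np.full((64, 64), 200.0))
        assert co.brightness_area_ratio(frame, 1, absolute_threshold=150.0) == 1.0

    def test_ratio_bounded(self):
        spec = syn.ColonyMovieSpec(seed=22, n_colonies=4, n_frames=2,
                                   image_shape=(256, 256), speckle_fraction=0.5)
        frames, _, _ = syn.gen_colony_movie(spec)
        for lab in frames[0].labels():
            r = co.brightness_area_ratio(frames[0], lab)
            assert 0.0 <= r <= 1.0


class TestAxisRatio:
    def test_circle_is_one(self):
        assert co.axis_ratio(ellipse_frame(50, 50), 1) == pytest.approx(1.0, rel=0.01)

    def test_ellipse_80_40_is_two(self):
        assert co.axis_ratio(ellipse_frame(80, 40), 1) == pytest.approx(2.0, rel=0.03)

    def test_rotation_invariance(self):
        upright = co.axis_ratio(ellipse_frame(80, 40), 1)
        rotated = co.axis_ratio(ellipse_frame(80, 40, angle_deg=37.0), 1)
        assert rotated == pytest.approx(upright, rel=0.03)
        assert rotated == pytest.approx(2.0, rel=0.03)

    def test_translation_invariance(self):
        shape = (301, 301)
        m1 = _raster_ellipse(shape, (120, 120), 60, 30, 0.5)
        m2 = _raster_ellipse(shape, (170, 185), 60, 30, 0.5)
        r1 = co.axis_ratio(frame_from_mask(m1), 1)
        r2 = co.axis_ratio(frame_from_mask(m2), 1)
        assert r1 == pytest.approx(r2, rel=1e-6)
        a1 = co.colony_area(frame_from_mask(m1), 1)
        a2 = co.colony_area(frame_from_mask(m2), 1)
        assert a1 == a2

    def test_agrees_with_regionprops(self):
        frame = ellipse_frame(70, 35, angle_deg=20.0)
        props = regionprops(frame.label_image)[0]
        expected = props.axis_major_length / props.axis_minor_length
        assert co.axis_ratio(frame, 1) == pytest.approx(expected, rel=1e-6)

    def test_tiny_colony_rejected(self):
        label = np.zeros((10, 10), dtype=np.int32)
        label[5, 5] = 1
        with pytest.raises(ValueError, match="below minimum"):
            co.axis_ratio(co.MaskFrame(label, np.zeros((10, 10)), 0.0), 1)


class TestTracking:
    def test_static_labels_identity_tracks(self):
        frames, corr, _ = syn.gen_colony_movie(syn.ColonyMovieSpec(
            seed=31, n_colonies=4, n_frames=5, image_shape=(256, 256),
            walk_sd_px=0.0, permute_labels=False))
        tracks = co.track_colonies(frames)
        assert all(t.full_length for t in tracks)
        for t in tracks:
            assert len(set(t.labels)) == 1

    def test_drifting_colonies_tracked_against_truth(self):
        spec = syn.ColonyMovieSpec(seed=32, n_colonies=9, n_frames=8,
                                   image_shape=(512, 512),
                                   drift_px_per_frame=(1.5, 0.8), walk_sd_px=1.0)
        frames, corr, _ = syn.gen_colony_movie(spec)
        tracks = co.track_colonies(frames)
        full = [t for t in tracks if t.full_length]
        assert len(full) == 9
        first = corr[corr["frame"] == 0].set_index("label")["colony"]
        by_frame_colony = corr.set_index(["frame", "colony"])["label"]
        for t in full:
            true_colony = first[t.labels[0]]
            expected = [by_frame_colony[(fi, true_colony)] for fi in t.frame_indices]
            assert t.labels == expected  # 100% correct assignment

    def test_colony_leaving_field_truncated_and_excluded(self):
        shape = (128, 128)
        frames = []
        for fi in range(4):
            label = np.zeros(shape, dtype=np.int32)
            label[_raster_ellipse(shape, (40, 40), 12, 12, 0.0)] = 1
            if fi < 2:  # second colony disappears after frame 1
                label[_raster_ellipse(shape, (90, 90), 12, 12, 0.0)] = 2
            frames.append(co.MaskFrame(label, np.zeros(shape), float(fi)))
        tracks = co.track_colonies(frames)
        by_id = {t.colony_id: t for t in tracks}
        assert by_id[1].full_length
        assert not by_id[2].full_length
        table = co.feature_table(frames, tracks)
        assert set(table["colony_id"]) == {1}

    def test_needs_two_frames(self):
        frames, _, _ = syn.gen_colony_movie(syn.ColonyMovieSpec(
            seed=33, n_colonies=2, n_frames=2, image_shape=(128, 128)))
        with pytest.raises(ValueError, match=">= 2 frames"):
            co.track_colonies(frames[:1])


class TestMotility:
    def track_from_points(self, pts):
        t = co.ColonyTrack(colony_id=1)
        for i, p in enumerate(pts):
            t.frame_indices.append(i)
            t.timestamps_h.append(4.0 * i)
            t.labels.append(1)
            t.centroids.append(tuple(p))
            t.areas.append(100.0)
        return t

    def test_closed_square_path(self):
        pts = [(0, 0), (0, 10), (10, 10), (10, 0), (0, 0)]
        m = co.motility_features(self.track_from_points(pts))
        assert m["total_displacement"] == 0.0
        assert m["total_distance"] == pytest.approx(40.0)

    def test_straight_line_equality(self):
        pts = [(0, 0), (3, 4), (6, 8)]
        m = co.motility_features(self.track_from_points(pts))
        assert m["total_distance"] == pytest.approx(m["total_displacement"]) == 10.0

    def test_random_walk_monte_carlo(self):
        """RMS displacement ~ sigma*sqrt(2n); mean distance ~ n*sigma*sqrt(pi/2)."""
        rng = np.random.default_rng(99)
        sigma, n_steps, n_walks = 2.0, 40, 500
        disps, dists = [], []
        for _ in range(n_walks):
            steps = rng.normal(0, sigma, (n_steps, 2))
            pts = np.vstack([[0, 0], np.cumsum(steps, axis=0)])
            m = co.motility_features(self.track_from_points(pts))
            assert m["total_displacement"] <= m["total_distance"] + 1e-9
            disps.append(m["total_displacement"])
            dists.append(m["total_distance"])
        rms_disp = np.sqrt(np.mean(np.square(disps)))
        assert rms_disp == pytest.approx(sigma * np.sqrt(2 * n_steps), rel=0.10)
        assert np.mean(dists) == pytest.approx(
            n_steps * sigma * np.sqrt(np.pi / 2), rel=0.10
        )

    def test_single_frame_rejected(self):
        with pytest.raises(ValueError, match=">= 2 frames"):
            co.motility_features(self.track_from_points([(0, 0)]))


class TestNormalizeSeries:
    def test_constant_series_all_ones(self):
        assert np.allclose(co.normalize_series(np.full(5, 7.0)), 1.0)

    def test_doubling_series(self):
        out = co.normalize_series(np.array([100.0, 200.0, 400.0]))
        assert np.allclose(out, [1.0, 2.0, 4.0])

    def test_zero_first_value_rejected(self):
        with pytest.raises(ValueError, match="first value"):
            co.normalize_series(np.array([0.0, 1.0]))

    def test_growth_rate_recovery_from_normalized_area(self):
        spec = syn.ColonyMovieSpec(seed=41, n_colonies=4, n_frames=10,
                                   image_shape=(512, 512), initial_radius_px=25,
                                   growth_rate_per_h=0.02, walk_sd_px=0.0)
        frames, _, truth = syn.gen_colony_movie(spec)
        table = co.feature_table(frames)
        for _, grp in table.groupby("colony_id"):
            slope = np.polyfit(grp["time_h"], np.log(grp["normalized_area"]), 1)[0]
            assert slope == pytest.approx(truth["growth_rate_per_h"], rel=0.05)
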