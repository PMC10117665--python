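import itertools
import math

import numpy as np
import pytest

from droptrap.flow import classify_pattern
from droptrap.synth import _add_fish_ellipse, _add_gaussian_spot
from droptrap.tracking import (
    Detection,
    FrameStack,
    TrackedTrajectory,
    detect,
    detect_stack,
    fill_grid_to_disk,
    link,
    load_tracks,
    save_tracks,
    track_stack,
    tracks_to_physical,
    velocity_grid_from_tracks,
)


class TestDetect:
    def test_gaussian_spot_subpixel_centroid(self):
        frame = np.zeros((64, 96))
        _add_gaussian_spot(frame, 40.3, 17.8, sigma=2.0, amp=1.0)
        dets = detect(frame, threshold=0.3, min_area=4)
        assert len(dets) == 1
        assert dets[0].x_px == pytest.approx(40.3, abs=0.1)
        assert dets[0].y_px == pytest.approx(17.8, abs=0.1)

    def test_blank_frame_empty(self):
        assert detect(np.zeros((32, 32))) == []

    def test_ellipse_orientation_recovered(self):
        frame = np.zeros((128, 128))
        _add_fish_ellipse(frame, 64.0, 64.0, 37.0, 30.0, 6.0, head_boost=0.0)
        dets = detect(frame, threshold=0.5, min_area=20, with_orientation=True)
        assert len(dets) == 1
        assert dets[0].orientation_deg == pytest.approx(37.0, abs=1.0)

    def test_orientation_modulo_180(self):
        f1 = np.zeros((128, 128))
        f2 = np.zeros((128, 128))
        _add_fish_ellipse(f1, 64, 64, 20.0, 30.0, 6.0, head_boost=0.0)
        _add_fish_ellipse(f2, 64, 64, 200.0, 30.0, 6.0, head_boost=0.0)
        d1 = detect(f1, 0.5, 20, with_orientation=True)[0]
        d2 = detect(f2, 0.5, 20, with_orientation=True)[0]
        assert d1.orientation_deg == pytest.approx(d2.orientation_deg, abs=0.5)

    @pytest.mark.parametrize("true_angle", [20.0, 200.0, 95.0, 275.0])
    def test_head_disambiguation_from_brightness(self, true_angle):
        # the brighter ellipse end marks the head, lifting the 180 ambiguity
        frame = np.zeros((128, 128))
        _add_fish_ellipse(frame, 64, 64, true_angle, 30.0, 6.0, head_boost=0.8)
        d = detect(frame, 0.4, 20, with_orientation=True, resolve_head=True)[0]
        diff = abs(d.orientation_deg - true_angle) % 360.0
        assert min(diff, 360.0 - diff) < 1.5

    def test_intensity_scale_invariance(self):
        frame = np.zeros((64, 64))
        _add_gaussian_spot(frame, 20.0, 30.0, 2.0, 1.0)
        _add_gaussian_spot(frame, 45.2, 12.7, 2.0, 0.8)
        a = detect(frame, 0.3, 4)
        b = detect(frame * 137.0, 0.3, 4)
        assert [(d.x_px, d.y_px, d.area_px) for d in a] == [
            (d.x_px, d.y_px, d.area_px) for d in b
        ]

    def test_min_area_filters_specks(self):
        frame = np.zeros((32, 32))
        frame[5, 5] = 1.0
        assert detect(frame, threshold=0.5, min_area=4) == []


def _dets(frame, pts):
    return [Detection(frame, x, y, 1) for x, y in pts]


class TestLink:
    def test_parallel_tracks_keep_identity(self):
        per_frame = [
            _dets(k, [(10.0 + k, 10.0), (10.0 + k, 40.0)]) for k in range(20)
        ]
        tracks = link(per_frame, max_disp=5.0)
        assert len(tracks) == 2
        for tr in tracks:
            ys = {d.y_px for d in tr}
            assert len(ys) == 1  # never hops between the two lines
            assert len(tr) == 20

    def test_missing_frame_splits_track(self):
        per_frame = [_dets(0, [(5.0, 5.0)]), [], _dets(2, [(5.0, 5.0)])]
        tracks = link(per_frame, max_disp=5.0)
        assert sorted(len(t) for t in tracks) == [1, 1]

    def test_crossing_assignment_is_globally_optimal(self):
        # two particles swap-ambiguous at the crossing: the linker's total
        # displacement must not exceed the brute-force best assignment
        prev = [(10.0, 20.0), (10.0, 24.0)]
        cur = [(12.0, 21.9), (12.0, 22.1)]
        per_frame = [_dets(0, prev), _dets(1, cur)]
        tracks = link(per_frame, max_disp=10.0)
        chosen = 0.0
        for tr in tracks:
            assert len(tr) == 2
            chosen += math.hypot(tr[1].x_px - tr[0].x_px, tr[1].y_px - tr[0].y_px)
        best = min(
            sum(
                math.hypot(c[0] - p[0], c[1] - p[1])
                for p, c in zip(prev, perm)
            )
            for perm in itertools.permutations(cur)
        )
        assert chosen == pytest.approx(best)

    def test_far_jump_starts_new_track(self):
        per_frame = [_dets(0, [(5.0, 5.0)]), _dets(1, [(50.0, 50.0)])]
        tracks = link(per_frame, max_disp=5.0)
        assert sorted(len(t) for t in tracks) == [1, 1]

    def test_input_order_invariance(self):
        rng = np.random.default_rng(7)
        base = [
            [(10.0 + k, 10.0 + 3 * j) for j in range(5)] for k in range(10)
        ]
        per_frame = [_dets(k, pts) for k, pts in enumerate(base)]
        shuffled = []
        for k, pts in enumerate(base):
            pts = list(pts)
            rng.shuffle(pts)
            shuffled.append(_dets(k, pts))
        t1 = link(per_frame, max_disp=4.0)
        t2 = link(shuffled, max_disp=4.0)
        key = lambda tr: (tr[0].x_px, tr[0].y_px)
        for a, b in zip(sorted(t1, key=key), sorted(t2, key=key)):
            assert [(d.x_px, d.y_px) for d in a] == [(d.x_px, d.y_px) for d in b]


class TestVelocityGrid:
    def test_pure_strain_recovered_from_tracks(self):
        # advect ground-truth points through (u, v) = (x, -y); no imaging
        rng = np.random.default_rng(0)
        dt = 1 / 30
        tracks = []
        for tid in range(200):
            x0 = rng.uniform(-0.8, 0.8)
            y0 = rng.uniform(-0.8, 0.8)
            t = np.arange(10) * dt
            tracks.append(
                TrackedTrajectory(
                    tid, np.arange(10), t, x0 * np.exp(t), y0 * np.exp(-t)
                )
            )
        grid = velocity_grid_from_tracks(tracks, n_per_axis=32)
        X = np.broadcast_to(grid.x_coords, grid.u.shape)
        got = grid.u[grid.mask]
        want = X[grid.mask]
        r = np.corrcoef(got, want)[0, 1]
        assert r > 0.95

    def test_stationary_particles_zero_grid(self):
        t = np.arange(5) * 0.1
        tracks = [
            TrackedTrajectory(i, np.arange(5), t, np.full(5, float(i)), np.zeros(5))
            for i in range(3)
        ]
        grid = velocity_grid_from_tracks(tracks, n_per_axis=32)
        assert np.allclose(grid.u[grid.mask], 0.0)
        assert np.allclose(grid.v[grid.mask], 0.0)

    def test_no_samples_raises(self):
        t = np.array([0.0])
        tracks = [TrackedTrajectory(0, np.array([0]), t, np.zeros(1), np.zeros(1))]
        with pytest.raises(ValueError):
            velocity_grid_from_tracks(tracks)


class TestRoundTrip:
    def test_render_detect_link_recovers_positions(self, small_scene):
        spec, stack, truth = small_scene
        tracks_px = link(detect_stack(stack, threshold=0.3, min_area=3), max_disp=8.0)
        n_total = sum(len(f) for f in truth)
        n_matched = 0
        by_frame = {}
        for tr in tracks_px:
            for d in tr:
                by_frame.setdefault(d.frame_index, []).append(d)
        for k, gts in enumerate(truth):
            dets = by_frame.get(k, [])
            for g in gts:
                if dets and min(
                    math.hypot(d.x_px - g.x_px, d.y_px - g.y_px) for d in dets
                ) < 0.5:
                    n_matched += 1
        assert n_matched / n_total >= 0.99

    def test_no_identity_swaps_for_separated_tracks(self, small_scene):
        spec, stack, truth = small_scene
        tracks = track_stack(stack, threshold=0.3, min_area=3, max_disp=8.0)
        # a swap would show up as a step much larger than the advection step
        for tr in tracks:
            if len(tr) < 2:
                continue
            steps = np.hypot(np.diff(tr.x_m), np.diff(tr.y_m))
            assert steps.max() < 8.0 * spec.px_scale

    def test_recovered_grid_classifies_four_cell(self, dense_scene):
        spec, stack, truth = dense_scene
        tracks = track_stack(stack, threshold=0.3, min_area=3, max_disp=8.0)
        grid = velocity_grid_from_tracks(tracks, n_per_axis=32)
        cx = float(np.mean(grid.x_coords))
        cy = float(np.mean(grid.y_coords))
        grid = fill_grid_to_disk(grid, (cx, cy), 0.95 * spec.droplet_radius)
        label, n = classify_pattern(grid)
        assert label == "four_cell"


def test_tracks_csv_roundtrip(tmp_path, small_scene):
    _, stack, _ = small_scene
    tracks = track_stack(stack, threshold=0.3, min_area=3, max_disp=8.0)
    path = save_tracks(tracks, tmp_path / "tracks.csv")
    back = load_tracks(path)
    assert len(back) == len(tracks)
    np.testing.assert_allclose(back[0].x_m, tracks[0].x_m)
    np.testing.assert_allclose(back[0].times_s, tracks[0].times_s)
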