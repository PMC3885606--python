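"""Multi-worm tracking, trail smoothing, and velocity statistics."""

import numpy as np
import pytest

from wormquant import simulate
from wormquant.core import GrayImage
from wormquant.locomotion import (
    Track,
    TrackerParams,
    analyze_video,
    build_tracks,
    detect_frame_objects,
    is_stationary,
    smooth_track,
    summarize_velocities,
    track_speed_px_per_frame,
    track_velocity,
)


def make_track(path, fps_frames=None):
    path = np.asarray(path, dtype=float)
    frames = list(range(len(path))) if fps_frames is None else fps_frames
    t = Track(id=0, frames=frames, raw_centroids=path,
              areas=[100] * len(path), end_reason="video_end")
    t.smoothed_path = smooth_track(path)
    return t


class TestDetectFrameObjects:
    def test_blank_frame_gives_nothing(self):
        frame = GrayImage(np.full((200, 200), 220, np.uint8))
        assert detect_frame_objects(frame, TrackerParams()) == []

    def test_simulated_worms_all_detected(self):
        cfg = simulate.make_video_config([1.0] * 8, seed=21, n_frames=30)
        frames, _ = simulate.render_worm_video(cfg)
        regions = detect_frame_objects(GrayImage(frames[0]), TrackerParams())
        assert len(regions) == 8

    def test_round_blob_rejected_by_elongation(self):
        from skimage import draw as skdraw

        px = np.full((200, 200), 220, np.uint8)
        px[60:64, 30:70] = 30                 # elongated worm, area 160
        rr, cc = skdraw.disk((140, 140), 7)   # round blob, area ~154
        px[rr, cc] = 30
        regions = detect_frame_objects(GrayImage(px), TrackerParams())
        assert len(regions) == 1
        assert regions[0].eccentricity > 0.9


class TestBuildTracks:
    def test_single_worm_full_video_track(self):
        cfg = simulate.make_video_config([1.0], seed=2, n_frames=30)
        frames, _ = simulate.render_worm_video(cfg)
        tracks, _ = analyze_video(frames)
        assert len(tracks) == 1
        (t,) = tracks
        assert t.end_reason == "video_end"
        assert t.n_frames == 30

    def test_crossing_worms_end_in_collision_not_identity_swap(self):
        # two worms forced onto a simultaneous head-on crossing
        w1 = simulate.SimWorm(id=0, start=(100.0, 60.0), heading=0.0, speed=2.0)
        w2 = simulate.SimWorm(id=1, start=(100.0, 260.0), heading=np.pi,
                              speed=2.0)
        cfg = simulate.SimConfig(frame_size=(200, 320), n_frames=60,
                                 worms=[w1, w2], background_level=255,
                                 worm_level=0, noise_sd=0.0)
        frames, _ = render = simulate.render_worm_video(cfg)
        p = TrackerParams(min_track_frames=5)
        per = [detect_frame_objects(GrayImage(f), p) for f in frames]
        tracks = build_tracks(per, p, frame_shape=frames[0].shape)
        collided = [t for t in tracks if t.end_reason == "collision"]
        assert len(collided) >= 2
        # no surviving track spans the crossing with centroids from both sides
        for t in tracks:
            cols = t.raw_centroids[:, 1]
            assert cols.max() - cols.min() < 130

    def test_worm_leaving_frame_ends_with_boundary(self):
        w = simulate.SimWorm(id=0, start=(60.0, 80.0), heading=0.0, speed=2.0)
        cfg = simulate.SimConfig(frame_size=(120, 160), n_frames=60, worms=[w],
                                 background_level=255, worm_level=0,
                                 noise_sd=0.0)
        # worm exits the right edge mid-video; renderer only checks frame 0
        frames = []
        for t in range(cfg.n_frames):
            mask = np.zeros(cfg.frame_size, bool)
            simulate.stamp_polyline(mask, simulate.worm_centerline(w, t),
                                    w.thickness / 2)
            f = np.full(cfg.frame_size, 255, np.uint8)
            f[mask] = 0
            frames.append(f)
        frames = np.stack(frames)
        p = TrackerParams(min_track_frames=5)
        per = [detect_frame_objects(GrayImage(f), p) for f in frames]
        tracks = build_tracks(per, p, frame_shape=frames[0].shape)
        assert any(t.end_reason == "boundary" for t in tracks)

    def test_every_region_used_by_at_most_one_track(self):
        cfg = simulate.make_video_config([1.0] * 6, seed=31, n_frames=40)
        frames, _ = simulate.render_worm_video(cfg)
        p = TrackerParams()
        per = [detect_frame_objects(GrayImage(f), p) for f in frames]
        tracks = build_tracks(per, p, frame_shape=frames[0].shape)
        seen = set()
        for t in tracks:
            for fr, cen in zip(t.frames, t.raw_centroids):
                key = (fr, round(cen[0], 3), round(cen[1], 3))
                assert key not in seen
                seen.add(key)

    def test_tight_gate_fragments_but_never_misjoins(self):
        cfg = simulate.make_video_config([2.0] * 4, seed=41, n_frames=60)
        frames, truth = simulate.render_worm_video(cfg)
        p = TrackerParams(max_step=1.0, min_track_frames=2)
        per = [detect_frame_objects(GrayImage(f), p) for f in frames]
        tracks = build_tracks(per, p, frame_shape=frames[0].shape)
        # every fragment's centroids stay near a single true trajectory
        trajs = [np.asarray(o["centroids"]) for o in truth.objects]
        for t in tracks:
            dists = []
            for traj in trajs:
                d = [np.hypot(*(traj[fr] - cen))
                     for fr, cen in zip(t.frames, t.raw_centroids)]
                dists.append(max(d))
            assert min(dists) < 10


class TestSmoothing:
    def test_collinear_points_reproduced(self):
        pts = np.stack([np.linspace(0, 20, 30), np.linspace(5, 45, 30)], axis=1)
        out = smooth_track(pts)
        assert np.abs(out - pts).max() < 0.5

    def test_two_points_pass_through(self):
        pts = np.array([[0.0, 0.0], [1.0, 2.0]])
        assert np.array_equal(smooth_track(pts), pts)

    def test_noise_residual_shrinks(self):
        rng = np.random.default_rng(0)
        line = np.stack([np.zeros(100), np.arange(100.0)], axis=1)
        noisy = line + rng.normal(0, 1.0, line.shape)
        out = smooth_track(noisy)
        assert np.std(out - line) < np.std(noisy - line)

    def test_smoothing_never_lengthens_straight_truth_tracks(self):
        rng = np.random.default_rng(1)
        line = np.stack([np.zeros(80), np.arange(80.0)], axis=1)
        for _ in range(10):
            noisy = line + rng.normal(0, 0.5, line.shape)
            raw_len = np.hypot(*np.diff(noisy, axis=0).T).sum()
            sm_len = np.hypot(*np.diff(smooth_track(noisy), axis=0).T).sum()
            assert sm_len <= raw_len


class TestVelocity:
    def test_straight_track_arithmetic(self):
        # 1 px/frame at 7 fps and 20 um/px -> 7 px/s -> 140 um/s
        path = np.stack([np.full(30, 50.0), 10 + np.arange(30.0)], axis=1)
        t = make_track(path)
        p = TrackerParams(fps=7.0, scale=20.0)
        assert track_velocity(t, p) == pytest.approx(140.0, rel=1e-6)

    def test_zero_duration_rejected(self):
        t = Track(id=0, frames=[3], raw_centroids=np.array([[0.0, 0.0]]),
                  areas=[50], end_reason="lost")
        with pytest.raises(ValueError):
            track_velocity(t, TrackerParams())

    def test_stationary_undulating_worm_excluded(self):
        rng = np.random.default_rng(2)
        path = np.array([[100.0, 100.0]]) + rng.normal(0, 1.0, (60, 2))
        t = make_track(path)
        p = TrackerParams(stationary_box=5.0)
        assert is_stationary(t, p)
        s = summarize_velocities([t], p)
        assert s.empty and s.n_excluded_stationary == 1

    def test_slow_simulated_worm_recovered_within_five_percent(self):
        cfg = simulate.make_video_config([0.25], seed=13, n_frames=210)
        frames, _ = simulate.render_worm_video(cfg)
        tracks, _ = analyze_video(frames)
        (t,) = tracks
        est = track_speed_px_per_frame(t, TrackerParams())
        assert abs(est - 0.25) / 0.25 < 0.05


class TestSummaries:
    def test_population_mean_of_three_tracks(self):
        p = TrackerParams(fps=7.0, scale=20.0)
        tracks = []
        for v_um_s in (100.0, 140.0, 180.0):
            step = v_um_s / (p.fps * p.scale)   # px per frame
            path = np.stack([np.full(30, 50.0),
                             np.arange(30.0) * step], axis=1)
            tracks.append(make_track(path))
        s = summarize_velocities(tracks, p)
        assert s.n_tracks == 3
        assert s.mean == pytest.approx(140.0, rel=1e-6)

    def test_single_track_mean_is_its_velocity(self):
        p = TrackerParams()
        t = make_track(np.stack([np.full(30, 5.0), np.arange(30.0)], axis=1))
        s = summarize_velocities([t], p)
        assert s.mean == pytest.approx(track_velocity(t, p))

    def test_two_cohort_video_histogram_is_bimodal(self):
        cfg = simulate.make_video_config([1.0] * 4 + [0.25] * 4, seed=17,
                                         n_frames=140)
        frames, _ = simulate.render_worm_video(cfg)
        tracks, _ = analyze_video(frames)
        p = TrackerParams()
        speeds = sorted(track_speed_px_per_frame(t, p) for t in tracks)
        assert len(speeds) == 8
        assert all(s < 0.5 for s in speeds[:4])
        assert all(s > 0.5 for s in speeds[4:])
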