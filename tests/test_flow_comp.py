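import numpy as np
import pytest
from scipy import ndimage

from ippg import errors, flow_comp, synth


def gaussian_blob(shape, cx, cy, sigma=3.0, amp=100.0):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    return amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))


def subpixel_shift_oracle(prev, next_, point, window=15, search=1.0, step=0.01):
    """Independent displacement oracle: minimize the SSD between the fixed
    window of ``prev`` and spline-shifted windows of ``next_`` over a fine
    sub-pixel search grid."""
    x, y = point
    half = window // 2
    gy, gx = np.mgrid[y - half : y + half + 1, x - half : x + half + 1].astype(float)
    ref = ndimage.map_coordinates(prev, [gy, gx], order=3, mode="nearest")
    best, best_uv = np.inf, (0.0, 0.0)
    for u in np.arange(-search, search + step / 2, step):
        for v in np.arange(-search, search + step / 2, step):
            cand = ndimage.map_coordinates(next_, [gy + v, gx + u], order=3, mode="nearest")
            ssd = float(((cand - ref) ** 2).sum())
            if ssd < best:
                best, best_uv = ssd, (u, v)
    return best_uv


class TestLkFlow:
    def test_identical_frames_give_zero_flow(self, rng):
        frame = rng.uniform(0, 255, size=(40, 40))
        est = flow_comp.lk_flow(frame, frame, (20, 20))
        assert abs(est.u) < 1e-9 and abs(est.v) < 1e-9
        assert est.conditioning > 0

    def test_translated_blob_flow_matches_correlation_oracle(self):
        prev = gaussian_blob((40, 40), 20.0, 20.0)
        next_ = gaussian_blob((40, 40), 20.5, 20.0)  # true shift (0.5, 0)
        est = flow_comp.lk_flow(prev, next_, (20, 20))
        assert est.u == pytest.approx(0.5, abs=0.05)
        assert est.v == pytest.approx(0.0, abs=0.05)
        u_oracle, v_oracle = subpixel_shift_oracle(prev, next_, (20, 20))
        assert est.u == pytest.approx(u_oracle, abs=0.05)
        assert est.v == pytest.approx(v_oracle, abs=0.05)

    def test_uniform_window_is_degenerate(self):
        flat = np.full((40, 40), 10.0)
        with pytest.raises(errors.DegenerateFlowError):
            flow_comp.lk_flow(flat, flat + 1.0, (20, 20))

    def test_antisymmetric_under_frame_swap(self):
        prev = gaussian_blob((40, 40), 20.0, 20.0)
        next_ = gaussian_blob((40, 40), 20.3, 19.8)
        fwd = flow_comp.lk_flow(prev, next_, (20, 20))
        bwd = flow_comp.lk_flow(next_, prev, (20, 20))
        assert abs(fwd.u + bwd.u) < 0.05
        assert abs(fwd.v + bwd.v) < 0.05

    def test_point_near_border_is_rejected(self):
        frame = np.zeros((40, 40))
        with pytest.raises(errors.ConfigurationError):
            flow_comp.lk_flow(frame, frame, (2, 20))


class TestTrackPoints:
    def test_static_video_keeps_trajectories_at_seeds(self, rng):
        frame = ndimage.gaussian_filter(rng.uniform(0, 255, (40, 50)), 1.0)
        frames = np.stack([frame] * 8)
        trajs = flow_comp.track_points(frames, np.array([[25.0, 20.0]]))
        assert trajs[0].valid.all()
        np.testing.assert_allclose(trajs[0].positions, [[25.0, 20.0]] * 8, atol=1e-6)

    def test_global_translation_accumulates_to_known_shift(self):
        """0.2 px/frame horizontal and 0.1 px/frame vertical over 60 frames
        must integrate to ~(12, 6) px against the generator ground truth."""
        scenario = synth.Scenario(
            hr_hz=1.2, motion=("translate", 0.2, 0.1), duration_s=2.0,
            noise_sigma=1.0, seed=3,
        )
        seq, truth = synth.generate(scenario)
        green = seq.frames[..., 1].astype(float)
        seeds = np.array([[80.0, 60.0]])
        trajs = flow_comp.track_points(green, seeds)
        final = trajs[0].displacements()[-1]
        expected = truth.trajectory[-1] - truth.trajectory[0]
        np.testing.assert_allclose(final, expected, atol=0.5)
        assert np.hypot(*(final - np.array([11.8, 5.9]))) < 1.0

    def test_uniform_seed_is_flagged_invalid_immediately(self, rng):
        frame = np.zeros((40, 60))
        frame[:, :30] = ndimage.gaussian_filter(rng.uniform(0, 255, (40, 30)), 1.0)
        frames = np.stack([frame] * 6)
        trajs = flow_comp.track_points(frames, np.array([[15.0, 20.0], [45.0, 20.0]]))
        assert trajs[0].valid.all()  # textured seed survives
        assert trajs[1].valid[0] and not trajs[1].valid[1:].any()

    def test_all_dead_trajectories_raise(self):
        frames = np.zeros((6, 40, 40))
        with pytest.raises(errors.TrackingError):
            flow_comp.track_points(frames, np.array([[20.0, 20.0]]))


class TestSampleTraces:
    def test_static_trajectory_returns_fixed_pixel_series(self, rng):
        frames = rng.uniform(0, 255, size=(5, 10, 10, 3))
        traj = flow_comp.Trajectory(0, np.tile([4.0, 6.0], (5, 1)), np.ones(5, bool))
        traces = flow_comp.sample_traces(frames, [traj], fps=30)[0]
        np.testing.assert_allclose(traces.r, frames[:, 6, 4, 0])

    def test_integer_shift_sampling_is_exact(self, rng):
        f0 = rng.uniform(0, 255, size=(10, 12, 3))
        f1 = np.zeros_like(f0)
        f1[:, 1:] = f0[:, :-1]  # shifted right by exactly 1 px
        traj = flow_comp.Trajectory(0, np.array([[5.0, 4.0], [6.0, 4.0]]), np.ones(2, bool))
        traces = flow_comp.sample_traces(np.stack([f0, f1]), [traj], fps=30)[0]
        assert traces.g[1] == pytest.approx(traces.g[0], abs=1e-9)

    def test_half_pixel_sample_of_ramp_hits_midpoint(self):
        ramp = np.tile(10.0 * np.arange(12), (10, 1))
        frames = np.stack([np.stack([ramp] * 3, axis=-1)] * 2)
        traj = flow_comp.Trajectory(0, np.array([[5.0, 4.0], [5.5, 4.0]]), np.ones(2, bool))
        traces = flow_comp.sample_traces(frames, [traj], fps=30)[0]
        assert traces.r[1] == pytest.approx(55.0, abs=1e-9)

    def test_invalid_frames_filled_by_linear_interpolation(self):
        ramp = np.tile(10.0 * np.arange(12), (10, 1))
        frames = np.stack([np.stack([ramp] * 3, axis=-1)] * 3)
        pos = np.array([[4.0, 4.0], [4.0, 4.0], [6.0, 4.0]])
        valid = np.array([True, False, True])
        traces = flow_comp.sample_traces(frames, [flow_comp.Trajectory(0, pos, valid)], fps=30)[0]
        assert traces.r[1] == pytest.approx(50.0, abs=1e-9)  # midpoint of 40 and 60

    def test_tracked_traces_suppress_motion_artifact(self):
        """In a motion-only scene (no pulse, no noise) the tracked-point
        trace varies at least 5x less than the fixed-pixel trace."""
        scenario = synth.Scenario(
            hr_hz=1.2, pulse_amp=(0.0, 0.0, 0.0), motion=("sway", 1.5, 0.3),
            noise_sigma=0.0, duration_s=8.0, frame_size=(60, 80), seed=5,
        )
        seq, _ = synth.generate(scenario)
        green = seq.frames[..., 1].astype(float)
        mask = np.zeros((60, 80), dtype=bool)
        mask[20:40, 30:50] = True  # interior of the patch
        seeds = flow_comp.select_seeds(green[0], mask, n_seeds=3)
        trajs = flow_comp.track_points(green, seeds)
        tracked = flow_comp.sample_traces(seq.frames, trajs, fps=30)
        fixed_trajs = [
            flow_comp.Trajectory(i, np.tile(s, (seq.n_frames, 1)), np.ones(seq.n_frames, bool))
            for i, s in enumerate(seeds)
        ]
        fixed = flow_comp.sample_traces(seq.frames, fixed_trajs, fps=30)
        ratio = np.mean([f.g.std() / t.g.std() for f, t in zip(fixed, tracked)])
        assert ratio >= 5.0


class TestMedianDisplacement:
    def test_median_over_trajectories(self):
        p1 = flow_comp.Trajectory(0, np.array([[0.0, 0.0], [1.0, 0.0]]), np.ones(2, bool))
        p2 = flow_comp.Trajectory(1, np.array([[5.0, 5.0], [6.2, 5.1]]), np.ones(2, bool))
        p3 = flow_comp.Trajectory(2, np.array([[9.0, 2.0], [10.1, 2.0]]), np.ones(2, bool))
        disp = flow_comp.median_displacement([p1, p2, p3])
        np.testing.assert_allclose(disp[1], [1.1, 0.0])
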