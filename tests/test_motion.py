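"""Motion estimation: running averages, alignment, neighbour-weighted track fits."""

import numpy as np
import pytest
import scipy.ndimage
from hypothesis import given, settings
from hypothesis import strategies as st

from cryopolish import (
    AlignmentError,
    FrameShiftObservations,
    ImageGrid2D,
    LinearTrack,
    MovieParticle,
    ParameterError,
    PolishConfig,
    SimulationConfig,
    TrackFitError,
    align_translation,
    apply_shift,
    evaluate_track,
    fit_linear_tracks,
    neighbor_weights,
    observe_frame_shifts,
    running_averages,
    simulate_motion_field,
    simulate_movie,
)


def _movie_from_stack(stack, pixel_size=2.5):
    frames = [ImageGrid2D(plane, pixel_size) for plane in stack]
    return MovieParticle("p", "m", 0.0, 0.0, frames)


class TestRunningAverages:
    def test_width_one_is_identity(self, reference64):
        rng = np.random.default_rng(0)
        movie = _movie_from_stack(rng.standard_normal((4, 64, 64)))
        out = running_averages(movie, 1)
        for a, b in zip(out.frames, movie.frames):
            assert np.array_equal(a.pixels, b.pixels)

    def test_even_width_rejected(self):
        movie = _movie_from_stack(np.zeros((4, 16, 16)))
        with pytest.raises(ParameterError, match="odd"):
            running_averages(movie, 4)

    @given(width=st.sampled_from([1, 3, 5, 7]), n=st.integers(4, 16))
    @settings(derandomize=True, max_examples=20, deadline=None)
    def test_truncated_windows_match_loop_oracle(self, width, n):
        rng = np.random.default_rng(n * 100 + width)
        stack = rng.standard_normal((n, 16, 16))
        out = running_averages(_movie_from_stack(stack), width)
        half = (width - 1) // 2
        for f in range(n):
            window = [stack[g] for g in range(n) if abs(g - f) <= half]
            oracle = sum(window) / len(window)
            assert np.allclose(out.frames[f].pixels, oracle, atol=1e-12)

    def test_window_contents_frame1_and_frame8(self):
        # F = 16, width 5: frame 1 averages frames 1-3, frame 8 averages 6-10
        stack = np.zeros((16, 16, 16))
        for f in range(16):
            stack[f] = f + 1
        out = running_averages(_movie_from_stack(stack), 5)
        assert out.frames[0].pixels[0, 0] == pytest.approx(np.mean([1, 2, 3]))
        assert out.frames[7].pixels[0, 0] == pytest.approx(np.mean([6, 7, 8, 9, 10]))


class TestAlignTranslation:
    def test_integer_roll_gives_correcting_shift(self, reference64):
        rolled = ImageGrid2D(
            np.roll(reference64.pixels, (-2, 3), axis=(0, 1)), reference64.pixel_size
        )
        dx, dy = align_translation(rolled, reference64, 8.0)
        assert (dx, dy) == pytest.approx((-3.0, 2.0), abs=1e-3)

    def test_identity_alignment(self, reference64):
        assert align_translation(reference64, reference64, 8.0) == pytest.approx(
            (0.0, 0.0), abs=1e-6
        )

    def test_constant_image_rejected(self, reference64):
        flat = ImageGrid2D(np.ones((64, 64)), 2.5)
        with pytest.raises(AlignmentError):
            align_translation(flat, reference64, 8.0)

    def test_subpixel_half_pixel_recovery(self, reference64):
        shifted = apply_shift(reference64, 0.5, 0.0)
        dx, dy = align_translation(shifted, reference64, 8.0)
        assert (dx, dy) == pytest.approx((-0.5, 0.0), abs=0.05)

    def test_subpixel_matches_dense_grid_oracle(self, reference64):
        # oracle: real-space spline shifts on a 0.01-px grid, maximizing
        # correlation with the reference -- independent of the FFT route
        shifted = apply_shift(reference64, 0.37, -0.21)
        dx, dy = align_translation(shifted, reference64, 8.0)
        ref = reference64.pixels - reference64.pixels.mean()
        best, best_s = -np.inf, None
        for sx in np.arange(-0.45, -0.30, 0.01):
            moved = scipy.ndimage.shift(shifted.pixels, (0.21, sx), order=3, mode="wrap")
            c = np.sum((moved - moved.mean()) * ref)
            if c > best:
                best, best_s = c, sx
        assert dx == pytest.approx(best_s, abs=0.05)
        assert dy == pytest.approx(0.21, abs=0.05)

    def test_matches_phase_cross_correlation_oracle(self, reference64):
        from skimage.registration import phase_cross_correlation

        shifted = apply_shift(reference64, -1.3, 2.6)
        dx, dy = align_translation(shifted, reference64, 8.0)
        oracle, _, _ = phase_cross_correlation(
            reference64.pixels, shifted.pixels, upsample_factor=100,
            normalization=None,
        )
        assert (dy, dx) == pytest.approx(tuple(oracle), abs=0.02)


class TestObserveFrameShifts:
    def test_linear_track_recovered_without_noise(self, reference64, config):
        n = 6
        cfg = SimulationConfig(
            n_frames=n, image_noise_std=0.0,
            damage_b=np.zeros(n), damage_c=np.zeros(n), seed=1,
        )
        track = LinearTrack("p", alpha_x=1.0, alpha_y=-0.7, beta_x=-0.25, beta_y=0.2)
        movie = simulate_movie(reference64, track, cfg, seed=1)
        obs = observe_frame_shifts(movie, reference64, config)
        f = np.arange(1, n + 1)
        assert np.abs(obs.dx - (1.0 - 0.25 * f)).max() < 0.05
        assert np.abs(obs.dy - (-0.7 + 0.2 * f)).max() < 0.05
        assert obs.valid.all()

    def test_identical_frames_give_zero_shifts(self, reference64, config):
        movie = _movie_from_stack(np.stack([reference64.pixels] * 4))
        obs = observe_frame_shifts(movie, reference64, config)
        assert np.abs(obs.dx).max() < 1e-6
        assert np.abs(obs.dy).max() < 1e-6

    def test_unalignable_frame_flagged_not_fabricated(self, reference64, config):
        stack = np.stack([reference64.pixels, np.zeros((64, 64)), reference64.pixels])
        obs = observe_frame_shifts(_movie_from_stack(stack), reference64, config)
        assert list(obs.valid) == [True, False, True]
        assert np.isnan(obs.dx[1]) and np.isnan(obs.dy[1])


class TestNeighborWeights:
    def test_self_weight_is_one(self):
        coords = np.array([[0.0, 0.0], [50.0, 0.0]])
        w = neighbor_weights(coords, 0, 100.0)
        assert w[0] == 1.0

    def test_two_sigma_distance(self):
        coords = np.array([[0.0, 0.0], [200.0, 0.0]])
        w = neighbor_weights(coords, 0, 100.0)
        assert w[1] == pytest.approx(np.exp(-2.0), abs=1e-12)

    def test_one_sigma_distance_mitoribosome_setting(self):
        coords = np.array([[0.0, 0.0], [100.0, 0.0]])
        w = neighbor_weights(coords, 0, 100.0)
        assert w[1] == pytest.approx(0.60653066, abs=1e-6)


def _obs(particle_id, dx, dy, valid=None):
    dx = np.asarray(dx, dtype=float)
    valid = np.ones(dx.size, dtype=bool) if valid is None else np.asarray(valid)
    return FrameShiftObservations(particle_id, dx, np.asarray(dy, dtype=float), valid)


def _lstsq_oracle(observations, coords, sigma_nb, p, axis):
    """Independent route: weighted design matrix solved with lstsq."""
    rows, rhs = [], []
    for q, obs in enumerate(observations):
        d2 = np.sum((np.asarray(coords[q]) - np.asarray(coords[p])) ** 2)
        w = np.exp(-d2 / (2 * sigma_nb**2))
        data = obs.dx if axis == "x" else obs.dy
        for f in range(1, obs.n_frames + 1):
            if obs.valid[f - 1]:
                rows.append([np.sqrt(w), np.sqrt(w) * f])
                rhs.append(np.sqrt(w) * data[f - 1])
    sol, *_ = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)
    return sol


class TestFitLinearTracks:
    def test_exact_linear_single_particle(self):
        f = np.arange(1, 9)
        obs = [_obs("p", 1.0 + 0.5 * f, 2.0 - 0.1 * f)]
        (track,) = fit_linear_tracks(obs, np.array([[0.0, 0.0]]), 100.0)
        assert track.alpha_x == pytest.approx(1.0, abs=1e-12)
        assert track.beta_x == pytest.approx(0.5, abs=1e-12)
        assert track.alpha_y == pytest.approx(2.0, abs=1e-12)
        assert track.beta_y == pytest.approx(-0.1, abs=1e-12)

    def test_colocated_identical_particles_share_track(self):
        f = np.arange(1, 9)
        obs = [_obs("a", 0.3 * f, -f), _obs("b", 0.3 * f, -f)]
        coords = np.array([[5.0, 5.0], [5.0, 5.0]])
        ta, tb = fit_linear_tracks(obs, coords, 50.0)
        assert (ta.alpha_x, ta.beta_x, ta.alpha_y, ta.beta_y) == pytest.approx(
            (tb.alpha_x, tb.beta_x, tb.alpha_y, tb.beta_y), abs=1e-12
        )

    def test_random_instance_matches_lstsq_oracle(self):
        rng = np.random.default_rng(7)
        n_particles, n_frames = 10, 16
        coords = rng.uniform(0, 500, size=(n_particles, 2))
        f = np.arange(1, n_frames + 1)
        obs = []
        for p in range(n_particles):
            valid = rng.random(n_frames) > 0.1
            obs.append(
                _obs(
                    f"p{p}",
                    rng.normal(0, 1) + rng.normal(0, 0.2) * f + rng.normal(0, 0.5, n_frames),
                    rng.normal(0, 1) + rng.normal(0, 0.2) * f + rng.normal(0, 0.5, n_frames),
                    valid,
                )
            )
        tracks = fit_linear_tracks(obs, coords, 150.0)
        for p, track in enumerate(tracks):
            ax, bx = _lstsq_oracle(obs, coords, 150.0, p, "x")
            ay, by = _lstsq_oracle(obs, coords, 150.0, p, "y")
            assert track.alpha_x == pytest.approx(ax, abs=1e-8)
            assert track.beta_x == pytest.approx(bx, abs=1e-8)
            assert track.alpha_y == pytest.approx(ay, abs=1e-8)
            assert track.beta_y == pytest.approx(by, abs=1e-8)

    def test_degenerate_fit_raises(self):
        obs = [_obs("p", [1.0, 2.0], [0.0, 0.0], valid=[True, False])]
        with pytest.raises(TrackFitError):
            fit_linear_tracks(obs, np.array([[0.0, 0.0]]), 100.0)

    def test_axis_independence(self):
        rng = np.random.default_rng(3)
        f = np.arange(1, 9)
        obs = [
            _obs(f"p{p}", 0.1 * f + rng.normal(0, 1, 8), rng.normal(0, 1, 8))
            for p in range(4)
        ]
        coords = rng.uniform(0, 300, size=(4, 2))
        before = fit_linear_tracks(obs, coords, 100.0)
        permuted = [
            _obs(o.particle_id, o.dx, o.dy[::-1].copy(), o.valid) for o in obs
        ]
        after = fit_linear_tracks(permuted, coords, 100.0)
        for t0, t1 in zip(before, after):
            assert t0.alpha_x == t1.alpha_x and t0.beta_x == t1.beta_x

    def test_small_sigma_reduces_to_per_particle_regression(self):
        rng = np.random.default_rng(11)
        f = np.arange(1, 11)
        obs = [
            _obs(f"p{p}", rng.normal(0, 1, 10), rng.normal(0, 1, 10))
            for p in range(5)
        ]
        coords = rng.uniform(0, 1000, size=(5, 2))
        tracks = fit_linear_tracks(obs, coords, 1e-3)
        for o, t in zip(obs, tracks):
            bx, ax = np.polyfit(f, o.dx, 1)
            assert t.alpha_x == pytest.approx(ax, abs=1e-8)
            assert t.beta_x == pytest.approx(bx, abs=1e-8)


class TestSigmaNbNoiseSuppression:
    def test_rmse_decreases_with_sigma_nb_on_shared_motion(self):
        """With shared smooth motion and i.i.d. noise, pooling neighbours helps."""
        cfg = SimulationConfig(n_particles=30, n_frames=16, heterogeneity=0.0)
        f = np.arange(1, 17)
        sigmas = [1e-3, 100.0, 300.0]
        mean_rmse = []
        for sigma in sigmas:
            rmses = []
            for s in range(20):
                coords, truth = simulate_motion_field(cfg, 500 + s)
                obs = [
                    _obs(
                        t.particle_id,
                        t.alpha_x + t.beta_x * f + np.random.default_rng(900 + s * 40 + i).normal(0, 1.0, 16),
                        t.alpha_y + t.beta_y * f + np.random.default_rng(901 + s * 40 + i).normal(0, 1.0, 16),
                    )
                    for i, t in enumerate(truth)
                ]
                fits = fit_linear_tracks(obs, coords, sigma)
                err = []
                for t, fit in zip(truth, fits):
                    err.append((fit.alpha_x + fit.beta_x * f) - (t.alpha_x + t.beta_x * f))
                    err.append((fit.alpha_y + fit.beta_y * f) - (t.alpha_y + t.beta_y * f))
                rmses.append(np.sqrt(np.mean(np.square(err))))
            mean_rmse.append(np.mean(rmses))
        assert mean_rmse[0] > mean_rmse[1] > mean_rmse[2]


class TestEvaluateTrack:
    def test_zero_track(self):
        track = LinearTrack("p", 0, 0, 0, 0)
        assert evaluate_track(track, 3) == (0.0, 0.0)

    def test_arithmetic(self):
        track = LinearTrack("p", 1.0, 0.0, 0.5, 0.0)
        assert evaluate_track(track, 4)[0] == pytest.approx(3.0)
        assert evaluate_track(track, 1)[0] == pytest.approx(1.5)

    def test_out_of_range_frame(self):
        track = LinearTrack("p", 0, 0, 0, 0)
        with pytest.raises(ParameterError):
            evaluate_track(track, 0)
        with pytest.raises(ParameterError):
            evaluate_track(track, 9, n_frames=8)
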