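"""Self-contained simulation studies quantifying each stage of the pipeline.

Each routine builds its own synthetic inputs from a seed, runs the method,
and returns the measured quantity — track-recovery errors, neighbour-pooling
RMSEs, relative-B-factor recovery errors, polishing benefit.  They are used
both by the test suite and by the reproduction script.
"""

from __future__ import annotations

import numpy as np

from .config import PolishConfig
from .damage import (
    FrameDamageModel,
    FrequencyShells,
    amplitude_ratio,
    fit_relative_guinier,
    frame_weights,
    fsc_curve,
)
from .motion import (
    LinearTrack,
    fit_linear_tracks,
    observe_frame_shifts,
)
from .polish import polish_particle
from .synthetic import (
    SimulationConfig,
    make_reference,
    simulate_halfmap_series,
    simulate_motion_field,
    simulate_movie,
    simulate_shift_observations,
)

__all__ = [
    "random_track_instance",
    "noiseless_recovery_errors",
    "pooling_rmse_pair",
    "b_recovery_errors",
    "polish_benefit_pair",
]


def random_track_instance(seed: int, max_particles: int = 5, max_frames: int = 8):
    """A small random track-fitting instance: observations, coords, sigma_nb."""
    rng = np.random.default_rng(seed)
    n_particles = int(rng.integers(1, max_particles + 1))
    n_frames = int(rng.integers(2, max_frames + 1))
    coords = rng.uniform(0, 600, size=(n_particles, 2))
    sigma_nb = float(rng.uniform(50, 400))
    f = np.arange(1, n_frames + 1)
    from .motion import FrameShiftObservations

    observations = []
    for p in range(n_particles):
        valid = rng.random(n_frames) > 0.15
        if valid.sum() < 2:
            valid[:2] = True
        observations.append(
            FrameShiftObservations(
                f"p{p}",
                rng.normal(0, 1.5) + rng.normal(0, 0.3) * f + rng.normal(0, 0.5, n_frames),
                rng.normal(0, 1.5) + rng.normal(0, 0.3) * f + rng.normal(0, 0.5, n_frames),
                valid,
            )
        )
    return observations, coords, sigma_nb


def noiseless_recovery_errors(seed: int, n_particles: int = 3, n_frames: int = 8):
    """End-to-end zero-noise check: max |observed - true| shift per frame (px).

    Simulates noiseless movies along known tracks, runs the observation stage
    (running average width 1 + alignment) and the track fit, and returns the
    worst absolute error of both the raw observations and the fitted tracks.
    """
    cfg = SimulationConfig(
        n_particles=n_particles,
        n_frames=n_frames,
        image_noise_std=0.0,
        damage_b=np.zeros(n_frames),
        damage_c=np.zeros(n_frames),
        heterogeneity=0.05,
        seed=seed,
    )
    reference = make_reference(cfg.box_size, cfg.pixel_size, seed)
    coords, tracks = simulate_motion_field(cfg, seed + 1)
    pcfg = PolishConfig(
        pixel_size=cfg.pixel_size, running_avg_width=1, max_shift=8.0
    )
    f = np.arange(1, n_frames + 1)
    obs_err, fit_err = 0.0, 0.0
    observations = []
    for p, track in enumerate(tracks):
        movie = simulate_movie(reference, track, cfg, seed + 100 + p)
        obs = observe_frame_shifts(movie, reference, pcfg)
        observations.append(obs)
        obs_err = max(
            obs_err,
            np.abs(obs.dx - (track.alpha_x + track.beta_x * f)).max(),
            np.abs(obs.dy - (track.alpha_y + track.beta_y * f)).max(),
        )
    fitted = fit_linear_tracks(observations, coords, sigma_nb=1e-3)
    for fit, truth in zip(fitted, tracks):
        fit_err = max(
            fit_err,
            np.abs((fit.alpha_x + fit.beta_x * f) - (truth.alpha_x + truth.beta_x * f)).max(),
            np.abs((fit.alpha_y + fit.beta_y * f) - (truth.alpha_y + truth.beta_y * f)).max(),
        )
    return obs_err, fit_err


def pooling_rmse_pair(
    seed: int,
    sigma_wide: float = 300.0,
    sigma_narrow: float = 1e-3,
    n_particles: int = 50,
    n_frames: int = 16,
    obs_noise: float = 2.0,
):
    """Per-frame shift RMSE of the track fit with wide vs narrow sigma_NB.

    One field of 50 particles sharing a smooth motion field, observation
    noise of ``obs_noise`` pixels; returns (rmse_wide, rmse_narrow).
    """
    cfg = SimulationConfig(
        n_particles=n_particles, n_frames=n_frames, heterogeneity=0.0
    )
    coords, truth = simulate_motion_field(cfg, seed)
    observations = simulate_shift_observations(truth, n_frames, obs_noise, seed + 1)
    f = np.arange(1, n_frames + 1)

    def rmse(sigma_nb):
        fitted = fit_linear_tracks(observations, coords, sigma_nb)
        err = []
        for fit, t in zip(fitted, truth):
            err.append((fit.alpha_x + fit.beta_x * f) - (t.alpha_x + t.beta_x * f))
            err.append((fit.alpha_y + fit.beta_y * f) - (t.alpha_y + t.beta_y * f))
        return float(np.sqrt(np.mean(np.square(err))))

    return rmse(sigma_wide), rmse(sigma_narrow)


def b_recovery_errors(seed: int, n_seeds: int = 5, n_frames: int = 16):
    """Relative-B-factor recovery from synthetic half-map series.

    Runs ``n_seeds`` replicate experiments at the generator's default study
    conditions (box 64) and returns (true_b, mean recovered b per frame).
    """
    cfg = SimulationConfig(n_frames=n_frames, box_size=64)
    pcfg = PolishConfig(pixel_size=cfg.pixel_size)
    recovered = np.zeros(n_frames)
    true_b = None
    for s in range(n_seeds):
        series = simulate_halfmap_series(cfg, seed + s)
        true_b = series.true_b
        fsc_a = fsc_curve(*series.average_pair)
        for f, (h1, h2) in enumerate(series.frame_pairs, start=1):
            fsc_f = fsc_curve(h1, h2)
            ratio = amplitude_ratio(fsc_f, fsc_a)
            recovered[f - 1] += fit_relative_guinier(ratio, fsc_f, pcfg, f).b
    return true_b, recovered / n_seeds


def polish_benefit_pair(seed: int, n_frames: int = 16):
    """Correlation with ground truth: polished vs naive average, one trial.

    A particle movie with a random linear track, the default dose-dependent
    damage schedule and unit image noise is polished using the true track and
    the weights implied by the true schedule; the naive competitor is the
    unshifted, unweighted frame average.  Returns (corr_polished, corr_naive).
    """
    cfg = SimulationConfig(n_frames=n_frames, image_noise_std=1.0)
    rng = np.random.default_rng(seed)
    reference = make_reference(cfg.box_size, cfg.pixel_size, seed)
    beta = rng.normal(0.0, 0.25, 2)
    center = (n_frames + 1) / 2.0
    track = LinearTrack(
        "trial", -beta[0] * center, -beta[1] * center, beta[0], beta[1]
    )
    movie = simulate_movie(reference, track, cfg, seed + 1)
    shells = FrequencyShells.for_box(cfg.box_size, cfg.pixel_size, ndim=2)
    models = [
        FrameDamageModel(f + 1, cfg.damage_b[f], cfg.damage_c[f])
        for f in range(n_frames)
    ]
    table = frame_weights(models, shells)
    polished = polish_particle(movie, track, table)
    naive = np.mean([fr.pixels for fr in movie.frames], axis=0)

    def corr(a, b):
        a = a - a.mean()
        b = b - b.mean()
        return float(np.sum(a * b) / np.sqrt(np.sum(a**2) * np.sum(b**2)))

    truth = reference.pixels
    return corr(polished.image.pixels, truth), corr(naive, truth)
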