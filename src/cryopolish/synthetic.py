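"""Synthetic data with the statistical structure the polishing model assumes.

Three generators cover the three stages of the pipeline:

* :func:`simulate_motion_field` draws particle coordinates and spatially
  smooth linear movement tracks over a field of view (smooth random Gaussian
  bumps plus an optional per-particle heterogeneity), emulating the complex
  but locally correlated beam-induced movement patterns seen on real
  micrographs.
* :func:`simulate_movie` renders a particle movie from a reference image:
  each frame is the reference filtered per frequency shell by the damage
  model exp(B_f nu^2/4 + C_f), displaced by minus the track's correcting
  shift, plus white Gaussian noise.
* :func:`simulate_halfmap_series` builds per-frame half-map pairs from a
  common band-limited random signal volume, with equal noise power in every
  half — the exact assumption under which FSC-derived amplitude ratios are
  valid.

Everything is deterministic given the seed; changing only the seed changes
noise realizations, never the configured truth.

Tracks follow the package-wide sign convention: the stored (alpha, beta) are
*correcting* shifts, so frames are rendered displaced by the negated track
and alignment recovers the track with positive sign.  Intercepts are chosen
as alpha = -beta (F+1)/2 so the mean correcting shift over the movie is zero,
mirroring the fact that shifts are measured relative to the refined position
of the *average* particle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage

from .damage import FrequencyShells
from .errors import ParameterError
from .io_formats import ImageGrid2D, MovieParticle, VolumeGrid3D
from .motion import FrameShiftObservations, LinearTrack

__all__ = [
    "SimulationConfig",
    "HalfMapSeries",
    "default_damage_schedule",
    "make_reference",
    "simulate_motion_field",
    "simulate_shift_observations",
    "simulate_movie",
    "simulate_micrograph",
    "simulate_halfmap_series",
]


def default_damage_schedule(n_frames: int, spread: float = 20.0) -> tuple[np.ndarray, np.ndarray]:
    """Default per-frame (B_f, C_f) schedule.

    The shape mirrors what dose series show in practice: depressed B_f for the
    first couple of frames (large initial beam-induced movement), a peak
    around frame 3, and a steady decline at higher dose (radiation damage).
    Because relative B-factors are measured against the all-frame average,
    the schedule is mean-centred; ``spread`` sets its standard deviation in
    A^2.  C_f declines gently with dose and is also mean-centred.
    """
    f = np.arange(1, n_frames + 1, dtype=float)
    raw = -8.0 * np.maximum(0.0, 3.0 - f) ** 1.5 - 1.2 * np.maximum(0.0, f - 3.0) ** 1.6
    raw -= raw.mean()
    std = raw.std()
    b = raw * (spread / std) if std > 0 else raw
    c = np.linspace(0.08, -0.08, n_frames)
    c -= c.mean()
    return b, c


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generators.

    Defaults describe a typical direct-detector dataset: a few dozen boxed
    particles on a ~2k-pixel field of view, 16 movie frames, 64-pixel boxes at
    2.5 A/px, drift of a fraction of a pixel per frame that varies smoothly
    across the field, and a mean-centred dose-like damage schedule.
    """

    n_particles: int = 50
    field_size: float = 2048.0
    n_frames: int = 16
    box_size: int = 64
    pixel_size: float = 2.5
    mean_drift: float = 0.2            # px/frame, scale of the smooth slope field
    correlation_length: float = 600.0  # px, spatial scale of the motion field
    heterogeneity: float = 0.0         # px/frame, per-particle slope scatter
    obs_noise_std: float = 2.0         # px, noise on raw per-frame shift estimates
    image_noise_std: float = 1.0       # real-space noise std per movie frame
    signal_envelope_b: float = 300.0   # A^2, absolute fall-off of the signal
    signal_amplitude: float = 5.0      # amplitude SNR scale of half-map signal
    halfmap_noise_std: float = 1.0     # real-space noise std per half map
    damage_b: np.ndarray | None = None  # per-frame relative B (A^2)
    damage_c: np.ndarray | None = None  # per-frame intercepts
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ParameterError("n_frames must be >= 2")
        if self.box_size % 2 != 0:
            raise ParameterError("box_size must be even")
        if self.damage_b is None:
            self.damage_b, default_c = default_damage_schedule(self.n_frames)
            if self.damage_c is None:
                self.damage_c = default_c
        elif self.damage_c is None:
            self.damage_c = np.zeros(self.n_frames)
        self.damage_b = np.asarray(self.damage_b, dtype=float)
        self.damage_c = np.asarray(self.damage_c, dtype=float)
        if self.damage_b.size != self.n_frames or self.damage_c.size != self.n_frames:
            raise ParameterError("damage schedules must have one entry per frame")


@dataclass
class HalfMapSeries:
    """Per-frame half-map pairs plus the all-frame pair and the injected truth."""

    frame_pairs: list = field(default_factory=list)  # [(half1, half2), ...]
    average_pair: tuple = ()
    true_b: np.ndarray = None
    true_c: np.ndarray = None


def make_reference(box_size: int, pixel_size: float, seed: int, envelope_b: float = 300.0) -> ImageGrid2D:
    """Band-limited filtered white noise: smooth random blobs, unit variance.

    Structureless but spectrally realistic content — enough for alignment and
    spectral tests without any dependency on real structural data.
    """
    rng = np.random.default_rng(seed)
    white = rng.standard_normal((box_size, box_size))
    freqs = np.fft.fftfreq(box_size, d=pixel_size)
    nu2 = freqs[:, None] ** 2 + freqs[None, :] ** 2
    env = np.exp(-envelope_b * nu2 / 4.0)
    # hard band limit below Nyquist: keeps fractional Fourier shifts exactly
    # reversible (no content in the symmetry-breaking Nyquist bins)
    env[nu2 >= (0.9 / (2.0 * pixel_size)) ** 2] = 0.0
    pixels = np.fft.ifft2(np.fft.fft2(white) * env).real
    pixels = (pixels - pixels.mean()) / pixels.std()
    return ImageGrid2D(pixels=pixels, pixel_size=pixel_size)


def _smooth_field(rng: np.random.Generator, coords: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Evaluate a smooth random scalar field (constant + Gaussian bumps)."""
    value = np.full(coords.shape[0], rng.normal(0.0, config.mean_drift))
    n_bumps = 6
    centers = rng.uniform(0.0, config.field_size, size=(n_bumps, 2))
    amps = rng.normal(0.0, config.mean_drift, size=n_bumps)
    ell2 = 2.0 * config.correlation_length**2
    for center, amp in zip(centers, amps):
        d2 = np.sum((coords - center) ** 2, axis=1)
        value += amp * np.exp(-d2 / ell2)
    return value


def simulate_motion_field(
    config: SimulationConfig, seed: int | None = None
) -> tuple[np.ndarray, list[LinearTrack]]:
    """Draw particle coordinates and spatially smooth true linear tracks.

    Coordinates are uniform over the field; per-axis slopes are a smooth
    random field of (x, y) plus i.i.d. per-particle heterogeneity; intercepts
    centre each track on its own movie average.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    coords = rng.uniform(0.0, config.field_size, size=(config.n_particles, 2))
    beta_x = _smooth_field(rng, coords, config)
    beta_y = _smooth_field(rng, coords, config)
    if config.heterogeneity > 0:
        beta_x = beta_x + rng.normal(0.0, config.heterogeneity, config.n_particles)
        beta_y = beta_y + rng.normal(0.0, config.heterogeneity, config.n_particles)
    center = (config.n_frames + 1) / 2.0
    tracks = [
        LinearTrack(
            particle_id=f"particle_{p:05d}",
            alpha_x=-beta_x[p] * center,
            alpha_y=-beta_y[p] * center,
            beta_x=beta_x[p],
            beta_y=beta_y[p],
        )
        for p in range(config.n_particles)
    ]
    return coords, tracks


def simulate_shift_observations(
    tracks: list[LinearTrack],
    n_frames: int,
    noise_std: float,
    seed: int,
) -> list[FrameShiftObservations]:
    """True per-frame track shifts plus i.i.d. Gaussian observation noise."""
    rng = np.random.default_rng(seed)
    f = np.arange(1, n_frames + 1, dtype=float)
    observations = []
    for track in tracks:
        observations.append(
            FrameShiftObservations(
                particle_id=track.particle_id,
                dx=track.alpha_x + track.beta_x * f + rng.normal(0, noise_std, n_frames),
                dy=track.alpha_y + track.beta_y * f + rng.normal(0, noise_std, n_frames),
                valid=np.ones(n_frames, dtype=bool),
            )
        )
    return observations


def _shell_filter_2d(box_size: int, pixel_size: float, b: float, c: float) -> np.ndarray:
    """Per-shell (piecewise-constant) damage filter exp(B nu_k^2/4 + C) on the 2-D grid."""
    idx = np.fft.fftfreq(box_size) * box_size
    r = np.sqrt(idx[:, None] ** 2 + idx[None, :] ** 2)
    k = np.rint(r).astype(int)
    n_shells = box_size // 2 + 1
    nu = np.arange(max(n_shells, k.max() + 1)) / (box_size * pixel_size)
    values = np.exp(b * nu**2 / 4.0 + c)
    return values[k]


def _shell_filter_3d(box_size: int, pixel_size: float, gains: np.ndarray) -> np.ndarray:
    """Per-shell gain lookup on the 3-D FFT grid (gains indexed by shell)."""
    idx = np.fft.fftfreq(box_size) * box_size
    grids = np.meshgrid(idx, idx, idx, indexing="ij")
    k = np.rint(np.sqrt(sum(g**2 for g in grids))).astype(int)
    table = np.zeros(k.max() + 1)
    table[: gains.size] = gains
    if k.max() + 1 > gains.size:
        table[gains.size:] = gains[-1]
    return table[k]


def simulate_movie(
    reference: ImageGrid2D,
    track: LinearTrack,
    config: SimulationConfig,
    seed: int | None = None,
) -> MovieParticle:
    """Render a particle movie: damage-filtered, displaced, noisy frames.

    Frame f is the reference filtered per shell by exp(B_f nu^2/4 + C_f),
    translated by minus the track's correcting shift at f (so that alignment
    recovers the track), plus white Gaussian noise of ``image_noise_std``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    box = reference.side
    spectrum = np.fft.fft2(reference.pixels)
    frames = []
    for f in range(1, config.n_frames + 1):
        gain = _shell_filter_2d(
            box, reference.pixel_size,
            float(config.damage_b[f - 1]), float(config.damage_c[f - 1]),
        )
        dx = track.alpha_x + track.beta_x * f
        dy = track.alpha_y + track.beta_y * f
        moved = scipy.ndimage.fourier_shift(spectrum * gain, (-dy, -dx))
        pixels = np.fft.ifft2(moved).real
        if config.image_noise_std > 0:
            pixels = pixels + rng.normal(0.0, config.image_noise_std, (box, box))
        frames.append(ImageGrid2D(pixels=pixels, pixel_size=reference.pixel_size))
    return MovieParticle(
        particle_id=track.particle_id,
        micrograph_id="synthetic_micrograph",
        coord_x=0.0,
        coord_y=0.0,
        frames=frames,
    )


def simulate_micrograph(
    config: SimulationConfig, seed: int | None = None
) -> tuple[ImageGrid2D, np.ndarray, list[LinearTrack], list[MovieParticle]]:
    """A full synthetic micrograph: one shared reference, many particle movies."""
    base = config.seed if seed is None else seed
    reference = make_reference(config.box_size, config.pixel_size, base)
    coords, tracks = simulate_motion_field(config, base + 1)
    particles = []
    for p, track in enumerate(tracks):
        movie = simulate_movie(reference, track, config, base + 100 + p)
        movie.coord_x, movie.coord_y = coords[p]
        particles.append(movie)
    return reference, coords, tracks, particles


def simulate_halfmap_series(
    config: SimulationConfig, seed: int | None = None
) -> HalfMapSeries:
    """Per-frame half-map pairs with known relative damage parameters.

    A common signal volume S (band-limited filtered white noise) is filtered
    per shell by exp(B_f nu^2/4 + C_f) for each frame; each half map adds an
    independent noise volume of identical power (the equal-noise-power
    assumption of the amplitude-ratio formula).  The all-frame pair uses the
    unweighted 1/F average of the frame signals plus fresh noise of the same
    power.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    box = config.box_size
    px = config.pixel_size
    shells = FrequencyShells.for_box(box, px)
    envelope = config.signal_amplitude * np.exp(
        -config.signal_envelope_b * shells.nu**2 / 4.0
    )
    signal_spectrum = np.fft.fftn(rng.standard_normal((box, box, box)))
    signal_spectrum *= _shell_filter_3d(box, px, envelope)

    def _half(signal_real: np.ndarray) -> VolumeGrid3D:
        noise = rng.normal(0.0, config.halfmap_noise_std, (box, box, box))
        return VolumeGrid3D(voxels=signal_real + noise, pixel_size=px)

    frame_pairs = []
    avg_spectrum = np.zeros_like(signal_spectrum)
    for f in range(config.n_frames):
        gains = np.exp(config.damage_b[f] * shells.nu**2 / 4.0 + config.damage_c[f])
        spec_f = signal_spectrum * _shell_filter_3d(box, px, gains)
        avg_spectrum += spec_f / config.n_frames
        signal_real = np.fft.ifftn(spec_f).real
        frame_pairs.append((_half(signal_real), _half(signal_real)))
    avg_real = np.fft.ifftn(avg_spectrum).real
    average_pair = (_half(avg_real), _half(avg_real))
    return HalfMapSeries(
        frame_pairs=frame_pairs,
        average_pair=average_pair,
        true_b=config.damage_b.copy(),
        true_c=config.damage_c.copy(),
    )
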