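"""Per-particle beam-induced motion estimation.

The pipeline here is: (1) replace each movie frame by a running average of an
odd number of neighbouring frames to boost SNR, (2) align every averaged frame
translationally against a common reference to obtain noisy per-frame shift
observations, (3) fit one straight track per particle and axis by weighted
least squares, where every particle on the micrograph contributes with a
Gaussian weight in its distance to the target particle.

Sign convention (fixed here, relied on by the polish module): an observation
(dx, dy) is the *correcting* shift — ``apply_shift(frame, dx, dy)`` brings the
frame into register with the reference.  Equivalently dx is the refined
position of the average particle minus the refined position of the frame.

Frame indices f run 1, ..., F in all formulas; the fitted track predicts the
shift at frame f as ``alpha + beta * f``, so the intercept alpha is the
extrapolated shift at f = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import PolishConfig
from .errors import AlignmentError, ParameterError, ShapeError, TrackFitError
from .io_formats import ImageGrid2D, MovieParticle

__all__ = [
    "FrameShiftObservations",
    "LinearTrack",
    "running_averages",
    "align_translation",
    "observe_frame_shifts",
    "neighbor_weights",
    "fit_linear_tracks",
    "evaluate_track",
]


@dataclass
class FrameShiftObservations:
    """Per-frame translation estimates for one particle.

    ``dx[f-1], dy[f-1]`` is the correcting shift observed for frame f; frames
    whose alignment failed carry ``valid=False`` and NaN shifts.
    """

    particle_id: str
    dx: np.ndarray
    dy: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.dx = np.asarray(self.dx, dtype=float)
        self.dy = np.asarray(self.dy, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.dx.shape == self.dy.shape == self.valid.shape):
            raise ShapeError("dx, dy and valid must have identical length F")

    @property
    def n_frames(self) -> int:
        return self.dx.size


@dataclass
class LinearTrack:
    """Straight movement track: intercept (px) and slope (px/frame) per axis."""

    particle_id: str
    alpha_x: float
    alpha_y: float
    beta_x: float
    beta_y: float

    def __post_init__(self) -> None:
        for value in (self.alpha_x, self.alpha_y, self.beta_x, self.beta_y):
            if not np.isfinite(value):
                raise ParameterError(
                    f"track {self.particle_id}: non-finite parameter"
                )


def running_averages(particle: MovieParticle, width: int) -> MovieParticle:
    """Replace each frame by the mean of an odd-width window of frames.

    The window is truncated at the movie ends, so every frame yields exactly
    one output and frames near the ends average fewer inputs.
    """
    n = particle.n_frames
    if width % 2 == 0 or width < 1:
        raise ParameterError(
            f"the number of frames in a running average can only be an odd "
            f"number, got {width}"
        )
    if width > 2 * n - 1:
        raise ParameterError(f"width {width} too large for {n} frames")
    half = (width - 1) // 2
    stack = np.stack([fr.pixels for fr in particle.frames])
    averaged = []
    for f in range(n):
        lo = max(0, f - half)
        hi = min(n, f + half + 1)
        averaged.append(
            ImageGrid2D(
                pixels=stack[lo:hi].mean(axis=0),
                pixel_size=particle.pixel_size,
            )
        )
    return MovieParticle(
        particle_id=particle.particle_id,
        micrograph_id=particle.micrograph_id,
        coord_x=particle.coord_x,
        coord_y=particle.coord_y,
        frames=averaged,
    )


def _upsampled_correlation(cross: np.ndarray, ys: np.ndarray, xs: np.ndarray) -> np.ndarray:
    """Evaluate the cross-correlation surface at arbitrary (sub-pixel) shifts.

    ``cross`` is fft2(reference) * conj(fft2(image)); the correlation at shift
    (sy, sx) is the inverse DFT of ``cross`` evaluated off-grid by explicit
    matrix multiplication (deterministic, no iteration).
    """
    n = cross.shape[0]
    freqs = np.fft.fftfreq(n)
    ey = np.exp(2j * np.pi * np.outer(ys, freqs))  # (len(ys), n)
    ex = np.exp(2j * np.pi * np.outer(freqs, xs))  # (n, len(xs))
    return np.real(ey @ cross @ ex) / (n * n)


def align_translation(
    image: ImageGrid2D, reference: ImageGrid2D, max_shift: float
) -> tuple[float, float]:
    """Sub-pixel translational alignment by FFT cross-correlation.

    Returns the correcting shift (dx, dy) maximizing the correlation between
    ``apply_shift(image, dx, dy)`` and ``reference``, searched within
    ``+-max_shift`` pixels.  Sub-pixel precision comes from two stages of
    local DFT upsampling of the correlation peak (~0.002 px).
    """
    if image.pixels.shape != reference.pixels.shape:
        raise ShapeError("image and reference must have the same shape")
    n = image.side
    if max_shift >= n / 4:
        raise ParameterError(f"max_shift must be below side/4 = {n / 4}")
    a = image.pixels - image.pixels.mean()
    b = reference.pixels - reference.pixels.mean()
    if a.std() == 0 or b.std() == 0:
        raise AlignmentError("constant (zero-variance) image cannot be aligned")
    cross = np.fft.fft2(b) * np.conj(np.fft.fft2(a))
    cc = np.real(np.fft.ifft2(cross))
    m = int(np.floor(max_shift))
    candidates = np.arange(-m, m + 1)
    window = cc[np.ix_(candidates % n, candidates % n)]
    iy, ix = np.unravel_index(np.argmax(window), window.shape)
    sy0, sx0 = float(candidates[iy]), float(candidates[ix])
    # stage 1: +-1 px at 0.02 px; stage 2: +-0.03 px at 0.002 px
    for span, step in ((1.0, 0.02), (0.03, 0.002)):
        ys = sy0 + np.arange(-span, span + step / 2, step)
        xs = sx0 + np.arange(-span, span + step / 2, step)
        surf = _upsampled_correlation(cross, ys, xs)
        jy, jx = np.unravel_index(np.argmax(surf), surf.shape)
        sy0, sx0 = float(ys[jy]), float(xs[jx])
    dx = float(np.clip(sx0, -max_shift, max_shift))
    dy = float(np.clip(sy0, -max_shift, max_shift))
    return dx, dy


def observe_frame_shifts(
    particle: MovieParticle, reference: ImageGrid2D, config: PolishConfig
) -> FrameShiftObservations:
    """Estimate per-frame shifts: running averages, then alignment per frame.

    The observation from the window centred on frame f is attributed to frame
    index f.  Frames whose alignment fails are flagged invalid rather than
    fabricated.
    """
    if reference.pixels.shape != particle.frames[0].pixels.shape:
        raise ShapeError("reference shape must match the particle frames")
    averaged = running_averages(particle, config.running_avg_width)
    n = particle.n_frames
    dx = np.full(n, np.nan)
    dy = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    for f in range(n):
        try:
            dx[f], dy[f] = align_translation(
                averaged.frames[f], reference, config.max_shift
            )
            valid[f] = True
        except AlignmentError:
            pass
    return FrameShiftObservations(
        particle_id=particle.particle_id, dx=dx, dy=dy, valid=valid
    )


def neighbor_weights(
    coords: np.ndarray, target_index: int, sigma_nb: float
) -> np.ndarray:
    """Gaussian neighbour weights w_p' = exp(-d^2 / (2 sigma_NB^2)).

    ``coords`` is an (P, 2) array of (x, y) particle positions in pixels; the
    self-weight is exactly 1.  Distant particles underflow to 0, which is the
    intended behaviour.
    """
    if sigma_nb <= 0:
        raise ParameterError("sigma_nb must be positive")
    coords = np.asarray(coords, dtype=float)
    d2 = np.sum((coords - coords[target_index]) ** 2, axis=1)
    with np.errstate(under="ignore"):
        return np.exp(-d2 / (2.0 * sigma_nb**2))


def fit_linear_tracks(
    observations: list[FrameShiftObservations],
    coords: np.ndarray,
    sigma_nb: float,
) -> list[LinearTrack]:
    """Fit one straight track per particle by neighbour-weighted least squares.

    For each particle p and each axis independently, (alpha_p, beta_p)
    minimize

        sum_p' w_p' sum_f (obs_{p',f} - alpha_p - beta_p * f)^2

    where the outer sum runs over ALL particles on the micrograph (including
    p itself), w_p' is the Gaussian neighbour weight, f = 1..F, and invalid
    frames are excluded from the inner sum.  The returned parameters are the
    exact minimizer from the 2x2 weighted normal equations.
    """
    coords = np.asarray(coords, dtype=float)
    n_particles = len(observations)
    if coords.shape[0] != n_particles:
        raise ShapeError("coords and observations disagree on particle count")
    # per-particle sufficient statistics over valid frames
    stats = []
    for obs in observations:
        f = np.arange(1, obs.n_frames + 1, dtype=float)
        v = obs.valid
        stats.append(
            {
                "n": float(v.sum()),
                "sf": float(f[v].sum()),
                "sff": float((f[v] ** 2).sum()),
                "sx": float(obs.dx[v].sum()),
                "sfx": float((f[v] * obs.dx[v]).sum()),
                "sy": float(obs.dy[v].sum()),
                "sfy": float((f[v] * obs.dy[v]).sum()),
            }
        )
    tracks = []
    for p in range(n_particles):
        w = neighbor_weights(coords, p, sigma_nb)
        a11 = sum(w[q] * stats[q]["n"] for q in range(n_particles))
        a12 = sum(w[q] * stats[q]["sf"] for q in range(n_particles))
        a22 = sum(w[q] * stats[q]["sff"] for q in range(n_particles))
        matrix = np.array([[a11, a12], [a12, a22]])
        det = a11 * a22 - a12 * a12
        if a11 == 0 or det <= 1e-12 * max(a11 * a22, 1.0):
            raise TrackFitError(
                f"particle {observations[p].particle_id}: degenerate track fit "
                "(fewer than 2 valid frames reachable through neighbour weights)"
            )
        bx = np.array(
            [
                sum(w[q] * stats[q]["sx"] for q in range(n_particles)),
                sum(w[q] * stats[q]["sfx"] for q in range(n_particles)),
            ]
        )
        by = np.array(
            [
                sum(w[q] * stats[q]["sy"] for q in range(n_particles)),
                sum(w[q] * stats[q]["sfy"] for q in range(n_particles)),
            ]
        )
        ax, betx = np.linalg.solve(matrix, bx)
        ay, bety = np.linalg.solve(matrix, by)
        tracks.append(
            LinearTrack(
                particle_id=observations[p].particle_id,
                alpha_x=float(ax),
                alpha_y=float(ay),
                beta_x=float(betx),
                beta_y=float(bety),
            )
        )
    return tracks


def evaluate_track(
    track: LinearTrack, f: int, n_frames: int | None = None
) -> tuple[float, float]:
    """Predicted correcting shift (x, y) of frame f (1-based) under a track."""
    if f < 1 or (n_frames is not None and f > n_frames):
        raise ParameterError(f"frame index {f} out of range")
    return (
        track.alpha_x + track.beta_x * f,
        track.alpha_y + track.beta_y * f,
    )
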