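"""Polished particle construction: shift-corrected, damage-weighted averages.

Each movie frame is translated by the correcting shift the fitted track
predicts for it, multiplied in Fourier space by its per-frequency damage
weight (the 1-D shell weights interpolated radially), and the weighted frames
are summed.  Because the weights sum to one within every shell, a movie of
identical frames polishes to exactly that frame — re-weighting never sharpens
or dampens the data overall.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage

from .config import PolishConfig
from .damage import FrameWeightTable, FrequencyShells
from .errors import MissingInputError, ParameterError
from .io_formats import ImageGrid2D, MovieParticle
from .motion import LinearTrack, evaluate_track

__all__ = ["PolishedParticle", "apply_shift", "polish_particle", "polish_dataset"]


@dataclass
class PolishedParticle:
    """A polished average particle with provenance back to its inputs."""

    particle_id: str
    image: ImageGrid2D
    track_id: str = ""
    weight_table_id: str = ""


def apply_shift(image: ImageGrid2D, dx: float, dy: float) -> ImageGrid2D:
    """Translate an image by (dx, dy) pixels via Fourier phase modulation.

    Positive dx moves content toward larger x (axis 1); boundary handling is
    circular.  Shifting by (dx, dy) then (-dx, -dy) recovers the input to
    floating-point precision.
    """
    if not (np.isfinite(dx) and np.isfinite(dy)):
        raise ParameterError("shift must be finite")
    side = image.side
    if abs(dx) >= side / 4 or abs(dy) >= side / 4:
        raise ParameterError(f"|shift| must be below side/4 = {side / 4}")
    f = np.fft.fft2(image.pixels)
    shifted = np.fft.ifft2(scipy.ndimage.fourier_shift(f, (dy, dx))).real
    return ImageGrid2D(pixels=shifted, pixel_size=image.pixel_size)


def _radial_weight_grid(
    weights_1d: np.ndarray, shells: FrequencyShells, side: int, pixel_size: float
) -> np.ndarray:
    """Interpolate 1-D shell weights onto the 2-D Fourier grid of an image."""
    freqs = np.fft.fftfreq(side, d=pixel_size)
    nu2d = np.sqrt(freqs[:, None] ** 2 + freqs[None, :] ** 2)
    # linear interpolation between shell centres; beyond the last shell the
    # last value is held
    return np.interp(nu2d, shells.nu, weights_1d)


def polish_particle(
    particle: MovieParticle,
    track: LinearTrack,
    weights: FrameWeightTable,
    shells: FrequencyShells | None = None,
) -> PolishedParticle:
    """Shift every frame onto the refined average position and sum with weights.

    Frame f is translated by ``evaluate_track(track, f)`` (the correcting
    shift), its Fourier transform multiplied by w_f(|nu|) with the shell
    weights interpolated radially, and the weighted transforms accumulated
    before a single inverse transform.
    """
    if shells is None:
        shells = weights.shells
    n_frames = particle.n_frames
    if weights.n_frames != n_frames:
        raise ParameterError(
            f"weight table has {weights.n_frames} frames, particle has {n_frames}"
        )
    side = particle.frames[0].side
    pixel_size = particle.pixel_size
    acc = np.zeros((side, side), dtype=complex)
    for f in range(1, n_frames + 1):
        dx, dy = evaluate_track(track, f, n_frames)
        frame = particle.frames[f - 1]
        spectrum = scipy.ndimage.fourier_shift(np.fft.fft2(frame.pixels), (dy, dx))
        acc += spectrum * _radial_weight_grid(
            weights.weights[f - 1], shells, side, pixel_size
        )
    polished = ImageGrid2D(pixels=np.fft.ifft2(acc).real, pixel_size=pixel_size)
    return PolishedParticle(
        particle_id=particle.particle_id,
        image=polished,
        track_id=track.particle_id,
        weight_table_id=f"{weights.n_frames}x{weights.shells.n_shells}",
    )


def polish_dataset(
    particles: list[MovieParticle],
    tracks: dict[str, LinearTrack],
    weights: FrameWeightTable,
    config: PolishConfig,
    skip_missing: bool = False,
) -> tuple[list[PolishedParticle], pd.DataFrame]:
    """Polish every particle in a dataset, preserving input order.

    Particles without a track are collected into an error report; the run
    aborts with :class:`MissingInputError` unless ``skip_missing`` is set, in
    which case they are dropped (and listed in the returned table's absence).
    """
    missing = [p.particle_id for p in particles if p.particle_id not in tracks]
    if missing and not skip_missing:
        raise MissingInputError(
            "particles missing a fitted track: " + ", ".join(missing),
            missing_ids=missing,
        )
    polished = []
    rows = []
    for idx, particle in enumerate(particles):
        if particle.particle_id not in tracks:
            continue
        result = polish_particle(particle, tracks[particle.particle_id], weights)
        polished.append(result)
        rows.append(
            {
                "rlnMicrographName": particle.micrograph_id,
                "rlnCoordinateX": particle.coord_x,
                "rlnCoordinateY": particle.coord_y,
                "rlnImageName": particle.particle_id,
                "polishStackIndex": len(polished) - 1,
            }
        )
    return polished, pd.DataFrame(rows)
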