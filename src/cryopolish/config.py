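"""Shared run configuration for particle polishing."""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ParameterError


@dataclass
class PolishConfig:
    """Parameters shared across the polishing pipeline.

    Attributes
    ----------
    sigma_nb:
        Standard deviation, in pixels, of the Gaussian kernel that weights the
        shift observations of neighbouring particles in the track fit.  Larger
        values pool more particles (less noise, less flexibility); values of
        100-300 px are typical for fields of view of a few thousand pixels.
    running_avg_width:
        Number of movie frames averaged before each alignment.  Must be odd so
        the window is centred on the frame it is attributed to.  Wider windows
        accumulate more dose (higher SNR per alignment) at the cost of temporal
        resolution; 5-7 frames is typical.
    pixel_size:
        Detector pixel size in Angstrom per pixel; converts pixel radii on the
        Fourier grid to spatial frequencies in 1/A.
    max_shift:
        Half-width, in pixels, of the translational search during alignment.
    fsc_fit_min_freq:
        Lower bound (1/A) of the frequency window used for the relative
        Guinier fit; default 1/20 A^-1.
    fsc_threshold:
        FSC value defining the upper frequency bound of the fit window
        (gold-standard resolution criterion, default 0.143).
    random_seed:
        Seed for any stochastic step.
    """

    sigma_nb: float = 200.0
    running_avg_width: int = 7
    pixel_size: float = 1.77
    max_shift: float = 10.0
    fsc_fit_min_freq: float = 1.0 / 20.0
    fsc_threshold: float = 0.143
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_nb <= 0:
            raise ParameterError("sigma_nb must be positive")
        if self.running_avg_width < 1 or self.running_avg_width % 2 == 0:
            raise ParameterError(
                "running_avg_width must be an odd number of frames "
                f"(got {self.running_avg_width})"
            )
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be positive")
        if self.max_shift <= 0:
            raise ParameterError("max_shift must be positive")
        if not (0.0 < self.fsc_threshold < 1.0):
            raise ParameterError("fsc_threshold must lie in (0, 1)")
        nyquist = 1.0 / (2.0 * self.pixel_size)
        if self.fsc_fit_min_freq >= nyquist:
            raise ParameterError(
                f"fsc_fit_min_freq ({self.fsc_fit_min_freq:.4f} 1/A) must be "
                f"below Nyquist ({nyquist:.4f} 1/A)"
            )
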