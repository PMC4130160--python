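"""Dose-dependent radiation-damage weighting from half-set FSC curves.

A reconstruction from a single movie frame carries less high-frequency signal
than the reconstruction from all frames, because of radiation damage (late
frames) and beam-induced blurring (early frames).  Given half-set FSC curves
for each single-frame reconstruction (FSC_f) and for the all-frame
reconstruction (FSC_a), the spectral SNR relation SNR = FSC/(1-FSC) yields the
per-shell ratio of signal amplitudes tau_f/tau_a.  A straight-line fit of
ln(tau_f/tau_a) against nu^2 — a "relative Guinier" plot — gives a relative
B-factor B_f (4x the slope, in A^2; negative means the frame's signal falls
off faster than the all-frame average) and a frequency-independent intercept
C_f.  These parametrize per-frame weights

    w_f(nu) = exp(B_f nu^2 / 4 + C_f) / sum_f' exp(B_f' nu^2 / 4 + C_f')

which sum to one within every frequency shell, so re-weighting never sharpens
or dampens the data overall; only differences between frames matter.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .config import PolishConfig
from .errors import ParameterError, ShapeError, UnfittableFrameError
from .io_formats import VolumeGrid3D

__all__ = [
    "FrequencyShells",
    "FSCCurve",
    "AmplitudeRatioCurve",
    "FrameDamageModel",
    "FrameWeightTable",
    "ThresholdCrossing",
    "fsc_curve",
    "snr_from_fsc",
    "threshold_frequency",
    "amplitude_ratio",
    "fit_relative_guinier",
    "frame_weights",
    "resolve_unfittable",
    "write_weight_table",
    "read_weight_table",
]


@dataclass
class FrequencyShells:
    """Integer-radius shells of the FFT grid of a box of side N.

    Shell k collects voxels whose frequency-index radius rounds to k; its
    centre frequency is nu_k = k / (N * pixel_size) in 1/A, up to Nyquist.
    """

    nu: np.ndarray
    counts: np.ndarray
    box_size: int
    pixel_size: float

    @classmethod
    def for_box(cls, box_size: int, pixel_size: float, ndim: int = 3) -> "FrequencyShells":
        idx = np.fft.fftfreq(box_size) * box_size
        grids = np.meshgrid(*([idx] * ndim), indexing="ij")
        r = np.sqrt(sum(g**2 for g in grids))
        k = np.rint(r).astype(int)
        n_shells = box_size // 2 + 1
        counts = np.bincount(k.ravel(), minlength=n_shells)[:n_shells]
        nu = np.arange(n_shells) / (box_size * pixel_size)
        return cls(nu=nu, counts=counts, box_size=box_size, pixel_size=pixel_size)

    @property
    def n_shells(self) -> int:
        return self.nu.size

    @property
    def nyquist(self) -> float:
        return 1.0 / (2.0 * self.pixel_size)


@dataclass
class FSCCurve:
    """Fourier shell correlation per shell; shell 0 (DC) is excluded from fits."""

    shells: FrequencyShells
    fsc: np.ndarray
    flagged: np.ndarray = field(default=None)  # shells with zero power

    def __post_init__(self) -> None:
        self.fsc = np.asarray(self.fsc, dtype=float)
        if self.fsc.size != self.shells.n_shells:
            raise ShapeError("fsc length must match shell count")
        if np.any(self.fsc > 1.0 + 1e-9) or np.any(self.fsc < -1.0 - 1e-9):
            raise ParameterError("FSC values must lie in [-1, 1]")
        if self.flagged is None:
            self.flagged = np.zeros(self.fsc.size, dtype=bool)


@dataclass
class AmplitudeRatioCurve:
    """Per-shell signal amplitude ratio tau_f / tau_a with validity flags."""

    shells: FrequencyShells
    ratio: np.ndarray
    valid: np.ndarray


@dataclass
class FrameDamageModel:
    """Fitted relative Guinier line for one movie frame.

    ``b`` is the relative B-factor in A^2 (4x the slope of ln ratio vs nu^2);
    ``c`` the unitless intercept.  ``fit_shells`` records the shell indices
    used; ``residual`` the root-mean-square fit residual in log space.
    """

    frame_index: int
    b: float
    c: float
    fit_shells: tuple = ()
    residual: float = 0.0
    copied_from: int | None = None


@dataclass
class FrameWeightTable:
    """Normalized per-frame, per-shell weights: columns sum to 1 per shell."""

    shells: FrequencyShells
    weights: np.ndarray  # (F, n_shells)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[1] != self.shells.n_shells:
            raise ShapeError("weights must be (F, n_shells)")

    @property
    def n_frames(self) -> int:
        return self.weights.shape[0]


class ThresholdCrossing(NamedTuple):
    frequency: float
    flag: str  # 'crossed' | 'never_below' | 'below_from_start'


def _shell_index(box_size: int, ndim: int) -> np.ndarray:
    idx = np.fft.fftfreq(box_size) * box_size
    grids = np.meshgrid(*([idx] * ndim), indexing="ij")
    r = np.sqrt(sum(g**2 for g in grids))
    return np.rint(r).astype(int)


def fsc_curve(half1: VolumeGrid3D, half2: VolumeGrid3D) -> FSCCurve:
    """Fourier shell correlation between two half-set reconstructions.

    Per shell k: Re(sum F1 F2*) / sqrt(sum |F1|^2 * sum |F2|^2) over voxels
    whose frequency radius rounds to k.  Zero-power shells get FSC 0 and are
    flagged.
    """
    if half1.voxels.shape != half2.voxels.shape:
        raise ShapeError("half maps must have the same shape")
    if half1.pixel_size != half2.pixel_size:
        raise ParameterError("half maps must have the same pixel size")
    n = half1.side
    f1 = np.fft.fftn(half1.voxels)
    f2 = np.fft.fftn(half2.voxels)
    k = _shell_index(n, 3).ravel()
    n_shells = n // 2 + 1
    keep = k < n_shells
    k = k[keep]
    cross = np.real(f1 * np.conj(f2)).ravel()[keep]
    p1 = np.abs(f1).ravel()[keep] ** 2
    p2 = np.abs(f2).ravel()[keep] ** 2
    s_cross = np.bincount(k, weights=cross, minlength=n_shells)
    s_p1 = np.bincount(k, weights=p1, minlength=n_shells)
    s_p2 = np.bincount(k, weights=p2, minlength=n_shells)
    denom = np.sqrt(s_p1 * s_p2)
    flagged = denom == 0
    fsc = np.zeros(n_shells)
    np.divide(s_cross, denom, out=fsc, where=~flagged)
    fsc = np.clip(fsc, -1.0, 1.0)
    shells = FrequencyShells.for_box(n, half1.pixel_size)
    return FSCCurve(shells=shells, fsc=fsc, flagged=flagged)


def snr_from_fsc(fsc: float) -> float:
    """Spectral SNR from FSC: SNR = FSC / (1 - FSC), clamped at 0 for FSC <= 0."""
    if fsc >= 1.0:
        raise ParameterError("FSC = 1 implies infinite SNR")
    return max(fsc, 0.0) / (1.0 - fsc)


def threshold_frequency(curve: FSCCurve, threshold: float) -> ThresholdCrossing:
    """Frequency of the first downward crossing of ``threshold``.

    Linearly interpolated between the bracketing shells; shell 0 (DC) is
    ignored.  If the curve never drops below the threshold, Nyquist (the last
    shell frequency) is returned with flag 'never_below'; if it is already
    below at the first non-DC shell, that shell's frequency is returned with
    flag 'below_from_start'.
    """
    fsc = curve.fsc
    nu = curve.shells.nu
    if fsc.size < 2:
        raise ParameterError("FSC curve has no non-DC shells")
    if fsc[1] < threshold:
        return ThresholdCrossing(float(nu[1]), "below_from_start")
    for k in range(2, fsc.size):
        if fsc[k] < threshold <= fsc[k - 1]:
            frac = (fsc[k - 1] - threshold) / (fsc[k - 1] - fsc[k])
            freq = nu[k - 1] + frac * (nu[k] - nu[k - 1])
            return ThresholdCrossing(float(min(freq, nu[-1])), "crossed")
    return ThresholdCrossing(float(nu[-1]), "never_below")


def amplitude_ratio(fsc_f: FSCCurve, fsc_a: FSCCurve) -> AmplitudeRatioCurve:
    """Signal amplitude ratio tau_f/tau_a per shell from the two FSC curves.

    ratio_k = sqrt( FSC_f (1 - FSC_a) / ( FSC_a (1 - FSC_f) ) )
            = sqrt( SNR_f / SNR_a ),
    using SNR = FSC/(1-FSC) and equal noise power in all reconstructions.
    Shells where either FSC is <= 0 (or >= 1, or DC) are flagged invalid.
    """
    if fsc_f.shells.n_shells != fsc_a.shells.n_shells:
        raise ShapeError("FSC curves must share the same shells")
    ff = fsc_f.fsc
    fa = fsc_a.fsc
    valid = (ff > 0) & (fa > 0) & (ff < 1) & (fa < 1)
    valid[0] = False
    ratio = np.zeros_like(ff)
    with np.errstate(divide="ignore", invalid="ignore"):
        np.sqrt(
            (ff * (1.0 - fa)) / (fa * (1.0 - ff)),
            out=ratio,
            where=valid,
        )
    # noise-free limit: both curves exactly 1 => equal signal, ratio -> 1
    both_unity = (ff >= 1.0 - 1e-12) & (fa >= 1.0 - 1e-12)
    both_unity[0] = False
    ratio[both_unity] = 1.0
    valid |= both_unity
    if not valid.any():
        raise ParameterError("no valid shells in amplitude ratio curve")
    return AmplitudeRatioCurve(shells=fsc_f.shells, ratio=ratio, valid=valid)


def fit_relative_guinier(
    ratio: AmplitudeRatioCurve,
    fsc_f: FSCCurve,
    config: PolishConfig,
    frame_index: int = 0,
) -> FrameDamageModel:
    """Fit ln(tau_f/tau_a) against nu^2 over the useful frequency window.

    The window runs from ``config.fsc_fit_min_freq`` (default 1/20 A^-1) to
    the frequency where FSC_f crosses ``config.fsc_threshold`` (default
    0.143).  B_f = 4 * slope (A^2), C_f = intercept, so that
    ratio ~= exp(B_f nu^2 / 4 + C_f).  If fewer than 3 valid shells fall in
    the window, the fit falls back to all valid shells above the lower bound;
    if still fewer than 3, :class:`UnfittableFrameError` is raised.
    """
    nu = ratio.shells.nu
    nu_max = threshold_frequency(fsc_f, config.fsc_threshold).frequency
    usable = ratio.valid & (ratio.ratio > 0)
    in_range = usable & (nu >= config.fsc_fit_min_freq) & (nu <= nu_max)
    if in_range.sum() < 3:
        in_range = usable & (nu >= config.fsc_fit_min_freq)
    if in_range.sum() < 3:
        raise UnfittableFrameError(
            f"frame {frame_index}: only {int(in_range.sum())} valid shells "
            "above the lower fit bound (need 3)"
        )
    x = nu[in_range] ** 2
    y = np.log(ratio.ratio[in_range])
    slope, intercept = np.polyfit(x, y, 1)
    resid = float(np.sqrt(np.mean((y - (slope * x + intercept)) ** 2)))
    return FrameDamageModel(
        frame_index=frame_index,
        b=float(4.0 * slope),
        c=float(intercept),
        fit_shells=tuple(np.nonzero(in_range)[0]),
        residual=resid,
    )


def resolve_unfittable(
    models: list[FrameDamageModel | None],
) -> list[FrameDamageModel]:
    """Replace unfittable frames (None) by the nearest fittable frame's (B, C).

    Ties between equally distant neighbours resolve to the earlier frame.
    This preserves the unity-sum weight contract without inventing damage
    parameters; the substitution is recorded in ``copied_from``.
    """
    fitted = [i for i, m in enumerate(models) if m is not None]
    if not fitted:
        raise UnfittableFrameError("no movie frame could be fitted")
    resolved = []
    for i, m in enumerate(models):
        if m is not None:
            resolved.append(m)
            continue
        src = min(fitted, key=lambda j: (abs(j - i), j))
        donor = models[src]
        resolved.append(
            FrameDamageModel(
                frame_index=i,
                b=donor.b,
                c=donor.c,
                fit_shells=donor.fit_shells,
                residual=donor.residual,
                copied_from=src,
            )
        )
    return resolved


def frame_weights(
    models: list[FrameDamageModel], shells: FrequencyShells
) -> FrameWeightTable:
    """Normalized per-shell frame weights from fitted (B_f, C_f).

    w[f, k] = exp(B_f nu_k^2 / 4 + C_f), normalized so every shell column
    sums to 1.  The per-shell maximum exponent is subtracted before
    exponentiation for numerical stability; the normalization makes the table
    invariant to adding any constant to all B_f or all C_f.
    """
    if not models:
        raise ParameterError("need at least one frame model")
    b = np.array([m.b for m in models])
    c = np.array([m.c for m in models])
    expo = b[:, None] * shells.nu[None, :] ** 2 / 4.0 + c[:, None]
    expo -= expo.max(axis=0, keepdims=True)
    w = np.exp(expo)
    w /= w.sum(axis=0, keepdims=True)
    return FrameWeightTable(shells=shells, weights=w)


def write_weight_table(
    table: FrameWeightTable, models: list[FrameDamageModel], path: str
) -> None:
    """Write frame, B_f, C_f and per-shell weights as a TSV file."""
    data = {"frame": [m.frame_index for m in models],
            "b_factor": [m.b for m in models],
            "intercept": [m.c for m in models]}
    for k in range(table.shells.n_shells):
        data[f"w_nu_{table.shells.nu[k]:.6f}"] = table.weights[:, k]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_weight_table(path: str, pixel_size: float | None = None) -> tuple[FrameWeightTable, pd.DataFrame]:
    """Read a weight TSV back; shell frequencies are parsed from the header."""
    df = pd.read_csv(path, sep="\t")
    w_cols = [c for c in df.columns if c.startswith("w_nu_")]
    nu = np.array([float(c[len("w_nu_"):]) for c in w_cols])
    weights = df[w_cols].to_numpy()
    n_shells = nu.size
    box = 2 * (n_shells - 1)
    px = pixel_size
    if px is None:
        px = 1.0 / (box * nu[1]) if n_shells > 1 and nu[1] > 0 else 1.0
    shells = FrequencyShells.for_box(box, px)
    shells = FrequencyShells(nu=nu, counts=shells.counts, box_size=box, pixel_size=px)
    return FrameWeightTable(shells=shells, weights=weights), df
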