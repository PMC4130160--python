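"""Diagnostic plots: exaggerated movement tracks and damage-weight figures."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .damage import FrameDamageModel, FrameWeightTable
from .motion import LinearTrack

__all__ = ["plot_tracks", "plot_damage_weights"]


def plot_tracks(
    coords: np.ndarray,
    tracks: list[LinearTrack],
    n_frames: int,
    path: str,
    exaggeration: float = 50.0,
    field_size: float | None = None,
) -> None:
    """Draw fitted linear tracks at their particle positions, exaggerated.

    Start points are marked green, end points red, mirroring how movement
    tracks are conventionally overlaid on micrographs.
    """
    fig, ax = plt.subplots(figsize=(7, 7))
    f = np.arange(1, n_frames + 1)
    for (x0, y0), track in zip(np.asarray(coords), tracks):
        xs = x0 + exaggeration * (track.alpha_x + track.beta_x * f)
        ys = y0 + exaggeration * (track.alpha_y + track.beta_y * f)
        ax.plot(xs, ys, "-", color="white", lw=1.0)
        ax.plot(xs[0], ys[0], ".", color="green", ms=4)
        ax.plot(xs[-1], ys[-1], ".", color="red", ms=4)
    ax.set_facecolor("0.35")
    if field_size:
        ax.set_xlim(0, field_size)
        ax.set_ylim(0, field_size)
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    ax.set_title(f"fitted movement tracks ({exaggeration:.0f}x exaggerated)")
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_damage_weights(
    models: list[FrameDamageModel], table: FrameWeightTable, path: str
) -> None:
    """Two-panel figure: B_f/C_f per frame, and stacked relative weights vs nu."""
    frames = [m.frame_index for m in models]
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(7, 8))
    ax1.plot(frames, [m.b for m in models], "o-", label="relative B-factor (A^2)")
    ax1b = ax1.twinx()
    ax1b.plot(frames, [m.c for m in models], "s--", color="tab:orange", label="intercept C")
    ax1.set_xlabel("movie frame")
    ax1.set_ylabel("B_f (A^2)")
    ax1b.set_ylabel("C_f")
    ax1.legend(loc="lower left")
    ax1b.legend(loc="lower right")
    nu = table.shells.nu
    ax2.stackplot(nu, table.weights, lw=0)
    ax2.set_xlabel("spatial frequency (1/A)")
    ax2.set_ylabel("relative weight per frame")
    ax2.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
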