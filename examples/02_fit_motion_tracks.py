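"""Fit straight movement tracks with and without neighbour pooling.

Simulates noisy per-frame shift observations for a 50-particle field sharing
a smooth motion field, fits per-particle linear tracks by neighbour-weighted
least squares, and compares the per-frame RMS track error for a wide Gaussian
kernel (sigma_NB = 300 px) against independent per-particle fits.
"""

import numpy as np

from cryopolish import (
    SimulationConfig,
    fit_linear_tracks,
    simulate_motion_field,
    simulate_shift_observations,
)

config = SimulationConfig(n_particles=50, n_frames=16, heterogeneity=0.0)
coords, truth = simulate_motion_field(config, seed=1)
observations = simulate_shift_observations(truth, 16, noise_std=2.0, seed=2)
f = np.arange(1, 17)

for sigma_nb, label in ((300.0, "sigma_NB = 300 px (pooling neighbours)"),
                        (1e-3, "sigma_NB -> 0   (each particle alone)")):
    fitted = fit_linear_tracks(observations, coords, sigma_nb)
    err = []
    for fit, t in zip(fitted, truth):
        err.append((fit.alpha_x + fit.beta_x * f) - (t.alpha_x + t.beta_x * f))
        err.append((fit.alpha_y + fit.beta_y * f) - (t.alpha_y + t.beta_y * f))
    rmse = np.sqrt(np.mean(np.square(err)))
    print(f"{label}: per-frame shift RMSE {rmse:.3f} px")

print("with 2 px of observation noise per frame, borrowing strength from")
print("neighbouring particles cuts the track error roughly threefold.")
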