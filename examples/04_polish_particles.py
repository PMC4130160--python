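"""Polish a particle movie and compare against a naive average.

Simulates one particle movie moving along a known track with a dose-dependent
damage schedule and unit noise per frame, then builds two averages: the naive
one (no shifts, equal weights) and the polished one (track-corrected shifts,
per-frequency damage weights).  The correlation with the clean ground-truth
image quantifies the gain.
"""

import numpy as np

from cryopolish import (
    FrameDamageModel,
    FrequencyShells,
    LinearTrack,
    SimulationConfig,
    frame_weights,
    make_reference,
    polish_particle,
    simulate_movie,
)

config = SimulationConfig(n_frames=16, image_noise_std=1.0)
reference = make_reference(config.box_size, config.pixel_size, seed=7)
track = LinearTrack("demo", alpha_x=-2.0, alpha_y=1.5, beta_x=0.24, beta_y=-0.18)
movie = simulate_movie(reference, track, config, seed=8)

shells = FrequencyShells.for_box(config.box_size, config.pixel_size, ndim=2)
models = [
    FrameDamageModel(f + 1, config.damage_b[f], config.damage_c[f])
    for f in range(config.n_frames)
]
table = frame_weights(models, shells)
polished = polish_particle(movie, track, table)
naive = np.mean([frame.pixels for frame in movie.frames], axis=0)


def corr(a, b):
    a = a - a.mean()
    b = b - b.mean()
    return float(np.sum(a * b) / np.sqrt(np.sum(a**2) * np.sum(b**2)))


print(f"correlation with ground truth, naive average:    {corr(naive, reference.pixels):.4f}")
print(f"correlation with ground truth, polished average: {corr(polished.image.pixels, reference.pixels):.4f}")
print("the polished average undoes the ~4.5 px of drift blurring and")
print("down-weights the damaged high-frequency content of early/late frames.")
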