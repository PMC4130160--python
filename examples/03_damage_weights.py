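"""Estimate per-frame damage weights from half-set FSC curves.

Generates a synthetic half-map series with a known damage schedule, computes
per-frame and all-frame FSC curves, converts them to signal amplitude ratios,
fits relative Guinier lines, and prints the recovered (B_f, C_f) next to the
injected truth together with the weight-table contract.
"""

import numpy as np

from cryopolish import (
    PolishConfig,
    SimulationConfig,
    amplitude_ratio,
    fit_relative_guinier,
    frame_weights,
    fsc_curve,
    simulate_halfmap_series,
)

config = SimulationConfig(n_frames=8, box_size=64)
series = simulate_halfmap_series(config, seed=3)
fsc_a = fsc_curve(*series.average_pair)
pcfg = PolishConfig(pixel_size=config.pixel_size)

models = []
print("frame   true B_f   fitted B_f   fitted C_f")
for f, (h1, h2) in enumerate(series.frame_pairs, start=1):
    fsc_f = fsc_curve(h1, h2)
    ratio = amplitude_ratio(fsc_f, fsc_a)
    model = fit_relative_guinier(ratio, fsc_f, pcfg, frame_index=f)
    models.append(model)
    print(f"{f:5d}   {series.true_b[f - 1]:8.1f}   {model.b:10.1f}   {model.c:10.3f}")

table = frame_weights(models, fsc_a.shells)
sums = table.weights.sum(axis=0)
print(f"weight columns sum to 1 within {np.abs(sums - 1).max():.1e} per shell,")
print("so re-weighting redistributes signal between frames without any net")
print("sharpening or dampening; frames with less negative B_f dominate the")
print("high frequencies.")
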