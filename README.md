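# cryopolish

Beam-induced motion correction and radiation-damage weighting for
single-particle cryo-EM movies — "particle polishing".

## The problem

The electron beam that images a frozen-hydrated specimen also moves it.
Over a typical exposure, particles drift by several pixels, blurring the
accumulated image and destroying high-resolution signal.  Fast
direct-electron detectors record the exposure as a movie of F short
sub-frames, which makes the motion correctable — but the per-frame images of
a small particle are far too noisy to track it reliably on its own.  At the
same time, radiation damage progressively erases the high-frequency signal
of later frames, while the large beam-induced movements of the first frames
blur theirs, so frames should not contribute equally at every spatial
frequency.

`cryopolish` implements both corrections:

1. **Neighbour-weighted straight tracks.**  Running averages of an odd
   number of movie frames are aligned (translation only) against a common
   reference, giving noisy per-frame shift observations Δx_{p,f}.  For each
   particle *p* and each axis independently, a straight track is fitted by
   minimizing

       min_{α_p, β_p}  Σ_{p'} w_{p'} Σ_{f=1}^{F} ( Δx_{p',f} − α_p − β_p f )²

   where the outer sum runs over **all** particles on the field of view and
   w_{p'} = exp(−d²/2σ_NB²) is a Gaussian in the distance between particles
   p and p'.  Nearby particles move alike, so pooling them suppresses
   observation noise while still following spatially varying motion; σ_NB
   (pixels) controls the trade-off.

2. **Relative Guinier damage weighting.**  From half-set reconstructions of
   each single frame and of all frames together, per-shell FSC curves give
   the spectral signal-to-noise ratio SNR(ν) = FSC/(1−FSC), and with equal
   noise power in every reconstruction, the signal amplitude ratio

       τ_f(ν)/τ_a(ν) = sqrt( SNR_f(ν) / SNR_a(ν) ).

   Fitting ln(τ_f/τ_a) against ν² between 1/20 Å⁻¹ and the frequency where
   FSC_f = 0.143 yields a *relative B-factor* B_f = 4·slope (Å², negative
   when the frame's signal falls off faster than the all-frame average) and
   an intercept C_f.  These define per-frame, per-frequency weights

       w_f(ν) = exp(B_f ν²/4 + C_f) / Σ_{f'} exp(B_{f'} ν²/4 + C_{f'})

   which sum to one within every frequency shell — re-weighting never
   sharpens or dampens the data overall.

3. **Polishing.**  Each frame is translated by the correcting shift its
   fitted track predicts, weighted per Fourier pixel by w_f(|ν|), and the
   frames are summed into a "polished" average particle with improved SNR,
   ready for downstream classification or refinement.

The package is aimed at method developers and practitioners who want a
transparent, test-covered reference implementation of these estimators with
a first-class synthetic-data module, not at replacing a production pipeline.

## Conventions

* Images are indexed `pixels[y, x]`; coordinates `(x, y)` are 0-based pixels
  with the origin at the first stored pixel (STAR files in the wild mix
  conventions — this package is explicit).
* All shifts are in pixels; a stored shift is always the *correcting* shift
  that registers a frame onto the reference.  Frequencies are in 1/Å derived
  from the pixel size.
* MRC files are written as 32-bit real (mode 2); modes 0/1/2/6 are accepted
  on read.  Readers never reorder particles or frames.

## Worked example

`examples/` contains one short script per capability.  Fitting tracks on a
synthetic 50-particle field with 2 px of observation noise per frame
(`examples/02_fit_motion_tracks.py`) prints:

```
sigma_NB = 300 px (pooling neighbours): per-frame shift RMSE 0.211 px
sigma_NB -> 0   (each particle alone): per-frame shift RMSE 0.669 px
```

i.e. pooling neighbours cuts the track error roughly threefold relative to
fitting each particle alone.  Polishing a movie that drifts ~4.5 px under
the default dose-dependent damage schedule
(`examples/04_polish_particles.py`) prints:

```
correlation with ground truth, naive average:    0.7785
correlation with ground truth, polished average: 0.9711
```

— the polished average recovers most of the signal the naive unshifted,
unweighted average blurs away.  `examples/03_damage_weights.py` shows the
damage side: recovered (B_f, C_f) per frame next to the injected truth, and
the per-shell weight sums equal to 1 to machine precision.

There is also a thin CLI over the same functions:

```bash
cryopolish simulate --out data --preset small --seed 4
cryopolish fit-tracks --particles data/particles.star --reference data/reference.mrcs \
    --out tracks.star --pixel-size 2.5 --avg-width 1 --max-shift 8
cryopolish estimate-weights --halfmap-dir data --out weights.tsv --pixel-size 2.5
cryopolish polish --particles data/particles.star --tracks tracks.star \
    --weights weights.tsv --out-stack polished.mrcs --out-star polished.star --pixel-size 2.5
```

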