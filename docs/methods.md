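# Methods

This note records the models implemented in `cryopolish`, the assumptions
they rest on, the numerical choices made where the design was open, and what
the synthetic-data generators do and do not emulate.

## Motion model

Per-particle beam-induced motion is modelled as a straight track in the
field of view: the correcting shift of frame *f* (the translation that
registers the frame onto the refined average position) is α + β·f per axis,
with *f* = 1, …, F.  The intercept α is therefore the extrapolated shift at
*f* = 0; this is pure bookkeeping and does not affect applied shifts.
Rotations are never searched: for the particle sizes this method targets,
per-frame images are too noisy to determine orientations, and observed
beam-induced rotations are comparable to the orientation accuracy anyway.

### Shift observations

Before alignment, each frame is replaced by the unweighted mean of an
odd-width window of frames (`running_avg_width`, default 7).  Windows are
truncated at the movie ends rather than dropped, so every frame yields one
observation; the alternative (skipping end frames) would discard exactly the
low-dose early frames the damage model later identifies as valuable at low
frequency.  End-window observations are not down-weighted — within-particle
frames enter the track fit with equal weight.

Alignment is translation-only cross-correlation against a common reference,
computed via FFT.  The integer peak (constrained to ±`max_shift`) is refined
by two stages of local matrix-multiply DFT upsampling of the correlation
surface (steps 0.02 px then 0.002 px).  This is deterministic,
non-iterative, and accurate to ~0.002 px on noiseless data; a 3-point
parabolic peak interpolation was rejected because its bias (up to ~0.1 px at
quarter-pixel offsets) is of the same order as the accuracy the track fit
needs.  Frames that cannot be aligned (zero variance) are flagged invalid
and excluded from the fit rather than fabricated.

The reference is taken as given input.  It is not CTF-modulated here (CTF
handling is out of scope), which is a fidelity limitation on real data where
the particle images carry the CTF.

### Track fitting

For each particle and axis independently, (α, β) minimize the
neighbour-weighted least-squares target over **all** particles on the
micrograph, with Gaussian weights w = exp(−d²/2σ_NB²).  The kernel is
deliberately unnormalized with self-weight 1: any common scale factor
cancels in the minimizer.  The solution is the exact 2×2 weighted
normal-equations minimizer; a fit is refused (error naming the particle)
when the system is degenerate, i.e. when fewer than two valid frame indices
are reachable through non-underflowed weights.  As σ_NB → 0 the fit reduces
to each particle's own ordinary regression; as σ_NB grows it approaches a
single micrograph-wide track.  σ_NB is interpreted in pixels throughout
(values of 100–300 px are typical for ~2–4k px fields of view).

Straight tracks cannot describe bent or zig-zag motion.  The intended use
for such data is to pre-align whole frames externally and feed the residual
(approximately linear) motion to this package; no higher-order track model
is provided.

## Damage model

Radiation damage and early-exposure blurring are modelled per frame by a
Gaussian fall-off of signal amplitude relative to the all-frame average
reconstruction: τ_f(ν)/τ_a(ν) ≈ exp(B_f ν²/4 + C_f).  The inputs are FSC
curves between independently refined half-set reconstructions, per frame and
for all frames, evaluated on integer-radius voxel shells of the FFT grid
(ν_k = k/(N·pixel_size)).  The amplitude ratio per shell is
sqrt(SNR_f/SNR_a) with SNR = FSC/(1−FSC), which assumes **equal noise power
in every reconstruction** — valid when every half uses the same number of
particles and the same reconstruction pipeline.  Shells where either FSC is
≤ 0 are excluded from fits (the log is undefined); they are not clamped.
The degenerate noise-free case FSC_f = FSC_a = 1 is mapped to ratio 1, its
analytic limit.

The relative Guinier fit is unweighted OLS of ln(ratio) on ν² over shells
between `fsc_fit_min_freq` (default 1/20 Å⁻¹, inclusive) and the frequency
where FSC_f first crosses 0.143 downward (linearly interpolated between
bracketing shells; a curve that never crosses is truncated at Nyquist and
flagged).  Per-shell variance weighting was considered and rejected: it is
not part of the standard recipe and adds an estimator choice the data do not
constrain.  If fewer than 3 valid shells fall in the window, the window is
widened to all valid shells above the lower bound; frames that still cannot
be fitted copy (B, C) from the nearest fittable frame by index (ties to the
earlier frame) — this preserves the unity-sum weight contract without
inventing damage parameters, and the substitution is recorded on the model.

Weights are a per-shell softmax of B_f ν²/4 + C_f, stabilized by
subtracting the per-shell maximum exponent.  Two contracts follow and are
enforced by tests: every shell column sums to 1 (within 1e−10), and the
table is invariant to adding any constant to all B_f or all C_f — only
differences between frames matter.

### Identifiability of relative B-factors

Because the reference for "relative" is the average reconstruction, and the
average's own fall-off is the log-mean-exp of the per-frame damage filters,
the per-frame ratio curves share a common, slightly non-linear background
term.  A straight-line fit absorbs its local slope, so injected schedules
are recoverable only up to this common tilt; the residual bias grows with
the variance of the schedule and the width of the fit window.  This is a
property of the estimator itself, not of the implementation.  The synthetic
half-map defaults (below) keep this bias comfortably inside the recovery
tolerance used in the tests; on real data it is absorbed into the overall
B-factor of the final reconstruction and is harmless, because the weights
only use differences between frames.

## Polishing

Each frame is shifted by its track's correcting shift (Fourier phase
modulation, circular boundary — acceptable because particle boxes are
windowed with margins), multiplied per Fourier pixel by its weight with the
1-D shell weights interpolated linearly in radius (the last shell's value is
held beyond Nyquist radius in the grid corners), and accumulated; one
inverse FFT yields the polished image.  Linear radial interpolation was
preferred over nearest-shell lookup for smoothness.  Because weights sum to
one per shell, a movie of identical frames polishes to exactly that frame.
Polished images are not re-normalized in real space.  The operation is
linear in the frame images.

## Synthetic data

The generators produce data with exactly the statistical structure the
estimators assume, so every stage is testable without external data:

* **References / signal volumes** are band-limited filtered white noise
  (Gaussian envelope with an absolute B of 300 Å², hard cutoff at 0.9×
  Nyquist).  The cutoff keeps fractional Fourier shifts exactly reversible
  (no content in the symmetry-breaking Nyquist bins).  Smooth random blobs
  are sufficient for alignment and spectral tests; no atomic models.
* **Motion fields**: coordinates uniform on a 2048 px field; per-axis
  slopes are a smooth random field (a constant plus six Gaussian bumps of
  correlation length 600 px, amplitude scale 0.2 px/frame) plus optional
  i.i.d. per-particle heterogeneity.  Intercepts are set so each track's
  mean shift over the movie is zero, consistent with shifts being measured
  against the refined *average* particle position.
* **Movies**: frame f is the reference filtered per shell by
  exp(B_f ν²/4 + C_f), displaced by minus the correcting shift, plus white
  Gaussian noise (default std 1.0 against a unit-variance reference —
  pessimistic for an average cryo-EM frame, but convenient).
* **Half-map series**: a common signal volume filtered per shell per frame;
  each half adds independent noise of identical power (the method's stated
  assumption holds by construction); the all-frame pair averages the frame
  signals with weight 1/F and adds fresh noise.
* **Damage schedule default**: mean-centred, standard deviation 20 Å², with
  depressed values for the first two frames (initial beam-induced motion),
  a peak at frame 3, and a steady decline at higher dose.  Mean-centring
  reflects that relative B-factors are measured against the average of the
  same frames; the moderate spread and the half-map pixel size of
  2.5 Å/voxel at box 64 keep the fit window (1/20 Å⁻¹ to the FSC = 0.143
  crossing, ~10–20 shells) wide enough that the shell-sampling noise floor
  and the identifiability bias discussed above stay within a few Å².

Everything is deterministic given the seed; changing the seed changes noise
realizations, never configured truth.

What the synthetic data does **not** contain: CTF modulation, detector MTF,
ice/solvent background, dose-rate–dependent physics, non-linear tracks, or
real structural features.  Passing tests therefore demonstrate estimator
correctness under the model's own assumptions, not end-to-end performance on
real micrographs.

## Problem sizes

The simulation studies use deliberately small instances: oracle-equivalence
checks on ≤ 5 particles × ≤ 8 frames, noise-suppression fields of 50
particles × 16 frames over 20 seeds, B-factor recovery at box 64 over 5
seeds, and polishing benefit over 40 single-particle trials at box 64.
These sizes make the whole suite and the reproduction script run in seconds
on a single CPU while leaving the statistics well-resolved.

## Known limitations

* Tracks are straight lines; complex motion must be pre-corrected upstream.
* The alignment reference is not CTF-modulated.
* FSC curves are used as computed; no masking or noise-substitution
  correction is applied.
* Absolute B-factor estimation (absolute Guinier analysis, map sharpening)
  is out of scope.
* Boundary handling for shifts is circular; particles must be boxed with
  sufficient margins.
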