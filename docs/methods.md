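# Methods

This note documents the models, numerical choices and known limitations
of the `nirseeg` pipeline.  Units are fixed package-wide: time in
seconds, concentration changes in μM, EEG in μV, attenuation in OD,
wavelengths in nm.

## Chromophore resolution (modified Beer–Lambert / UCLn)

Attenuation changes at each channel and wavelength are modelled as

ΔA(λ, t) = Σᵢ εᵢ(λ) · Δcᵢ(t) · d · DPF(λ),  i ∈ {HbO₂, HHb, oxCCO},

with d the source–detector separation (2.5 cm on the default 4-source,
14-detector, 19-channel probe) and DPF the differential pathlength
factor, an infant-appropriate constant 5.13 by default (`ucln_invert`
accepts a per-wavelength DPF table).  Inversion is ordinary least
squares over all wavelengths inside the 780–900 nm fit range via the
pseudoinverse of the (n_λ × 3) design; a rank check rejects degenerate
extinction submatrices.  ΔA is treated as natural optical density; a
log₁₀ convention in a user-supplied extinction table only rescales Δc
uniformly.

Extinction spectra: the package does not bundle measured coefficients.
`synthetic_extinction_table()` generates three smooth, linearly
independent synthetic curves at 1 nm resolution whose qualitative shapes
echo the NIR features of the real chromophores (it is labelled synthetic
in its docstring); measured tables load through `read_extinction_csv`.
All forward/inverse round-trip guarantees (noise-free error ≤ 1e-9 μM;
noise error decreasing monotonically from 3 to 120 wavelengths) are
independent of which table is used, provided it has rank 3.

## Motion correction

Per channel and wavelength the attenuation signal is decomposed with
Daubechies-5 wavelets to the maximum depth the record length allows;
at every detail level, coefficients outside the interquartile fence
[Q1 − α·IQR, Q3 + α·IQR] (α = 0.8) are zeroed before reconstruction.
Constants pass through untouched; brief spikes — modelled in the
generator as ≤1 s transients added identically to all wavelengths of a
channel, since motion disturbs optode coupling, not chromophores — are
strongly attenuated.  Spike energy that reaches the (untouched)
approximation band survives as a small smooth residual spread over
roughly ±20 samples around the spike; tests therefore assess off-spike
fidelity outside that neighbourhood.

## Temporal filtering

bNIRS chromophore traces: zero-phase (forward–backward) Butterworth
band-pass, order 4, 0.01–0.4 Hz.  At the default 1.4 s multiplexing
period the Nyquist frequency is 0.357 Hz, below the nominal 0.4 Hz upper
edge; the edge is clamped to 0.95 × Nyquist with a warning rather than
guessing a different acquisition rate.  Zero-phase filtering is used so
that block averages are not phase-shifted.

EEG: zero-phase Butterworth band-pass 0.1–100 Hz plus 48–52 Hz band-stop
notch.  The 0.1 Hz high-pass has a transient lasting several seconds, so
`filtfilt` is run with padding up to 30 s (default padding leaks edge
drift across the record).  Band RMS filters applied to 1 s segments use
maximal padding (segment length − 1) for the same reason; without it the
RMS of a mid-band sinusoid reads ~12 % low.

## EEG segmentation and band power

Each analysed block spans the 8 s pre-stimulus baseline plus the 8–12 s
stimulus.  One segment per second is cut, each holding the last 200 ms
of the preceding second plus 800 ms of its own second; the leading
200 ms mean is subtracted (within-segment baseline correction), so the
first stimulus segment is referenced to the end of the baseline period.
Segments are rejected when any channel exceeds 200 μV or when their
second is marked inattentive (the generator draws inattention as
Bernoulli per second; real attention coding from video is out of scope).
Channels whose 1 s windows exceed 200 μV in more than 30 % of windows
are interpolated from their three nearest neighbours
(inverse-distance weights on the standard 10/20 montage geometry
shipped with MNE).

Band RMS is computed per segment, channel and band (theta 3–6, alpha
8–12, beta 13–30, gamma 20–60, high-gamma 60–80 Hz — gamma deliberately
overlaps beta; the bands are used as conventionally printed) by
zero-phase 4th-order Butterworth filtering and time-domain RMS over the
800 ms unique portion; an FFT band-power alternative sits behind
`method="fft"`.  Block baseline correction subtracts the mean RMS of the
final 2 s of the baseline (interpreted as the 2 s immediately before
stimulus onset) from the whole block; blocks are aligned on stimulus
onset and averaged, keeping 8 baseline and the first 8 stimulus seconds.
Since blocks last 8–12 s, stimulus-period averages for statistics use
the first 8 s consistently, matching the window the coupling GLM
consumes.  Paired t-tests (the subject is the unit; a Welch option
exists) compare social vs baseline, non-social vs baseline and social vs
non-social per channel and band, with Benjamini–Hochberg FDR across the
32 channels within each band × contrast family.

## Response-function estimation

The HRF/MRF basis is a difference of unit-scale gamma densities,
h(t) = g(t; a=δ_r) − g(t; a=δ_u)/r, peak-normalised; with unit scale the
shape parameter plays the role of the delay (adult canonical 6/16/6).
The exhaustive search covers δ_r ∈ 5–15, δ_u ∈ 5–20, r ∈ 2–6 in 1 s
steps (880 combinations).  Each candidate regressor (event boxcar ⊛
kernel) is z-scored before the OLS fit of the grand average, so β is
proportional to the correlation and "highest significant β" coincides
with best fit; without a common scale the β ordering would depend on
kernel norms.  Significance uses p < 0.05 (uncorrected); ties break
lexicographically on (δ_r, δ_u, r).  When no fit is significant the
argmax-β combination is returned flagged non-significant.

Identifiability: at grid points with δ_r = δ_u the two lobes merge and
the kernel is independent of r; the search then returns the smallest
ratio by the tie rule.  Self-consistency recovery (noise-free grand
averages generated from a grid point) is exact everywhere else, verified
over a thinned sub-grid and, for the reported infant parameter triples,
in the acceptance checks.  Recovered parameters are reported as absolute
values plus signed offsets from the adult canonical; no direction is
hard-coded.

Carryover caveat: with 8 s baselines the undershoot of the previous
trial's response leaks into the next epoch's baseline.  On pipeline
grand averages (as opposed to noise-free single-event traces) the grid
fit can absorb that pre-onset dip into an early-undershoot kernel
(δ_u < δ_r), and a distorted kernel can flip the sign of downstream
coupling β while leaving detection and FDR control intact — the
planted-coupling tests assert significance and error control, not β
sign.  HHb responses are negative-going; the pipeline fits the inverted
HHb grand average so that β remains positive for a well-formed response.

## Coupling GLM

Channels analysed are the sorted union of the per-condition,
per-chromophore channel sets showing haemodynamic–metabolic coupling
(default lists give {11, 12, 13, 14, 16, 18}); the set is held identical
across chromophores and conditions.  The neural regressor is the double
convolution written into the analysis: predicted = events ⊛ kernel on a
1 s working grid, then regressor = predicted ⊛ RMS-power block
(stimulus-period, 8 samples at 1 s), causal and onset-anchored,
truncated to the 8 s stimulus window, linearly interpolated onto the
bNIRS grid (1.4 s default) and z-scored so β is comparable across cells.
A conventional alternative (RMS ⊛ kernel first) is not the default but
can be composed from the exposed primitives.  Each subject's social and
non-social block-averaged stimulus windows enter one OLS fit with an
intercept and one regressor per condition (zero outside its own span),
yielding per-condition β from a single design.  Group inference is a
one-sample t against 0 per cell and a paired social−non-social contrast,
each BH-FDR corrected across the six bNIRS channels within every
(chromophore, EEG channel, band, condition) family — EEG channels are
deliberately not corrected over.  Zero-variance cells are reported with
NaN t and an "undefined-t" note (identically-zero samples give the
conventional t = 0).

## Synthetic-data generator

The generator emulates the study design: an opening ≥10 s rest, then
alternating 8 s baselines (1–3 s static images summing to 8 s) and
social/non-social blocks of 8–12 s.  Chromophore ground truth is
amplitude × (boxcar ⊛ kernel) per channel and condition, with default
peak amplitudes 1.0 μM HbO₂, −0.4 μM HHb, 0.15 μM oxCCO (functional
haemoglobin changes of order 1 μM; oxCCO an order of magnitude smaller)
and the infant kernels (8/7/2 for haemoglobin, 9/7/3 for oxCCO) as
generating bases.  Attenuation follows the forward Beer–Lambert model
plus i.i.d. Gaussian noise (default 0.002 OD) and optional spikes;
synthetic per-channel intensity counts (default uniform 5000–35,000)
feed the QC stage.  EEG is pink-noise background (20 μV RMS) plus
band-limited carriers (8 μV RMS) whose amplitude during a condition's
blocks is scaled by per-(channel, band, condition) gains, with optional
>200 μV bursts and a Bernoulli inattention mask.  All randomness derives
from explicit seeds; identical seeds give bit-identical datasets.

What the generator does not emulate: systemic physiology (heartbeat,
respiration, Mayer waves), spatially correlated optode noise, real
extinction spectra, volume conduction or oscillatory phase structure in
EEG, and real attention behaviour.  Passing tests therefore demonstrate
the correctness of the algorithms and the statistical guarantees under
the modelled conditions, not performance on infant recordings.

## Problem sizes used in the test and acceptance runs

The default synthetic cohort is 14 subjects × 6 trials.  The end-to-end
planted-coupling test runs the complete pipeline on two cohorts of 10
subjects (a deliberate scaled-down choice; power at the planted cell is
ample), asserting FDR-corrected detection of the planted cell and a
per-family false-discovery proportion within the BH guarantee; the
100-replicate FDR-control property is exercised at the group-statistics
stage, where the error control is implemented, on simulated 14-subject
β tables.  Grid-search self-consistency uses noise-free grand averages
on a 45 s, 1 s grid.

## Known limitations

- The 0.4 Hz band edge cannot be honoured at the 1.4 s sampling period;
  clamping is announced but changes the effective pass band.
- Wavelet correction leaves a smooth residual of large spikes in the
  approximation band (see above).
- Carryover at short inter-stimulus intervals biases kernel estimation
  on real-schedule grand averages; interpret recovered undershoot timing
  and coupling β signs accordingly.
- Counts-based QC uses per-channel mean counts; no averaging window is
  modelled.
- The haemodynamic–metabolic coupling statistic that defines the channel
  lists is consumed as input, not re-derived.
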