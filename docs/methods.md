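# Methods

## Scope and model

`cardiokymo` analyzes confocal line-scan recordings of isolated, field-
stimulated cardiomyocytes.  A kymograph is a 2D image whose rows are
repeated acquisitions of a single scan line placed along the cell's long
axis (rows = time, columns = space); because the scan line is longer than
the cell, contraction appears as a symmetric narrowing of the bright
intracellular band, and the Fluo-4 signal inside the band carries the
intracellular Ca²⁺ transient.  From each record the package measures, per
twitch and averaged over the third and fourth stimuli (quasi-steady
state):

* **cell shortening** — diastolic length minus the minimum length in the
  beat window, in µm and as % of diastolic length;
* **maximal shortening velocity** — peak of −dL/dt during contraction;
* **TTPS** — time from contraction onset to peak shortening;
* **TTHR** — time from peak shortening to 50% length recovery;
* **Ca²⁺ transient amplitude** — the maximal F/F₀ (the peak ratio itself,
  not the peak-minus-baseline excursion);
* **time to peak** and **raise rate** — amplitude / time-to-peak (s⁻¹);
* **T50** — time for the transient to decay by half of its
  peak-minus-baseline excursion.

No suitable public dataset exists for this acquisition mode, so the
package ships a first-class synthetic-data generator that emulates the
study system (control vs doxorubicin-treated mouse ventricular myocytes,
paced at 0.5/1/3 Hz with 0/10/20/30% Gaussian stimulus noise), and the
test suite requires the full image pipeline to recover the generator's
calibrated group effects.

## Stimulus model

A stimulation run is a train of `n_pulses` rectangular pulses (defaults:
4 pulses, 20 V/cm, 5 ms) at the pacing frequency, sampled at 10 kHz
(≥ 50 samples per pulse), with a noise-free tail.  "x% stimulus noise"
is zero-mean Gaussian white noise with σ = x% of the pulse amplitude
(an RMS convention; the percentage could also have denoted a peak or
peak-to-peak measure, but σ is the standard parameterization of Gaussian
white noise).  Noise is added on the closed window from the first pulse
onset to the last pulse offset — riding on top of the pulses as well as
between them — is white at the waveform sampling rate (no band-limiting
filter), and is not clipped; amplifier saturation is not modeled.  Pulses
are aligned to the nearest waveform sample so onset sample indices are
exactly `round(i·fs/f)`.

## Twitch kernel and cell model

The generator's twitch time course is a peak-normalized
double-exponential,

    k(t) = N · (1 − e^(−t/τ_c)) · e^(−t/τ_r),  t ≥ 0,
    peak time = τ_c · ln(1 + τ_r/τ_c),  N chosen so max k = 1,

used for both the mechanical twitch (defaults τ_c = 20 ms, τ_r = 120 ms)
and the Ca²⁺ transient (τ_rise = 10 ms, τ_decay = 80 ms — faster, so Ca²⁺
leads shortening as in real myocytes).  Per record,

    L(t)    = L₀ · (1 − f_s · Σᵢ k(t − onsetᵢ)),
    F/F₀(t) = 1 + Δ · Σᵢ k_Ca(t − onsetᵢ),

with resting length L₀ = 120 µm, shortening fraction f_s = 0.08 and peak
excess Δ = 1.0 by default.  These absolute values are plausible mouse
ventricular numbers chosen once as generator defaults; only *relative*
group effects are calibrated (see below), so all recovery targets are
ratios that do not depend on them.

Rendering: each scan line samples L and F/F₀ at the line time; pixels in
[center − L/2, center + L/2] have expected intensity
`baseline · F/F₀(t)` (baseline 150 counts), outside `background`
(10 counts); edge pixels receive their geometric coverage fraction (both
edges move symmetrically inward).  Poisson shot noise is applied to the
expected image, then Gaussian read noise (σ = 2 counts), then uint16
quantization.  Records start 0.5 s before the first pulse (for F₀ and
diastolic baselines) and end 0.5 s after the last, at 2 ms/line and
0.2 µm/pixel on a 768-pixel (153.6 µm) scan line — e.g. 1750 lines at
1 Hz, 3500 at 0.5 Hz.  Optics PSF, sarcomeric striation texture,
t-tubules and spontaneous Ca²⁺ sparks/waves are not modeled.

## Group presets and endpoint gains

A `GroupPreset` carries multiplicative per-endpoint factors: a `baseline`
relative to the control group at 0% noise, and a `(frequency, noise) →
gain` table for the noise-induced response.  Calibration (all entries are
the study's printed percent effects):

| endpoint            | DOX baseline | CTRL gain @10% noise | DOX gain @20% noise |
|---------------------|-------------:|---------------------:|--------------------:|
| shortening          | 0.83         | 1.20 @0.5 Hz, 1.16 @1 Hz | 1/0.83 (rescue) |
| max velocity        | 0.88         | 1.17 @0.5 Hz         | 1.0 (no response)   |
| Ca²⁺ amplitude      | 0.85         | 1.0                  | 1/0.85 (rescue)     |
| raise rate          | 0.85         | 1.0                  | 1/0.85 (rescue)     |

Entries without a printed value default to 1.0, with one deliberate
exception: where a shortening gain is printed but the velocity gain is
not (CTRL at 1 Hz), the velocity gain tracks the shortening gain so that
twitch timing is noise-invariant, consistent with the reported
insensitivity of TTPS/TTHR to stimulus noise.  Control Ca²⁺ responses to
noise are reported qualitatively only (no percentage), so their gains
stay at 1.0.  The DOX 20%-noise entries are set so the group returns
exactly to the control zero-noise baseline (the "rescue"), except max
velocity, which is reported as not responding.

How a gain is realized matters for what the pipeline measures:

* **shortening** scales f_s directly (the measured shortening is linear
  in it);
* **amplitude** acts on the *measured* endpoint, the peak F/F₀: the
  generative excess becomes Δ′ = g·(1 + Δ) − 1.  A multiplier applied to
  Δ instead would dilute through the +1 baseline (a 0.85 multiplier on Δ
  changes peak F/F₀ by only ~7.5% at Δ = 1) and the pipeline could never
  report the intended percent effect;
* **velocity** and **raise rate** gains that differ from their amplitude
  counterparts are realized by uniform time-scaling of the corresponding
  kernel (both taus × g_amplitude/g_rate), which changes the kinetic
  endpoint exactly while leaving the peak untouched.  Side effect: the
  DOX mechanical kernel is ~6% faster (0.83/0.88), a timing shift well
  inside the reported SEMs for TTPS/TTHR.

Whether the noise response of a real cell is a deterministic gain or a
threshold/recruitment phenomenon cannot be decided from group-mean data;
the generator uses a deterministic gain, which is sufficient for
pipeline validation but should not be read as a mechanistic claim.

## Population structure and yoking

Per-cell truths are lognormal around the preset means (between-cell CV
0.15 on the endpoint-bearing parameters, CV 0.10 on kinetics, CV 0.05 on
resting length and baseline intensity), with a multiplicative per-animal
random effect (lognormal, mean 1, CV 0.05).  Defaults: 6 control and 8
treated animals × 40 cells, matching the study design.

The latent draws are keyed only by `(base_seed, animal index, cell
index)` — not by group, frequency or noise level — so populations
generated from the same base seed are **yoked**: the same underlying
cells are re-stimulated under each condition, and different groups share
their latent pool.  Group contrasts therefore reflect the preset
multipliers rather than finite-sample noise (with unpaired 6-vs-8-animal
draws at these CVs, the sampling error of a group-mean ratio is ≈3%,
which would swamp a 3-point recovery check), while within-group
variability — and hence every SEM and statistical test — remains
realistic.  Yoking mirrors the study's own normalization-to-control
strategy and is standard variance-reduction practice in simulation
benchmarks.

## Image analysis

* **Binarization**: one global threshold per image (Otsu by default;
  fixed or range-fraction alternatives; a polarity flag for inverted
  contrast), with connected components under 64 px removed.
* **Edges**: per line, the cell spans the largest run of intracellular
  pixels after a morphological closing that bridges gaps ≤ 2 px (dark
  bands and single-pixel holes must not shrink the length).  The two
  boundary pixels are refined to sub-pixel positions by coverage-fraction
  interpolation against per-line interior and background intensity
  levels; the integer outermost-pixel rule is available as
  `subpixel=False`.  Sub-pixel edges matter quantitatively: at 0.2 µm
  pixels the quantized length staircase maps to crossing-time errors of
  ~3 line periods at the relaxation slope, which would dominate TTHR.  A
  3-line running median suppresses single-line dropouts.
* **Event conventions**: the trace is optionally Savitzky–Golay smoothed
  (local quadratic, 7-line window — raw pixel-quantized lengths make
  dL/dt noisy); the beat window is [onsetᵢ, onsetᵢ₊₁); the diastolic
  baseline is the mean over 50 ms before the stimulus; contraction onset
  is the 10%-amplitude crossing (a stimulus-time option exists);
  threshold crossings are refined by linear interpolation and strict
  extrema by a guarded parabolic fit (plateaus and square edges keep the
  sample value, so discontinuous test signals are not over-refined).
  Beats with amplitude below 0.5 µm (or, for transients, below 3× the
  baseline sd) are rejected with a warning; a record with no usable beat
  raises a no-response/no-transient error.
* **F/F₀**: per-line mean intensity over the binarization mask eroded by
  2 px per side (partial edge pixels would dilute the mean), divided by
  F₀ = the pre-first-stimulus mean (20 ms guard).  F₀ is global; the
  50%-decay reference uses the per-beat diastolic baseline.

Ground truth returned with each synthetic record applies the same
parameter definitions to the closed-form noiseless traces on a dense
0.1 ms grid, so analyzer-vs-truth comparisons test the imaging and
extraction chain, not a change of definition.  The dense-grid truth is
itself checked against an independently coded brute-force computation;
all fields agree to 1e−6 except max velocity, which is grid-limited at
the kernel's onset kink (O(dt) convergence) and is checked at 1e−3.

Known estimator bias: the smoothed derivative attenuates the velocity
peak at the onset kink by ~10–15% (window-dependent).  The attenuation is
common to all conditions and cancels to within ~1–2 points in the
between-condition ratios that constitute every calibrated target; the
noiseless oracle test therefore disables smoothing.

## Auxiliary assays

* **Cell volume**: suprathreshold voxel count × pixel area × z-step on a
  calcein z-stack (Otsu or fixed threshold).  The generator produces
  ellipsoidal cells (5 : 1.4 : 1 axis ratio) whose true volume is the
  interior voxel count, exact up to one voxel shell.  Presets: control
  20 000 µm³, treated × 0.70.
* **Fibrotic index**: %blue/%red of a pre-classified label image
  (0 = unclassified, 1 = red, 2 = blue).  Color deconvolution of real
  trichrome stains is out of scope — no classification rule is specified
  for it — so the module takes label images and the generator draws
  i.i.d. labels.
* **Cross-sectional area**: pixel count × pixel area of an elliptical
  mask; presets 280 µm² control, × 0.80 treated.
* **2^−ΔΔCt**: the standard fold-change; the generator's BNP/HPRT tables
  use ΔΔCt = −1 for the treated group (two-fold up-regulation).  qPCR
  efficiency correction is out of scope.
* **Respirometry**: each state flux is the mean over [event + settle,
  next event) with a 60 s default settle time (the estimator and settle
  time are conventions of this package; configurable).  RCR =
  state3/state4; the state4/state3 and uncoupled/state4 conventions are
  both reported, since both appear in practice, and neither is silently
  preferred.  Cox activity = TMPD/ascorbate flux − KCN-resistant flux.
  Citrate-synthase normalization divides all fluxes (leaving ratios
  unchanged); non-mitochondrial subtraction is off by default and
  affects only the ratios when enabled.  Treated presets: state-3 and
  uncoupled rates × 0.5, lower Cox and citrate-synthase activity.

## Statistics

The experimental unit is the animal: cells are averaged per animal and
condition (cells with analysis errors are excluded and counted), group
summaries are mean ± SEM over animal means, and normalization divides
animal means by a control reference mean — either the control at the
same frequency ("per-frequency") or the control at the same frequency
with 0% noise ("zero-noise").  Between-group tests: Student's t (pooled
variance) by default, Welch and Mann–Whitney U available (U exact when
min(n) ≤ 8 without ties, tie-corrected normal approximation otherwise);
one-way and two-way fixed-effects ANOVA with Tukey HSD post-hoc; α =
0.05; no further multiplicity correction.  A per-cell analysis mode
exists but is non-default — figure-legend n's refer to animals, so SEMs
are taken over animals.

## Problem sizes and numerical choices

Recovery runs use the full study design (240 control / 320 treated cells
per condition at ~1750–3500 lines × 768 px per record); the morphometry
runs use 40 stacks and 100 masks per group.  The whole suite targets a
single CPU: one record simulates and analyzes in ~0.2–0.4 s, populations
stream one cell at a time (bounded memory), and the renderer works in
float32.  Degenerate inputs fail loudly and early: constant images,
empty scan lines (with the line index), empty baselines, missing
titration events, zero-variance samples in t/F tests.  Ties in the
largest-run selection break to the rightmost run; RNG streams derive
from `numpy` SeedSequences keyed by (seed, animal, cell), so every
output is bit-reproducible under a fixed seed at every level.

## Limitations

Synthetic validation shows the pipeline recovers known effects under the
stated noise model; it cannot certify performance on real images with
focus drift, photobleaching, motion artifacts along z, or arrhythmic
beats — none of which are modeled.  The calibrated gains reproduce
group-mean effects only; distributional claims (e.g. cell-level
responder fractions) are outside what the generator encodes.  The
double-exponential kernel is a convenience with the right number of
degrees of freedom for the measured kinetics, not a biophysical model of
cross-bridge or SERCA dynamics.
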