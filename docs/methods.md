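# Methods

## Signal model

At 570 nm, reflectance is (to first order) inversely related to total
hemoglobin, so an evoked CBV increase appears as an intensity decrease.
The renderer composes each frame as

```
I_t(x) = B(x, s_t) · (1 − a(x)/100 · k_t) · (1 + o_t) + ε_t(x)
```

where `B(x, s_t)` is the resting scene — parenchyma at 4000 counts,
vessels 40 % darker, rasterized from centerline segments whose widths are
scaled by the dilation profile `s_t` and then blurred by a 1-px Gaussian
point-spread function; `a(x)` is the injected peak amplitude map (% of
baseline), `k_t` the temporal kernel, `o_t` global sinusoidal
physiological oscillations (defaults: 1 Hz at 0.2 % "respiration", 4 Hz at
0.1 % "cardiac alias"), and `ε` white Gaussian noise (default SD 0.2 % of
baseline). The analysis layer flips the sign so reported ΔCBV is positive.

**Temporal kernel.** A gamma variate
`k(τ) ∝ (τ/t_p)^α · exp(α(1 − τ/t_p))` with shape `α = 3`, zero before
stimulation onset and discretely normalized so its maximum frame weight is
exactly 1 (so the injected peak amplitude is attained on the frame grid).
`t_p` is the injected time-to-peak measured from stimulus onset. The
falling phase (~5 s decay) is a free simulator parameter; the data the
model emulates constrain the rise, not the recovery.

**Vessel geometry.** Trunk arteries are 0.24 mm wide (6 px at the default
0.04 mm/px), children thin by ~25 % per branch; one trunk is always routed
through the response center so the footprint contains artery. Veins are
rendered 1.6× wider and never dilate. Each pixel stores its distance to
the nearest segment divided by that segment's rest half-width, so
rasterizing at any width scale `s` is the comparison `dist_norm ≤ s`; this
makes per-frame dilation exact and gives the tests a closed-form
rasterization oracle. Artery segments are split at the footprint circle,
and exactly the inside pieces dilate by `1 + d/100 · k_t`.

**Amplitude map.** Gaussian, σ = half the footprint radius (default
footprint 1.0 mm), peak equal to the injected amplitude.

**Cohorts.** Per-animal amplitude, time-to-peak and dilation are drawn
from normal distributions centred on the group means with between-animal
SDs recovered from printed group SEMs via `SD = SEM·√n` (amplitude:
0.34·√10 control / 0.32·√10 stress; time-to-peak: 0.25·√10 / 0.59·√10;
dilation: 2.38·√6 / 1.02·√5). The dilation SDs are large relative to their
means, so draws are truncated at zero (and time-to-peak clipped to
[0.5 s, stimulus + 5 s]); this biases the smallest means slightly upward,
which the sampler tests account for.

## Analysis choices

- **Low-pass filter**: 4th-order Butterworth, zero-phase (`filtfilt`),
  default cutoff **0.5 Hz**. The evoked response (rise over ~4 s) lives
  below ~0.3 Hz and passes with |H|² > 0.999; the 1 Hz respiratory
  component is attenuated by >20 dB. A 1 Hz cutoff would pass respiration
  at half amplitude and visibly perturb time-to-peak at small response
  amplitudes. The cutoff is a parameter everywhere.
- **ROI objective**: the 7×7 window maximizing the window mean of the
  per-pixel temporal maximum of ΔCBV during the stimulus-to-end epoch;
  ties go to the smallest (row, col). This matches "max ΔCBV" reporting
  and is checked against exhaustive search.
- **Time references**: time-to-peak and onset are measured from stimulus
  onset. The 3-frame moving average uses centered windows, truncated at
  the edges; trace bins are non-overlapping 3-frame means (0.3 s at
  10 Hz) reported at bin centers, the final partial bin averaged over its
  actual length.
- **SD map**: computed on the trial-averaged, low-pass-filtered movie over
  all frames, divisor N, then smoothed with a normalized 3×3 Gaussian
  (σ = 0.8 px, reflect padding; the discrete kernel carries >95 % of the
  continuous mass). The responsive threshold mean + 2 SD uses the
  population SD of the map, consistent with the divisor-N convention.
  Thresholding the probability map then intersecting is boolean-equivalent
  to multiplying the map into the mask and thresholding.
- **Segmentation**: the classifier sees the temporal mean of the baseline
  frames (highest SNR, no stimulus contamination). Training scribbles are
  either user-supplied label images or sampled from ground truth one pixel
  off the mask boundary. A vessel/tissue Michelson-contrast metric is
  reported for quality gating instead of silently dropping low-contrast
  recordings. The exact feature set of interactive tools varies; the
  17-feature family here (blur/edge/ridge at four scales) covers the same
  families and is swappable.
- **Dilation counting**: pixels darker than Otsu's threshold (computed on
  the baseline-mean image inside the neighborhood) count as vessel, within
  a 3-px morphological dilation of the selected artery region; other
  vessels plus a 1-px rim are excluded from the neighborhood so their
  blurred edges cannot leak into the count. In the full pipeline the
  exclusion keeps vessel components connected to the responsive artery
  (the SD map tends to select the dilating *edges*, leaving the artery
  interior "non-responsive"; excluding it would shrink the denominator and
  roughly double the reported percent change). The onset threshold uses a
  floor of 1e-6 trace units on the baseline SD so noiseless traces still
  define an onset.
- **Statistics**: Mann–Whitney is exact for tie-free samples with n ≤ 8
  per group, tie-corrected asymptotic otherwise; the t test defaults to
  Welch (the variant is recorded). Frame-wise trace tests are unadjusted by
  default — matching the shaded-frames convention — with an optional
  Benjamini–Hochberg flag. Fisher-LSD p values use the pooled MSE with
  N − k degrees of freedom.

## What the generator does and does not emulate

It reproduces the acquisition protocol (trial structure, frame rate,
stimulus timing), the reflectance sign convention, vessel/tissue contrast,
stimulus-locked dilation confined to a footprint, trial-to-trial noise and
global oscillations, and between-animal effect-size spread. It does not
model photon transport or wavelength-dependent absorption, oxy/deoxy
separation, motion or pulsation artifacts beyond global sinusoids, vessel
wall profiles (vessels are hard-edged rasters under a fixed 1-px PSF), or
spatially varying illumination. Passing recovery tests therefore
demonstrates the correctness and calibration of the analysis chain on data
obeying the stated model — not robustness to every artifact of real
recordings.

## Problem sizes and numerical tolerances

Benchmarks choose field sizes to keep desk-scale runtimes while preserving
the protocol (always 200 frames, 10 Hz, 8 trials unless noted):
amplitude/timing recovery at 128×128 (20 seeded runs per amplitude);
dilation sweeps noiseless at 256×256 and a single trial, where a 2 % width
change moves O(100) pixels so count quantization sits well below the 25 %
comparison tolerance; replicate cohorts at 48×48 with dilation off (100
cohorts of 2×10 animals render in minutes). At 48–64 px the 7×7 ROI spans
a larger fraction of the response footprint, diluting the measured group
mean by ~5–8 % relative to the injected amplitude; this affects the
descriptive group means, not the power or type-I calibration, which
compare groups measured identically. CBV-recovery scenarios set dilation
to zero: under the hard-edged vessel model a dilating edge pixel swings by
the full vessel contrast, and a 7×7 ROI catching such edges would report
the dilation artifact rather than the parenchymal amplitude.

Degenerate inputs are contracts, not silent NaNs: non-positive baselines
name the offending pixel, empty regions and single-class label masks
raise, constant images standardize to zero features, and a flat trace
reports zero change at onset with no onset/slope rather than erroring.
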