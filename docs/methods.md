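# Methods

## Model and assumptions

The aligner estimates a single rigid translation, in ppm, between two
processed real-valued frequency-domain spectra. The model is therefore:
the two spectra show (mostly) the same resonances, mis-referenced by a
global per-axis offset; lineshapes, relative intensities and peak sets
may differ, but no warping (field-dependent or temperature-dependent
per-region shifts) is corrected. Registration is circular: the FFT
cross-correlation wraps content across the spectrum edges. No apodization
window is applied; instead the peak search is restricted to a fraction of
the axis extent (`max_shift_frac`, default 0.25), which excludes
wrap-around false maxima for realistic referencing errors.

## Coordinate conventions

* Internal rasters index from the minimum-ppm edge: index increases with
  ppm on every axis; the NMRPipe reader/writer flips axes accordingly.
* The chemical shift is affine in the 1-based pixel index with slope
  `SS = (sw/obs)/n` and `center_ppm = origin_ppm + ((n+1)/2)·SS`. Only
  relative offsets matter downstream, so this center identity is the one
  normative statement; no per-pixel edge convention is otherwise assumed.
* Reported `shift_ppm` is the offset of the moving spectrum relative to
  the reference (positive = moving spectrum at higher ppm). Subtracting
  it from the moving spectrum's referencing (`apply_shift`) aligns the
  pair. The center-referenced origin difference enters the total as
  `O₂(center) − O₁(center)`, consistent with that sign choice.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `filter.fwhm` | 0.2355 | FWHM of the Gaussian subtracted from 1 to form the high-pass, in normalized spatial frequency (cycles/pixel, Nyquist = 0.5); 0.2355 ⇔ σ = 0.1 |
| `filter.enabled` | true | disable to correlate unfiltered spectra |
| `max_shift_frac` | 0.25 | search window half-width as a fraction of each axis extent |
| `subpixel` | true | 3-point parabola refinement per axis |
| `score_surface` | conditioned | surface on which before/after scores are computed (`raw` available) |
| projection `mode` | max | maximum-value projection preserves peak SNR; `sum` provided for comparison |

The FWHM unit is a design choice: the scalar 0.2355 is dimensionless and
equals 2.3548 × 0.1, so it is read as σ = 0.1 in normalized frequency —
the convention of cross-correlation image alignment — and exposed as a
knob so other readings can be tested. The "inverse Gaussian" is the
complement `1 − G` (a true high-pass), not the reciprocal, which would
diverge at high frequency and amplify noise. The filter is isotropic in
normalized per-axis units; anisotropy in physical units is handled
upstream by resampling. Standardization uses the population variance
(divisor N); only relative scores matter downstream.

## Numerical choices

* **Eq. rounding** — the resampled size `n₂·SS₂/SS₁` is rounded half-up;
  the span error is then at most half a target pixel.
* **Fourier resize Nyquist handling** — cropping to an even size folds
  the two symmetric source bins into the output Nyquist bin; padding from
  an even size splits the Nyquist energy evenly. This keeps real data
  real and makes up/down round trips exact for band-limited input. The
  mean (DC) is preserved exactly.
* **Sub-pixel translation** — Fourier phase ramps, consistent with the
  interpolation philosophy of the resampler and exactly invertible for
  band-limited content. Real output is enforced by taking the real part,
  which acts as a cosine ramp on the Nyquist bin: content at exactly the
  Nyquist frequency (e.g. the Nyquist band of white noise) is attenuated
  rather than translated. Synthetic peaks of ≥ 0.1 ppm linewidth at
  0.05 ppm/pixel are band-limited to well below Nyquist, so this affects
  noise, not signal.
* **Parabola refinement** — per axis independently through the peak and
  its two neighbors (circular wrap at map edges);
  `δ = (c₋₁ − c₊₁) / (2(c₋₁ − 2c₀ + c₊₁))`, clamped to ±0.5 px so the
  refined position stays within the winning pixel; zero curvature yields
  δ = 0 with a warning.
* **Tie-breaking** — equal CCF maxima resolve to the smallest Euclidean
  displacement, then lexicographic order: the most conservative
  correction, deterministically.
* **Degenerate inputs** — flat (zero-variance) spectra, sub-2-pixel
  resample targets, mismatched dimensionality and non-finite rasters
  raise explicit errors rather than propagating NaNs.

## Scores

`score_before` is the Pearson-type correlation of the two conditioned
(or raw) rasters overlaid *as referenced* — i.e. with only the header
origin difference compensated — and `score_after` the same quantity at
the estimated total shift, applied by phase ramp with both rasters
re-standardized. For pairs identical up to translation the post-score
reaches 1.00; for pairs with partially overlapping peak sets it saturates
at the shared-signal fraction of the total variance, which after
high-pass filtering can be far below 1 even when the shift estimate is
accurate. Scores are diagnostics of overlay quality, not of shift
accuracy.

## Synthetic data

The generator renders sparse sums of analytic Gaussian/Lorentzian line
shapes on a flat baseline with seeded white noise, emulating a
¹³C–¹³C-correlation-like region: 256×256 points at 0.05 ppm/pixel
(12.8 ppm span at 150.9 MHz), 20–60 peaks, linewidths 0.1–0.4 ppm,
amplitudes 0.3–1, noise quoted relative to the strongest peak (0.1 =
peak SNR 10). Offsets are applied to the analytic peak positions in ppm
space before rendering, so sub-pixel ground truths are exact and recovery
error is attributable entirely to the aligner. With shared noise the
single noise realization is circularly translated with the content,
making the two rasters identical up to translation (the controlled-offset
construction); with independent noise each spectrum gets its own
realization.

What the generator does **not** emulate: t₁-noise ridges, solvent or
spinning sidebands, baseline distortions, NUS reconstruction artifacts,
intensity changes between mixing schemes, or field-dependent peak-specific
shifts. Passing tests demonstrate accurate recovery of rigid offsets
under realistic sparsity, linewidth and noise, not robustness to every
real-world artifact.

## Validation conditions and problem sizes

The headline controlled-offset experiment uses the default fixture with
30 peaks, SNR 10, seed 42 and a 0.1 ppm offset in both axes; recovery is
required within ±0.01 ppm with post-score ≥ 0.999. The sub-pixel sweep
runs 200 seeded trials with offsets uniform in ±1 ppm under the same
construction. The mixed-peak robustness suite (60% shared peaks, 40%
extra, independent noise, 100 trials) uses noise at 1/50 of the strongest
peak: it emulates co-addition-quality spectra of the same sample under
different mixing conditions, which are high-SNR by selection. At SNR 10
that scenario becomes CCF-noise-limited in the sub-pixel stage — the
high-pass filter removes most of the energy of 0.2–0.4 ppm-wide peaks,
leaving a conditioned correlation of ~0.02 — and recovery degrades to
roughly ±0.03 ppm even though the integer-pixel peak remains correct.
Oracle equivalences (FFT vs. brute-force correlation, projection vs.
triple loop) run on 16–32 pixel grids where exhaustive enumeration is
exact and fast.

## Known limitations

* Pairwise only: multi-spectrum studies align each spectrum against a
  chosen reference; no joint refinement.
* No weighted or per-region correlation variants; a single global shift
  per axis.
* 3D volumes are aligned through 2D projections; the collapsed
  dimension's referencing is untouched.
* NMRPipe support covers single-file real frequency-domain data only;
  complex/interleaved layouts and multi-file plane series are rejected
  explicitly.
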