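# spectralign

Objective, whole-spectrum chemical-shift referencing alignment for
processed 2D/3D NMR spectra.

## The problem

Chemical-shift referencing drifts. Spectra of the same sample recorded
months apart, on different spectrometers, or with different calibration
settings can be rigidly offset from one another by anything from a few
hundredths to several ppm — enough to break peak matching, co-addition of
acquisition blocks, and cross-experiment assignment. The usual fix,
eyeballing a reference peak and nudging the origin, is subjective and
irreproducible.

`spectralign` treats a processed frequency-domain spectrum as an image
and registers a pair of spectra globally: every peak votes, no peak is
picked by hand, and the result is a deterministic per-axis offset in ppm
together with before/after correlation scores that quantify how well the
pair overlays.

## Method

For each axis the **spectral sampling** (ppm per pixel) is

    SS = (sw / obs) / n

with `sw` the spectral width (Hz), `obs` the observe frequency (MHz) and
`n` the point count. If the two spectra differ in sampling, the moving
spectrum is Fourier-interpolated onto the reference sampling
(`n_new = n₂ · SS₂ / SS₁`), then symmetrically cropped or zero-padded in
real space until the physical extents match, both operations preserving
the chemical shift at the grid center. Because the minimum-ppm origin `O`
moves under these operations, the residual header offset is bookkept at
the center:

    O_offset = (O₂ + (n+1)/2 · SS) − (O₁ + (n+1)/2 · SS)

Both rasters are then conditioned: high-pass filtered in Fourier space by
an inverse Gaussian `H(f) = 1 − exp(−|f|²/2σ²)` (FWHM 0.2355 in
cycles/pixel, i.e. σ = 0.1, suppressing baseline rolls and other
low-resolution structure), zero-floated to mean 0 and normalized to unit
variance. The circular cross-correlation function

    CCF = F⁻¹( F(I₁)* · F(I₂) )

is computed in one FFT pass; its peak, searched within ±25% of each axis
extent, gives the integer-pixel translation, and a three-point parabola
fit per axis refines it to sub-pixel precision. The reported offset is

    shift_ppm = shift_px · SS + O_offset

per axis, with the convention that a positive shift means the moving
spectrum resonates at higher ppm than the reference. 3D spectra are
collapsed to 2D by a maximum-value (default) or sum projection and then
treated exactly like measured planes.

On synthetic spectra with known ground truth the aligner recovers
sub-pixel offsets to ±0.01 ppm at 0.05 ppm/pixel sampling.

## Worked example

Generate a synthetic 256×256 ¹³C–¹³C-style spectrum (30 Gaussian peaks,
peak SNR 10) and a copy whose peak positions are shifted by exactly
0.1 ppm in both dimensions, then align them:

```sh
spectralign simulate demo --seed 42 --offset 0.1 --offset 0.1
spectralign align demo/reference.ft2 demo/moving.ft2
```

which prints (abridged):

```json
{
  "ccf_peak_px": [2, 2],
  "o_offset_ppm": [0.0, 0.0],
  "score_before": -0.0118,
  "score_after": 1.0,
  "shift_ppm": [0.10000000505592765, 0.10000000505592765],
  "shift_px": [2.0, 2.0]
}
```

The 0.1 ppm offset is 2.0 pixels at this sampling; the aligner reports it
to eight decimal places, and the normalized correlation rises from −0.01
(peaks essentially uncorrelated at this linewidth) to 1.00 after the
correction. `spectralign apply demo/moving.ft2 fixed.ft2 --shift 0.1
--shift 0.1` writes the corrected spectrum; re-aligning it against the
reference reports a residual of ~0 ppm.

Other subcommands: `project` (3D→2D max/sum projection), `info` (header
dump), and YAML config via `align --config`; run any of them with
`--help`.

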