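"""Cross-correlation registration: FFT/brute-force equivalence, peak
search, sub-pixel refinement, ppm conversion, scores, and the full chain."""

import numpy as np
import pytest

from spectralign import (
    AlignmentConfig,
    SpectrumGrid,
    align,
    apply_shift,
    correlation_score,
    cross_correlation,
    find_peak,
    fourier_translate,
    make_offset_pair,
    pixels_to_ppm,
    preprocess,
    random_spec,
    render,
    subpixel_refine,
)

from conftest import make_axis


def _conditioned(data):
    axes = [make_axis(n=n, sw=100.0 * n) for n in data.shape]
    return preprocess(SpectrumGrid(np.asarray(data, float), axes))


def brute_force_ccf(a, b):
    """Independent spatial-domain oracle: C[d] = sum_x a(x) * b(x+d),
    arranged like the FFT map (zero displacement at n//2)."""
    shape = a.shape
    out = np.empty(shape)
    for idx in np.ndindex(*shape):
        d = tuple(i - n // 2 for i, n in zip(idx, shape))
        out[idx] = np.sum(a * np.roll(b, tuple(-di for di in d), axis=range(a.ndim)))
    return out


class TestCrossCorrelation:
    def test_autocorrelation_peaks_at_zero_with_value_n(self, rng):
        g = _conditioned(rng.normal(size=(16, 16)))
        ccf = cross_correlation(g, g)
        zero = (8, 8)
        assert np.unravel_index(np.argmax(ccf.data), ccf.shape) == zero
        assert ccf.data[zero] == pytest.approx(g.data.size, rel=1e-9)

    @pytest.mark.parametrize("shift", [(3, -2), (0, 5), (-7, -1)])
    def test_shift_theorem(self, rng, shift):
        g = _conditioned(rng.normal(size=(16, 16)))
        rolled = SpectrumGrid(np.roll(g.data, shift, axis=(0, 1)), g.axes)
        ccf = cross_correlation(g, rolled)
        peak = np.unravel_index(np.argmax(ccf.data), ccf.shape)
        assert tuple(p - 8 for p in peak) == shift

    @pytest.mark.parametrize("n", [16, 32])
    def test_equals_brute_force_oracle(self, rng, n):
        a = _conditioned(rng.normal(size=(n, n)))
        b = _conditioned(rng.normal(size=(n, n)))
        fft_map = cross_correlation(a, b).data
        oracle = brute_force_ccf(a.data, b.data)
        np.testing.assert_allclose(
            fft_map, oracle, rtol=1e-9, atol=1e-9 * np.abs(oracle).max()
        )

    def test_shape_mismatch_rejected(self, rng):
        a = _conditioned(rng.normal(size=(8, 8)))
        b = _conditioned(rng.normal(size=(8, 10)))
        with pytest.raises(ValueError):
            cross_correlation(a, b)


def _ccf_map(data):
    axes = [make_axis(n=n, sw=100.0 * n) for n in data.shape]
    return SpectrumGrid(np.asarray(data, float), axes)


class TestFindPeak:
    def test_unique_maximum(self):
        data = np.zeros((16, 16))
        data[10, 6] = 5.0  # displacement (2, -2)
        peak, warnings = find_peak(_ccf_map(data))
        assert peak == (2, -2)
        assert warnings == []

    def test_tie_broken_by_smallest_displacement(self):
        data = np.zeros((32, 32))
        data[16 + 2, 16] = 1.0
        data[16 + 5, 16] = 1.0
        peak, _ = find_peak(_ccf_map(data))
        assert peak == (2, 0)

    def test_tie_norm_then_lexicographic(self):
        data = np.zeros((32, 32))
        data[16 + 3, 16] = 1.0
        data[16 - 3, 16] = 1.0
        peak, _ = find_peak(_ccf_map(data))
        assert peak == (-3, 0)

    def test_out_of_window_maximum_warned_and_ignored(self, caplog):
        data = np.zeros((32, 32))
        data[16 + 2, 16 + 1] = 1.0  # lesser max inside window
        data[1, 1] = 9.0  # global max at displacement (-15, -15)
        peak, warnings = find_peak(_ccf_map(data), AlignmentConfig(max_shift_frac=0.25))
        assert peak == (2, 1)
        assert len(warnings) == 1 and "outside" in warnings[0]


class TestSubpixel:
    def test_symmetric_neighbors_give_zero_delta(self):
        data = np.zeros((16, 16))
        data[8, 8] = 2.0
        data[7, 8] = data[9, 8] = 1.0
        data[8, 7] = data[8, 9] = 1.0
        refined, _ = subpixel_refine(_ccf_map(data), (0, 0))
        assert refined == (0.0, 0.0)

    @pytest.mark.parametrize("vertex", [0.3, -0.45, 0.12])
    def test_exact_parabola_vertex_recovered(self, vertex):
        data = np.zeros((16, 16))
        for k in (-1, 0, 1):
            val = 10.0 - (k - vertex) ** 2
            data[8 + k, 8] = val
        data[8, 7] = data[8, 9] = data[8, 8] - 1.0  # symmetric on other axis
        refined, _ = subpixel_refine(_ccf_map(data), (0, 0))
        assert refined[0] == pytest.approx(vertex, abs=1e-12)
        assert refined[1] == 0.0

    def test_zero_curvature_flagged(self):
        data = np.zeros((8, 8))
        data[4, 4] = data[3, 4] = data[5, 4] = 1.0
        data[4, 3] = data[4, 5] = 0.5
        refined, warnings = subpixel_refine(_ccf_map(data), (0, 0))
        assert refined[0] == 0.0
        assert any("curvature" in w for w in warnings)

    def test_phase_ramp_shift_recovered(self, rng):
        """A 0.37-pixel Fourier translation of a smooth spectrum is
        recovered to better than 0.05 px."""
        g = render(random_spec(n_peaks=12, seed=5, noise_sigma=0.0,
                               axes=(make_axis(n=64, sw=320.0, obs=100.0),) * 2))
        moved = SpectrumGrid(fourier_translate(g.data, (0.37, 0.0)), g.axes)
        c1, c2 = preprocess(g), preprocess(moved)
        ccf = cross_correlation(c1, c2)
        peak, _ = find_peak(ccf)
        refined, _ = subpixel_refine(ccf, peak)
        assert refined[0] == pytest.approx(0.37, abs=0.05)
        assert refined[1] == pytest.approx(0.0, abs=0.05)


class TestPixelsToPpm:
    def test_zero(self):
        assert pixels_to_ppm((0.0, 0.0), (0.01, 0.01), (0.0, 0.0)) == (0.0, 0.0)

    def test_forced_by_formula(self):
        assert pixels_to_ppm((10.0,), (0.01,), (0.0,)) == (0.1,)

    def test_header_only_offset(self):
        """Identical rasters whose origins differ by 0.5 ppm: the whole
        shift comes from the header arithmetic."""
        spec = random_spec(n_peaks=8, seed=2, noise_sigma=0.0)
        s1 = render(spec)
        shifted_axes = [ax.with_(origin_ppm=ax.origin_ppm + 0.5) for ax in s1.axes]
        s2 = SpectrumGrid(s1.data.copy(), shifted_axes)
        est = align(s1, s2)
        assert est.shift_px == pytest.approx((0.0, 0.0), abs=1e-6)
        assert est.shift_ppm == pytest.approx((0.5, 0.5), abs=1e-6)


class TestCorrelationScore:
    def test_self_correlation_is_one(self, rng):
        g = _conditioned(rng.normal(size=(16, 16)))
        assert correlation_score(g, g, (0.0, 0.0)) == pytest.approx(1.0, abs=1e-9)

    def test_exact_realignment_scores_one(self, rng):
        g = _conditioned(rng.normal(size=(16, 16)))
        rolled = SpectrumGrid(np.roll(g.data, (3, -2), axis=(0, 1)), g.axes)
        assert correlation_score(g, rolled, (3.0, -2.0)) == pytest.approx(1.0, abs=1e-6)

    def test_anticorrelation_bound(self, rng):
        g = _conditioned(rng.normal(size=(16, 16)))
        neg = SpectrumGrid(-g.data, g.axes)
        assert correlation_score(g, neg, (0.0, 0.0)) == pytest.approx(-1.0, abs=1e-9)


class TestAlignChain:
    def test_identity(self):
        s1 = render(random_spec(n_peaks=10, seed=7, noise_sigma=0.05))
        est = align(s1, s1.copy())
        assert est.shift_ppm == pytest.approx((0.0, 0.0), abs=1e-9)
        assert est.score_before == pytest.approx(1.0, abs=1e-9)
        assert est.score_after == pytest.approx(1.0, abs=1e-9)

    def test_controlled_tenth_ppm_offset(self):
        spec = random_spec(n_peaks=30, seed=42, noise_sigma=0.1)
        s1, s2, truth = make_offset_pair(spec, (0.1, 0.1))
        est = align(s1, s2)
        for got, want in zip(est.shift_ppm, truth):
            assert got == pytest.approx(want, abs=0.01)
        assert est.score_after >= 0.999

    def test_mixed_peak_sets_with_independent_noise(self):
        spec = random_spec(n_peaks=30, seed=11, noise_sigma=0.02)
        s1, s2, truth = make_offset_pair(
            spec, (0.58, 0.61), overlap_frac=0.6, extra_peaks=12,
            noise_independent=True,
        )
        est = align(s1, s2)
        for got, want in zip(est.shift_ppm, truth):
            assert got == pytest.approx(want, abs=0.02)
        assert est.score_after > est.score_before

    def test_differing_sampling_and_size(self):
        """The moving spectrum on a coarser, larger grid is resampled and
        cropped onto the reference geometry before correlation."""
        axes1 = (make_axis(n=128, sw=640.0, obs=100.0, origin_ppm=45.0),) * 2
        axes2 = (make_axis(n=96, sw=768.0, obs=100.0, origin_ppm=44.6),) * 2
        spec1 = random_spec(n_peaks=15, seed=21, noise_sigma=0.0, axes=axes1,
                            margin_ppm=1.8)
        s1 = render(spec1)
        from dataclasses import replace
        peaks2 = tuple(
            replace(pk, position_ppm=tuple(p + 0.3 for p in pk.position_ppm))
            for pk in spec1.peaks
        )
        from spectralign.synth import SyntheticSpec
        s2 = render(SyntheticSpec(peaks2, axes2, 0.0, 0))
        est = align(s1, s2)
        assert est.shift_ppm == pytest.approx((0.3, 0.3), abs=0.02)

    def test_affine_intensity_invariance(self):
        spec = random_spec(n_peaks=20, seed=3, noise_sigma=0.05)
        s1, s2, _ = make_offset_pair(spec, (0.23, -0.41))
        est = align(s1, s2)
        scaled = SpectrumGrid(4.2 * s2.data + 17.0, s2.axes)
        est2 = align(s1, scaled)
        assert est2.shift_ppm == pytest.approx(est.shift_ppm, abs=1e-9)
        assert est2.score_after == pytest.approx(est.score_after, abs=1e-9)

    def test_antisymmetry(self):
        spec = random_spec(n_peaks=20, seed=8, noise_sigma=0.05)
        s1, s2, _ = make_offset_pair(spec, (0.33, -0.27))
        fwd = align(s1, s2)
        rev = align(s2, s1)
        ss = s1.axes[0].ss
        for f, r in zip(fwd.shift_ppm, rev.shift_ppm):
            assert f == pytest.approx(-r, abs=ss)

    def test_monotone_improvement(self):
        for seed in range(4):
            spec = random_spec(n_peaks=25, seed=seed, noise_sigma=0.05)
            s1, s2, _ = make_offset_pair(
                spec, (0.4, -0.2), overlap_frac=0.7, extra_peaks=5,
                noise_independent=True,
            )
            est = align(s1, s2)
            assert est.score_after >= est.score_before

    def test_dimensionality_mismatch_rejected(self, small_grid, volume):
        with pytest.raises(ValueError):
            align(small_grid, volume)


class TestApplyShift:
    def test_zero_shift_is_identity(self, small_grid):
        out = apply_shift(small_grid, (0.0, 0.0))
        np.testing.assert_array_equal(out.data, small_grid.data)
        assert out.axes == small_grid.axes

    def test_inverse(self):
        # band-limited fixture (smooth peaks, no noise): the phase-ramp
        # translation is exactly invertible for such content
        g = render(random_spec(n_peaks=10, seed=13, noise_sigma=0.0,
                               linewidth_range_ppm=(0.3, 0.4)))
        shift = (0.237, -0.114)
        back = apply_shift(apply_shift(g, shift), tuple(-s for s in shift))
        np.testing.assert_allclose(back.data, g.data, atol=1e-6 * np.abs(g.data).max())
        for a, b in zip(back.axes, g.axes):
            assert a.origin_ppm == pytest.approx(b.origin_ppm, abs=1e-9)

    def test_align_apply_realign_fixed_point(self):
        spec = random_spec(n_peaks=25, seed=17, noise_sigma=0.05)
        s1, s2, _ = make_offset_pair(spec, (0.58, 0.61))
        est = align(s1, s2)
        corrected = apply_shift(s2, est.shift_ppm)
        residual = align(s1, corrected)
        for r in residual.shift_ppm:
            assert abs(r) <= 0.01
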