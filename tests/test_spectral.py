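"""Spectral decomposition: bands, amplitude convention, ALFF, fALFF."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from bandalff import (
    amplitude_spectrum,
    band_alff,
    band_by_name,
    compute_band_maps,
    falff,
    normalize_global,
    standard_bands,
    BoldRun,
    VolumeGrid,
)
from bandalff.errors import (
    DegenerateInputError,
    DomainError,
    EmptyBandError,
    InvalidBandError,
)
from bandalff.spectral import FrequencyBand, band_bin_mask

SLOW4 = band_by_name("slow4")
SLOW5 = band_by_name("slow5")


class TestStandardBands:
    def test_canonical_edges_and_order(self):
        bands = standard_bands()
        edges = [(b.name, b.f_low, b.f_high) for b in bands]
        assert edges == [
            ("slow-6", 0.0, 0.01),
            ("slow-5", 0.01, 0.027),
            ("slow-4", 0.027, 0.073),
            ("slow-3", 0.073, 0.198),
            ("slow-2", 0.198, 0.25),
        ]

    def test_boundary_frequency_belongs_to_upper_band(self):
        # 0.027 Hz is the slow-4 lower edge under the half-open convention
        assert SLOW4.contains(0.027)
        assert not SLOW5.contains(0.027)
        assert SLOW4.contains(0.05)

    def test_bands_partition_all_nonzero_bins(self):
        freqs = np.arange(0, 51) * 0.005  # df = 0.005 up to Nyquist 0.25
        counts = sum(b.contains(freqs[1:]).astype(int) for b in standard_bands())
        assert np.all(counts == 1)

    def test_unknown_band_name_rejected(self):
        with pytest.raises(InvalidBandError):
            band_by_name("slow9")


class TestAmplitudeSpectrum:
    def test_bin_centered_sinusoid_reads_off_amplitude(self):
        n, tr = 100, 2.0
        x = 3.0 * np.sin(2 * np.pi * 0.05 * np.arange(n) * tr)
        spec = amplitude_spectrum(x, tr)
        assert spec.df == pytest.approx(1.0 / (n * tr))
        assert spec.amplitudes[10] == pytest.approx(3.0, abs=1e-10)
        assert np.all(np.delete(spec.amplitudes, 10) <= 1e-10)

    def test_constant_series_has_zero_nonzero_bins(self):
        spec = amplitude_spectrum(np.full(64, 7.0), 2.0)
        assert np.all(spec.amplitudes[1:] <= 1e-12)

    def test_sinusoid_sum_amplitudes_add_per_bin(self):
        n, tr = 100, 2.0
        t = np.arange(n)
        x = 2.0 * np.sin(2 * np.pi * 0.05 * t * tr) + 1.5 * np.sin(2 * np.pi * 0.1 * t * tr)
        spec = amplitude_spectrum(x, tr)
        assert spec.amplitudes[10] == pytest.approx(2.0, abs=1e-10)
        assert spec.amplitudes[20] == pytest.approx(1.5, abs=1e-10)

    def test_too_short_series_rejected(self):
        with pytest.raises(DomainError):
            amplitude_spectrum(np.ones(5), 2.0)

    def test_parseval_identity_under_convention(self, rng):
        # sum x^2 = (N/2) sum interior amp^2 + N (amp_DC^2 + amp_Nyq^2), even N
        from bandalff import detrend_linear

        x = detrend_linear(rng.standard_normal((20, 230)))
        spec = amplitude_spectrum(x, 2.0)
        amp = spec.amplitudes
        n = 230
        lhs = (x ** 2).sum(axis=-1)
        rhs = (n / 2) * (amp[:, 1:-1] ** 2).sum(axis=-1) + n * (
            amp[:, 0] ** 2 + amp[:, -1] ** 2
        )
        assert np.abs(lhs / rhs - 1).max() < 1e-6


class TestBandAlff:
    def test_single_peak_averaged_over_hand_counted_bins(self):
        # df=0.005: slow-4 covers the 9 bins 0.030..0.070; one peak of 3.0
        n, tr = 100, 2.0
        x = 3.0 * np.sin(2 * np.pi * 0.05 * np.arange(n) * tr)
        spec = amplitude_spectrum(x, tr)
        assert band_bin_mask(spec, SLOW4).sum() == 9
        assert band_alff(spec, SLOW4) == pytest.approx(3.0 / 9, abs=1e-10)

    def test_zero_spectrum_gives_zero(self):
        spec = amplitude_spectrum(np.zeros(100), 2.0)
        assert band_alff(spec, SLOW4) == 0.0

    def test_band_above_nyquist_rejected(self):
        spec = amplitude_spectrum(np.ones(100), 2.0)
        with pytest.raises(InvalidBandError):
            band_alff(spec, FrequencyBand("too-high", 0.3, 0.4))

    def test_band_with_no_bins_rejected(self):
        spec = amplitude_spectrum(np.ones(16), 2.0)  # df = 1/32 Hz, coarse
        with pytest.raises(EmptyBandError):
            band_alff(spec, FrequencyBand("sliver", 0.0401, 0.0402))

    @given(st.floats(0.1, 10.0))
    def test_scale_equivariance(self, c):
        x = np.sin(2 * np.pi * 0.05 * np.arange(100) * 2.0) + 0.3 * np.cos(
            2 * np.pi * 0.02 * np.arange(100) * 2.0
        )
        a1 = band_alff(amplitude_spectrum(x, 2.0), SLOW4)
        a2 = band_alff(amplitude_spectrum(c * x, 2.0), SLOW4)
        assert a2 == pytest.approx(c * a1, rel=1e-9)


class TestFalff:
    def test_energy_in_band_gives_one_and_zero_elsewhere(self):
        x = 3.0 * np.sin(2 * np.pi * 0.05 * np.arange(100) * 2.0)
        spec = amplitude_spectrum(x, 2.0)
        assert falff(spec, SLOW4) == pytest.approx(1.0, abs=1e-12)
        assert falff(spec, SLOW5) == pytest.approx(0.0, abs=1e-12)

    def test_partition_identity_sums_to_one(self, rng):
        from bandalff import detrend_linear

        x = detrend_linear(rng.standard_normal((30, 230)))
        spec = amplitude_spectrum(x, 2.0)
        total = sum(np.asarray(falff(spec, b)) for b in standard_bands())
        assert np.abs(total - 1).max() < 1e-9

    def test_zero_total_flagged_nan(self):
        spec = amplitude_spectrum(np.zeros(100), 2.0)
        assert np.isnan(falff(spec, SLOW4))

    def test_scale_invariance(self, rng):
        x = rng.standard_normal(230)
        f1 = falff(amplitude_spectrum(x, 2.0), SLOW4)
        f2 = falff(amplitude_spectrum(5.0 * x, 2.0), SLOW4)
        assert f2 == pytest.approx(f1, rel=1e-12)


class TestNormalizeGlobal:
    def test_values_divided_by_in_mask_mean(self):
        values = np.zeros((3, 1, 1))
        values[:, 0, 0] = [1.0, 2.0, 3.0]
        mask = np.ones_like(values, dtype=bool)
        out = normalize_global(values, mask)
        assert np.allclose(out[:, 0, 0], [0.5, 1.0, 1.5])
        assert abs(out[mask].mean() - 1.0) < 1e-12

    def test_uniform_map_becomes_ones(self):
        out = normalize_global(np.full((4, 4, 4), 3.3), np.ones((4, 4, 4), bool))
        assert np.allclose(out, 1.0)

    def test_out_of_mask_is_nan_and_zero_mean_rejected(self):
        values = np.ones((4, 4, 4))
        mask = np.zeros((4, 4, 4), bool)
        mask[0, 0, 0] = True
        out = normalize_global(values, mask)
        assert np.isnan(out[1, 1, 1])
        with pytest.raises(DegenerateInputError):
            normalize_global(np.zeros((4, 4, 4)), np.ones((4, 4, 4), bool))


class TestComputeBandMaps:
    def _run(self, data, tr=2.0, voxel=3.0):
        grid = VolumeGrid.isotropic(data.shape[:3], voxel)
        return BoldRun(data, tr, grid)

    def test_planted_band_signal_dominates_roi(self, rng):
        from bandalff import detrend_linear, plant_band_signal

        dims = (6, 6, 6)
        data = np.zeros(dims + (120,))
        sig = plant_band_signal(120, 2.0, SLOW4, 2.0, 3)
        data[2, 2, 2] = sig
        data += 0.01 * rng.standard_normal(data.shape)
        run = self._run(detrend_linear(data))
        bm = compute_band_maps(run, bands=[SLOW4], normalize=True)
        alff = bm.alff["slow-4"]
        assert alff[2, 2, 2] > 10 * np.nanmax(np.delete(alff.ravel(), np.ravel_multi_index((2, 2, 2), dims)))

    def test_rescaling_run_leaves_normalized_and_falff_unchanged(self, rng):
        data = rng.standard_normal((4, 4, 4, 64))
        r1 = compute_band_maps(self._run(data))
        r2 = compute_band_maps(self._run(2.0 * data))
        assert np.allclose(2 * r1.alff["slow-4"], r2.alff["slow-4"])
        assert np.allclose(r1.alff_norm["slow-4"], r2.alff_norm["slow-4"], equal_nan=True)
        assert np.allclose(r1.falff["slow-4"], r2.falff["slow-4"], equal_nan=True)

    def test_constant_run_degenerate_at_normalization(self):
        with pytest.raises(DegenerateInputError):
            compute_band_maps(self._run(np.full((4, 4, 4, 64), 5.0)))
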