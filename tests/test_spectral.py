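"""Filtering, Welch grid, percent-power normalization, band powers, 1/f
fitting and channel selection."""

import numpy as np
import pytest

from pallidal_sleep import SignalRecord, spectral
from pallidal_sleep.spectral import Band, BandDefinition, SpectralEstimate


def sine_record(freq, fs=1000.0, dur=10.0, amp=1.0):
    t = np.arange(int(dur * fs)) / fs
    return SignalRecord([("c", "LFP")], fs, amp * np.sin(2 * np.pi * freq * t)[None, :])


class TestPreprocess:
    def test_mains_attenuated_20db(self):
        rec = spectral.preprocess(sine_record(50.0))
        mid = rec.data[0][1000:-1000]  # away from filter edges
        atten = 20 * np.log10(np.sqrt(np.mean(mid**2)) / (1 / np.sqrt(2)))
        assert atten < -20

    def test_passband_preserved(self):
        rec = spectral.preprocess(sine_record(20.0))
        mid = rec.data[0][1000:-1000]
        assert np.sqrt(2) * np.sqrt(np.mean(mid**2)) == pytest.approx(1.0, rel=0.01)

    def test_downsample_to_500(self):
        rec = spectral.preprocess(sine_record(20.0, fs=1000.0, dur=4.0))
        assert rec.sample_rate == 500.0
        assert rec.n_samples == 2000

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError, match="sample rate"):
            spectral.preprocess(sine_record(20.0, fs=250.0))


class TestWelch:
    def test_grid_spacing_is_500_over_512(self, rng):
        spec = spectral.welch_psd(rng.standard_normal(5000))
        assert np.allclose(np.diff(spec.freqs), 500 / 512)
        assert spec.freqs[0] >= 2.0 and spec.freqs[-1] <= 80.0

    def test_white_noise_flat(self, rng):
        spec = spectral.welch_psd(rng.standard_normal(500 * 200))
        assert spec.power.std() / spec.power.mean() < 0.15

    def test_peak_at_nearest_grid_point(self, rng):
        """Welch localizes a sinusoid to the same bin as a direct DFT oracle."""
        fs = 500.0
        for f0 in (7.3, 20.0, 27.9, 61.2):
            t = np.arange(20000) / fs
            x = np.sin(2 * np.pi * f0 * t) + 0.01 * rng.standard_normal(t.size)
            spec = spectral.welch_psd(x)
            # oracle: DFT magnitude on the same 512-point grid
            dft_freqs = np.fft.rfftfreq(512, 1 / fs)
            dft = np.abs(np.fft.rfft(x[:512] * np.hanning(512)))
            keep = (dft_freqs >= 2) & (dft_freqs <= 80)
            assert spec.freqs[np.argmax(spec.power)] == pytest.approx(
                dft_freqs[keep][np.argmax(dft[keep])]
            )

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError, match="512"):
            spectral.welch_psd(np.zeros(100))


class TestNormalization:
    def test_norm_range_sums_to_100(self, rng):
        spec = spectral.normalize_psd(spectral.welch_psd(rng.standard_normal(5000)))
        mask = spectral._norm_mask(spec.freqs, BandDefinition())
        assert spec.power[mask].sum() == pytest.approx(100.0)

    def test_scale_invariance(self, rng):
        x = rng.standard_normal(5000)
        a = spectral.normalize_psd(spectral.welch_psd(x))
        b = spectral.normalize_psd(spectral.welch_psd(2.0 * x))
        assert np.allclose(a.power, b.power)

    def test_double_normalization_rejected(self, rng):
        spec = spectral.normalize_psd(spectral.welch_psd(rng.standard_normal(5000)))
        with pytest.raises(ValueError, match="already normalized"):
            spectral.normalize_psd(spec)

    def test_constructed_half_power_peak(self):
        freqs = np.arange(2.0, 80.0, 1.0)
        power = np.ones_like(freqs)
        mask = spectral._norm_mask(freqs, BandDefinition())
        power[freqs == 10.0] = mask.sum() - 1  # peak holds half the norm-range power
        spec = spectral.normalize_psd(SpectralEstimate(freqs, power))
        assert spec.power[freqs == 10.0].sum() == pytest.approx(50.0)


class TestBandPower:
    @pytest.fixture
    def flat_norm_spec(self, rng):
        return spectral.normalize_psd(spectral.welch_psd(rng.standard_normal(500 * 500)))

    def test_beta_below_total(self, flat_norm_spec):
        assert spectral.band_power(flat_norm_spec, "beta") <= 100.0

    def test_low_plus_high_equals_beta(self, flat_norm_spec):
        bd = BandDefinition()
        total = spectral.band_power(flat_norm_spec, "low_beta", bd) + spectral.band_power(
            flat_norm_spec, "high_beta", bd
        )
        assert total == pytest.approx(spectral.band_power(flat_norm_spec, "beta", bd))

    def test_flat_spectrum_power_proportional_to_width(self):
        freqs = np.arange(2.0, 80.5, 0.5)
        spec = spectral.normalize_psd(SpectralEstimate(freqs, np.ones_like(freqs)))
        b1 = spectral.band_power(spec, Band(10.0, 20.0, hi_inclusive=False))
        b2 = spectral.band_power(spec, Band(30.0, 50.0, hi_inclusive=False))
        assert b2 / b1 == pytest.approx(2.0, rel=0.01)

    def test_band_outside_grid_rejected(self, flat_norm_spec):
        with pytest.raises(ValueError, match="outside"):
            spectral.band_power(flat_norm_spec, Band(150.0, 200.0))


class TestAperiodic:
    def test_pure_power_law_recovered(self):
        freqs = np.arange(2.0, 80.0, 0.5)
        for chi in (0.5, 1.5, 2.5):
            spec = SpectralEstimate(freqs, 3.0 * freqs**-chi)
            fit = spectral.fit_aperiodic(spec)
            assert fit.exponent == pytest.approx(chi, abs=0.05)

    def test_white_spectrum_zero_exponent(self, rng):
        spec = spectral.welch_psd(rng.standard_normal(500 * 100))
        assert abs(spectral.fit_aperiodic(spec).exponent) < 0.1

    def test_peak_isolated_in_residual(self):
        freqs = np.arange(2.0, 80.0, 0.5)
        power = 10.0 * freqs**-1.5
        power += 5.0 * power[freqs == 20.0] * np.exp(-0.5 * ((freqs - 20.0) / 1.5) ** 2)
        fit = spectral.fit_aperiodic(SpectralEstimate(freqs, power))
        assert fit.freqs[np.argmax(fit.residual_periodic)] == pytest.approx(20.0, abs=1.0)
        assert fit.exponent == pytest.approx(1.5, abs=0.1)

    def test_nonpositive_power_rejected(self):
        freqs = np.arange(2.0, 45.0, 1.0)
        with pytest.raises(ValueError, match="positive"):
            spectral.fit_aperiodic(SpectralEstimate(freqs, np.zeros_like(freqs)))


class TestChannelSelection:
    def test_argmax(self):
        assert spectral.select_channel({"c01": 1.2, "c12": 3.4, "c23": 2.0}) == "c12"

    def test_single_candidate(self):
        assert spectral.select_channel({"c01": 0.1}) == "c01"

    def test_tie_breaks_lexicographically(self):
        assert spectral.select_channel({"c12": 2.0, "c01": 2.0}) == "c01"

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="no candidate"):
            spectral.select_channel({})


class TestStageSpectra:
    def test_identical_epochs_average_to_single_epoch(self, rng):
        from pallidal_sleep import staging
        from conftest import make_hypnogram

        x = rng.standard_normal(15000)
        rec = SignalRecord([("c", "LFP")], 500.0, np.tile(x, 3)[None, :])
        ep = staging.epoch_signal(rec, staging.hypnogram_as_consensus(make_hypnogram(["N2"] * 3)))
        spectra = spectral.stage_spectra(ep, ("NREM",))
        single = spectral.normalize_psd(spectral.welch_psd(x))
        assert np.allclose(spectra["NREM"].power, single.power)
        assert spectra["NREM"].n_epochs_averaged == 3

    def test_nrem_average_is_epoch_weighted_substage_mean(self, rng):
        from pallidal_sleep import staging
        from conftest import make_hypnogram

        rec = SignalRecord([("c", "LFP")], 500.0, rng.standard_normal((1, 6 * 15000)))
        h = make_hypnogram(["N1", "N2", "N2", "N3", "N3", "N3"])
        ep = staging.epoch_signal(rec, staging.hypnogram_as_consensus(h))
        spectra = spectral.stage_spectra(ep, ("NREM", "N1", "N2", "N3"))
        weighted = (
            1 * spectra["N1"].power + 2 * spectra["N2"].power + 3 * spectra["N3"].power
        ) / 6
        assert np.allclose(spectra["NREM"].power, weighted)

    def test_missing_stage_omitted(self, rng):
        from pallidal_sleep import staging
        from conftest import make_hypnogram

        rec = SignalRecord([("c", "LFP")], 500.0, rng.standard_normal((1, 15000)))
        ep = staging.epoch_signal(rec, staging.hypnogram_as_consensus(make_hypnogram(["N2"])))
        spectra = spectral.stage_spectra(ep, ("W", "NREM", "R"))
        assert set(spectra) == {"NREM"}
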