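"""Epoch spectra (resolution, Parseval), band power, aperiodic slope and
phase-amplitude coupling."""

import numpy as np
import pandas as pd
import pytest

from vds import spectral, synth
from vds.recording import Hypnogram, NREM

FS = 256.0


class TestEpochSpectra:
    def test_resolution_and_bin_count(self):
        sp = spectral.epoch_spectra(np.zeros(1024 * 3), fs=FS)
        assert sp.power.shape == (3, 481)
        assert sp.freqs[1] - sp.freqs[0] == pytest.approx(0.25)
        assert sp.freqs[-1] == pytest.approx(120.0)

    def test_sine_peak_bin(self):
        t = np.arange(1024) / FS
        sp = spectral.epoch_spectra(np.sin(2 * np.pi * 10 * t), fs=FS)
        assert sp.freqs[np.argmax(sp.power[0])] == pytest.approx(10.0)

    def test_sine_band_power_equals_variance(self):
        t = np.arange(1024) / FS
        x = 50 * np.sin(2 * np.pi * 10 * t)
        sp = spectral.epoch_spectra(x, fs=FS)
        assert sp.power[0].sum() == pytest.approx(np.var(x), rel=0.01)

    def test_white_noise_parseval_within_5pct(self):
        x = np.random.default_rng(0).standard_normal(1024 * 20)
        sp = spectral.epoch_spectra(x, fs=FS)
        # 0-120 Hz carries 120/128 of white-noise variance
        expected = np.var(x) * (120.0 / 128.0)
        assert sp.power.sum(axis=1).mean() == pytest.approx(expected, rel=0.05)

    def test_wrong_sample_rate_rejected(self):
        with pytest.raises(ValueError, match="256"):
            spectral.epoch_spectra(np.zeros(1000), fs=250.0)


class TestBandPower:
    def test_disjoint_bands_sum_to_union(self):
        x = np.random.default_rng(1).standard_normal(1024 * 5)
        sp = spectral.epoch_spectra(x, fs=FS)
        lo = spectral.band_power(sp, spectral.BandDefinition("a", 0.5, 4.0))
        hi = spectral.band_power(sp, spectral.BandDefinition("b", 4.25, 10.0))
        both = spectral.band_power(sp, spectral.BandDefinition("c", 0.5, 10.0))
        assert np.allclose(lo + hi, both)

    def test_all_power_in_band_equals_total(self):
        t = np.arange(1024) / FS
        sp = spectral.epoch_spectra(np.sin(2 * np.pi * 2 * t), fs=FS)
        bp = spectral.band_power(sp, spectral.SWA_BAND)
        assert bp[0] == pytest.approx(sp.power[0].sum(), rel=1e-6)

    def test_timecourse_excludes_artefacts_and_normalizes(self):
        power = np.zeros((4, 481))
        power[:, 8] = [10.0, 100.0, 10.0, 10.0]  # 2 Hz bin
        sp = spectral.EpochSpectra(np.arange(481) * 0.25, power, derivation="frontal")
        art = pd.DataFrame({"frontal": [False, True, False, False],
                            "occipital": [False] * 4, "emg": [False] * 4, "lfp": [False] * 4})
        hyp = Hypnogram(np.array([NREM] * 4, dtype=object), 4.0, artefact=art)
        tc = spectral.band_power_timecourse(sp, hyp, spectral.SWA_BAND, NREM,
                                            bin_minutes=4 * 4 / 60.0, reference=5.0)
        # epoch 1 excluded -> mean is 10; 10 is 200% of the reference 5
        assert tc[0] == pytest.approx(200.0)

    def test_empty_bins_are_missing(self):
        sp = spectral.EpochSpectra(np.arange(481) * 0.25, np.ones((2, 481)))
        hyp = Hypnogram(np.array(["WAKE", "WAKE"], dtype=object), 4.0)
        tc = spectral.band_power_timecourse(sp, hyp, spectral.SWA_BAND, NREM, 4 / 60.0)
        assert np.all(np.isnan(tc))


class TestSlope:
    def test_flat_spectrum_gives_zero_slope(self):
        f = np.arange(481) * 0.25
        fit = spectral.fit_spectral_slope(f, np.full(481, 7.0))
        assert fit.slope == 0.0

    def test_linear_log_spectrum_recovered_exactly(self):
        f = np.arange(481) * 0.25
        fit = spectral.fit_spectral_slope(f, 10 ** (-0.01 * f + 2.0))
        assert abs(fit.slope + 0.01) < 1e-10
        assert abs(fit.intercept - 2.0) < 1e-8

    def test_global_scaling_moves_only_intercept(self):
        f = np.arange(481) * 0.25
        p = 10 ** (-0.02 * f + 1.0)
        a = spectral.fit_spectral_slope(f, p)
        b = spectral.fit_spectral_slope(f, p * 10)
        assert b.slope == pytest.approx(a.slope, abs=1e-12)
        assert b.intercept - a.intercept == pytest.approx(1.0, abs=1e-9)

    def test_nonpositive_power_rejected(self):
        f = np.arange(481) * 0.25
        p = np.ones(481)
        p[200] = 0.0
        with pytest.raises(ValueError, match="positive"):
            spectral.fit_spectral_slope(f, p)

    def test_background_exponent_recovered(self):
        x = synth.one_over_f_noise(np.random.default_rng(2), 1024 * 60, FS, 2.0, 15.0)
        sp = spectral.epoch_spectra(x, fs=FS)
        est = spectral.estimate_background_exponent(sp.freqs, sp.power.mean(axis=0))
        assert est == pytest.approx(2.0, rel=0.10)


def _pac_signal(depth, seed, seconds=60.0, f_phase=2.0, f_amp=40.0):
    t = np.arange(int(seconds * FS)) / FS
    rng = np.random.default_rng(seed)
    am = 1 - depth * (1 + np.cos(2 * np.pi * f_phase * t)) / 2
    return (np.sin(2 * np.pi * f_phase * t)
            + 0.3 * am * np.sin(2 * np.pi * f_amp * t)
            + 0.1 * rng.standard_normal(len(t)))


class TestModulationIndex:
    def test_uniform_coupling_is_near_zero(self):
        assert spectral.modulation_index(_pac_signal(0.0, 0), FS, (1.5, 2.5), (35, 45)) < 0.01

    def test_single_bin_concentration_is_exactly_one(self):
        ph = np.linspace(0, 2 * np.pi, 1800, endpoint=False)
        amp = (ph < 2 * np.pi / 18).astype(float)
        assert spectral.phase_amplitude_mi(ph, amp, 18) == 1.0

    def test_deeper_coupling_gives_larger_mi(self):
        lo = spectral.modulation_index(_pac_signal(0.0, 3), FS, (1.5, 2.5), (35, 45))
        hi = spectral.modulation_index(_pac_signal(0.9, 3), FS, (1.5, 2.5), (35, 45))
        assert hi > lo

    def test_amplitude_scale_invariant(self):
        x = _pac_signal(0.6, 4)
        a = spectral.modulation_index(x, FS, (1.5, 2.5), (35, 45))
        b = spectral.modulation_index(10 * x, FS, (1.5, 2.5), (35, 45))
        assert b == pytest.approx(a, rel=1e-9)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            spectral.modulation_index(np.zeros(int(FS * 60)), FS, (1.5, 2.5), (120, 130))

    def test_uncoupled_surrogates_near_zero(self):
        # 95th percentile of the MI null (independent noise surrogates)
        noise = [spectral.modulation_index(
            np.random.default_rng(k).standard_normal(int(60 * FS)), FS, (1.5, 2.5), (35, 45))
            for k in range(20)]
        assert np.percentile(noise, 95) < 0.02


class TestComodulogram:
    def test_injected_coupling_located_on_grid(self):
        com = spectral.comodulogram(_pac_signal(0.9, 6, seconds=90), FS)
        i, j = np.unravel_index(np.argmax(com.mi), com.mi.shape)
        assert com.phase_freqs[i] == pytest.approx(2.0, abs=1.0)
        assert com.amp_freqs[j] == pytest.approx(40.0, abs=5.1)

    def test_white_noise_grid_below_002(self):
        x = np.random.default_rng(7).standard_normal(int(90 * FS))
        com = spectral.comodulogram(x, FS)
        assert com.mi.max() < 0.02

    def test_mi_values_in_unit_interval(self):
        com = spectral.comodulogram(_pac_signal(0.5, 8, seconds=60), FS)
        assert np.all(com.mi >= 0) and np.all(com.mi <= 1)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError, match="60 s"):
            spectral.comodulogram(np.zeros(int(30 * FS)), FS)
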