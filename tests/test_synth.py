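"""The generator must actually contain the structure the pipeline assumes:
state-dependent oscillations and EMG tone, spike-silent OFF periods under
every injected wave, drug effects confined to the drug window, and full
determinism under a fixed seed."""

import collections

import numpy as np
import pytest

from vds import io as vio, spectral, synth
from vds.recording import MA, NREM, REM, WAKE, epochs_of


def _chain_fractions_oracle(config, factor=10):
    """Brute-force long-run simulation of the same semi-Markov chain with
    an independent implementation (plain python loop, separate rng)."""
    rng = np.random.default_rng(12345)
    trans = config.transitions or synth.DEFAULT_TRANSITIONS
    n = config.n_epochs * factor
    counts = collections.Counter()
    state = WAKE if WAKE in trans else next(iter(trans))
    i = 0
    while i < n:
        mean_epochs = max(config.mean_bout_s[state] / config.epoch_s, 1.0)
        bout = min(int(rng.geometric(1.0 / mean_epochs)), n - i)
        counts[state] += bout
        i += bout
        nxt = trans.get(state, {})
        if not nxt:
            counts[state] += n - i
            break
        targets = list(nxt)
        p = np.array([nxt[t] for t in targets])
        state = targets[rng.choice(len(targets), p=p / p.sum())]
    return {s: counts[s] / n for s in (WAKE, NREM, REM)}


class TestHypnogram:
    def test_wake_only_chain_stays_awake(self):
        cfg = synth.SynthConfig(seed=1, duration_h=0.5, transitions={WAKE: {WAKE: 1.0}},
                                ma_rate_per_h=0.0)
        assert set(synth.generate_hypnogram(cfg)) == {WAKE}

    def test_deterministic_under_seed(self):
        cfg = synth.SynthConfig(seed=42, duration_h=0.5)
        a = synth.generate_hypnogram(cfg)
        b = synth.generate_hypnogram(cfg)
        assert np.array_equal(a, b)

    def test_state_fractions_match_long_run_oracle(self):
        cfg = synth.SynthConfig(seed=0, duration_h=24.0)
        labels = synth.generate_hypnogram(cfg)
        frac = {s: np.mean(labels == s) for s in (WAKE, NREM, REM)}
        oracle = _chain_fractions_oracle(cfg, factor=10)
        for s in (WAKE, NREM, REM):
            assert abs(frac[s] - oracle[s]) < 0.10, (s, frac[s], oracle[s])

    def test_rem_entered_only_from_nrem(self):
        cfg = synth.SynthConfig(seed=3, duration_h=24.0, ma_rate_per_h=0.0)
        labels = synth.generate_hypnogram(cfg)
        prev = labels[:-1][np.asarray(labels[1:] == REM) & np.asarray(labels[:-1] != REM)]
        assert set(prev) <= {NREM}

    def test_nonpositive_bout_means_rejected(self):
        cfg = synth.SynthConfig(mean_bout_s={WAKE: -1.0, NREM: 120.0, REM: 60.0})
        with pytest.raises(ValueError, match="bout"):
            synth.generate_hypnogram(cfg)


class TestSignals:
    def test_background_only_spectrum_decays(self):
        cfg = synth.SynthConfig(seed=2, duration_h=0.05, delta_amp_nrem=1e-9,
                                theta_amp_rem=1e-9, theta_amp_wake_occ=1e-9,
                                wave_rate_nrem=1e-9, ma_rate_per_h=0.0)
        rec, _ = synth.synthesize_signals(synth.generate_hypnogram(cfg), cfg)
        sp = spectral.epoch_spectra(rec, "frontal")
        mean = sp.power.mean(axis=0)
        bands = [(1, 4), (4, 16), (16, 64), (64, 120)]
        powers = [mean[(sp.freqs >= lo) & (sp.freqs < hi)].mean() for lo, hi in bands]
        assert all(a > b for a, b in zip(powers, powers[1:]))

    def test_nrem_delta_exceeds_wake_delta(self, mixed_study):
        _, rec, gt = mixed_study
        sp = spectral.epoch_spectra(rec, "frontal")
        bp = spectral.band_power(sp, spectral.SWA_BAND)
        assert bp[gt.labels == NREM].mean() > 5 * bp[gt.labels == WAKE].mean()

    def test_emg_tone_graded_wake_nrem_rem(self, mixed_study):
        cfg, rec, gt = mixed_study
        spe = int(cfg.fs * cfg.epoch_s)
        rms = np.sqrt(np.mean(epochs_of(rec.channels["emg"].data, cfg.fs, cfg.epoch_s) ** 2, axis=1))
        means = {s: rms[gt.labels == s].mean() for s in (WAKE, NREM, REM)}
        assert means[WAKE] > means[NREM] > means[REM]

    def test_off_intervals_are_spike_free(self, nrem_study):
        _, rec, gt = nrem_study
        inside = 0
        for lo, hi in gt.off_intervals:
            i0, i1 = np.searchsorted(rec.spike_times, [lo, hi])
            inside += i1 - i0
        assert inside == 0

    def test_every_off_interval_brackets_a_wave_peak(self, nrem_study):
        _, _, gt = nrem_study
        for lo, hi in gt.off_intervals:
            assert np.any((gt.wave_times >= lo) & (gt.wave_times <= hi))

    def test_incompatible_fs_epoch_rejected(self):
        cfg = synth.SynthConfig(fs=256.0, epoch_s=4.3)
        with pytest.raises(ValueError, match="samples per epoch"):
            cfg.validate()

    def test_byte_identical_regeneration(self):
        cfg = synth.SynthConfig(seed=11, duration_h=0.05)
        labels = synth.generate_hypnogram(cfg)
        r1, g1 = synth.synthesize_signals(labels, cfg)
        r2, g2 = synth.synthesize_signals(labels, cfg)
        for role in r1.channels:
            assert np.array_equal(r1.channels[role].data, r2.channels[role].data)
        assert np.array_equal(r1.spike_times, r2.spike_times)
        assert np.array_equal(g1.wave_times, g2.wave_times)


class TestDrugEffects:
    def test_unit_gains_are_identity(self, mixed_study):
        _, rec, gt = mixed_study
        cfg = synth.SynthConfig(seed=7, duration_h=1.0, drug_swa_gain=1.0, drug_theta_gain=1.0)
        out = synth.apply_drug_effects(rec, gt.labels, cfg)
        for role in rec.channels:
            assert np.array_equal(out.channels[role].data, rec.channels[role].data)

    def test_zero_theta_gain_suppresses_occipital_theta(self, mixed_study):
        _, rec, gt = mixed_study
        cfg = synth.SynthConfig(seed=7, duration_h=1.0, drug_theta_gain=0.0)
        out = synth.apply_drug_effects(rec, gt.labels, cfg)
        starts = np.arange(len(gt.labels)) * cfg.epoch_s
        wake_in = (gt.labels == WAKE) & (starts >= 600) & (starts + 4 <= 3300)
        theta_drug = spectral.band_power(
            spectral.epoch_spectra(out, "occipital"), spectral.THETA_BAND)[wake_in].mean()
        theta_veh = spectral.band_power(
            spectral.epoch_spectra(rec, "occipital"), spectral.THETA_BAND)[wake_in].mean()
        assert theta_drug < 0.10 * theta_veh

    def test_samples_outside_window_unchanged(self, mixed_study):
        _, rec, gt = mixed_study
        cfg = synth.SynthConfig(seed=7, duration_h=1.0)
        out = synth.apply_drug_effects(rec, gt.labels, cfg)
        i0, i1 = int(600 * 256), int(3300 * 256)
        for role in rec.channels:
            a, b = rec.channels[role].data, out.channels[role].data
            assert np.max(np.abs(a[:i0] - b[:i0])) == 0.0
            assert np.max(np.abs(a[i1:] - b[i1:])) == 0.0

    def test_emg_untouched(self, mixed_study):
        _, rec, gt = mixed_study
        cfg = synth.SynthConfig(seed=7, duration_h=1.0)
        out = synth.apply_drug_effects(rec, gt.labels, cfg)
        assert np.array_equal(out.channels["emg"].data, rec.channels["emg"].data)

    def test_window_outside_recording_rejected(self, mixed_study):
        _, rec, gt = mixed_study
        cfg = synth.SynthConfig(seed=7, duration_h=1.0, drug_window=(600.0, 7200.0))
        with pytest.raises(ValueError, match="window"):
            synth.apply_drug_effects(rec, gt.labels, cfg)


class TestPupilSynthesis:
    def test_noiseless_trace_gives_exact_diameter(self):
        cfg = synth.SynthConfig(seed=1, duration_h=0.01, pupil_jitter_px=0.0,
                                pupil_noise_frac=0.0, dropout_frac=0.0)
        trace, t, d = synth.synthesize_pupil(cfg)
        ns = np.hypot(trace["north_x"] - trace["south_x"], trace["north_y"] - trace["south_y"])
        ew = np.hypot(trace["east_x"] - trace["west_x"], trace["east_y"] - trace["west_y"])
        assert np.allclose((ns + ew) / 2, d, atol=1e-9)

    def test_dropout_fraction_matches_config(self):
        cfg = synth.SynthConfig(seed=5, duration_h=0.2, dropout_frac=0.2)
        trace, _, _ = synth.synthesize_pupil(cfg)
        low = np.ones(len(trace), dtype=bool)
        bad = np.zeros(len(trace), dtype=bool)
        for p in synth.PUPIL_POINTS:
            bad |= trace[f"{p}_likelihood"].to_numpy() < 0.99
        n = len(trace)
        se = np.sqrt(0.2 * 0.8 / n)
        assert abs(bad.mean() - 0.2) < 4 * se

    def test_vehicle_has_no_transient(self):
        cfg = synth.SynthConfig(seed=5, duration_h=0.5)
        _, _, d = synth.synthesize_pupil(cfg, drug=False)
        assert d.max() / np.median(d) < 1.15

    def test_negative_diameter_rejected(self):
        cfg = synth.SynthConfig(pupil_baseline_px=-1.0)
        with pytest.raises(ValueError):
            synth.synthesize_pupil(cfg)


class TestStudyBundle:
    def test_bundle_round_trips_through_io(self, study_bundle):
        cfg, paths = study_bundle
        rec, hyp = vio.read_bundle(paths["vehicle"])
        direct, gt = synth.synthesize_signals(synth.generate_hypnogram(cfg), cfg)
        assert np.array_equal(hyp.labels, gt.labels)
        assert np.allclose(rec.spike_times, direct.spike_times, atol=1e-6)
        for role in direct.channels:
            err = np.max(np.abs(rec.channels[role].data - direct.channels[role].data))
            # bounded by one 16-bit step of the shared (two-arm) range
            assert err < np.ptp(direct.channels[role].data) * 3.0 / 65535.0

    def test_pre_injection_samples_identical_across_arms(self, study_bundle):
        cfg, paths = study_bundle
        rv, _ = vio.read_bundle(paths["vehicle"])
        rd, _ = vio.read_bundle(paths["drug"])
        i0 = int(cfg.drug_window[0] * cfg.fs)
        for role in rv.channels:
            assert np.array_equal(rv.channels[role].data[:i0], rd.channels[role].data[:i0])

    def test_missing_directory_error_names_path(self, tmp_path):
        cfg = synth.SynthConfig(seed=1, duration_h=0.2, drug_window=(60.0, 600.0))
        with pytest.raises(FileNotFoundError, match="no/such"):
            synth.generate_study(cfg, tmp_path / "no" / "such")
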