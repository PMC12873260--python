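"""Synthetic study generator.

Produces fully synthetic recordings with the statistical structure the
analysis pipeline assumes: a semi-Markov wake/NREM/REM hypnogram in 4-s
epochs, 1/f^chi EEG/LFP background with state-gated delta and theta
oscillations, EMG tone graded wake > NREM > REM, LFP slow waves with
time-locked multi-unit OFF periods, and a post-injection "drug window"
during which behaviourally awake epochs carry added slow waves, occipital
theta is suppressed, and the pupil transiently dilates.

Every random draw comes from named substreams of a single seed, so a fixed
:class:`SynthConfig` reproduces the same study byte for byte.  The
generator also returns the ground truth (state labels, injected wave peaks
and OFF intervals, true pupil diameter) against which scoring and
detection accuracy are measured.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter1d

from ._filters import butter_bandpass_sos, swa_sos, zero_phase
from .recording import MA, NREM, REM, STATES, WAKE, Channel, Hypnogram, Recording

#: default embedded-chain transition probabilities; REM is entered only
#: from NREM, as in rodent sleep.
DEFAULT_TRANSITIONS = {
    WAKE: {NREM: 1.0},
    NREM: {WAKE: 0.65, REM: 0.35},
    REM: {WAKE: 0.9, NREM: 0.1},
}

PUPIL_POINTS = ("north", "south", "east", "west")


@dataclass
class SynthConfig:
    """Parameters of one synthetic study.

    Magnitudes (oscillation amplitudes, EMG tone, wave rate) are free
    parameters chosen to be realistic for mouse epidural EEG / cortical
    LFP; the drug-effect parameters encode the reported effect directions
    (wake SWA roughly doubled, occipital theta strongly suppressed, ~75%
    peak pupil dilation over ~12 min).
    """

    seed: int = 0
    duration_h: float = 1.0
    epoch_s: float = 4.0
    fs: float = 256.0

    # hypnogram
    mean_bout_s: dict = field(default_factory=lambda: {WAKE: 120.0, NREM: 120.0, REM: 60.0})
    transitions: dict | None = None  # None -> DEFAULT_TRANSITIONS
    ma_rate_per_h: float = 6.0  # brief high-EMG intrusions inside NREM

    # background + oscillations (µV)
    background_exponent: float = 2.0
    eeg_background_rms: float = 15.0
    lfp_background_rms: float = 10.0
    delta_amp_nrem: float = 60.0
    delta_freq: float = 1.8
    theta_amp_rem: float = 30.0
    theta_amp_wake_occ: float = 20.0
    theta_freq: float = 8.0
    emg_rms: dict = field(
        default_factory=lambda: {WAKE: 40.0, NREM: 15.0, REM: 6.0, MA: 45.0}
    )

    # LFP slow waves and multi-unit activity
    wave_rate_nrem: float = 20.0  # events/min during NREM
    wave_amp_mean: float = 160.0  # µV, gamma-distributed peak amplitudes
    wave_amp_shape: float = 4.0
    off_duration_ms: tuple = (150.0, 30.0)  # mean, SD of OFF periods
    baseline_spike_rate: float = 30.0  # Hz, homogeneous Poisson MUA

    # drug condition
    drug_window: tuple = (600.0, 3300.0)  # seconds from start
    drug_swa_gain: float = 2.0  # multiplicative target on wake SWA
    drug_theta_gain: float = 0.4  # <= 1, occipital theta scaling
    drug_pupil_peak_frac: float = 0.75
    drug_pupil_duration_s: float = 720.0

    # pupillometry
    pupil_fps: float = 50.0
    pupil_baseline_px: float = 40.0
    pupil_noise_frac: float = 0.02
    pupil_jitter_px: float = 0.5
    dropout_frac: float = 0.05

    def validate(self) -> None:
        if self.duration_h * 3600 < self.epoch_s:
            raise ValueError("duration must cover at least one epoch")
        if any(v <= 0 for v in self.mean_bout_s.values()):
            raise ValueError("mean bout lengths must be positive")
        if any(v <= 0 for v in self.emg_rms.values()):
            raise ValueError("EMG RMS values must be positive")
        for name in ("fs", "epoch_s", "wave_rate_nrem", "wave_amp_mean",
                     "baseline_spike_rate", "pupil_fps", "pupil_baseline_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.pupil_jitter_px < 0 or self.pupil_noise_frac < 0:
            raise ValueError("pupil noise parameters must be non-negative")
        if not 0 <= self.dropout_frac < 1:
            raise ValueError("dropout_frac must be in [0, 1)")
        w0, w1 = self.drug_window
        if not 0 <= w0 < w1:
            raise ValueError("drug_window must be an increasing pair of times")
        spe = self.fs * self.epoch_s
        if abs(spe - round(spe)) > 1e-9:
            raise ValueError("fs and epoch_s give a non-integer number of samples per epoch")

    def validate_drug_window(self) -> None:
        """Containment check, enforced wherever the window is applied."""
        self.validate()
        if self.drug_window[1] > self.duration_h * 3600 + 1e-9:
            raise ValueError("drug_window extends beyond the recording")

    @property
    def n_epochs(self) -> int:
        return int(self.duration_h * 3600 / self.epoch_s)

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([int(self.seed), int(stream)]))


# named rng substreams
_S_HYP, _S_BG_F, _S_BG_O, _S_BG_L, _S_EMG, _S_WAVE, _S_SPIKE, _S_DRUG, _S_PUPIL, _S_PUPIL_DRUG = range(10)


@dataclass
class GroundTruth:
    """What the generator actually put into a recording."""

    labels: np.ndarray
    epoch_s: float
    wave_times: np.ndarray  # peak times, s
    wave_amps: np.ndarray  # injected peak amplitudes, µV
    off_intervals: np.ndarray  # (n, 2) start/end, s
    pupil_t: np.ndarray | None = None
    pupil_true: np.ndarray | None = None
    condition: str = "vehicle"
    injection_t: float | None = None

    def __post_init__(self) -> None:
        bad = set(np.asarray(self.labels, dtype=object)) - set(STATES)
        if bad:
            raise ValueError(f"unknown ground-truth labels: {sorted(map(str, bad))}")
        # every OFF interval must bracket an injected wave peak
        if len(self.off_intervals):
            lo, hi = self.off_intervals[:, 0], self.off_intervals[:, 1]
            idx = np.searchsorted(np.sort(self.wave_times), lo)
            wt = np.sort(self.wave_times)
            ok = (idx < len(wt)) & (wt[np.minimum(idx, len(wt) - 1)] <= hi + 1e-9)
            if not ok.all():
                raise ValueError("OFF interval without an overlapping wave peak")


def generate_hypnogram(config: SynthConfig) -> np.ndarray:
    """Semi-Markov state sequence with geometric (exponential-like) bout
    lengths around the configured means; micro-arousal epochs are inserted
    inside NREM bouts at ``ma_rate_per_h``."""
    config.validate()
    rng = config.rng(_S_HYP)
    trans = config.transitions if config.transitions is not None else DEFAULT_TRANSITIONS
    n = config.n_epochs
    labels = np.empty(n, dtype=object)
    state = WAKE if WAKE in trans else next(iter(trans))
    i = 0
    while i < n:
        mean_epochs = max(config.mean_bout_s[state] / config.epoch_s, 1.0)
        bout = int(rng.geometric(1.0 / mean_epochs))
        bout = min(bout, n - i)
        labels[i : i + bout] = state
        i += bout
        nxt = trans.get(state, {})
        if not nxt:
            labels[i:] = state
            break
        targets = list(nxt.keys())
        probs = np.array([nxt[t] for t in targets], dtype=float)
        state = targets[rng.choice(len(targets), p=probs / probs.sum())]
    # brief high-EMG intrusions: eligible epochs are NREM with NREM on both sides
    if config.ma_rate_per_h > 0:
        p_ma = config.ma_rate_per_h * config.epoch_s / 3600.0
        draws = rng.random(n)
        for k in range(1, n - 1):
            if (
                labels[k] == NREM
                and labels[k - 1] == NREM
                and labels[k + 1] == NREM
                and draws[k] < p_ma
            ):
                labels[k] = MA
    return labels


def one_over_f_noise(
    rng: np.random.Generator, n: int, fs: float, exponent: float, rms: float,
    floor_hz: float = 0.5,
) -> np.ndarray:
    """Gaussian noise with amplitude spectrum f^(-exponent/2) above
    ``floor_hz`` (flat below, zero DC), scaled to the requested RMS."""
    nf = n // 2 + 1
    spec = rng.standard_normal(nf) + 1j * rng.standard_normal(nf)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shape = np.maximum(f, floor_hz) ** (-exponent / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n)
    x *= rms / x.std()
    return x


def _wave_template(fs: float) -> tuple[np.ndarray, int]:
    """Biphasic slow-wave template: 0.35 s negative flanks around a 0.5 s
    positive lobe, band-limited to the SWA filter and renormalised so the
    positive peak is exactly 1.

    The raw shape is an exact palindrome and is filtered inside a long
    zero context, so the band-limited template stays time-symmetric about
    its peak (a second zero-phase filtering during detection then leaves
    the peak location unbiased).  Returns (template, peak_index) with the
    peak at the centre (support ±0.9 s).
    """
    n_neg = int(round(0.35 * fs))
    n_pos = int(round(0.5 * fs))
    k = np.arange(1, n_neg + 1)
    neg = -0.4 * np.sin(np.pi * k / (n_neg + 1))
    pos = np.sin(np.pi * (np.arange(n_pos) + 0.5) / n_pos)
    raw = np.concatenate([neg, pos, neg[::-1]])
    pad = np.zeros(int(2 * fs))
    filt = zero_phase(swa_sos(fs), np.concatenate([pad, raw, pad]))
    peak = int(np.argmax(filt))
    half = int(round(0.9 * fs))
    tpl = filt[peak - half : peak + half + 1]
    return tpl / tpl.max(), half


def _state_gate(labels: np.ndarray, state: str, spe: int) -> np.ndarray:
    return np.repeat(labels == state, spe).astype(float)


def _draw_waves(
    config: SynthConfig, labels: np.ndarray, wake_window: tuple | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Slot-based wave placement.

    Each epoch is divided into 2-s slots; a slot hosts at most one wave, so
    waves never overlap.  Slot occupancy, start jitter, amplitude and OFF
    duration are drawn for *every* epoch up front from seed-fixed streams,
    so two label sequences that agree on a prefix produce identical waves
    on that prefix.

    With ``wake_window=None`` waves go into NREM epochs at
    ``wave_rate_nrem``; otherwise they go into WAKE epochs inside the given
    window at a rate scaled by ``drug_swa_gain - 1`` (drug condition).

    Returns (peak_times, amplitudes, off_intervals).
    """
    stream = _S_WAVE if wake_window is None else _S_DRUG
    rng = config.rng(stream)
    n, epoch_s = config.n_epochs, config.epoch_s
    n_slots = max(int(epoch_s // 2), 1)
    slot_u = rng.random((n, n_slots))
    start_u = rng.uniform(0.1, 0.7, size=(n, n_slots))
    amps = rng.gamma(config.wave_amp_shape, config.wave_amp_mean / config.wave_amp_shape,
                     size=(n, n_slots))
    off_mean, off_sd = config.off_duration_ms
    offs = np.clip(rng.normal(off_mean, off_sd, size=(n, n_slots)), 30.0, None) / 1000.0

    p_slot = config.wave_rate_nrem / 60.0 * (epoch_s / n_slots)
    if wake_window is None:
        eligible = labels == NREM
    else:
        p_slot *= max(config.drug_swa_gain - 1.0, 0.0)
        t0 = np.arange(n) * epoch_s
        # a 1.0 s margin keeps the full ±0.9 s template support inside the
        # window, so samples outside it stay bit-identical
        eligible = (
            (labels == WAKE)
            & (t0 >= wake_window[0] + 1.0)
            & (t0 + epoch_s <= wake_window[1] - 1.0)
        )
    p_slot = min(p_slot, 1.0)

    slot_len = epoch_s / n_slots
    times, amplitudes, off_iv = [], [], []
    for k in np.flatnonzero(eligible):
        for j in range(n_slots):
            if slot_u[k, j] < p_slot:
                # wave peak sits mid-slot with jitter, so successive peaks
                # are at least ~1.4 s apart and positive lobes never overlap
                peak = k * epoch_s + j * slot_len + 0.65 + start_u[k, j]
                times.append(peak)
                amplitudes.append(amps[k, j])
                off_iv.append((peak - offs[k, j] / 2, peak + offs[k, j] / 2))
    return (
        np.asarray(times, dtype=float),
        np.asarray(amplitudes, dtype=float),
        np.asarray(off_iv, dtype=float).reshape(-1, 2),
    )


def _add_waves(data: np.ndarray, fs: float, times: np.ndarray, amps: np.ndarray,
               scale: float = 1.0) -> np.ndarray:
    """Add wave templates at the given peak times; returns the mask of
    waves that fit entirely inside the signal (only those are added)."""
    template, peak_off = _wave_template(fs)
    kept = np.zeros(len(times), dtype=bool)
    for w, (t, a) in enumerate(zip(times, amps)):
        i0 = int(round(t * fs)) - peak_off
        i1 = i0 + len(template)
        if i0 >= 0 and i1 <= len(data):
            data[i0:i1] += scale * a * template
            kept[w] = True
    return kept


def _delete_spikes(spikes: np.ndarray, intervals: np.ndarray) -> np.ndarray:
    if not len(intervals) or not len(spikes):
        return spikes
    keep = np.ones(len(spikes), dtype=bool)
    for lo, hi in intervals:
        i0, i1 = np.searchsorted(spikes, [lo, hi])
        keep[i0:i1] = False
    return spikes[keep]


def synthesize_signals(labels: np.ndarray, config: SynthConfig) -> tuple[Recording, GroundTruth]:
    """Render frontal EEG, occipital EEG, EMG, LFP and MUA spike times for
    a given epoch-label sequence."""
    config.validate()
    labels = np.asarray(labels, dtype=object)
    if len(labels) == 0:
        raise ValueError("labels must be non-empty")
    fs, epoch_s = config.fs, config.epoch_s
    spe = int(round(fs * epoch_s))
    n = len(labels) * spe
    t = np.arange(n) / fs
    chi = config.background_exponent

    frontal = one_over_f_noise(config.rng(_S_BG_F), n, fs, chi, config.eeg_background_rms)
    occipital = one_over_f_noise(config.rng(_S_BG_O), n, fs, chi, config.eeg_background_rms)
    lfp = one_over_f_noise(config.rng(_S_BG_L), n, fs, chi, config.lfp_background_rms)

    nrem_gate = _state_gate(labels, NREM, spe)
    delta = np.sin(2 * np.pi * config.delta_freq * t)
    frontal += config.delta_amp_nrem * nrem_gate * delta
    occipital += 0.7 * config.delta_amp_nrem * nrem_gate * delta

    theta = np.sin(2 * np.pi * config.theta_freq * t)
    occipital += config.theta_amp_rem * _state_gate(labels, REM, spe) * theta
    occipital += config.theta_amp_wake_occ * _state_gate(labels, WAKE, spe) * theta

    emg_rng = config.rng(_S_EMG)
    emg_gate = np.repeat([config.emg_rms[str(s)] for s in labels], spe)
    emg = emg_rng.standard_normal(n) * emg_gate

    wave_times, wave_amps, off_intervals = _draw_waves(config, labels)
    kept = _add_waves(lfp, fs, wave_times, wave_amps)
    wave_times, wave_amps, off_intervals = wave_times[kept], wave_amps[kept], off_intervals[kept]

    spike_rng = config.rng(_S_SPIKE)
    duration = n / fs
    n_spikes = spike_rng.poisson(config.baseline_spike_rate * duration)
    spikes = np.sort(spike_rng.uniform(0.0, duration, size=n_spikes))
    spikes = _delete_spikes(spikes, off_intervals)

    rec = Recording(
        channels={
            "frontal": Channel("Frontal", frontal, fs),
            "occipital": Channel("Occipital", occipital, fs),
            "emg": Channel("EMG", emg, fs),
            "lfp": Channel("LFP", lfp, fs),
        },
        spike_times=spikes,
    )
    gt = GroundTruth(
        labels=labels.copy(),
        epoch_s=epoch_s,
        wave_times=wave_times,
        wave_amps=wave_amps,
        off_intervals=off_intervals,
    )
    return rec, gt


def apply_drug_effects(
    recording: Recording,
    labels: np.ndarray,
    config: SynthConfig,
    ground_truth: GroundTruth | None = None,
) -> Recording:
    """Superimpose the acute drug signature inside ``config.drug_window``.

    Wake epochs fully inside the window receive added slow waves (rate
    scaled by ``drug_swa_gain - 1``, so a gain of 1 adds nothing) on LFP
    and both EEG derivations, each with a coupled spiking OFF period; the
    occipital theta-band component of those epochs is scaled by
    ``drug_theta_gain``.  EMG is untouched (behavioural wakefulness is
    preserved) and samples outside the window are bit-identical to the
    input.  If ``ground_truth`` is given, drug waves and OFF intervals are
    appended to it and its condition set to "drug".
    """
    config.validate_drug_window()
    labels = np.asarray(labels, dtype=object)
    w0, w1 = config.drug_window
    if w1 > recording.duration + 1e-9:
        raise ValueError("drug_window extends beyond the recording")
    out = recording.copy()
    out.condition = "drug"
    out.injection_t = w0
    fs = config.fs
    spe = int(round(fs * config.epoch_s))

    wave_times = np.empty(0)
    wave_amps = np.empty(0)
    off_iv = np.empty((0, 2))
    if config.drug_swa_gain != 1.0:
        wave_times, wave_amps, off_iv = _draw_waves(config, labels, wake_window=(w0, w1))
        kept = _add_waves(out.channels["lfp"].data, fs, wave_times, wave_amps)
        wave_times, wave_amps, off_iv = wave_times[kept], wave_amps[kept], off_iv[kept]
        _add_waves(out.channels["frontal"].data, fs, wave_times, wave_amps, scale=0.8)
        _add_waves(out.channels["occipital"].data, fs, wave_times, wave_amps, scale=0.5)
        if out.spike_times is not None:
            out.spike_times = _delete_spikes(out.spike_times, off_iv)

    if config.drug_theta_gain != 1.0:
        i0, i1 = int(round(w0 * fs)), int(round(w1 * fs))
        seg = out.channels["occipital"].data[i0:i1]
        theta_comp = zero_phase(butter_bandpass_sos(fs, 7.0, 12.5), seg)
        sample_state = np.repeat(labels, spe)[i0:i1]
        mask = (sample_state == WAKE).astype(float)
        seg += (config.drug_theta_gain - 1.0) * theta_comp * mask

    if ground_truth is not None:
        ground_truth.wave_times = np.concatenate([ground_truth.wave_times, wave_times])
        ground_truth.wave_amps = np.concatenate([ground_truth.wave_amps, wave_amps])
        ground_truth.off_intervals = np.vstack([ground_truth.off_intervals, off_iv])
        ground_truth.condition = "drug"
        ground_truth.injection_t = w0
    return out


def synthesize_pupil(
    config: SynthConfig, drug: bool = False, injection_t: float | None = None
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Frame-wise cardinal-point pose trace plus the true diameter series.

    Points lie on a circle of the true diameter with Gaussian coordinate
    jitter; ``dropout_frac`` of frames get one point with likelihood below
    0.99.  In the drug condition a raised-cosine dilation transient of peak
    fractional increase ``drug_pupil_peak_frac`` and duration
    ``drug_pupil_duration_s`` starts at the injection.

    Returns ``(trace, t, true_diameter)``.
    """
    config.validate()
    rng = config.rng(_S_PUPIL_DRUG if drug else _S_PUPIL)
    base_rng = config.rng(_S_PUPIL)
    fps = config.pupil_fps
    n = int(config.duration_h * 3600 * fps)
    t = np.arange(n) / fps
    d0 = config.pupil_baseline_px

    # slow physiological fluctuation (Gaussian-smoothed noise, sigma 2 s)
    noise = base_rng.standard_normal(n)
    noise = gaussian_filter1d(noise, sigma=2.0 * fps)
    if noise.std() > 0:
        noise = noise / noise.std()
    d = d0 * (1.0 + config.pupil_noise_frac * noise)

    if drug:
        ti = config.drug_window[0] if injection_t is None else injection_t
        dur = config.drug_pupil_duration_s
        rel = (t - ti) / dur
        bump = np.where((rel >= 0) & (rel <= 1), 0.5 * (1 - np.cos(2 * np.pi * rel)), 0.0)
        d = d * (1.0 + config.drug_pupil_peak_frac * bump)

    cx, cy = 160.0, 120.0
    r = d / 2.0
    coords = {
        "north": (cx + np.zeros(n), cy - r),
        "south": (cx + np.zeros(n), cy + r),
        "east": (cx + r, cy + np.zeros(n)),
        "west": (cx - r, cy + np.zeros(n)),
    }
    cols: dict[str, np.ndarray] = {"time": t}
    like = {p: rng.uniform(0.991, 1.0, size=n) for p in PUPIL_POINTS}
    dropped = rng.random(n) < config.dropout_frac
    which = rng.integers(0, len(PUPIL_POINTS), size=n)
    for j, p in enumerate(PUPIL_POINTS):
        sel = dropped & (which == j)
        like[p][sel] = rng.uniform(0.3, 0.989, size=sel.sum())
    for p in PUPIL_POINTS:
        x, y = coords[p]
        jx = rng.standard_normal(n) * config.pupil_jitter_px
        jy = rng.standard_normal(n) * config.pupil_jitter_px
        cols[f"{p}_x"] = x + jx
        cols[f"{p}_y"] = y + jy
        cols[f"{p}_likelihood"] = like[p]
    return pd.DataFrame(cols), t, d


def ground_truth_to_dict(gt: GroundTruth) -> dict:
    return {
        "labels": [str(s) for s in gt.labels],
        "epoch_s": gt.epoch_s,
        "wave_times": gt.wave_times.tolist(),
        "wave_amps": gt.wave_amps.tolist(),
        "off_intervals": gt.off_intervals.tolist(),
        "pupil_t": None if gt.pupil_t is None else gt.pupil_t.tolist(),
        "pupil_true": None if gt.pupil_true is None else gt.pupil_true.tolist(),
        "condition": gt.condition,
        "injection_t": gt.injection_t,
    }


def ground_truth_from_dict(d: dict) -> GroundTruth:
    return GroundTruth(
        labels=np.asarray(d["labels"], dtype=object),
        epoch_s=float(d["epoch_s"]),
        wave_times=np.asarray(d["wave_times"], dtype=float),
        wave_amps=np.asarray(d["wave_amps"], dtype=float),
        off_intervals=np.asarray(d["off_intervals"], dtype=float).reshape(-1, 2),
        pupil_t=None if d.get("pupil_t") is None else np.asarray(d["pupil_t"], dtype=float),
        pupil_true=None if d.get("pupil_true") is None else np.asarray(d["pupil_true"], dtype=float),
        condition=d.get("condition", "vehicle"),
        injection_t=d.get("injection_t"),
    )


def load_ground_truth(path: Path) -> GroundTruth:
    with open(path) as fh:
        return ground_truth_from_dict(json.load(fh))


def generate_study(config: SynthConfig, outdir: str | Path) -> dict[str, Path]:
    """Write a crossover-style bundle: one vehicle arm and one drug arm
    sharing the seed-derived pre-injection baseline.

    Each arm directory contains ``recording.edf``, ``spikes.txt``,
    ``pupil.csv`` (pose-estimation dialect), ``hypnogram.tsv``,
    ``ground_truth.json`` and a ``config.yaml`` snapshot.  Both arms' EDFs
    use a shared per-channel physical range so pre-injection samples are
    identical after 16-bit quantization.
    """
    from . import io as vio  # local import to avoid a cycle at import time

    config.validate_drug_window()
    outdir = Path(outdir)
    if not outdir.is_dir():
        raise FileNotFoundError(f"output directory does not exist: {outdir}")

    w0, w1 = config.drug_window
    labels_v = generate_hypnogram(config)
    # drug arm: behavioural wakefulness (NREM/REM suppression) inside the window
    labels_d = labels_v.copy()
    starts = np.arange(len(labels_v)) * config.epoch_s
    in_window = (starts >= w0) & (starts + config.epoch_s <= w1)
    labels_d[in_window] = WAKE

    rec_v, gt_v = synthesize_signals(labels_v, config)
    rec_v.injection_t = w0
    rec_d, gt_d = synthesize_signals(labels_d, config)
    rec_d = apply_drug_effects(rec_d, labels_d, config, ground_truth=gt_d)

    pup_v, tp, dv = synthesize_pupil(config, drug=False)
    pup_d, _, dd = synthesize_pupil(config, drug=True, injection_t=w0)
    gt_v.pupil_t, gt_v.pupil_true = tp, dv
    gt_d.pupil_t, gt_d.pupil_true = tp, dd
    gt_v.injection_t = w0

    # shared physical ranges so quantization is identical across arms
    phys_ranges = {}
    for role in rec_v.channels:
        lo = min(rec_v.channels[role].data.min(), rec_d.channels[role].data.min())
        hi = max(rec_v.channels[role].data.max(), rec_d.channels[role].data.max())
        pad = 0.05 * max(hi - lo, 1e-6)
        phys_ranges[role] = (lo - pad, hi + pad)

    paths: dict[str, Path] = {}
    for name, rec, gt, pup in (
        ("vehicle", rec_v, gt_v, pup_v),
        ("drug", rec_d, gt_d, pup_d),
    ):
        arm = outdir / name
        arm.mkdir(exist_ok=True)
        vio.write_edf(rec, arm / "recording.edf", phys_ranges=phys_ranges)
        vio.write_spike_times(rec.spike_times, arm / "spikes.txt")
        vio.write_pose_csv(pup, arm / "pupil.csv")
        vio.write_hypnogram(Hypnogram(gt.labels, config.epoch_s), arm / "hypnogram.tsv")
        with open(arm / "ground_truth.json", "w") as fh:
            json.dump(ground_truth_to_dict(gt), fh)
        with open(arm / "config.yaml", "w") as fh:
            snap = dataclasses.asdict(config)
            snap["condition"] = name
            yaml.safe_dump(snap, fh)
        paths[name] = arm
    return paths
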