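"""Rule-based 4-s-epoch vigilance-state scoring.

The classifier operationalises the conventional visual scoring criteria
for rodent sleep: wake = high EMG tone; NREM = low EMG with high-amplitude
frontal slow activity (0.5-4 Hz); REM = low EMG with occipital theta
(7-12.5 Hz) dominance.  Brief (1-4 epoch) waking intrusions flanked by
sleep are relabelled micro-arousals; runs of five or more stay wake.
Thresholds are auto-calibrated per recording from percentiles of the
epoch feature distributions, which makes the visual criteria reproducible
and documented.  Artefact flags are per epoch and per derivation and
never alter the state label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from ._filters import butter_bandpass_sos, swa_sos, zero_phase
from .recording import MA, NREM, REM, ROLES, WAKE, Hypnogram, Recording, epochs_of

SLEEP = (NREM, REM)


@dataclass
class ScoringThresholds:
    """Decision thresholds, all in the units of the epoch features.

    ``emg_hi``/``emg_lo`` split epochs into high-, mid- and low-EMG;
    ``swa_amp_min`` is the minimum frontal 0.5-4 Hz envelope for the slow-
    activity criterion; ``theta_dominance_min`` the minimum occipital
    theta/delta power ratio for REM; ``artefact_z`` the robust-z cutoff on
    epoch peak amplitude for artefact flagging.
    """

    emg_hi: float
    emg_lo: float
    swa_amp_min: float
    theta_dominance_min: float = 1.5
    artefact_z: float = 6.0

    def __post_init__(self) -> None:
        if not self.emg_lo < self.emg_hi:
            raise ValueError("require emg_lo < emg_hi")
        if min(self.emg_hi, self.emg_lo, self.swa_amp_min,
               self.theta_dominance_min, self.artefact_z) <= 0:
            raise ValueError("all thresholds must be positive")


def compute_epoch_features(recording: Recording, epoch_s: float = 4.0) -> pd.DataFrame:
    """Per-epoch features on half-open 4-s windows of a preprocessed
    256 Hz recording: EMG RMS, frontal SWA envelope amplitude (mean of the
    0.5-4 Hz analytic-signal magnitude), occipital theta and delta band
    power, and a saturation indicator per derivation."""
    fs = recording.fs
    if recording.duration < epoch_s:
        raise ValueError("recording shorter than one epoch")
    feats: dict[str, np.ndarray] = {}

    emg = recording.channels["emg"].data
    feats["emg_rms"] = np.sqrt(np.mean(epochs_of(emg, fs, epoch_s) ** 2, axis=1))

    frontal = recording.channels["frontal"].data
    swa = zero_phase(swa_sos(fs), frontal)
    env = np.abs(hilbert(swa))
    feats["frontal_swa_amp"] = np.mean(epochs_of(env, fs, epoch_s), axis=1)

    occ = recording.channels["occipital"].data
    theta = zero_phase(butter_bandpass_sos(fs, 7.0, 12.5), occ)
    delta = zero_phase(swa_sos(fs), occ)
    feats["occ_theta_power"] = np.mean(epochs_of(theta, fs, epoch_s) ** 2, axis=1)
    feats["occ_delta_power"] = np.mean(epochs_of(delta, fs, epoch_s) ** 2, axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = feats["occ_theta_power"] / feats["occ_delta_power"]
    ratio[~np.isfinite(ratio)] = 0.0
    feats["theta_dominance"] = ratio

    for role in ROLES:
        if role in recording.channels:
            feats[f"clip_{role}"] = _clipping_indicator(
                recording.channels[role].data, fs, epoch_s
            )
    return pd.DataFrame(feats)


def _clipping_indicator(data: np.ndarray, fs: float, epoch_s: float) -> np.ndarray:
    """True for epochs containing a saturation plateau: >= 3 consecutive
    samples pinned at the recording's extreme value."""
    ep = epochs_of(data, fs, epoch_s)
    lo, hi = data.min(), data.max()
    pinned = (ep >= hi) | (ep <= lo)
    runs = pinned[:, :-2] & pinned[:, 1:-1] & pinned[:, 2:]
    return runs.any(axis=1)


def calibrate_thresholds(features: pd.DataFrame) -> ScoringThresholds:
    """Per-recording auto-calibration of the EMG split.

    Epoch EMG RMS is strongly bimodal (sleep tone vs waking tone), so the
    wake threshold is placed between the two clusters found by a 2-means
    split of log EMG RMS (deterministic percentile initialisation).  This
    is robust to the wake/sleep mixture of the recording, unlike a fixed
    percentile, which mis-places the cut whenever time-in-state deviates
    from the calibration percentile.  ``emg_lo`` sits at 80% of ``emg_hi``
    (both inside the sleep-wake gap); ``swa_amp_min`` is the median
    frontal SWA envelope.  Falls back to a 60th-percentile cut for
    degenerate (near-constant) EMG.
    """
    from scipy.cluster.vq import kmeans2

    emg = features["emg_rms"].to_numpy(dtype=float)
    emg_hi = None
    pos = emg[emg > 0]
    if len(pos) >= 10 and np.ptp(np.log10(pos)) > 1e-6:
        logv = np.log10(pos)
        init = np.array([[np.percentile(logv, 25)], [np.percentile(logv, 90)]])
        cents, _ = kmeans2(logv.reshape(-1, 1), init, minit="matrix", seed=0)
        mid = float(10 ** cents.mean())
        if np.isfinite(mid) and mid > 0:
            emg_hi = mid
    if emg_hi is None:
        emg_hi = max(float(np.percentile(emg, 60)), 1e-6)
    return ScoringThresholds(
        emg_hi=emg_hi,
        emg_lo=0.8 * emg_hi,
        swa_amp_min=max(float(np.median(features["frontal_swa_amp"])), 1e-9),
    )


def classify_epochs(features: pd.DataFrame, thresholds: ScoringThresholds) -> np.ndarray:
    """Deterministic per-epoch rules, REM checked before NREM:

    WAKE if EMG RMS >= emg_hi; else REM if EMG RMS <= emg_lo and theta
    dominance >= theta_dominance_min; else NREM if EMG RMS <= emg_lo and
    the frontal SWA envelope >= swa_amp_min; every remaining non-wake
    epoch defaults to NREM.
    """
    emg = features["emg_rms"].to_numpy()
    theta_dom = features["theta_dominance"].to_numpy()
    swa = features["frontal_swa_amp"].to_numpy()
    labels = np.full(len(features), NREM, dtype=object)
    low = emg <= thresholds.emg_lo
    is_rem = low & (theta_dom >= thresholds.theta_dominance_min)
    labels[is_rem] = REM
    labels[~is_rem & low & (swa >= thresholds.swa_amp_min)] = NREM
    labels[emg >= thresholds.emg_hi] = WAKE
    return labels


def refine_microarousals(labels: np.ndarray) -> np.ndarray:
    """Relabel 1-4 epoch waking runs flanked by (NREM, NREM) or
    (REM, NREM) as micro-arousals; runs of >= 5 stay wake.  The rule is
    re-applied until fixpoint, so an epoch mistakenly scored one way on an
    earlier pass is corrected."""
    out = np.asarray(labels, dtype=object).copy()
    n = len(out)
    for _ in range(n + 1):
        prev = out.copy()
        # evaluate on WAKE/MA runs jointly so earlier relabels can be undone
        i = 0
        while i < n:
            if out[i] in (WAKE, MA):
                j = i
                while j < n and out[j] in (WAKE, MA):
                    j += 1
                run = j - i
                left = out[i - 1] if i > 0 else None
                right = out[j] if j < n else None
                sandwich = (
                    run <= 4
                    and left in SLEEP
                    and right == NREM
                )
                out[i:j] = MA if sandwich else WAKE
                i = j
            else:
                i += 1
        if np.array_equal(out, prev):
            break
    return out


def mark_artefacts(
    recording: Recording, thresholds: ScoringThresholds, epoch_s: float = 4.0
) -> pd.DataFrame:
    """Per-epoch, per-derivation artefact flags: an epoch is flagged when
    its peak absolute amplitude is a robust-z outlier (> artefact_z median
    absolute deviations above the median) or shows saturation."""
    flags = {}
    fs = recording.fs
    for role in ROLES:
        if role not in recording.channels:
            continue
        data = recording.channels[role].data
        peaks = np.max(np.abs(epochs_of(data, fs, epoch_s)), axis=1)
        med = np.median(peaks)
        mad = np.median(np.abs(peaks - med)) * 1.4826
        if mad == 0:
            z = np.zeros_like(peaks)
        else:
            z = (peaks - med) / mad
        flags[role] = (z > thresholds.artefact_z) | _clipping_indicator(data, fs, epoch_s)
    return pd.DataFrame(flags)


def score_recording(
    recording: Recording,
    thresholds: ScoringThresholds | None = None,
    epoch_s: float = 4.0,
) -> Hypnogram:
    """Full scoring pass: features -> (auto-calibrated) thresholds ->
    epoch rules -> micro-arousal refinement -> artefact flags."""
    features = compute_epoch_features(recording, epoch_s)
    if thresholds is None:
        thresholds = calibrate_thresholds(features)
    labels = refine_microarousals(classify_epochs(features, thresholds))
    artefact = mark_artefacts(recording, thresholds, epoch_s)
    return Hypnogram(labels, epoch_s, artefact=artefact)


def agreement(
    predicted: np.ndarray, truth: np.ndarray, exclude_ma: bool = True
) -> float:
    """Fraction of epochs on which two label sequences agree; micro-
    arousal epochs (in either sequence) are excluded by default because
    ground truth defines them only up to the scoring rules."""
    predicted = np.asarray(predicted, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if len(predicted) != len(truth):
        raise ValueError("label sequences differ in length")
    keep = np.ones(len(truth), dtype=bool)
    if exclude_ma:
        keep = (predicted != MA) & (truth != MA)
    if keep.sum() == 0:
        raise ValueError("no epochs left after exclusions")
    return float(np.mean(predicted[keep] == truth[keep]))
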