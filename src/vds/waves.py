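"""LFP slow-wave detection and peri-wave multi-unit OFF-period profiling.

A slow wave is a maximal positive excursion of the 0.5-4 Hz filtered LFP
bounded by zero crossings, accepted only when the immediately preceding
and following excursions both dip below zero.  Wave amplitude is the
positive peak of the filtered signal; duration spans the bounding zero
crossings of the positive excursion (the flanking sub-zero requirement is
a gate, not part of the span).  All detected waves feed the amplitude and
duration distributions; only waves whose peak exceeds the mean plus two
standard deviations of all detected amplitudes enter the multi-unit
analysis, where waves are aligned on their positive peak and the average
spike-rate profile (and its trough) is computed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._filters import swa_sos, zero_phase
from .recording import Hypnogram


@dataclass
class SlowWaveEvent:
    onset_t: float
    peak_t: float
    offset_t: float
    amplitude: float  # µV, filtered-signal positive peak
    state: str | None = None

    def __post_init__(self) -> None:
        if not (self.onset_t < self.peak_t < self.offset_t):
            raise ValueError("require onset < peak < offset")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")

    @property
    def duration(self) -> float:
        return self.offset_t - self.onset_t


@dataclass
class OffPeriodProfile:
    lags_ms: np.ndarray
    rates_hz: np.ndarray
    n_events: int
    trough_lag_ms: float
    trough_rate_hz: float

    def baseline_rate(self, outer_ms: float = 300.0) -> float:
        sel = np.abs(self.lags_ms) > outer_ms
        return float(self.rates_hz[sel].mean()) if sel.any() else float(self.rates_hz.mean())

    def trough_width_ms(self, rel: float = 0.5) -> float:
        """Span of the contiguous region around the minimum-rate bin where
        the rate stays below ``rel`` times the outer-lag baseline rate
        (isolated Poisson dips away from the trough are not counted)."""
        base = self.baseline_rate()
        if base <= 0:
            return 0.0
        below = self.rates_hz < rel * base
        k = int(np.argmin(self.rates_hz))
        if not below[k]:
            return 0.0
        i = j = k
        while i > 0 and below[i - 1]:
            i -= 1
        while j < len(below) - 1 and below[j + 1]:
            j += 1
        bin_ms = self.lags_ms[1] - self.lags_ms[0]
        return float((j - i + 1) * bin_ms)


def filter_swa(data: np.ndarray, fs: float) -> np.ndarray:
    """Zero-phase Chebyshev II slow-wave band-pass (passband 0.5-4 Hz,
    stopband edges 0.2/8 Hz, 40 dB)."""
    sos = swa_sos(fs)
    if len(data) < 3 * (2 * sos.shape[0] + 1):
        raise ValueError("signal too short for the slow-wave filter")
    return zero_phase(sos, data)


def detect_waves_indices(filtered: np.ndarray) -> list[tuple[int, int, int]]:
    """Vectorised wave detection on a filtered signal.

    Returns (start, peak, end) sample triples where ``[start, end)`` is a
    maximal run of strictly positive samples whose neighbouring
    excursions both contain strictly negative samples, and ``peak`` is the
    argmax within the run.  Events are non-overlapping and time-ordered.
    """
    x = np.asarray(filtered, dtype=float)
    if len(x) == 0:
        return []
    pos = x > 0
    diff = np.diff(pos.astype(np.int8))
    starts = np.flatnonzero(diff == 1) + 1
    ends = np.flatnonzero(diff == -1) + 1
    if pos[0]:
        starts = np.concatenate([[0], starts])
    if pos[-1]:
        ends = np.concatenate([ends, [len(x)]])
    # prefix count of strictly negative samples, for O(1) range queries
    negcum = np.concatenate([[0], np.cumsum(x < 0)])
    events: list[tuple[int, int, int]] = []
    for i, (s, e) in enumerate(zip(starts, ends)):
        prev_end = ends[i - 1] if i > 0 else 0  # gap before this positive run
        next_start = starts[i + 1] if i + 1 < len(starts) else len(x)
        has_neg_before = negcum[s] - negcum[prev_end] > 0
        has_neg_after = negcum[next_start] - negcum[e] > 0
        if has_neg_before and has_neg_after:
            peak = s + int(np.argmax(x[s:e]))
            events.append((int(s), peak, int(e)))
    return events


def detect_waves_bruteforce(filtered: np.ndarray) -> list[tuple[int, int, int]]:
    """Sample-by-sample oracle for wave detection: exhaustive scan over
    sign changes, independent of the vectorised implementation."""
    x = np.asarray(filtered, dtype=float)
    events = []
    n = len(x)
    i = 0
    while i < n:
        if x[i] > 0:
            s = i
            while i < n and x[i] > 0:
                i += 1
            e = i
            # scan left from s for a negative sample before any positive one
            j = s - 1
            neg_before = False
            while j >= 0:
                if x[j] < 0:
                    neg_before = True
                    break
                if x[j] > 0:
                    break
                j -= 1
            j = e
            neg_after = False
            while j < n:
                if x[j] < 0:
                    neg_after = True
                    break
                if x[j] > 0:
                    break
                j += 1
            if neg_before and neg_after:
                peak = s
                for k in range(s, e):
                    if x[k] > x[peak]:
                        peak = k
                events.append((s, peak, e))
        else:
            i += 1
    return events


def _interp_crossing(x: np.ndarray, idx: int, fs: float, rising: bool) -> float:
    """Sub-sample zero-crossing time just before sample ``idx`` (rising)
    or just after the last positive sample (falling)."""
    if rising:
        if idx == 0 or x[idx - 1] >= 0:
            return idx / fs
        a, b = x[idx - 1], x[idx]
        return (idx - 1 + (-a) / (b - a)) / fs
    if idx >= len(x) or x[idx] >= 0:
        return (idx - 1) / fs if idx > 0 else 0.0
    a, b = x[idx - 1], x[idx]
    return (idx - 1 + a / (a - b)) / fs


def detect_waves(filtered: np.ndarray, fs: float, hypnogram: Hypnogram | None = None) -> list[SlowWaveEvent]:
    """Slow-wave events with interpolated onset/offset times.  With a
    hypnogram, each wave is attributed to the state of the epoch
    containing its peak."""
    x = np.asarray(filtered, dtype=float)
    events = []
    for s, p, e in detect_waves_indices(x):
        onset = _interp_crossing(x, s, fs, rising=True)
        offset = _interp_crossing(x, e, fs, rising=False)
        state = None
        if hypnogram is not None:
            k = int((p / fs) // hypnogram.epoch_s)
            if k < hypnogram.n_epochs:
                state = str(hypnogram.labels[k])
        if offset <= p / fs:
            offset = (p + 1) / fs
        if onset >= p / fs:
            onset = max(0.0, (p - 1) / fs)
        events.append(SlowWaveEvent(onset, p / fs, offset, float(x[p]), state))
    return events


def select_high_amplitude(events: list[SlowWaveEvent]) -> list[SlowWaveEvent]:
    """Waves whose peak amplitude strictly exceeds the mean plus two
    (population) standard deviations of all detected amplitudes."""
    if len(events) < 2:
        raise ValueError("need at least two events to form the amplitude criterion")
    amps = np.array([e.amplitude for e in events])
    threshold = amps.mean() + 2.0 * amps.std()
    return [e for e in events if e.amplitude > threshold]


def amplitude_threshold(events: list[SlowWaveEvent]) -> float:
    amps = np.array([e.amplitude for e in events])
    return float(amps.mean() + 2.0 * amps.std())


def wave_distributions(
    events: list[SlowWaveEvent],
    amp_edges: np.ndarray,
    dur_edges: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalised amplitude and duration histograms (each sums to 1)."""
    if not events:
        raise ValueError("no events to histogram")
    amps = np.array([e.amplitude for e in events])
    durs = np.array([e.duration for e in events])
    ha, _ = np.histogram(amps, bins=amp_edges)
    hd, _ = np.histogram(durs, bins=dur_edges)
    return ha / len(events), hd / len(events)


def match_events(
    detected_peaks: np.ndarray, truth_peaks: np.ndarray, tol_s: float = 0.15
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy nearest-neighbour matching of detected wave peaks to known
    (injected) peaks within ``tol_s``.  Returns boolean masks
    (truth_matched, detected_matched)."""
    detected_peaks = np.asarray(detected_peaks, dtype=float)
    truth_peaks = np.asarray(truth_peaks, dtype=float)
    t_matched = np.zeros(len(truth_peaks), dtype=bool)
    d_matched = np.zeros(len(detected_peaks), dtype=bool)
    for i, t in enumerate(truth_peaks):
        if not len(detected_peaks):
            break
        d = np.abs(detected_peaks - t)
        d[d_matched] = np.inf
        j = int(np.argmin(d))
        if d[j] <= tol_s:
            t_matched[i] = True
            d_matched[j] = True
    return t_matched, d_matched


def peri_event_mua(
    events: list[SlowWaveEvent] | np.ndarray,
    spike_times: np.ndarray,
    window_ms: float = 500.0,
    bin_ms: float = 5.0,
) -> OffPeriodProfile:
    """Average spike-rate profile in lag bins around wave positive peaks.

    ``events`` may be SlowWaveEvent objects or an array of peak times.
    An empty spike train yields an all-zero profile.
    """
    if isinstance(events, np.ndarray) or (events and isinstance(events[0], (float, np.floating))):
        peaks = np.asarray(events, dtype=float)
    else:
        peaks = np.array([e.peak_t for e in events], dtype=float)
    if len(peaks) == 0:
        raise ValueError("no events for the peri-event profile")
    spikes = np.asarray(spike_times, dtype=float)
    w = window_ms / 1000.0
    b = bin_ms / 1000.0
    n_bins = int(round(2 * w / b))
    edges = np.linspace(-w, w, n_bins + 1)
    counts = np.zeros(n_bins)
    for p in peaks:
        i0, i1 = np.searchsorted(spikes, [p - w, p + w])
        if i1 > i0:
            counts += np.histogram(spikes[i0:i1] - p, bins=edges)[0]
    rates = counts / (len(peaks) * b)
    lags = (edges[:-1] + edges[1:]) / 2 * 1000.0
    minr = float(rates.min())
    k = int(np.argmin(rates))
    # trough centre: deficit-weighted centroid of the contiguous region
    # below half the outer-lag baseline around the minimum-rate bin (the
    # edges of the raw zero-count run are dominated by single-spike
    # Poisson noise; the deficit centroid is far more stable)
    outer = np.abs(lags) > 300.0
    base = float(rates[outer].mean()) if outer.any() else float(rates.mean())
    centre = float(lags[k])
    if base > 0 and minr < 0.5 * base:
        i = j = k
        while i > 0 and rates[i - 1] < 0.5 * base:
            i -= 1
        while j < n_bins - 1 and rates[j + 1] < 0.5 * base:
            j += 1
        deficit = base - rates[i : j + 1]
        centre = float(np.sum(lags[i : j + 1] * deficit) / np.sum(deficit))
    return OffPeriodProfile(lags, rates, len(peaks), centre, minr)
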