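"""Sleep-architecture and condition-contrast endpoints.

Time-in-state accounting, REM latency from injection, cumulative state
curves, frontal SWA dynamics from the first post-injection NREM episode,
and per-frequency-bin paired condition contrasts with significance runs.
The per-bin contrast uses uncorrected paired two-sided tests (the
per-frequency post-hoc convention), with a sign-flip permutation option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .recording import MA, NREM, REM, STATES, WAKE, Hypnogram
from .spectral import BandDefinition, EpochSpectra, band_power


@dataclass
class ArchitectureSummary:
    """Per-interval minutes in each state plus headline latencies."""

    table: pd.DataFrame  # columns: interval_start_s + minutes per state
    rem_latency_s: float | None = None
    first_nrem_onset_s: float | None = None


def state_time_per_interval(hypnogram: Hypnogram, interval_s: float) -> pd.DataFrame:
    """Minutes per state per interval (micro-arousal counted as its own
    category).  ``interval_s`` must be a multiple of the epoch length; a
    trailing partial interval is included, so totals conserve recording
    duration."""
    eps = hypnogram.epoch_s
    if abs(interval_s / eps - round(interval_s / eps)) > 1e-9:
        raise ValueError("interval must be a multiple of the epoch length")
    per = int(round(interval_s / eps))
    n = hypnogram.n_epochs
    rows = []
    for i0 in range(0, n, per):
        chunk = hypnogram.labels[i0 : i0 + per]
        row = {"interval_start_s": i0 * eps}
        for s in STATES:
            row[s] = float(np.sum(chunk == s)) * eps / 60.0
        rows.append(row)
    return pd.DataFrame(rows)


def rem_latency(hypnogram: Hypnogram, injection_t: float) -> float | None:
    """Seconds from injection to the start of the first REM epoch at or
    after the injection; None if none occurs."""
    if injection_t > hypnogram.n_epochs * hypnogram.epoch_s:
        raise ValueError("injection time beyond recording end")
    starts = hypnogram.epoch_times()
    sel = (hypnogram.labels == REM) & (starts >= injection_t)
    idx = np.flatnonzero(sel)
    if len(idx) == 0:
        return None
    return float(starts[idx[0]] - injection_t)


def cumulative_state(
    hypnogram: Hypnogram, state: str, horizon_h: float | None = None, interval_s: float = 600.0
) -> tuple[np.ndarray, np.ndarray]:
    """Running minutes spent in ``state``, sampled at interval ends.
    Returns (t_seconds, cumulative_minutes); the curve is non-decreasing
    and its final value equals total state time."""
    eps = hypnogram.epoch_s
    n = hypnogram.n_epochs
    if horizon_h is not None:
        n = min(n, int(horizon_h * 3600 / eps))
    in_state = (hypnogram.labels[:n] == state).astype(float) * eps / 60.0
    cum = np.cumsum(in_state)
    per = max(int(round(interval_s / eps)), 1)
    idx = np.arange(per - 1, n, per)
    if len(idx) == 0 or idx[-1] != n - 1:
        idx = np.concatenate([idx, [n - 1]])
    return (idx + 1) * eps, cum[idx]


def find_first_nrem_episode(
    hypnogram: Hypnogram,
    injection_t: float,
    episode_min_epochs: int = 15,
    max_interruption: int = 1,
) -> int | None:
    """Index of the first epoch of the first post-injection NREM episode:
    at least ``episode_min_epochs`` NREM epochs tolerating at most
    ``max_interruption`` interrupting epochs; None if no episode
    qualifies."""
    labels = hypnogram.labels
    start_epoch = int(np.ceil(injection_t / hypnogram.epoch_s))
    n = hypnogram.n_epochs
    for k in range(start_epoch, n):
        if labels[k] != NREM:
            continue
        interruptions = 0
        count = 0
        j = k
        while j < n:
            if labels[j] == NREM:
                count += 1
            else:
                interruptions += 1
                if interruptions > max_interruption:
                    break
            if count >= episode_min_epochs:
                return k
            j += 1
        if count >= episode_min_epochs:
            return k
    return None


def swa_dynamics_from_first_nrem(
    spectra: EpochSpectra,
    hypnogram: Hypnogram,
    injection_t: float,
    reference: float,
    band: BandDefinition | None = None,
    episode_min_epochs: int = 15,
) -> tuple[float, np.ndarray] | None:
    """SWA per NREM epoch from the onset of the first qualifying post-
    injection NREM episode, as percent of ``reference`` (typically the
    per-subject baseline-day NREM SWA mean).  Returns (onset_s, series),
    or None with no qualifying episode."""
    if band is None:
        band = BandDefinition("swa", 0.5, 4.0)
    if reference <= 0:
        raise ValueError("reference must be positive")
    onset = find_first_nrem_episode(hypnogram, injection_t, episode_min_epochs)
    if onset is None:
        return None
    bp = band_power(spectra, band)
    ok = (hypnogram.labels == NREM) & ~hypnogram.is_artefact(spectra.derivation or "frontal")
    sel = np.flatnonzero(ok[onset:]) + onset
    return float(onset * hypnogram.epoch_s), bp[sel] / reference * 100.0


@dataclass
class SpectraContrast:
    """Per-frequency-bin paired contrast between two conditions."""

    freqs: np.ndarray
    mean_a: np.ndarray
    mean_b: np.ndarray
    statistic: np.ndarray
    p_value: np.ndarray
    significant: np.ndarray
    runs: list  # maximal contiguous significant (f_lo, f_hi) spans
    alpha: float = 0.05


def _significant_runs(freqs: np.ndarray, sig: np.ndarray) -> list[tuple[float, float]]:
    runs = []
    i = 0
    n = len(sig)
    while i < n:
        if sig[i]:
            j = i
            while j < n and sig[j]:
                j += 1
            runs.append((float(freqs[i]), float(freqs[j - 1])))
            i = j
        else:
            i += 1
    return runs


def spectra_contrast(
    subjects_a: np.ndarray,
    subjects_b: np.ndarray,
    freqs: np.ndarray,
    alpha: float = 0.05,
    method: str = "ttest",
    n_permutations: int = 1000,
    rng: np.random.Generator | None = None,
) -> SpectraContrast:
    """Per-bin paired contrast of within-subject mean power.

    ``subjects_a``/``subjects_b`` are (n_subjects, n_bins) arrays of
    per-subject mean power, paired by row.  ``method`` is "ttest" (paired
    two-sided t, uncorrected) or "permutation" (sign-flip null of the
    paired difference).
    """
    a = np.asarray(subjects_a, dtype=float)
    b = np.asarray(subjects_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("condition arrays must have the same shape")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 paired subjects")
    diff = a - b
    if method == "ttest":
        t, p = stats.ttest_rel(a, b, axis=0)
    elif method == "permutation":
        if rng is None:
            rng = np.random.default_rng(0)
        obs = diff.mean(axis=0)
        signs = rng.choice([-1.0, 1.0], size=(n_permutations, a.shape[0]))
        null = signs @ diff / a.shape[0]
        p = (np.sum(np.abs(null) >= np.abs(obs)[None, :], axis=0) + 1) / (n_permutations + 1)
        t = obs / (diff.std(axis=0, ddof=1) / np.sqrt(a.shape[0]) + 1e-300)
    else:
        raise ValueError(f"unknown method {method!r}")
    sig = np.asarray(p) < alpha
    return SpectraContrast(
        freqs=np.asarray(freqs, dtype=float),
        mean_a=a.mean(axis=0),
        mean_b=b.mean(axis=0),
        statistic=np.asarray(t, dtype=float),
        p_value=np.asarray(p, dtype=float),
        significant=sig,
        runs=_significant_runs(np.asarray(freqs), sig),
        alpha=alpha,
    )


def architecture_summary(
    hypnogram: Hypnogram, injection_t: float | None = None, interval_s: float = 3600.0
) -> ArchitectureSummary:
    table = state_time_per_interval(hypnogram, interval_s)
    lat = rem_latency(hypnogram, injection_t) if injection_t is not None else None
    onset_idx = (
        find_first_nrem_episode(hypnogram, injection_t) if injection_t is not None else None
    )
    onset = None if onset_idx is None else onset_idx * hypnogram.epoch_s
    return ArchitectureSummary(table, rem_latency_s=lat, first_nrem_onset_s=onset)
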