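"""Per-epoch spectra, band power, aperiodic slope and phase-amplitude
coupling.

Spectra are Hanning-windowed periodograms of 4-s epochs at 256 Hz, giving
exactly 0.25 Hz bins; the exported range is 0-120 Hz (481 bins).  The
density scaling is window-corrected so band-summed power equals signal
variance.  The aperiodic "spectral slope" is an ordinary least-squares
straight line through log10(power) against frequency in Hz over
20-120 Hz (linear-log space); a companion log-log fit recovers the 1/f
power-law exponent itself.  Cross-frequency coupling uses the
entropy-based modulation index (18 phase bins, third-order Butterworth
zero-phase band-passing, analytic-signal phase/envelope).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy.signal import hilbert

from ._filters import butter_bandpass_sos, zero_phase
from .recording import Hypnogram, Recording, epochs_of

N_BINS = 481  # 0..120 Hz at 0.25 Hz
DF = 0.25


@dataclass
class BandDefinition:
    """A frequency band with inclusive edges (both edge bins counted)."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.lo < self.hi <= 120):
            raise ValueError(f"band {self.name}: need 0 <= lo < hi <= 120")


#: standard band definitions; analysis theta is the scoring-range
#: definition (7-12.5 Hz), configurable per call.
SWA_BAND = BandDefinition("swa", 0.5, 4.0)
THETA_BAND = BandDefinition("theta", 7.0, 12.5)
SIGMA_BAND = BandDefinition("sigma", 10.0, 15.0)


@dataclass
class EpochSpectra:
    """Per-epoch power (µV²) at 0.25 Hz bins from 0 to 120 Hz."""

    freqs: np.ndarray
    power: np.ndarray  # (n_epochs, 481)
    derivation: str = ""
    epoch_s: float = 4.0

    def __post_init__(self) -> None:
        if self.power.ndim != 2 or self.power.shape[1] != N_BINS:
            raise ValueError(f"power must be (n_epochs, {N_BINS})")
        if np.any(self.power < 0):
            raise ValueError("power must be non-negative")

    @property
    def n_epochs(self) -> int:
        return self.power.shape[0]


@dataclass
class SlopeFit:
    slope: float  # log10-power units per Hz
    intercept: float
    fit_range: tuple = (20.0, 120.0)
    residual_rms: float = 0.0


@dataclass
class Comodulogram:
    phase_freqs: np.ndarray
    amp_freqs: np.ndarray
    mi: np.ndarray  # (n_phase, n_amp)
    n_phase_bins: int = 18


def epoch_spectra(
    recording_or_data: Recording | np.ndarray,
    derivation: str = "frontal",
    fs: float = 256.0,
    epoch_s: float = 4.0,
) -> EpochSpectra:
    """Hanning-windowed per-epoch periodogram with 0.25 Hz resolution.

    Accepts a Recording (picking ``derivation``) or a raw 256 Hz array.
    The window power correction makes band-summed power match signal
    variance (Parseval) for both noise and sinusoids.
    """
    if isinstance(recording_or_data, Recording):
        ch = recording_or_data.channels[derivation]
        data, fs = ch.data, ch.fs
    else:
        data = np.asarray(recording_or_data, dtype=float)
    if abs(fs - 256.0) > 1e-9:
        raise ValueError(f"epoch spectra require 256 Hz input, got {fs}")
    ep = epochs_of(data, fs, epoch_s)
    nper = ep.shape[1]
    freqs, psd = sps.periodogram(
        ep, fs=fs, window="hann", nfft=nper, detrend=False, scaling="density", axis=-1
    )
    power = psd * (freqs[1] - freqs[0])  # µV² per bin
    keep = freqs <= 120.0 + 1e-9
    return EpochSpectra(freqs[keep], power[:, keep], derivation=derivation, epoch_s=epoch_s)


def band_indices(freqs: np.ndarray, band: BandDefinition) -> np.ndarray:
    return np.flatnonzero((freqs >= band.lo - 1e-9) & (freqs <= band.hi + 1e-9))


def band_power(spectra: EpochSpectra, band: BandDefinition) -> np.ndarray:
    """Per-epoch power summed over the band's bins (edges inclusive)."""
    return spectra.power[:, band_indices(spectra.freqs, band)].sum(axis=1)


def band_power_timecourse(
    spectra: EpochSpectra,
    hypnogram: Hypnogram,
    band: BandDefinition,
    state_filter: str | None = None,
    bin_minutes: float = 10.0,
    reference: float | None = None,
) -> np.ndarray:
    """Mean band power over artefact-free epochs of the given state per
    time bin; bins with no qualifying epoch are NaN.  With ``reference``
    the values are expressed as percent of it."""
    if spectra.n_epochs != hypnogram.n_epochs:
        raise ValueError("spectra and hypnogram are not aligned")
    bp = band_power(spectra, band)
    ok = ~hypnogram.is_artefact(spectra.derivation) if spectra.derivation else np.ones(len(bp), bool)
    if state_filter is not None:
        ok &= hypnogram.labels == state_filter
    epochs_per_bin = int(round(bin_minutes * 60 / hypnogram.epoch_s))
    n_bins = int(np.ceil(len(bp) / epochs_per_bin))
    out = np.full(n_bins, np.nan)
    for b in range(n_bins):
        sel = ok[b * epochs_per_bin : (b + 1) * epochs_per_bin]
        vals = bp[b * epochs_per_bin : (b + 1) * epochs_per_bin][sel]
        if len(vals):
            out[b] = vals.mean()
    if reference is not None:
        if reference <= 0:
            raise ValueError("reference must be positive")
        out = out / reference * 100.0
    return out


def fit_spectral_slope(
    freqs: np.ndarray, power: np.ndarray, fit_range: tuple = (20.0, 120.0)
) -> SlopeFit:
    """OLS straight line through log10(power) vs frequency (Hz) over the
    fit range — the linear-log aperiodic slope convention."""
    sel = (freqs >= fit_range[0] - 1e-9) & (freqs <= fit_range[1] + 1e-9)
    f = freqs[sel]
    p = np.asarray(power, dtype=float)[sel]
    if np.any(p <= 0):
        raise ValueError("power must be strictly positive on the fit range")
    y = np.log10(p)
    slope, intercept = _ols(f, y)
    resid = y - (slope * f + intercept)
    return SlopeFit(float(slope), float(intercept), fit_range, float(np.sqrt(np.mean(resid**2))))


def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    # centred form: exactly zero slope for constant y
    xc = x - x.mean()
    yc = y - y.mean()
    slope = float(np.dot(xc, yc) / np.dot(xc, xc))
    return slope, float(y.mean() - slope * x.mean())


def estimate_background_exponent(
    freqs: np.ndarray, power: np.ndarray, fit_range: tuple = (20.0, 120.0)
) -> float:
    """Power-law exponent chi of a 1/f^chi background, from OLS in log-log
    space over the same 20-120 Hz range used for the linear-log slope."""
    sel = (freqs >= fit_range[0] - 1e-9) & (freqs <= fit_range[1] + 1e-9) & (freqs > 0)
    p = np.asarray(power, dtype=float)[sel]
    if np.any(p <= 0):
        raise ValueError("power must be strictly positive on the fit range")
    slope, _ = _ols(np.log10(freqs[sel]), np.log10(p))
    return float(-slope)


def phase_amplitude_mi(phase: np.ndarray, amplitude: np.ndarray, n_bins: int = 18) -> float:
    """Entropy-based modulation index of an amplitude series against a
    phase series: mean amplitude per phase bin, normalized to a
    distribution P; MI = (log N - H(P)) / log N, in [0, 1]."""
    phase = np.mod(np.asarray(phase, dtype=float), 2 * np.pi)
    amplitude = np.asarray(amplitude, dtype=float)
    edges = np.linspace(0, 2 * np.pi, n_bins + 1)
    idx = np.clip(np.digitize(phase, edges) - 1, 0, n_bins - 1)
    means = np.zeros(n_bins)
    np.add.at(means, idx, amplitude)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    nz = counts > 0
    means[nz] /= counts[nz]
    total = means.sum()
    if total <= 0:
        return 0.0
    p = means / total
    pnz = p[p > 0]
    entropy = -np.sum(pnz * np.log(pnz))
    return float(max((np.log(n_bins) - entropy) / np.log(n_bins), 0.0))


def modulation_index(
    data: np.ndarray,
    fs: float,
    phase_band: tuple,
    amp_band: tuple,
    n_bins: int = 18,
) -> float:
    """Tort-style MI: zero-phase third-order Butterworth band-passes, the
    slow band's instantaneous phase and the fast band's amplitude envelope
    via the analytic signal, then the entropy-based index."""
    nyq = fs / 2.0
    if phase_band[1] >= nyq or amp_band[1] >= nyq:
        raise ValueError("band edges must lie below Nyquist")
    if len(data) < 10 * fs / phase_band[0]:
        raise ValueError("need at least 10 cycles of the phase frequency")
    slow = zero_phase(butter_bandpass_sos(fs, *phase_band), data)
    fast = zero_phase(butter_bandpass_sos(fs, *amp_band), data)
    phase = np.angle(hilbert(slow))
    amplitude = np.abs(hilbert(fast))
    return phase_amplitude_mi(phase, amplitude, n_bins)


def comodulogram(
    data: np.ndarray,
    fs: float,
    phase_range: tuple = (1.5, 10.5),
    amp_range: tuple = (0.25, 100.5),
    phase_step: float = 1.0,
    phase_bw: float = 0.5,
    amp_step: float = 5.0,
    amp_bw: float = 5.0,
    n_bins: int = 18,
) -> Comodulogram:
    """MI on a grid of phase (1.5-10.5 Hz) x amplitude (0.25-100.5 Hz)
    band centres; grid steps and bandwidths are configuration values."""
    if len(data) < 60 * fs:
        raise ValueError("comodulogram requires at least 60 s of signal")
    nyq = fs / 2.0
    pf = np.arange(phase_range[0] + phase_bw, phase_range[1] - phase_bw + 1e-9, phase_step)
    af = np.arange(max(amp_range[0] + amp_bw, 2.5), min(amp_range[1] - amp_bw, 0.98 * nyq), amp_step)
    mi = np.zeros((len(pf), len(af)))
    for i, p0 in enumerate(pf):
        slow = zero_phase(butter_bandpass_sos(fs, p0 - phase_bw, p0 + phase_bw), data)
        phase = np.angle(hilbert(slow))
        for j, a0 in enumerate(af):
            fast = zero_phase(butter_bandpass_sos(fs, a0 - amp_bw, a0 + amp_bw), data)
            amplitude = np.abs(hilbert(fast))
            mi[i, j] = phase_amplitude_mi(phase, amplitude, n_bins)
    return Comodulogram(pf, af, mi, n_bins)
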