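"""Shared zero-phase filter designs.

All band-pass prefilters are Chebyshev Type II (flat, monotonic passband;
equiripple stopband) applied forward-backward (``sosfiltfilt``), so the net
response is the squared magnitude with zero phase distortion.  Designs are
minimum-order for 40 dB stopband attenuation and at most 3 dB passband
deviation.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy import signal


@lru_cache(maxsize=32)
def cheby2_bandpass_sos(
    fs: float,
    pass_lo: float,
    pass_hi: float,
    stop_lo: float,
    stop_hi: float,
    gpass: float = 3.0,
    gstop: float = 40.0,
) -> np.ndarray:
    nyq = fs / 2.0
    if pass_hi >= nyq:
        raise ValueError(f"passband edge {pass_hi} Hz not below Nyquist ({nyq} Hz)")
    wp = [pass_lo / nyq, pass_hi / nyq]
    ws = [stop_lo / nyq, stop_hi / nyq]
    n, wn = signal.cheb2ord(wp, ws, gpass, gstop)
    return signal.cheby2(n, gstop, wn, btype="bandpass", output="sos")


def swa_sos(fs: float) -> np.ndarray:
    """Slow-wave band-pass: passband 0.5-4 Hz, stopband edges 0.2/8 Hz."""
    return cheby2_bandpass_sos(fs, 0.5, 4.0, 0.2, 8.0)


def eeg_prefilter_sos(fs: float) -> np.ndarray:
    """Acquisition prefilter for EEG/LFP: passband 0.5-120 Hz.

    Stopband edges are half the lower passband edge and 1.15x the upper one,
    capped just below Nyquist (only the passband edges are fixed by the
    acquisition convention; the transition bands are a design choice).
    """
    nyq = fs / 2.0
    stop_hi = min(120.0 * 1.15, 0.995 * nyq)
    return cheby2_bandpass_sos(fs, 0.5, 120.0, 0.25, stop_hi)


def emg_prefilter_sos(fs: float) -> np.ndarray:
    """Acquisition prefilter for EMG: passband 10-45 Hz."""
    nyq = fs / 2.0
    stop_hi = min(45.0 * 1.5, 0.995 * nyq)
    return cheby2_bandpass_sos(fs, 10.0, 45.0, 5.0, stop_hi)


def butter_bandpass_sos(fs: float, lo: float, hi: float, order: int = 3) -> np.ndarray:
    """Third-order Butterworth band-pass (phase-amplitude coupling convention)."""
    nyq = fs / 2.0
    return signal.butter(order, [lo / nyq, hi / nyq], btype="bandpass", output="sos")


def zero_phase(sos: np.ndarray, x: np.ndarray) -> np.ndarray:
    return signal.sosfiltfilt(sos, x)
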