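"""Core in-memory containers for multichannel recordings and hypnograms.

Conventions used throughout the package: time is in seconds from recording
start, sample indexing is 0-based, and epoch ``k`` covers the half-open
interval ``[k * epoch_s, (k + 1) * epoch_s)``.  Signal amplitudes are in
microvolts (µV).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Vigilance-state labels.  MA = micro-arousal (brief waking intrusion
#: between sleep epochs, scored separately from wake).
WAKE = "WAKE"
NREM = "NREM"
REM = "REM"
MA = "MA"
STATES = (WAKE, NREM, REM, MA)

#: Channel roles the pipeline understands.
ROLES = ("frontal", "occipital", "emg", "lfp")


@dataclass
class Channel:
    """One sampled signal: ``label`` is the on-disk channel name, ``data``
    the samples in µV, ``fs`` the sampling rate in Hz."""

    label: str
    data: np.ndarray
    fs: float

    @property
    def duration(self) -> float:
        return len(self.data) / self.fs


@dataclass
class Recording:
    """A multichannel recording with optional spikes and pupil trace.

    ``channels`` maps a role from :data:`ROLES` to a :class:`Channel`.
    ``spike_times`` are multi-unit spike times in seconds, sorted.
    ``pupil`` is a frame-wise DataFrame (see :mod:`vds.pupil`).
    ``t0_zt`` is the Zeitgeber time of the first sample, in hours.
    """

    channels: dict[str, Channel] = field(default_factory=dict)
    spike_times: np.ndarray | None = None
    pupil: pd.DataFrame | None = None
    t0_zt: float = 0.0
    condition: str = "vehicle"
    injection_t: float | None = None

    def __post_init__(self) -> None:
        for role in self.channels:
            if role not in ROLES:
                raise ValueError(f"unknown channel role {role!r}; expected one of {ROLES}")
        if self.spike_times is not None:
            st = np.asarray(self.spike_times, dtype=float)
            if np.any(np.diff(st) < 0):
                raise ValueError("spike times must be sorted")
            if len(st) and (st[0] < 0 or st[-1] > self.duration + 1e-9):
                raise ValueError("spike times must lie within [0, duration]")
            self.spike_times = st

    @property
    def fs(self) -> float:
        return next(iter(self.channels.values())).fs

    @property
    def duration(self) -> float:
        if not self.channels:
            return 0.0
        return min(ch.duration for ch in self.channels.values())

    def copy(self) -> "Recording":
        return Recording(
            channels={r: Channel(c.label, c.data.copy(), c.fs) for r, c in self.channels.items()},
            spike_times=None if self.spike_times is None else self.spike_times.copy(),
            pupil=None if self.pupil is None else self.pupil.copy(),
            t0_zt=self.t0_zt,
            condition=self.condition,
            injection_t=self.injection_t,
        )


@dataclass
class Hypnogram:
    """Per-epoch vigilance-state labels with per-derivation artefact flags.

    ``labels`` is an array of strings from :data:`STATES`.  ``artefact`` is a
    boolean DataFrame with one row per epoch and one column per derivation;
    artefact flags mark epochs for exclusion from spectral analyses but never
    alter the state label itself.
    """

    labels: np.ndarray
    epoch_s: float = 4.0
    artefact: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        bad = set(self.labels) - set(STATES)
        if bad:
            raise ValueError(f"unknown state label(s): {sorted(map(str, bad))}")
        if self.artefact is not None and len(self.artefact) != len(self.labels):
            raise ValueError("artefact table must have one row per epoch")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_epochs(self) -> int:
        return len(self.labels)

    def epoch_times(self) -> np.ndarray:
        """Start time of each epoch in seconds."""
        return np.arange(self.n_epochs) * self.epoch_s

    def is_artefact(self, derivation: str) -> np.ndarray:
        if self.artefact is None:
            return np.zeros(self.n_epochs, dtype=bool)
        return self.artefact[derivation].to_numpy(dtype=bool)


def epochs_of(data: np.ndarray, fs: float, epoch_s: float) -> np.ndarray:
    """Reshape a 1-D signal into (n_epochs, samples_per_epoch), dropping any
    trailing partial epoch.  Raises if ``fs * epoch_s`` is not integral."""
    spe = fs * epoch_s
    if abs(spe - round(spe)) > 1e-9:
        raise ValueError(f"non-integer samples per epoch: fs={fs}, epoch_s={epoch_s}")
    spe = int(round(spe))
    n = len(data) // spe
    if n == 0:
        raise ValueError("signal shorter than one epoch")
    return data[: n * spe].reshape(n, spe)


__all__ = [
    "WAKE", "NREM", "REM", "MA", "STATES", "ROLES",
    "Channel", "Recording", "Hypnogram", "epochs_of", "replace",
]
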