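"""Readers, writers and acquisition-side preprocessing.

Formats handled: European Data Format (EDF, 16-bit, one 1-s data record
per second) for signals; plain-text spike lists (one time in seconds per
line); pose-estimation CSV in the DeepLabCut dialect (three header rows:
scorer / bodyparts / coords) for pupil keypoints; tab-separated hypnogram
text; YAML key-value config snapshots.

EDF reading goes through :func:`mne.io.read_raw_edf`; writing is done by a
small encoder in this module (per-channel physical scaling padded 5%
around the data range, so the 16-bit round-trip error is bounded by one
quantization step).

Preprocessing follows the acquisition convention: zero-phase Chebyshev
Type II band-pass (0.5-120 Hz for EEG/LFP, 10-45 Hz for EMG) followed by
polyphase resampling to 256 Hz.
"""

from __future__ import annotations

import struct
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import signal as sps

from ._filters import eeg_prefilter_sos, emg_prefilter_sos, zero_phase
from .recording import ROLES, STATES, Channel, Hypnogram, Recording

TARGET_FS = 256.0

#: substrings used to resolve EDF channel labels to pipeline roles when no
#: explicit map is given.
_DEFAULT_LABEL_HINTS = {
    "front": "frontal",
    "occ": "occipital",
    "emg": "emg",
    "lfp": "lfp",
}


def _resolve_role(label: str, channel_map: dict[str, str] | None) -> str | None:
    if channel_map is not None:
        for k, v in channel_map.items():
            if k.lower() == label.lower():
                if v not in ROLES:
                    raise ValueError(f"channel map target {v!r} is not one of {ROLES}")
                return v
        return None
    low = label.lower()
    for hint, role in _DEFAULT_LABEL_HINTS.items():
        if hint in low:
            return role
    return None


def read_edf(path: str | Path, channel_map: dict[str, str] | None = None) -> Recording:
    """Read an EDF file into a :class:`Recording` (amplitudes in µV).

    ``channel_map`` maps EDF channel labels to roles (frontal / occipital /
    emg / lfp); without it, labels are matched on standard substrings.
    Unresolvable labels raise.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"EDF file not found: {path}")
    raw = mne.io.read_raw_edf(path, preload=True, verbose="ERROR")
    channels: dict[str, Channel] = {}
    for name in raw.ch_names:
        role = _resolve_role(name, channel_map)
        if role is None:
            raise ValueError(f"cannot resolve EDF channel label {name!r} to a role")
        data = raw.get_data(picks=[name])[0] * 1e6  # mne returns volts
        channels[role] = Channel(name, np.asarray(data, dtype=float), float(raw.info["sfreq"]))
    if not channels:
        raise ValueError(f"no channels found in {path}")
    return Recording(channels=channels)


def _fmt8(x: float) -> bytes:
    """Format a float into at most 8 ASCII bytes (EDF numeric field)."""
    for spec in (".6g", ".4g", ".2g", ".1e"):
        s = format(float(x), spec)
        if len(s) <= 8:
            return s.encode("ascii")
    raise ValueError(f"cannot format {x} in 8 characters")


def write_edf(
    recording: Recording,
    path: str | Path,
    phys_ranges: dict[str, tuple[float, float]] | None = None,
) -> None:
    """Write a recording as 16-bit EDF with one 1-s data record per second.

    Physical min/max default to the per-channel data range padded by 5% (to
    maximize 16-bit resolution); ``phys_ranges`` overrides them per role.
    All channels must have an integer number of samples per second; a
    trailing partial second is zero-padded.
    """
    if not recording.channels:
        raise ValueError("cannot write an EDF with no channels")
    path = Path(path)
    roles = list(recording.channels)
    ns = len(roles)
    spr = []
    for role in roles:
        fs = recording.channels[role].fs
        if abs(fs - round(fs)) > 1e-9:
            raise ValueError(f"channel {role!r}: non-integer samples per 1-s record (fs={fs})")
        spr.append(int(round(fs)))
    n_records = int(np.ceil(max(
        len(recording.channels[r].data) / s for r, s in zip(roles, spr)
    )))
    if n_records == 0:
        raise ValueError("cannot write an empty recording")

    # physical scaling: written (string-rounded) values are re-parsed and
    # used for digitization so the quantization bound holds exactly
    pmins, pmaxs, scaled = [], [], []
    for role, s in zip(roles, spr):
        data = recording.channels[role].data
        if phys_ranges is not None and role in phys_ranges:
            lo, hi = phys_ranges[role]
        else:
            lo, hi = float(np.min(data)), float(np.max(data))
            pad = 0.05 * (hi - lo)
            if pad == 0:
                pad = max(abs(hi), 1.0) * 0.05
            lo, hi = lo - pad, hi + pad
        lo = float(_fmt8(lo))
        hi = float(_fmt8(hi))
        if hi <= lo:
            raise ValueError(f"degenerate physical range for channel {role!r}")
        pmins.append(lo)
        pmaxs.append(hi)
        padded = np.zeros(n_records * s)
        padded[: len(data)] = np.clip(data, lo, hi)
        dig = np.round((padded - lo) / (hi - lo) * 65535.0 - 32768.0)
        scaled.append(dig.astype("<i2"))

    def pad(s: str, width: int) -> bytes:
        b = s.encode("ascii")
        if len(b) > width:
            b = b[:width]
        return b.ljust(width)

    with open(path, "wb") as fh:
        fh.write(pad("0", 8))
        fh.write(pad("X X X X", 80))
        fh.write(pad("Startdate 01-JAN-2000 X X X", 80))
        fh.write(pad("01.01.00", 8))
        fh.write(pad("00.00.00", 8))
        fh.write(pad(str(256 * (ns + 1)), 8))
        fh.write(pad("", 44))
        fh.write(pad(str(n_records), 8))
        fh.write(pad("1", 8))
        fh.write(pad(str(ns), 4))
        labels = [recording.channels[r].label for r in roles]
        for lab in labels:
            fh.write(pad(lab, 16))
        for _ in roles:
            fh.write(pad("", 80))  # transducer
        for _ in roles:
            fh.write(pad("uV", 8))
        for lo in pmins:
            fh.write(pad(_fmt8(lo).decode(), 8))
        for hi in pmaxs:
            fh.write(pad(_fmt8(hi).decode(), 8))
        for _ in roles:
            fh.write(pad("-32768", 8))
        for _ in roles:
            fh.write(pad("32767", 8))
        for _ in roles:
            fh.write(pad("", 80))  # prefiltering
        for s in spr:
            fh.write(pad(str(s), 8))
        for _ in roles:
            fh.write(pad("", 32))
        for rec_i in range(n_records):
            for ch_i, s in enumerate(spr):
                fh.write(struct.pack(f"<{s}h", *scaled[ch_i][rec_i * s : (rec_i + 1) * s]))


def edf_quantization_step(recording_or_range, role: str | None = None) -> float:
    """One 16-bit quantization step for the default 5%-padded range."""
    if isinstance(recording_or_range, tuple):
        lo, hi = recording_or_range
    else:
        data = recording_or_range.channels[role].data
        lo, hi = float(np.min(data)), float(np.max(data))
        pad = 0.05 * (hi - lo)
        lo, hi = lo - pad, hi + pad
    return (hi - lo) / 65535.0


def preprocess(recording: Recording) -> Recording:
    """Acquisition-side preprocessing: zero-phase Chebyshev II band-pass
    (0.5-120 Hz EEG/LFP, 10-45 Hz EMG), then resample every channel to
    256 Hz by rational polyphase resampling.  Output duration is preserved
    to within one sample."""
    out_channels: dict[str, Channel] = {}
    for role, ch in recording.channels.items():
        if ch.fs < TARGET_FS:
            raise ValueError(
                f"channel {role!r}: fs={ch.fs} Hz is below the 256 Hz target "
                "(and below twice the 120 Hz passband edge)"
            )
        sos = emg_prefilter_sos(ch.fs) if role == "emg" else eeg_prefilter_sos(ch.fs)
        data = zero_phase(sos, ch.data)
        if abs(ch.fs - TARGET_FS) > 1e-9:
            frac = Fraction(TARGET_FS / ch.fs).limit_denominator(10000)
            data = sps.resample_poly(data, frac.numerator, frac.denominator)
        out_channels[role] = Channel(ch.label, data, TARGET_FS)
    return Recording(
        channels=out_channels,
        spike_times=recording.spike_times,
        pupil=recording.pupil,
        t0_zt=recording.t0_zt,
        condition=recording.condition,
        injection_t=recording.injection_t,
    )


# ---------------------------------------------------------------------------
# pose-estimation CSV (DeepLabCut dialect)

_POSE_POINTS = ("north", "south", "east", "west")


def read_pose_csv(path: str | Path, fps: float = 50.0) -> pd.DataFrame:
    """Read a pose-estimation CSV with three header rows (scorer /
    bodyparts / coords) into a frame-wise table with ``time`` (from the
    stated fps) and ``<point>_{x,y,likelihood}`` columns for the four
    cardinal pupil points."""
    path = Path(path)
    with open(path) as fh:
        header = [fh.readline().rstrip("\n") for _ in range(3)]
    if len(header) < 3 or not header[2]:
        raise ValueError(f"{path}: expected three header rows (scorer/bodyparts/coords)")
    parts = [h.split(",") for h in header]
    if parts[1][0].strip().lower() != "bodyparts" or parts[2][0].strip().lower() != "coords":
        raise ValueError(f"{path}: malformed header (rows 2/3 must be 'bodyparts' and 'coords')")
    bodyparts = [p.strip().lower() for p in parts[1][1:]]
    coords = [c.strip().lower() for c in parts[2][1:]]
    columns = {}
    for j, (bp, co) in enumerate(zip(bodyparts, coords)):
        columns[(bp, co)] = j + 1
    for point in _POSE_POINTS:
        for co in ("x", "y", "likelihood"):
            if (point, co) not in columns:
                raise ValueError(f"{path}: missing column for bodypart {point!r} ({co})")
    raw = pd.read_csv(path, skiprows=3, header=None)
    out = {"time": np.arange(len(raw)) / fps}
    for point in _POSE_POINTS:
        for co in ("x", "y", "likelihood"):
            col = raw.iloc[:, columns[(point, co)]]
            vals = pd.to_numeric(col, errors="coerce")
            bad = vals.isna() & col.notna()
            if bad.any():
                row = int(bad.idxmax()) + 4  # 1-based file row, after 3 header rows
                raise ValueError(
                    f"{path}: non-numeric value {col[bad.idxmax()]!r} for "
                    f"{point} {co} at file row {row}"
                )
            out[f"{point}_{co}"] = vals.to_numpy(dtype=float)
    return pd.DataFrame(out)


def write_pose_csv(trace: pd.DataFrame, path: str | Path, scorer: str = "synthetic") -> None:
    """Write a frame-wise trace in the three-header-row pose CSV dialect."""
    path = Path(path)
    cols = [(p, c) for p in _POSE_POINTS for c in ("x", "y", "likelihood")]
    with open(path, "w") as fh:
        fh.write("scorer," + ",".join(scorer for _ in cols) + "\n")
        fh.write("bodyparts," + ",".join(p for p, _ in cols) + "\n")
        fh.write("coords," + ",".join(c for _, c in cols) + "\n")
        arr = np.column_stack([trace[f"{p}_{c}"].to_numpy() for p, c in cols])
        for i in range(len(trace)):
            fh.write(str(i) + "," + ",".join(format(v, ".6g") for v in arr[i]) + "\n")


# ---------------------------------------------------------------------------
# hypnogram and spike text formats

_ART_COLS = [f"art_{r}" for r in ROLES]


def write_hypnogram(hyp: Hypnogram, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("epoch\tlabel\t" + "\t".join(_ART_COLS) + "\n")
        for k, lab in enumerate(hyp.labels):
            if hyp.artefact is not None:
                flags = [str(int(hyp.artefact.iloc[k].get(r, False))) for r in ROLES]
            else:
                flags = ["0"] * len(ROLES)
            fh.write(f"{k}\t{lab}\t" + "\t".join(flags) + "\n")


def read_hypnogram(path: str | Path, epoch_s: float = 4.0) -> Hypnogram:
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        return Hypnogram(np.empty(0, dtype=object), epoch_s)
    body = lines[1:] if lines[0].startswith("epoch") else lines
    labels, flags = [], []
    for ln in body:
        fields = ln.split("\t")
        lab = fields[1]
        if lab not in STATES:
            raise ValueError(f"{path}: unknown state label {lab!r}")
        labels.append(lab)
        flags.append([bool(int(v)) for v in fields[2 : 2 + len(ROLES)]] or [False] * len(ROLES))
    art = pd.DataFrame(flags, columns=list(ROLES))
    return Hypnogram(np.asarray(labels, dtype=object), epoch_s, artefact=art)


def write_spike_times(spikes: np.ndarray | None, path: str | Path) -> None:
    with open(path, "w") as fh:
        if spikes is not None:
            for t in spikes:
                fh.write(format(float(t), ".6f") + "\n")


def read_spike_times(path: str | Path) -> np.ndarray:
    with open(path) as fh:
        vals = [float(ln) for ln in fh if ln.strip()]
    arr = np.asarray(vals, dtype=float)
    if np.any(np.diff(arr) < 0):
        raise ValueError(f"{path}: spike times are not sorted")
    return arr


def write_config_snapshot(config: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh)


def read_config_snapshot(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def read_bundle(arm_dir: str | Path, fps: float = 50.0) -> tuple[Recording, Hypnogram]:
    """Load one study-arm directory written by the generator: EDF signals,
    spike list and pupil pose trace into a Recording, plus the hypnogram."""
    arm_dir = Path(arm_dir)
    rec = read_edf(arm_dir / "recording.edf")
    spikes = arm_dir / "spikes.txt"
    if spikes.exists():
        rec.spike_times = read_spike_times(spikes)
    pupil = arm_dir / "pupil.csv"
    if pupil.exists():
        rec.pupil = read_pose_csv(pupil, fps=fps)
    hyp = read_hypnogram(arm_dir / "hypnogram.tsv")
    cfg_path = arm_dir / "config.yaml"
    if cfg_path.exists():
        snap = read_config_snapshot(cfg_path)
        rec.condition = snap.get("condition", rec.condition)
        rec.injection_t = snap.get("drug_window", [None])[0]
    return rec, hyp
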