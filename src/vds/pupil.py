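"""Pupil diameter from four tracked cardinal points.

Diameter is the average of the north-south and east-west point distances,
computed only for frames where all four points were tracked with
likelihood at or above the confidence cutoff (default 0.99); other frames
are missing.  Time courses are binned means expressed as percent of a
baseline-window mean, and pupil-EEG coupling is an ordinary least-squares
regression with Pearson r².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

POINTS = ("north", "south", "east", "west")


@dataclass
class CorrelationResult:
    r_squared: float
    slope: float
    intercept: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if not 0 <= self.r_squared <= 1 + 1e-12:
            raise ValueError("r_squared out of [0, 1]")
        if self.n < 3:
            raise ValueError("need n >= 3")


def compute_diameter(trace: pd.DataFrame, min_likelihood: float = 0.99) -> pd.DataFrame:
    """Add a ``diameter`` column: (‖N−S‖ + ‖E−W‖) / 2 where all four
    likelihoods are >= ``min_likelihood``, NaN elsewhere."""
    out = trace.copy()
    ns = np.hypot(
        out["north_x"] - out["south_x"], out["north_y"] - out["south_y"]
    )
    ew = np.hypot(out["east_x"] - out["west_x"], out["east_y"] - out["west_y"])
    d = (ns + ew) / 2.0
    ok = np.ones(len(out), dtype=bool)
    for p in POINTS:
        ok &= out[f"{p}_likelihood"].to_numpy() >= min_likelihood
    d = d.to_numpy(dtype=float)
    d[~ok] = np.nan
    out["diameter"] = d
    return out


def interpolate_short_gaps(trace: pd.DataFrame, max_gap_s: float = 1.0) -> pd.DataFrame:
    """Optional linear interpolation of missing diameters across gaps of
    at most ``max_gap_s`` (off by default in the pipeline)."""
    out = trace.copy()
    t = out["time"].to_numpy()
    fps = 1.0 / np.median(np.diff(t))
    limit = max(int(round(max_gap_s * fps)), 1)
    out["diameter"] = out["diameter"].interpolate(limit=limit, limit_area="inside")
    return out


def bin_timecourse(
    trace: pd.DataFrame,
    bin_s: float,
    baseline_window: tuple,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin mean of non-missing diameters as percent of the baseline-
    window mean.  Returns (bin_start_times, percent values); empty bins
    are NaN."""
    t = trace["time"].to_numpy()
    d = trace["diameter"].to_numpy(dtype=float)
    b0, b1 = baseline_window
    base = d[(t >= b0) & (t < b1)]
    base = base[~np.isnan(base)]
    if len(base) == 0:
        raise ValueError("baseline window contains no valid frames")
    ref = base.mean()
    n_bins = int(np.ceil((t[-1] + 1e-9) / bin_s))
    out = np.full(n_bins, np.nan)
    idx = np.minimum((t / bin_s).astype(int), n_bins - 1)
    for b in range(n_bins):
        vals = d[idx == b]
        vals = vals[~np.isnan(vals)]
        if len(vals):
            out[b] = vals.mean() / ref * 100.0
    return np.arange(n_bins) * bin_s, out


def correlate_pupil_eeg(
    pupil_bins: np.ndarray, band_power_bins: np.ndarray
) -> CorrelationResult:
    """OLS regression of band power on pupil size over paired bins
    (missing values dropped pairwise), with Pearson r² and a two-sided
    p-value."""
    x = np.asarray(pupil_bins, dtype=float)
    y = np.asarray(band_power_bins, dtype=float)
    if len(x) != len(y):
        raise ValueError("bin series differ in length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("need at least 3 paired bins")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in one of the variables")
    fit = stats.linregress(x, y)
    return CorrelationResult(
        r_squared=float(fit.rvalue**2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        p_value=float(fit.pvalue),
        n=len(x),
    )
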