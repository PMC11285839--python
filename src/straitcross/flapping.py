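"""Flapping classification from heave-amplitude of acceleration bursts.

A tag records a 20 s, 1 Hz burst of the heave (dorsoventral) acceleration
axis every 3 min.  Wing flapping drives a large-amplitude oscillation of
heave; passive gliding leaves only small-amplitude noise.  A burst is
labelled "flapping" when its amplitude summary strictly exceeds a
calibration threshold (``flap_threshold_g``); the threshold is a required
configuration parameter, calibrated from a labelled burst set.

The default amplitude summary is the mean peak-to-trough excursion over
the burst.  Because "amplitude" admits several readings, two alternatives
are available behind ``amplitude_method``: RMS deviation about the burst
mean, and total range (max − min).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InputError


def _extrema_values(x: np.ndarray) -> np.ndarray:
    """Values of successive interior local extrema, plateaus collapsed.

    Endpoints are excluded: a series cut mid-swing would otherwise
    contribute partial excursions and bias the mean downward.
    """
    keep = np.concatenate(([True], np.diff(x) != 0))
    y = x[keep]
    if y.size < 3:
        return y[:0]
    d = np.sign(np.diff(y))
    turning = d[1:] != d[:-1]
    return y[1:-1][turning]


def burst_amplitude(heave, method: str = "peak_to_trough") -> float:
    """Amplitude summary of one heave series.

    ``peak_to_trough``: mean |difference| between successive local extrema
    (a constant series has no extrema pair and scores 0).  ``rms``: root
    mean square about the series mean.  ``range``: max − min.
    """
    x = np.asarray(heave, dtype=float)
    if x.size < 2:
        raise InputError("burst amplitude needs >= 2 samples")
    if not np.all(np.isfinite(x)):
        raise InputError("non-finite heave sample")
    if method == "peak_to_trough":
        ext = _extrema_values(x)
        if ext.size < 2:
            return 0.0
        return float(np.mean(np.abs(np.diff(ext))))
    if method == "rms":
        return float(np.sqrt(np.mean((x - x.mean()) ** 2)))
    if method == "range":
        return float(x.max() - x.min())
    raise InputError(f"unknown amplitude method {method!r}")


def classify_flapping(amplitude: float, threshold: float) -> bool:
    """Flapping iff the amplitude strictly exceeds the threshold."""
    if threshold <= 0:
        raise InputError("flapping threshold must be positive")
    return bool(amplitude > threshold)


def classify_bursts(
    bursts: pd.DataFrame, threshold: float, method: str = "peak_to_trough"
) -> pd.DataFrame:
    """Summarise and label every burst in a long-format burst table.

    Returns one row per (bird_id, t): mean_amplitude and flapping label.
    """
    if bursts.empty:
        return pd.DataFrame(columns=["bird_id", "t", "mean_amplitude", "flapping"])
    rows = []
    for (bird, t0), grp in bursts.groupby(["bird_id", "t"], sort=True):
        amp = burst_amplitude(grp.sort_values("sample_idx")["heave"].to_numpy(), method)
        rows.append((bird, t0, amp, classify_flapping(amp, threshold)))
    return pd.DataFrame(rows, columns=["bird_id", "t", "mean_amplitude", "flapping"])


def join_bursts_to_frame(
    frame: pd.DataFrame, classified: pd.DataFrame, max_gap_s: float = 90.0
) -> pd.DataFrame:
    """Attach each classified burst to its bird's nearest retained fix.

    Bursts with no fix of the same bird within ``max_gap_s`` are dropped.
    Returns the frame rows matched by at least one burst, one row per
    burst, with ``flapping`` and ``mean_amplitude`` columns.
    """
    if frame.empty or classified.empty:
        out = frame.iloc[0:0].copy()
        out["mean_amplitude"] = pd.Series(dtype=float)
        out["flapping"] = pd.Series(dtype=bool)
        return out
    pieces = []
    for bird, bgrp in classified.groupby("bird_id", sort=False):
        fgrp = frame[frame["bird_id"] == bird]
        if fgrp.empty:
            continue
        ft = fgrp["t"].to_numpy(dtype="datetime64[ns]").astype("int64") / 1e9
        bt = bgrp["t"].to_numpy(dtype="datetime64[ns]").astype("int64") / 1e9
        pos = np.searchsorted(ft, bt)
        left = np.clip(pos - 1, 0, len(ft) - 1)
        right = np.clip(pos, 0, len(ft) - 1)
        use_left = np.abs(bt - ft[left]) <= np.abs(ft[right] - bt)
        nearest = np.where(use_left, left, right)
        gap = np.abs(bt - ft[nearest])
        ok = gap <= max_gap_s
        if not ok.any():
            continue
        matched = fgrp.iloc[nearest[ok]].reset_index(drop=True)
        matched["mean_amplitude"] = bgrp["mean_amplitude"].to_numpy()[ok]
        matched["flapping"] = bgrp["flapping"].to_numpy()[ok]
        pieces.append(matched)
    if not pieces:
        out = frame.iloc[0:0].copy()
        out["mean_amplitude"] = pd.Series(dtype=float)
        out["flapping"] = pd.Series(dtype=bool)
        return out
    return pd.concat(pieces, ignore_index=True)
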