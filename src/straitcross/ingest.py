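"""Readers and filters turning raw CSV inputs into the analysis tables.

Tabular layout (all pandas DataFrames):

* fixes  — ``bird_id, age_class, t (UTC), lon, lat`` plus derived kinematic
  columns added downstream; timestamps strictly increasing within a bird.
* wind   — ``station_id, t, wind_speed_ms, wind_dir_deg`` at nominal 10-min
  spacing; the caller supplies a pre-merged stream when several stations
  alternate in time.
* bursts — long format ``bird_id, burst_start, sample_idx, heave`` (1 Hz
  heave in gravitational units, 20 samples per burst).

Filtering order is fixed: geofence clip → coastal buffer → wind
annotation → kinematics (on the raw 10-s stream) → 3-min subsample.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd
from shapely import contains_xy
from shapely.prepared import prep

from . import geo
from .errors import InputError

log = logging.getLogger("straitcross")

AGE_CLASSES = ("juvenile", "adult")

FIX_COLUMNS = ["bird_id", "timestamp", "lon", "lat"]
WIND_COLUMNS = ["station_id", "timestamp", "wind_speed_ms", "wind_dir_deg"]
BURST_COLUMNS = ["bird_id", "burst_start", "sample_idx", "heave"]


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing columns {missing}")
    return df


def _parse_times(df: pd.DataFrame, col: str, path) -> pd.Series:
    t = pd.to_datetime(df[col], utc=True, errors="coerce", format="ISO8601")
    bad = t.isna() & df[col].notna()
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2  # header is line 1
        raise InputError(f"{path}: unparseable timestamp at line {line}")
    if t.isna().any():
        line = int(np.flatnonzero(t.isna())[0]) + 2
        raise InputError(f"{path}: empty timestamp at line {line}")
    return t


def read_ages(path) -> dict[str, str]:
    """Read the bird_id → age_class table."""
    df = _read_csv(path, ["bird_id", "age_class"])
    bad = ~df["age_class"].isin(AGE_CLASSES)
    if bad.any():
        raise InputError(f"{path}: unknown age_class {df.loc[bad, 'age_class'].iloc[0]!r}")
    return dict(zip(df["bird_id"].astype(str), df["age_class"]))


def read_fixes(path, age_table: Mapping[str, str]) -> pd.DataFrame:
    """Read GPS fixes, attach age classes, sort, and drop duplicate timestamps.

    Duplicate (bird, timestamp) rows keep the first occurrence.  A bird_id
    absent from ``age_table`` is an error.
    """
    df = _read_csv(path, FIX_COLUMNS)
    if df.empty:
        return pd.DataFrame(columns=["bird_id", "age_class", "t", "lon", "lat"])
    for col in ("lon", "lat"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            line = int(np.flatnonzero(vals.isna())[0]) + 2
            raise InputError(f"{path}: unparseable {col} at line {line}")
        df[col] = vals
    if (df["lon"].abs() > 180).any() or (df["lat"].abs() > 90).any():
        raise InputError(f"{path}: coordinate out of range")
    df["t"] = _parse_times(df, "timestamp", path)
    df["bird_id"] = df["bird_id"].astype(str)
    unknown = set(df["bird_id"]) - set(age_table)
    if unknown:
        raise InputError(f"{path}: bird_id(s) missing from age table: {sorted(unknown)}")
    df["age_class"] = df["bird_id"].map(age_table)
    df = (
        df.sort_values(["bird_id", "t"], kind="stable")
        .drop_duplicates(["bird_id", "t"], keep="first")
        .reset_index(drop=True)
    )
    return df[["bird_id", "age_class", "t", "lon", "lat"]]


def read_wind(path) -> pd.DataFrame:
    """Read the (pre-merged) weather-station stream, sorted by time."""
    df = _read_csv(path, WIND_COLUMNS)
    if df.empty:
        return pd.DataFrame(columns=["station_id", "t", "wind_speed_ms", "wind_dir_deg"])
    df["t"] = _parse_times(df, "timestamp", path)
    speed = pd.to_numeric(df["wind_speed_ms"], errors="coerce")
    if speed.isna().any() or (speed < 0).any() or not np.isfinite(speed).all():
        raise InputError(f"{path}: wind_speed_ms must be finite and non-negative")
    df["wind_speed_ms"] = speed
    df["wind_dir_deg"] = pd.to_numeric(df["wind_dir_deg"], errors="coerce") % 360.0
    return df.sort_values("t", kind="stable").reset_index(drop=True)[
        ["station_id", "t", "wind_speed_ms", "wind_dir_deg"]
    ]


def read_bursts(path) -> pd.DataFrame:
    """Read 1-Hz heave bursts in long format."""
    df = _read_csv(path, BURST_COLUMNS)
    if df.empty:
        return pd.DataFrame(columns=["bird_id", "t", "sample_idx", "heave"])
    df["t"] = _parse_times(df, "burst_start", path)
    df["bird_id"] = df["bird_id"].astype(str)
    df["heave"] = pd.to_numeric(df["heave"], errors="coerce")
    if df["heave"].isna().any():
        raise InputError(f"{path}: unparseable heave value")
    return df.sort_values(["bird_id", "t", "sample_idx"], kind="stable").reset_index(drop=True)[
        ["bird_id", "t", "sample_idx", "heave"]
    ]


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def clip_to_strait(
    fixes: pd.DataFrame,
    geofence,
    spain: geo.Coastline,
    morocco: geo.Coastline,
    buffer_m: float = 500.0,
) -> pd.DataFrame:
    """Keep fixes inside the geofence and at least ``buffer_m`` from both shores.

    The coastal exclusion is strict: a fix strictly closer than the buffer
    to either coastline is removed (coastal-uplift soaring contaminates
    over-water flight parameters).  Order is preserved.
    """
    if fixes.empty:
        return fixes.copy()
    inside = contains_xy(geofence, fixes["lon"].to_numpy(), fixes["lat"].to_numpy())
    n_fence = int((~inside).sum())
    kept = fixes.loc[inside]
    if not kept.empty:
        _, d_sp = geo.nearest_points_batch(kept["lon"].to_numpy(), kept["lat"].to_numpy(), spain)
        _, d_mo = geo.nearest_points_batch(kept["lon"].to_numpy(), kept["lat"].to_numpy(), morocco)
        clear = (d_sp >= buffer_m) & (d_mo >= buffer_m)
        n_buffer = int((~clear).sum())
        kept = kept.loc[clear]
    else:
        n_buffer = 0
    log.info("clip_to_strait: dropped %d fixes outside geofence, %d within %.0f m of a coast",
             n_fence, n_buffer, buffer_m)
    return kept.reset_index(drop=True)


def subsample_3min(fixes: pd.DataFrame, min_gap_s: float = 180.0) -> pd.DataFrame:
    """Greedy per-bird temporal thinning to reduce serial autocorrelation.

    Forward pass per bird: keep a fix iff it is at least ``min_gap_s``
    after the last kept fix; the first fix is always kept.
    """
    if fixes.empty:
        return fixes.copy()
    keep_idx: list[int] = []
    for _, grp in fixes.groupby("bird_id", sort=False):
        times = grp["t"].to_numpy(dtype="datetime64[ns]").astype("int64") / 1e9
        last = -np.inf
        for i, tt in zip(grp.index, times):
            if tt - last >= min_gap_s or not np.isfinite(last):
                keep_idx.append(i)
                last = tt
    out = fixes.loc[keep_idx]
    log.info("subsample_3min: kept %d of %d fixes", len(out), len(fixes))
    return out.reset_index(drop=True)


def annotate_wind(
    fixes: pd.DataFrame, wind: pd.DataFrame, max_gap_s: float = 600.0
) -> pd.DataFrame:
    """Pair each fix with the station record nearest in time.

    Ties break toward the earlier record.  Fixes with no record within
    ``max_gap_s`` (the data's native 10-min resolution) are dropped and
    counted in the log.
    """
    if fixes.empty:
        out = fixes.copy()
        for c in ("wind_speed_ms", "wind_dir_deg", "wind_u", "wind_v"):
            out[c] = pd.Series(dtype=float)
        return out
    if wind.empty:
        raise InputError("annotate_wind: empty wind record stream")
    from .wind import met_to_uv

    rec_t = wind["t"].to_numpy(dtype="datetime64[ns]").astype("int64") / 1e9
    fix_t = fixes["t"].to_numpy(dtype="datetime64[ns]").astype("int64") / 1e9
    right = np.searchsorted(rec_t, fix_t, side="left")
    left = np.clip(right - 1, 0, len(rec_t) - 1)
    right = np.clip(right, 0, len(rec_t) - 1)
    d_left = np.abs(fix_t - rec_t[left])
    d_right = np.abs(rec_t[right] - fix_t)
    # ties (equal distance) go to the earlier record
    use_left = d_left <= d_right
    nearest = np.where(use_left, left, right)
    gap = np.where(use_left, d_left, d_right)
    ok = gap <= max_gap_s
    n_drop = int((~ok).sum())
    if n_drop:
        log.info("annotate_wind: dropped %d fixes with no wind record within %.0f s", n_drop, max_gap_s)
    out = fixes.loc[ok].reset_index(drop=True)
    matched = wind.iloc[nearest[ok]]
    out["wind_speed_ms"] = matched["wind_speed_ms"].to_numpy()
    out["wind_dir_deg"] = matched["wind_dir_deg"].to_numpy()
    u, v = met_to_uv(out["wind_speed_ms"].to_numpy(), out["wind_dir_deg"].to_numpy())
    out["wind_u"] = u
    out["wind_v"] = v
    return out
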