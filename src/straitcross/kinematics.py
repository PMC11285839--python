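"""Ground velocity, wind-triangle airspeed, and axis decompositions.

Every speed in the analysis derives from the horizontal wind triangle

    ground velocity  =  air velocity  +  wind velocity,

worked in a local east–north tangent plane at each fix (curvature over a
10-s GPS step is negligible).  Components are taken relative to a
*reference bearing* — either the target bearing (toward the nearest point
on the destination coast) or the travel bearing (the bird's own track):

* ``tailwind``          — wind component along the reference bearing;
* ``crosswind_signed``  — wind component on the perpendicular axis,
  positive 90° clockwise from the reference (the bird's right when facing
  the reference);
* ``sideways_speed``    — ground-velocity component on that same signed
  perpendicular axis (the drift response variable);
* ``airspeed``          — |ground velocity − wind velocity|.

Sign convention: for a southbound reference bearing the clockwise
perpendicular points west, so an easterly (Levanter) wind has positive
crosswind and a bird drifting west has positive sideways speed — full
drift is then a sideways-vs-crosswind slope of +1.

Velocities are computed on the raw 10-s stream (adjacent-fix
differences) and carried onto the 3-min subsample, preserving
instantaneous speeds rather than 3-min straight-line averages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import geo, ingest
from .errors import InputError

FRAME_COLUMNS = [
    "bird_id", "age_class", "t", "lon", "lat", "regime",
    "wind_u", "wind_v", "wind_speed_ms",
    "tailwind_target", "crosswind_target_signed", "sideways",
    "tailwind_travel", "crosswind_travel_abs",
    "airspeed", "ground_speed", "dist_morocco",
]


@dataclass(frozen=True)
class Decomposition:
    """Wind and ground-velocity components relative to one reference bearing."""

    reference: str  # "target" or "travel"
    ref_bearing: float
    tailwind: float
    crosswind_signed: float
    sideways_speed: float
    airspeed: float
    ground_speed: float

    @property
    def crosswind_abs(self) -> float:
        return abs(self.crosswind_signed)


def _unit(bearing_deg):
    """East/north unit vector of a compass bearing."""
    rad = np.radians(np.asarray(bearing_deg, dtype=float))
    return np.sin(rad), np.cos(rad)


def decompose_arrays(wind_u, wind_v, gs, track_deg, ref_deg):
    """Vectorised decomposition; returns a dict of component arrays.

    The perpendicular axis is 90° clockwise from the reference bearing.
    Track bearings may be nan (stationary fix): sideways and airspeed are
    then nan.
    """
    wind_u = np.asarray(wind_u, dtype=float)
    wind_v = np.asarray(wind_v, dtype=float)
    gs = np.asarray(gs, dtype=float)
    if np.any(gs < 0):
        raise InputError("ground speed must be non-negative")
    re, rn = _unit(ref_deg)
    pe, pn = rn, -np.sin(np.radians(np.asarray(ref_deg, dtype=float)))  # 90° cw: (cos b, −sin b)
    te, tn = _unit(track_deg)
    ge, gn = gs * te, gs * tn
    tailwind = wind_u * re + wind_v * rn
    crosswind = wind_u * pe + wind_v * pn
    sideways = ge * pe + gn * pn
    airspeed = np.hypot(ge - wind_u, gn - wind_v)
    return {
        "tailwind": tailwind,
        "crosswind_signed": crosswind,
        "sideways": sideways,
        "airspeed": airspeed,
        "ground_speed": gs,
    }


def decompose(wind, gs: float, track_deg: float, ref_deg: float, reference: str = "target") -> Decomposition:
    """Single-fix decomposition of wind and ground velocity about ``ref_deg``."""
    parts = decompose_arrays(wind.u, wind.v, gs, track_deg, ref_deg)
    return Decomposition(
        reference=reference,
        ref_bearing=float(ref_deg),
        tailwind=float(parts["tailwind"]),
        crosswind_signed=float(parts["crosswind_signed"]),
        sideways_speed=float(parts["sideways"]),
        airspeed=float(parts["airspeed"]),
        ground_speed=float(gs),
    )


def add_ground_velocity(fixes: pd.DataFrame, max_gap_s: float = 60.0) -> pd.DataFrame:
    """Per-bird ground speed and track bearing from adjacent-fix differences.

    The velocity over (prev → curr) is assigned to ``curr``.  Gaps longer
    than ``max_gap_s`` (raw stream is 10 s) yield no velocity; zero
    displacement yields speed 0 with an undefined (nan) bearing.
    """
    out = fixes.copy()
    n = len(out)
    speed = np.full(n, np.nan)
    bearing = np.full(n, np.nan)
    if n:
        lon = out["lon"].to_numpy()
        lat = out["lat"].to_numpy()
        tsec = out["t"].to_numpy(dtype="datetime64[ns]").astype("int64") / 1e9
        same_bird = out["bird_id"].to_numpy()[1:] == out["bird_id"].to_numpy()[:-1]
        dt = np.diff(tsec)
        dist = geo.haversine_arrays(lon[:-1], lat[:-1], lon[1:], lat[1:])
        brg = geo.bearing_arrays(lon[:-1], lat[:-1], lon[1:], lat[1:])
        ok = same_bird & (dt > 0) & (dt <= max_gap_s)
        speed[1:][ok] = dist[ok] / dt[ok]
        bearing[1:][ok] = brg[ok]  # nan where displacement is zero
        speed[1:][ok & (dist == 0)] = 0.0
    out["ground_speed"] = speed
    out["track_bearing"] = bearing
    return out


def add_target_bearing(fixes: pd.DataFrame, morocco: geo.Coastline) -> pd.DataFrame:
    """Bearing and distance to the nearest point on the destination coast.

    The target direction is recomputed at every fix: the bird is assumed
    to aim for the closest point on the Moroccan coast at each step.
    """
    out = fixes.copy()
    if out.empty:
        out["target_bearing"] = pd.Series(dtype=float)
        out["dist_morocco"] = pd.Series(dtype=float)
        return out
    brg, dist = geo.nearest_points_batch(out["lon"].to_numpy(), out["lat"].to_numpy(), morocco)
    out["target_bearing"] = brg
    out["dist_morocco"] = dist
    return out


def build_frame(
    fixes: pd.DataFrame,
    wind_records: pd.DataFrame,
    spain: geo.Coastline,
    morocco: geo.Coastline,
    geofence,
    config=None,
) -> pd.DataFrame:
    """Run the full filtering + kinematics pipeline to the analysis frame.

    Order: geofence clip → coastal buffer → wind annotation → velocities
    (raw stream) → target bearings → decompositions → 3-min subsample.
    Rows without a defined track bearing (first fix of a bird, long gaps,
    stationary fixes) are dropped from the modelling frame.
    """
    from .config import PipelineConfig
    from .wind import regime_from_east_components

    cfg = config or PipelineConfig()
    clipped = ingest.clip_to_strait(fixes, geofence, spain, morocco, cfg.buffer_m)
    annotated = ingest.annotate_wind(clipped, wind_records, cfg.wind_match_max_s)
    vel = add_ground_velocity(annotated, cfg.max_velocity_gap_s)
    vel = add_target_bearing(vel, morocco)
    sub = ingest.subsample_3min(vel, cfg.subsample_s)
    sub = sub[np.isfinite(sub["track_bearing"].to_numpy(dtype=float))].reset_index(drop=True)
    if sub.empty:
        return pd.DataFrame(columns=FRAME_COLUMNS)

    tgt = decompose_arrays(
        sub["wind_u"], sub["wind_v"], sub["ground_speed"], sub["track_bearing"], sub["target_bearing"]
    )
    trv = decompose_arrays(
        sub["wind_u"], sub["wind_v"], sub["ground_speed"], sub["track_bearing"], sub["track_bearing"]
    )
    sub["tailwind_target"] = tgt["tailwind"]
    sub["crosswind_target_signed"] = tgt["crosswind_signed"]
    sub["sideways"] = tgt["sideways"]
    sub["tailwind_travel"] = trv["tailwind"]
    sub["crosswind_travel_abs"] = np.abs(trv["crosswind_signed"])
    sub["airspeed"] = tgt["airspeed"]

    # whole-crossing regime: majority vote over per-fix east components
    regimes = {
        b: regime_from_east_components(-g["wind_u"].to_numpy())
        for b, g in sub.groupby("bird_id", sort=False)
    }
    sub["regime"] = sub["bird_id"].map(regimes)
    return sub[FRAME_COLUMNS].copy()
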