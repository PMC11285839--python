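"""Synthetic study generator: wind regimes, a stylised strait, bird tracks
and acceleration bursts with known ground truth.

The generator is the inverse of the analysis.  Each simulated bird aims
at the nearest point of the destination (southern) coast and flies, at
every 10-s step, an intended air velocity

    v_air = s·r̂ − γ·(w·r̂⊥)·r̂⊥,
    s     = preferred_airspeed + a_t·tailwind + a_c·|crosswind|,

where r̂ is the unit target bearing, r̂⊥ its clockwise perpendicular, w
the current station wind and γ ∈ [0, 1] the compensation coefficient: a
fraction γ of the crosswind is cancelled, so the analysis-side drift
slope of sideways speed on crosswind is 1 − γ (γ = 0 full drift, γ = 1
full compensation).  Ground velocity is v_air + w plus isotropic noise
(sd 0.5 m s⁻¹ per component — small against the 9–13 m s⁻¹ winds of
interest).

Every 3 min the bird emits a 20 s, 1 Hz heave burst.  The flap decision
is logistic in the bird's absolute sideways speed; flapping bursts carry
a sinusoidal heave oscillation, gliding bursts only noise, with
separated amplitude scales so threshold classification is clean.

Wind follows a scripted regime sequence emulating the strait's weather:
easterly (Levanter) episodes are strong with steady direction (draws
N(90°, small jitter), speed N(mean, 1.5) truncated at 0), westerly
episodes weaker with heterogeneous direction, and inter-episode
relaxation days have low, directionless wind.  Default Levanter speed is
11 m s⁻¹, inside the 9–13 m s⁻¹ band characteristic of
crossing-restricting conditions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely import contains_xy

from . import geo
from .config import PipelineConfig
from .errors import InputError

GS_NOISE_SD = 0.5  # m s⁻¹ per component, isotropic
FIX_INTERVAL_S = 10
BURST_INTERVAL_S = 180
BURST_LEN_S = 20
BURST_HZ = 1
MAX_CROSSING_S = 4 * 3600
ARRIVAL_DIST_M = 500.0
FLAP_SINE_HZ = 0.25  # 4-s wingbeat envelope period, well sampled at 1 Hz

_DEG_PER_M_LAT = 180.0 / (np.pi * geo.EARTH_RADIUS_M)


@dataclass
class BirdSpec:
    """Behavioural ground truth for one simulated bird."""

    age_class: str = "adult"
    compensation: float = 0.9  # γ: fraction of crosswind cancelled
    preferred_airspeed: float = 12.0  # m s⁻¹
    airspeed_tailwind_slope: float = -0.3
    airspeed_crosswind_slope: float = 0.3
    flap_intercept: float = -1.5  # logistic, in |sideways| (m s⁻¹)
    flap_slope: float = 0.6
    flap_heave_amp: float = 1.2  # g
    glide_heave_amp: float = 0.08  # g (noise sd while gliding)
    heave_noise_sd: float = 0.05  # g, additive sensor noise

    def __post_init__(self):
        if not (0.0 <= self.compensation <= 1.0):
            raise InputError("compensation must be in [0, 1]")
        if self.preferred_airspeed <= 0 or self.flap_heave_amp <= 0 or self.glide_heave_amp <= 0:
            raise InputError("speeds and amplitudes must be positive")


#: study-condition defaults: adults compensate strongly, juveniles drift
DEFAULT_SPECS = {
    "adult": BirdSpec(age_class="adult", compensation=0.9),
    "juvenile": BirdSpec(age_class="juvenile", compensation=0.1),
}


@dataclass
class WindEpisode:
    start_day: int
    duration_days: int
    regime: str  # "east" | "west"
    mean_speed: float
    dir_jitter_sd: float
    speed_sd: float = 1.5


@dataclass
class WindScript:
    """Non-overlapping wind episodes over a span of days; 10-min sampling."""

    episodes: list[WindEpisode]
    n_days: int
    start_date: str = "2012-08-01"
    sampling_s: int = 600

    def __post_init__(self):
        spans = sorted((e.start_day, e.start_day + e.duration_days) for e in self.episodes)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            if b0 < a1:
                raise InputError("wind episodes overlap")
        if spans and spans[-1][1] > self.n_days:
            raise InputError("episode extends past the script span")


def default_wind_script() -> WindScript:
    """Three strong Levanter days, a relaxation (drop) day, then weak westerlies."""
    return WindScript(
        episodes=[
            WindEpisode(0, 3, "east", 11.0, 10.0),
            WindEpisode(4, 2, "west", 5.0, 30.0),
        ],
        n_days=6,
    )


def gen_wind(script: WindScript, rng: np.random.Generator, station_id: str = "synthetic") -> pd.DataFrame:
    """Realise a WindScript as a 10-min station record stream."""
    t0 = pd.Timestamp(script.start_date, tz="UTC")
    n = int(script.n_days * 86400 // script.sampling_s)
    times = t0 + pd.to_timedelta(np.arange(n) * script.sampling_s, unit="s")
    day = (np.arange(n) * script.sampling_s) // 86400
    speed = np.empty(n)
    direction = np.empty(n)
    in_episode = np.zeros(n, dtype=bool)
    for ep in script.episodes:
        m = (day >= ep.start_day) & (day < ep.start_day + ep.duration_days)
        centre = 90.0 if ep.regime == "east" else 270.0
        direction[m] = rng.normal(centre, ep.dir_jitter_sd, m.sum()) % 360.0
        speed[m] = np.clip(rng.normal(ep.mean_speed, ep.speed_sd, m.sum()), 0.0, None)
        in_episode |= m
    calm = ~in_episode
    speed[calm] = np.clip(rng.normal(2.5, 1.0, calm.sum()), 0.0, None)
    direction[calm] = rng.uniform(0.0, 360.0, calm.sum())
    return pd.DataFrame(
        {"station_id": station_id, "t": times, "wind_speed_ms": speed, "wind_dir_deg": direction}
    )


# ---------------------------------------------------------------------------
# stylised strait geometry
# ---------------------------------------------------------------------------

NARROWEST_GAP_M = 14_000.0
_CENTRE_LON = -5.65
_HALF_SPAN = 0.45


def _spain_lat(lon):
    return 36.00 + 0.10 * ((np.asarray(lon) - _CENTRE_LON) / _HALF_SPAN) ** 2


def _morocco_lat(lon):
    gap_deg = NARROWEST_GAP_M * _DEG_PER_M_LAT
    return 36.00 - gap_deg - 0.12 * ((np.asarray(lon) - _CENTRE_LON) / _HALF_SPAN) ** 2


def gen_coastlines():
    """Deterministic stylised strait: two near-parallel shores, narrowest
    gap exactly 14 km, widening east- and westward; plus the default
    geofence polygon."""
    lons = np.round(np.arange(-6.10, -5.20 + 1e-9, 0.02), 4)
    spain = geo.Coastline("spain", lons, _spain_lat(lons))
    morocco = geo.Coastline("morocco", lons, _morocco_lat(lons))
    geofence = PipelineConfig().geofence_polygon()
    return spain, morocco, geofence


# ---------------------------------------------------------------------------
# agent-based bird simulator
# ---------------------------------------------------------------------------

def _heave_burst(flapping: bool, spec: BirdSpec, rng: np.random.Generator) -> np.ndarray:
    k = np.arange(BURST_LEN_S * BURST_HZ)
    noise = rng.normal(0.0, spec.heave_noise_sd, k.size)
    if flapping:
        return 1.0 + spec.flap_heave_amp * np.sin(2 * np.pi * FLAP_SINE_HZ * k) + noise
    return 1.0 + rng.normal(0.0, spec.glide_heave_amp, k.size) + noise


def simulate_bird(
    bird_id: str,
    spec: BirdSpec,
    wind: pd.DataFrame,
    start: geo.GeoPoint,
    start_time: pd.Timestamp,
    morocco: geo.Coastline,
    geofence,
    rng: np.random.Generator,
    max_duration_s: int = MAX_CROSSING_S,
    gs_noise_sd: float = GS_NOISE_SD,
):
    """Simulate one crossing at 10-s resolution.

    Returns (fixes, bursts, info): fixes with per-step ground truth
    columns, long-format heave bursts, and a dict with the arrival/exit
    status.  The run ends on reaching within 500 m of the destination
    coast, on leaving the geofence (truncated with an exit flag — the
    bird was blown out of the analysis region), or after 4 h.
    """
    rec_t = wind["t"].to_numpy(dtype="datetime64[ns]").astype("int64") / 1e9
    from .wind import met_to_uv

    rec_u, rec_v = met_to_uv(wind["wind_speed_ms"].to_numpy(), wind["wind_dir_deg"].to_numpy())
    t0 = start_time.value / 1e9

    lon, lat = start.lon, start.lat
    fix_rows = []
    burst_rows = []
    prev_g = None
    status = "timeout"
    for step in range(max_duration_s // FIX_INTERVAL_S + 1):
        t_s = step * FIX_INTERVAL_S
        now = t0 + t_s
        brg, dist = geo.nearest_points_batch([lon], [lat], morocco)
        brg, dist = float(brg[0]), float(dist[0])
        if dist < ARRIVAL_DIST_M:
            status = "arrived"
            break
        if not contains_xy(geofence, lon, lat):
            status = "exited"
            break
        # nearest wind record in time
        i = int(np.clip(np.searchsorted(rec_t, now), 0, rec_t.size - 1))
        if i > 0 and abs(now - rec_t[i - 1]) <= abs(rec_t[i] - now):
            i -= 1
        wu, wv = rec_u[i], rec_v[i]

        rad = np.radians(brg)
        re, rn = np.sin(rad), np.cos(rad)
        pe, pn = rn, -re  # 90° clockwise from the target bearing
        tailwind = wu * re + wv * rn
        crosswind = wu * pe + wv * pn
        s = max(
            1.0,
            spec.preferred_airspeed
            + spec.airspeed_tailwind_slope * tailwind
            + spec.airspeed_crosswind_slope * abs(crosswind),
        )
        air_e = s * re - spec.compensation * crosswind * pe
        air_n = s * rn - spec.compensation * crosswind * pn
        ge = air_e + wu + rng.normal(0.0, gs_noise_sd)
        gn = air_n + wv + rng.normal(0.0, gs_noise_sd)

        fix_rows.append(
            (bird_id, now, lon, lat, crosswind, tailwind, ge * pe + gn * pn,
             float(np.hypot(air_e, air_n)))
        )

        # burst uses the velocity of the step that *ends* at this fix, the
        # same quantity the analysis assigns to it
        if t_s % BURST_INTERVAL_S == 0 and prev_g is not None:
            side_prev = prev_g[0] * pe + prev_g[1] * pn
            p_flap = 1.0 / (1.0 + np.exp(-(spec.flap_intercept + spec.flap_slope * abs(side_prev))))
            flapping = bool(rng.random() < p_flap)
            heave = _heave_burst(flapping, spec, rng)
            for k, h in enumerate(heave):
                burst_rows.append((bird_id, now, k, h, flapping))

        gs = float(np.hypot(ge, gn))
        if gs > 0:
            dest = geo.destination_point(
                geo.GeoPoint(lon, lat), float(np.degrees(np.arctan2(ge, gn))), gs * FIX_INTERVAL_S
            )
            lon, lat = dest.lon, dest.lat
        prev_g = (ge, gn)

    fixes = pd.DataFrame(
        fix_rows,
        columns=["bird_id", "t_s", "lon", "lat", "true_crosswind", "true_tailwind",
                 "true_sideways", "true_airspeed"],
    )
    fixes["t"] = pd.to_datetime((fixes["t_s"] * 1e9).round().astype("int64"), utc=True)
    bursts = pd.DataFrame(burst_rows, columns=["bird_id", "t_s", "sample_idx", "heave", "true_flapping"])
    if len(bursts):
        bursts["t"] = pd.to_datetime((bursts["t_s"] * 1e9).round().astype("int64"), utc=True)
    else:
        bursts["t"] = pd.Series(dtype="datetime64[ns, UTC]")
    info = {"bird_id": bird_id, "status": status, "n_fixes": len(fixes), "n_bursts": len(burst_rows) // (BURST_LEN_S * BURST_HZ) if burst_rows else 0}
    return fixes, bursts, info


# ---------------------------------------------------------------------------
# cohort generation and file bundle
# ---------------------------------------------------------------------------

def gen_cohort(
    n_juv: int,
    n_adult: int,
    spec_by_age: dict[str, BirdSpec] | None = None,
    script: WindScript | None = None,
    seed: int = 0,
    out_dir=None,
    start_window_days: tuple[float, float] | None = None,
    start_lon_range: tuple[float, float] = (-5.85, -5.45),
    gs_noise_sd: float = GS_NOISE_SD,
):
    """Generate a full ingest-ready input bundle with its truth manifest.

    Birds depart from just south of the northern shore at random
    longitudes, at times drawn uniformly from ``start_window_days``
    (default: the whole script span minus the last 5 h so every crossing
    has wind coverage).  Same seed ⇒ identical bundle.
    """
    spec_by_age = spec_by_age or DEFAULT_SPECS
    script = script or default_wind_script()
    rng = np.random.default_rng(seed)
    wind = gen_wind(script, rng)
    spain, morocco, geofence = gen_coastlines()
    if start_window_days is None:
        start_window_days = (0.0, max(script.n_days - 5.0 / 24.0 - MAX_CROSSING_S / 86400.0, 0.25))
    t0 = pd.Timestamp(script.start_date, tz="UTC")

    all_fixes, all_bursts, truth_birds = [], [], []
    ages: dict[str, str] = {}
    plan = [("J%02d" % (i + 1), "juvenile") for i in range(n_juv)] + [
        ("A%02d" % (i + 1), "adult") for i in range(n_adult)
    ]
    for bird_id, age in plan:
        spec = spec_by_age[age]
        lon = float(rng.uniform(*start_lon_range))
        lat = float(_spain_lat(lon) - 0.02)  # ≈2.2 km south of the northern shore
        day = float(rng.uniform(*start_window_days))
        start_time = t0 + pd.Timedelta(seconds=round(day * 86400 / 10) * 10)
        fixes, bursts, info = simulate_bird(
            bird_id, spec, wind, geo.GeoPoint(lon, lat), start_time, morocco, geofence, rng,
            gs_noise_sd=gs_noise_sd,
        )
        ages[bird_id] = age
        all_fixes.append(fixes)
        all_bursts.append(bursts)
        truth_birds.append(
            {
                "bird_id": bird_id,
                "age_class": age,
                "start_lon": lon,
                "start_lat": lat,
                "start_time": str(start_time),
                **{f.name: getattr(spec, f.name) for f in dataclasses.fields(spec)},
                **info,
            }
        )

    fixes = (
        pd.concat(all_fixes, ignore_index=True)
        if all_fixes
        else pd.DataFrame(columns=["bird_id", "t", "lon", "lat", "true_crosswind",
                                   "true_tailwind", "true_sideways", "true_airspeed"])
    )
    bursts = (
        pd.concat(all_bursts, ignore_index=True)
        if all_bursts
        else pd.DataFrame(columns=["bird_id", "t", "sample_idx", "heave", "true_flapping"])
    )
    truth = {"seed": seed, "n_juv": n_juv, "n_adult": n_adult, "birds": truth_birds}
    bundle = {
        "fixes": fixes,
        "bursts": bursts,
        "wind": wind,
        "ages": ages,
        "spain": spain,
        "morocco": morocco,
        "geofence": geofence,
        "truth": truth,
    }
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def write_bundle(bundle, out_dir) -> None:
    """Write the bundle as the CSV/GeoJSON files the ingest readers expect."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fx = bundle["fixes"]
    pd.DataFrame(
        {
            "bird_id": fx["bird_id"],
            "timestamp": fx["t"].dt.strftime("%Y-%m-%dT%H:%M:%SZ") if len(fx) else [],
            "lon": fx["lon"].round(7) if len(fx) else [],
            "lat": fx["lat"].round(7) if len(fx) else [],
        }
    ).to_csv(out / "fixes.csv", index=False)
    pd.DataFrame(
        {"bird_id": list(bundle["ages"]), "age_class": list(bundle["ages"].values())}
    ).to_csv(out / "ages.csv", index=False)
    w = bundle["wind"]
    pd.DataFrame(
        {
            "station_id": w["station_id"],
            "timestamp": w["t"].dt.strftime("%Y-%m-%dT%H:%M:%SZ"),
            "wind_speed_ms": w["wind_speed_ms"].round(4),
            "wind_dir_deg": w["wind_dir_deg"].round(3),
        }
    ).to_csv(out / "wind.csv", index=False)
    b = bundle["bursts"]
    pd.DataFrame(
        {
            "bird_id": b["bird_id"],
            "burst_start": b["t"].dt.strftime("%Y-%m-%dT%H:%M:%SZ") if len(b) else [],
            "sample_idx": b["sample_idx"] if len(b) else [],
            "heave": b["heave"].round(5) if len(b) else [],
        }
    ).to_csv(out / "bursts.csv", index=False)
    gj = geo.coastlines_to_geojson([bundle["spain"], bundle["morocco"]], bundle["geofence"])
    with open(out / "coastlines.geojson", "w") as fh:
        json.dump(gj, fh)
        fh.write("\n")
    with open(out / "truth.json", "w") as fh:
        json.dump(bundle["truth"], fh, indent=2, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# labelled calibration bursts (flapping model recovery)
# ---------------------------------------------------------------------------

def gen_flap_bursts(
    n_birds: int,
    n_bursts: int,
    spec: BirdSpec | None = None,
    seed: int = 0,
    sideways_sd: float = 2.0,
):
    """Labelled burst set: |sideways| per burst, logistic flap draw, heave series.

    Emulates the video-calibration design: sideways speeds are drawn
    half-normal(sd), the flap label follows the bird's logistic model and
    the heave series follow the flap/glide amplitude distributions.
    Returns (long-format burst table, per-burst truth frame).
    """
    spec = spec or DEFAULT_SPECS["adult"]
    rng = np.random.default_rng(seed)
    t0 = pd.Timestamp("2012-08-01", tz="UTC")
    burst_rows, truth_rows = [], []
    for b in range(n_birds):
        bird_id = "B%03d" % (b + 1)
        for j in range(n_bursts):
            t = t0 + pd.Timedelta(seconds=(b * n_bursts + j) * BURST_INTERVAL_S)
            abs_side = abs(rng.normal(0.0, sideways_sd))
            p = 1.0 / (1.0 + np.exp(-(spec.flap_intercept + spec.flap_slope * abs_side)))
            flapping = bool(rng.random() < p)
            heave = _heave_burst(flapping, spec, rng)
            for k, h in enumerate(heave):
                burst_rows.append((bird_id, t, k, h))
            truth_rows.append((bird_id, t, abs_side, flapping))
    bursts = pd.DataFrame(burst_rows, columns=["bird_id", "t", "sample_idx", "heave"])
    truth = pd.DataFrame(truth_rows, columns=["bird_id", "t", "abs_sideways", "true_flapping"])
    return bursts, truth


# ---------------------------------------------------------------------------
# end-to-end drift recovery experiment
# ---------------------------------------------------------------------------

def drift_recovery_experiment(
    gamma: float,
    n_birds: int = 20,
    seed: int = 0,
    wind_mean: float = 10.0,
    dir_jitter_sd: float = 15.0,
    regime: str = "east",
) -> dict:
    """Simulate a cohort at compensation γ under one steady wind episode,
    run the full ingest + kinematics pipeline, and fit the drift model.

    Returns the crosswind slope with its robust 95 % CI — the quantity
    whose expectation is 1 − γ by construction of the generator.
    """
    from . import kinematics
    from .stats import fit_gee_independence

    script = WindScript(episodes=[WindEpisode(0, 1, regime, wind_mean, dir_jitter_sd)], n_days=1)
    spec = BirdSpec(age_class="adult", compensation=gamma)
    bundle = gen_cohort(
        0,
        n_birds,
        spec_by_age={"adult": spec},
        script=script,
        seed=seed,
        start_window_days=(0.05, 0.70),
    )
    frame = kinematics.build_frame(
        bundle["fixes"][["bird_id", "t", "lon", "lat"]].assign(
            age_class=bundle["fixes"]["bird_id"].map(bundle["ages"])
        ),
        bundle["wind"],
        bundle["spain"],
        bundle["morocco"],
        bundle["geofence"],
    )
    fit = fit_gee_independence(
        frame, "sideways", ["crosswind_target_signed", "tailwind_target"], family="gaussian"
    )
    lo, hi = fit.ci95("crosswind_target_signed")
    return {
        "slope": fit["crosswind_target_signed"],
        "lo95": lo,
        "hi95": hi,
        "n_obs": fit.n_obs,
        "n_clusters": fit.n_clusters,
        "frame": frame,
        "fit": fit,
    }
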