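"""The model suite: drift verdicts, flapping models, speed modulation,
per-crossing summaries and age-class comparisons.

The central question is whether birds drift with or compensate for the
crosswind.  Over a crossing, a bird's sideways speed (ground-velocity
component perpendicular to the target bearing) is regressed on the
signed crosswind component while correcting for tailwind:

    sideways ~ crosswind_target_signed + tailwind_target      (Gaussian GEE)

Full drift corresponds to a crosswind slope of 1 (the bird is carried in
direct proportion to the crosswind), full compensation to a slope with
no significant effect.  Verdicts are read from the robust 95 % CI of the
slope: "compensation" if the CI contains 0 and excludes 1, "full_drift"
if it contains 1 and excludes 0, "partial_drift" otherwise.

Models are fitted per age class × wind regime.  The flapping-probability
model is restricted to the east (Levanter) regime, where acceleration
coverage is adequate by design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geo
from .errors import InputError
from .stats import FitResult, chisq_2x2_yates, fit_gee_independence, welch_t

MIN_CLUSTERS = 3


@dataclass
class CrossingSummary:
    """One bird-crossing: departure geometry, wind exposure, timing."""

    bird_id: str
    age_class: str
    regime: str
    start_time: pd.Timestamp
    start_dist_morocco: float
    mean_crosswind_target: float
    crossed_on_drop_day: bool


@dataclass
class DriftVerdict:
    """Crosswind slope of the sideways-speed model and its reading."""

    slope: float
    ci95: tuple[float, float]
    verdict: str  # full_drift | partial_drift | compensation


@dataclass
class InsufficientData:
    """Explicit marker for a stratum too small (or excluded by design) to model."""

    reason: str
    by_design: bool = False


def _stratum(frame: pd.DataFrame, age_class: str | None, regime: str | None) -> pd.DataFrame:
    sel = frame
    if age_class is not None:
        sel = sel[sel["age_class"] == age_class]
    if regime is not None:
        sel = sel[sel["regime"] == regime]
    return sel


def classify_drift(slope: float, ci95: tuple[float, float]) -> str:
    """Verdict rules; exhaustive and mutually exclusive for any interval."""
    lo, hi = ci95
    contains0 = lo <= 0.0 <= hi
    contains1 = lo <= 1.0 <= hi
    if contains0 and not contains1:
        return "compensation"
    if contains1 and not contains0:
        return "full_drift"
    return "partial_drift"


def fit_drift_model(
    frame: pd.DataFrame, age_class: str | None = None, regime: str | None = None
) -> tuple[FitResult, DriftVerdict] | InsufficientData:
    """Sideways-speed drift model for one age × regime stratum."""
    sel = _stratum(frame, age_class, regime)
    n_clusters = sel["bird_id"].nunique() if not sel.empty else 0
    if n_clusters < MIN_CLUSTERS:
        return InsufficientData(
            f"drift model for age={age_class} regime={regime}: "
            f"{n_clusters} clusters < {MIN_CLUSTERS}"
        )
    fit = fit_gee_independence(
        sel, "sideways", ["crosswind_target_signed", "tailwind_target"], family="gaussian"
    )
    ci = fit.ci95("crosswind_target_signed")
    verdict = DriftVerdict(
        slope=fit["crosswind_target_signed"], ci95=ci, verdict=classify_drift(fit["crosswind_target_signed"], ci)
    )
    return fit, verdict


def fit_flap_model(
    frame_with_bursts: pd.DataFrame, age_class: str | None = None, regime: str = "east"
) -> FitResult | InsufficientData:
    """Binomial GEE: probability of flapping vs absolute sideways speed.

    West-regime calls are refused by design: acceleration coverage is
    inadequate there, mirroring the study's east-only comparison.
    """
    if regime != "east":
        return InsufficientData(
            f"flapping model restricted to the east regime (requested {regime!r})", by_design=True
        )
    sel = _stratum(frame_with_bursts, age_class, regime).copy()
    n_clusters = sel["bird_id"].nunique() if not sel.empty else 0
    if n_clusters < MIN_CLUSTERS:
        return InsufficientData(
            f"flap model for age={age_class}: {n_clusters} clusters < {MIN_CLUSTERS}"
        )
    sel["abs_sideways"] = sel["sideways"].abs()
    sel["flapping"] = sel["flapping"].astype(float)
    return fit_gee_independence(sel, "flapping", ["abs_sideways"], family="binomial")


def fit_flap_speed_effect(
    frame_with_bursts: pd.DataFrame, age_class: str = "adult", regime: str = "east"
) -> tuple[FitResult, FitResult] | InsufficientData:
    """Gaussian GEEs of airspeed and ground speed on the flapping indicator."""
    sel = _stratum(frame_with_bursts, age_class, regime).copy()
    n_clusters = sel["bird_id"].nunique() if not sel.empty else 0
    if n_clusters < MIN_CLUSTERS:
        return InsufficientData(
            f"flap-speed model for age={age_class} regime={regime}: "
            f"{n_clusters} clusters < {MIN_CLUSTERS}"
        )
    sel["flapping"] = sel["flapping"].astype(float)
    air = fit_gee_independence(sel, "airspeed", ["flapping"], family="gaussian")
    gnd = fit_gee_independence(sel, "ground_speed", ["flapping"], family="gaussian")
    return air, gnd


def fit_speed_models(
    frame: pd.DataFrame, age_class: str | None = None, regime: str | None = None
) -> tuple[FitResult, FitResult] | InsufficientData:
    """Airspeed- and ground-speed-modulation models (travel-referenced wind).

    airspeed ~ tailwind_travel + |crosswind_travel| and the same for
    ground speed; crosswind enters in absolute value (no left/right
    distinction).
    """
    sel = _stratum(frame, age_class, regime)
    n_clusters = sel["bird_id"].nunique() if not sel.empty else 0
    if n_clusters < MIN_CLUSTERS:
        return InsufficientData(
            f"speed models for age={age_class} regime={regime}: "
            f"{n_clusters} clusters < {MIN_CLUSTERS}"
        )
    preds = ["tailwind_travel", "crosswind_travel_abs"]
    air = fit_gee_independence(sel, "airspeed", preds, family="gaussian")
    gnd = fit_gee_independence(sel, "ground_speed", preds, family="gaussian")
    return air, gnd


# ---------------------------------------------------------------------------
# crossing summaries & timing
# ---------------------------------------------------------------------------

def detect_drop_days(
    wind: pd.DataFrame,
    high_thresh_ms: float = 9.0,
    drop_frac: float = 0.5,
    min_high_days: int = 2,
) -> set:
    """Calendar dates on which wind speed collapses after a strong easterly spell.

    A date qualifies iff each of the preceding ``min_high_days`` days had
    an easterly daily-mean regime with mean speed above ``high_thresh_ms``,
    and its own daily-mean speed is below ``drop_frac`` × the previous
    day's mean.
    """
    if wind.empty:
        return set()
    from .wind import met_to_uv

    w = wind.copy()
    w["date"] = w["t"].dt.date
    u, _ = met_to_uv(w["wind_speed_ms"].to_numpy(), w["wind_dir_deg"].to_numpy())
    w["east_comp"] = -u
    daily = w.groupby("date").agg(speed=("wind_speed_ms", "mean"), east=("east_comp", "mean"))
    daily = daily.sort_index()
    dates = list(daily.index)
    out = set()
    for i, d in enumerate(dates):
        if i < min_high_days:
            continue
        prior = daily.iloc[i - min_high_days : i]
        # the prior days must be consecutive calendar days
        expected = [d - pd.Timedelta(days=k).to_pytimedelta() for k in range(min_high_days, 0, -1)]
        if list(prior.index) != expected:
            continue
        if not ((prior["east"] > 0).all() and (prior["speed"] > high_thresh_ms).all()):
            continue
        if daily.iloc[i]["speed"] < drop_frac * prior["speed"].iloc[-1]:
            out.add(d)
    return out


def summarize_crossing(
    bird_frame: pd.DataFrame, drop_days: set
) -> CrossingSummary:
    """Per-crossing summary from one bird's retained analysis rows.

    The crossing start is the first retained fix; mean crosswind is the
    mean absolute target-referenced crosswind over retained fixes (the
    non-negative "crosswind speed experienced"); the regime is the
    whole-crossing majority label already on the frame.
    """
    if len(bird_frame) < 2:
        raise InputError("crossing summary needs >= 2 retained fixes")
    bird_frame = bird_frame.sort_values("t")
    first = bird_frame.iloc[0]
    return CrossingSummary(
        bird_id=str(first["bird_id"]),
        age_class=str(first["age_class"]),
        regime=str(first["regime"]),
        start_time=first["t"],
        start_dist_morocco=float(first["dist_morocco"]),
        mean_crosswind_target=float(bird_frame["crosswind_target_signed"].abs().mean()),
        crossed_on_drop_day=first["t"].date() in drop_days,
    )


def summarize_crossings(frame: pd.DataFrame, drop_days: set) -> pd.DataFrame:
    """All per-bird crossing summaries as a table; short crossings are skipped."""
    rows = []
    for _, grp in frame.groupby("bird_id", sort=False):
        if len(grp) < 2:
            continue
        s = summarize_crossing(grp, drop_days)
        rows.append(
            (s.bird_id, s.age_class, s.regime, s.start_time, s.start_dist_morocco,
             s.mean_crosswind_target, s.crossed_on_drop_day)
        )
    return pd.DataFrame(
        rows,
        columns=["bird_id", "age_class", "regime", "start_time", "start_dist_morocco",
                 "mean_crosswind_target", "crossed_on_drop_day"],
    )


def compare_ages(summaries: pd.DataFrame, regime: str) -> dict:
    """Juvenile-vs-adult comparisons within a wind regime.

    Welch t-tests on the per-crossing mean crosswind speed and on the
    start distance to the destination coast; Yates chi-square on
    drop-day crossing counts over all birds (both regimes pooled).
    """
    sel = summaries[summaries["regime"] == regime]
    juv = sel[sel["age_class"] == "juvenile"]
    adu = sel[sel["age_class"] == "adult"]
    report: dict = {"regime": regime, "n_juvenile": len(juv), "n_adult": len(adu)}
    for col, label in (
        ("mean_crosswind_target", "crosswind"),
        ("start_dist_morocco", "start_distance"),
    ):
        if len(juv) >= 2 and len(adu) >= 2:
            try:
                t, df, p = welch_t(juv[col], adu[col])
                report[label] = {"t": t, "df": df, "p": p}
            except InputError:
                report[label] = None  # degenerate (zero-variance) samples
        else:
            report[label] = None
    adu_all = summaries[summaries["age_class"] == "adult"]
    juv_all = summaries[summaries["age_class"] == "juvenile"]
    a = int(adu_all["crossed_on_drop_day"].sum())
    b = len(adu_all) - a
    c = int(juv_all["crossed_on_drop_day"].sum())
    d = len(juv_all) - c
    try:
        chi2, p = chisq_2x2_yates(a, b, c, d)
        report["drop_day"] = {"table": [[a, b], [c, d]], "chi2": chi2, "p": p}
    except InputError:
        report["drop_day"] = None
    return report


def fit_model_suite(frame: pd.DataFrame, frame_with_bursts: pd.DataFrame | None = None) -> dict:
    """Fit the full per-stratum model suite; returns a nested results dict.

    Strata with too few birds yield explicit insufficient-data markers
    rather than errors.
    """
    results: dict = {"drift": {}, "speed": {}, "flap": {}, "flap_speed": None}
    for age in ("juvenile", "adult"):
        for regime in ("east", "west"):
            key = f"{age}_{regime}"
            results["drift"][key] = fit_drift_model(frame, age, regime)
            results["speed"][key] = fit_speed_models(frame, age, regime)
    if frame_with_bursts is not None:
        for age in ("juvenile", "adult"):
            results["flap"][f"{age}_east"] = fit_flap_model(frame_with_bursts, age, "east")
        results["flap_speed"] = fit_flap_speed_effect(frame_with_bursts, "adult", "east")
    return results
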