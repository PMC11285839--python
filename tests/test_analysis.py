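"""Model suite, drift verdicts, drop-day detection, crossing summaries,
age comparisons."""

import numpy as np
import pandas as pd
import pytest

from straitcross import (
    InsufficientData,
    classify_drift,
    compare_ages,
    detect_drop_days,
    fit_drift_model,
    fit_flap_model,
    fit_flap_speed_effect,
    fit_model_suite,
    fit_speed_models,
    summarize_crossing,
    summarize_crossings,
)
from straitcross.stats import fit_gee_independence
from straitcross.synthetic import (
    BirdSpec,
    WindEpisode,
    WindScript,
    default_wind_script,
    gen_cohort,
    gen_flap_bursts,
    gen_wind,
)

from conftest import frame_from_bundle


class TestClassifyDrift:
    @pytest.mark.parametrize(
        "ci, expected",
        [
            ((-0.2, 0.3), "compensation"),  # contains 0, excludes 1
            ((0.7, 1.4), "full_drift"),  # contains 1, excludes 0
            ((-0.5, 1.5), "partial_drift"),  # contains both
            ((0.3, 0.6), "partial_drift"),  # contains neither
            ((0.0, 1.0), "partial_drift"),  # boundary: contains both
        ],
    )
    def test_rules_exhaustive_and_exclusive(self, ci, expected):
        assert classify_drift(np.mean(ci), ci) == expected

    def test_every_interval_gets_exactly_one_verdict(self, rng):
        for _ in range(100):
            lo = rng.uniform(-2, 2)
            hi = lo + rng.uniform(0, 3)
            v = classify_drift((lo + hi) / 2, (lo, hi))
            assert v in ("compensation", "full_drift", "partial_drift")


class TestDetectDropDays:
    @staticmethod
    def _wind_from_daily(day_speeds, day_dirs):
        rows = []
        t0 = pd.Timestamp("2012-08-01", tz="UTC")
        for d, (sp, di) in enumerate(zip(day_speeds, day_dirs)):
            for k in range(0, 86400, 600):
                rows.append(("s", t0 + pd.Timedelta(days=d, seconds=k), sp, di))
        return pd.DataFrame(rows, columns=["station_id", "t", "wind_speed_ms", "wind_dir_deg"])

    def test_constant_strong_easterly_has_no_drop(self):
        wind = self._wind_from_daily([12, 12, 12, 12], [90, 90, 90, 90])
        assert detect_drop_days(wind) == set()

    def test_drop_after_levanter_spell_is_flagged(self):
        wind = self._wind_from_daily([12, 12, 12, 3], [90, 90, 90, 200])
        days = detect_drop_days(wind)
        assert days == {pd.Timestamp("2012-08-04").date()}

    def test_westerly_spell_never_qualifies(self):
        wind = self._wind_from_daily([12, 12, 12, 3], [270, 270, 270, 200])
        assert detect_drop_days(wind) == set()

    def test_scripted_relaxation_day_recovered(self):
        """The default wind script's calm day after 3 Levanter days is the
        unique drop day."""
        rng = np.random.default_rng(77)
        wind = gen_wind(default_wind_script(), rng)
        days = detect_drop_days(wind)
        assert days == {pd.Timestamp("2012-08-04").date()}


class TestCrossingSummaries:
    @staticmethod
    def _frame(bird="b1", crosswinds=(2.0, -3.0), dist0=15000.0, regime="east"):
        t0 = pd.Timestamp("2012-08-01T10:00:00Z")
        n = len(crosswinds)
        return pd.DataFrame(
            {
                "bird_id": bird,
                "age_class": "adult",
                "t": [t0 + pd.Timedelta(seconds=180 * i) for i in range(n)],
                "regime": regime,
                "crosswind_target_signed": crosswinds,
                "dist_morocco": [dist0 - 1000 * i for i in range(n)],
            }
        )

    def test_start_distance_and_mean_abs_crosswind(self):
        s = summarize_crossing(self._frame(), set())
        assert s.start_dist_morocco == 15000.0
        assert s.mean_crosswind_target == pytest.approx(2.5)  # mean of |2|, |-3|
        assert not s.crossed_on_drop_day

    def test_zero_wind_crossing_has_zero_crosswind(self):
        s = summarize_crossing(self._frame(crosswinds=(0.0, 0.0, 0.0)), set())
        assert s.mean_crosswind_target == 0.0

    def test_drop_day_flag_uses_first_fix_date(self):
        s = summarize_crossing(self._frame(), {pd.Timestamp("2012-08-01").date()})
        assert s.crossed_on_drop_day

    def test_generated_crossing_regime_matches_generator(self, small_bundle):
        frame = frame_from_bundle(small_bundle)
        summaries = summarize_crossings(frame, set())
        # Levanter-only script: every crossing classified east
        assert (summaries["regime"] == "east").all()
        assert summaries["bird_id"].is_unique


class TestCompareAges:
    @staticmethod
    def _summaries(rng, n=15, juv_dist_offset=0.0):
        rows = []
        for i in range(n):
            rows.append(("J%d" % i, "juvenile", "east", 14000 + juv_dist_offset + rng.normal(0, 2000),
                         rng.normal(6, 1.5), i % 2 == 0))
            rows.append(("A%d" % i, "adult", "east", 14000 + rng.normal(0, 2000),
                         rng.normal(6, 1.5), True))
        return pd.DataFrame(
            rows,
            columns=["bird_id", "age_class", "regime", "start_dist_morocco",
                     "mean_crosswind_target", "crossed_on_drop_day"],
        ).assign(start_time=pd.Timestamp("2012-08-01", tz="UTC"))

    def test_identical_age_distributions_give_small_t(self, rng):
        rep = compare_ages(self._summaries(rng, n=40), "east")
        assert abs(rep["crosswind"]["t"]) < 2.5
        assert rep["n_juvenile"] == rep["n_adult"] == 40

    def test_start_distance_offset_detected(self, rng):
        rep = compare_ages(self._summaries(rng, n=15, juv_dist_offset=5000.0), "east")
        assert rep["start_distance"]["p"] < 0.05
        assert rep["start_distance"]["t"] > 0

    def test_drop_day_chi_square_on_printed_counts(self):
        rows = (
            [("A%d" % i, "adult", "east", 1.0, 1.0, True) for i in range(26)]
            + [("A%d" % i, "adult", "east", 1.0, 1.0, False) for i in range(26, 32)]
            + [("J%d" % i, "juvenile", "east", 1.0, 1.0, True) for i in range(18)]
            + [("J%d" % i, "juvenile", "east", 1.0, 1.0, False) for i in range(18, 30)]
        )
        df = pd.DataFrame(
            rows,
            columns=["bird_id", "age_class", "regime", "start_dist_morocco",
                     "mean_crosswind_target", "crossed_on_drop_day"],
        )
        rep = compare_ages(df, "east")
        assert rep["drop_day"]["chi2"] == pytest.approx(2.44, abs=0.005)
        assert rep["drop_day"]["table"] == [[26, 6], [18, 12]]


class TestModelStrata:
    def test_small_stratum_yields_marker_not_crash(self):
        frame = pd.DataFrame(
            {
                "bird_id": ["b1"] * 4,
                "age_class": "adult",
                "regime": "east",
                "sideways": [1.0, 2.0, 1.5, 2.5],
                "crosswind_target_signed": [1.0, 2.0, 3.0, 4.0],
                "tailwind_target": [0.1, 0.2, 0.1, 0.3],
            }
        )
        res = fit_drift_model(frame, "adult", "east")
        assert isinstance(res, InsufficientData)

    def test_flap_model_west_regime_refused_by_design(self):
        res = fit_flap_model(pd.DataFrame(), regime="west")
        assert isinstance(res, InsufficientData) and res.by_design

    def test_constant_flap_probability_recovers_null_slope(self):
        bursts, truth = gen_flap_bursts(
            12, 30, BirdSpec(flap_intercept=0.0, flap_slope=0.0), seed=21
        )
        truth["flapping"] = truth["true_flapping"].astype(float)
        fit = fit_gee_independence(truth, "flapping", ["abs_sideways"], family="binomial")
        lo, hi = fit.ci95("abs_sideways")
        assert lo <= 0.0 <= hi

    def test_flap_speed_effect_recovers_airspeed_delta(self, rng):
        """Flapping adds Δ to airspeed; the Gaussian GEE coefficient finds Δ,
        and permuted labels erase it."""
        delta = 2.5
        n_birds, m = 12, 20
        cl = np.repeat([f"b{i}" for i in range(n_birds)], m)
        flap = rng.random(n_birds * m) < 0.4
        air = 11.0 + delta * flap + rng.normal(0, 1.0, n_birds * m)
        frame = pd.DataFrame(
            {
                "bird_id": cl,
                "age_class": "adult",
                "regime": "east",
                "flapping": flap,
                "airspeed": air,
                "ground_speed": air + rng.normal(0, 0.5, n_birds * m),
            }
        )
        res = fit_flap_speed_effect(frame, "adult", "east")
        air_fit, _ = res
        lo, hi = air_fit.ci95("flapping")
        assert lo <= delta <= hi
        permuted = frame.assign(flapping=rng.permutation(flap))
        air_perm, _ = fit_flap_speed_effect(permuted, "adult", "east")
        assert abs(air_perm["flapping"]) < 0.5


class TestSpeedModels:
    @staticmethod
    def _cohort_frame(spec, seed, script=None):
        script = script or WindScript(
            episodes=[WindEpisode(0, 1, "east", 4.0, 30.0)], n_days=1
        )
        bundle = gen_cohort(
            0, 12, {"adult": spec}, script, seed=seed, start_window_days=(0.05, 0.7)
        )
        return frame_from_bundle(bundle)

    def test_tailwind_slope_recovered_crosswind_slope_positive(self):
        spec = BirdSpec(compensation=0.0, airspeed_tailwind_slope=-0.3,
                        airspeed_crosswind_slope=0.3)
        frame = self._cohort_frame(spec, seed=31)
        air, _ = fit_speed_models(frame, "adult", None)
        lo, hi = air.ci95("tailwind_travel")
        assert lo <= -0.3 <= hi
        # travel-referenced crosswind is a biased proxy for the generator's
        # target-referenced rule: sign and rough magnitude only
        assert 0.1 < air["crosswind_travel_abs"] < 0.8

    def test_calm_constant_airspeed_slopes_near_zero(self):
        spec = BirdSpec(compensation=0.0, airspeed_tailwind_slope=0.0,
                        airspeed_crosswind_slope=0.0)
        calm = WindScript(episodes=[], n_days=1)
        frame = self._cohort_frame(spec, seed=33, script=calm)
        air, _ = fit_speed_models(frame, "adult", None)
        for term in ("tailwind_travel", "crosswind_travel_abs"):
            lo, hi = air.ci95(term)
            assert lo <= 0.0 <= hi or abs(air[term]) < 0.1

    def test_constant_airspeed_ground_speed_tailwind_slope_is_one(self):
        """Pure wind-triangle addition: with fixed airspeed, ground speed rises
        one-for-one with travel tailwind."""
        spec = BirdSpec(compensation=1.0, airspeed_tailwind_slope=0.0,
                        airspeed_crosswind_slope=0.0)
        frame = self._cohort_frame(spec, seed=35)
        _, gnd = fit_speed_models(frame, "adult", None)
        assert gnd["tailwind_travel"] == pytest.approx(1.0, abs=0.15)


def test_model_suite_structure(small_bundle):
    frame = frame_from_bundle(small_bundle)
    results = fit_model_suite(frame)
    assert set(results["drift"]) == {
        "juvenile_east", "juvenile_west", "adult_east", "adult_west"
    }
    # all-adult Levanter bundle: juvenile strata are explicit markers
    assert isinstance(results["drift"]["juvenile_east"], InsufficientData)
    adult_east = results["drift"]["adult_east"]
    assert not isinstance(adult_east, InsufficientData)
    fit, verdict = adult_east
    assert verdict.verdict in ("compensation", "full_drift", "partial_drift")
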