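# Methods

## The scientific problem

Soaring birds crossing a sea strait lose the convective updrafts that
power their flight over land. Under strong crosswinds — in the Strait of
Gibraltar, the easterly "Levanter", which blows steadily toward the open
Atlantic at speeds that can restrict crossings altogether — a crossing
bird must either *drift* (let the wind carry it sideways while it holds
its heading toward the destination coast) or *compensate* (redirect part
of its air velocity into the wind, at extra energetic cost, often by
switching from gliding to flapping flight). This package quantifies
where individual birds sit on that drift–compensation continuum from
three routine biologging inputs: GPS trajectories, triaxial
acceleration bursts, and weather-station wind records.

## The wind-triangle decomposition

All speeds derive from the horizontal wind triangle

    v_ground = v_air + v_wind,

evaluated in a local east–north tangent plane at each fix. Given a
*reference bearing* — the **target bearing** (toward the nearest point
of the destination coastline, recomputed at every fix) or the **travel
bearing** (the bird's own track) — wind and ground velocity are
projected onto the reference axis and its 90°-clockwise perpendicular:

* *tailwind* = wind component along the reference;
* *crosswind* (signed) = wind component on the perpendicular;
* *sideways speed* = ground-velocity component on the same perpendicular;
* *airspeed* = |v_ground − v_wind|.

With a southbound reference the clockwise perpendicular points west, so
an easterly wind has positive crosswind and a westward-drifting bird has
positive sideways speed. **Full drift** is then a sideways-vs-crosswind
regression slope of +1; **full compensation** is a slope
indistinguishable from 0.

Velocities are finite differences of adjacent raw fixes (10-s stream,
gaps > 60 s yield no velocity) and are carried onto the 3-min subsample
used for modelling, preserving instantaneous speeds rather than 3-min
straight-line averages. Airspeed is the full horizontal vector
difference; GPS altitude and vertical wind are not used (station wind is
horizontal and near-surface).

## Filtering pipeline

Fixed order: geofence clip → coastal exclusion (drop fixes strictly
closer than 500 m to either shore, where slope/uplift soaring would
contaminate over-water behaviour) → wind annotation (nearest 10-min
station record in time, ties to the earlier record, no match within
10 min drops the fix with a logged count) → velocity computation on the
raw stream → greedy 3-min subsampling (keep a fix iff ≥ 180 s after the
last kept fix) to reduce serial autocorrelation. The default geofence is
the bounding box lon ∈ [−6.1, −5.2], lat ∈ [35.75, 36.15]; every
constant is a `PipelineConfig` field.

## Statistical machinery

Repeated measures per bird are handled with generalized estimating
equations under an **independence working correlation**: point estimates
are the pooled GLM (Gaussian-identity, or binomial-logit for the
flapping indicator), and the covariance is the cluster-level sandwich
B⁻¹(Σ_c s_c s_cᵀ)B⁻¹ with birds as clusters. No small-sample correction
is applied — plain robust covariance and Wald z, the geepack convention
— so comparability, not small-G refinement, is the design goal. Residual
autocorrelation can be checked with a within-cluster pooled ACF
(biased-denominator estimator, lags never crossing birds).
Consequences of this choice are visible in the tests: at 20–30 clusters
the Wald test is mildly anti-conservative (empirical size ≈ 0.06 at
nominal 0.05) and 95 % CIs cover at ≈ 91–94 %.

Model suite, fitted per age class × wind regime (regimes are labelled
from the signed east wind component, positive = easterly/Levanter;
whole crossings by per-fix majority vote, ties to the first fix):

| model | form |
|---|---|
| drift | sideways ~ signed target crosswind + target tailwind (Gaussian) |
| flapping | flap ~ \|sideways\| (binomial; east regime only, by design) |
| flap effect | airspeed ~ flap, ground speed ~ flap (Gaussian) |
| speed modulation | airspeed / ground speed ~ travel tailwind + \|travel crosswind\| |

The drift verdict reads the crosswind slope's robust 95 % CI:
*compensation* if it contains 0 and excludes 1, *full_drift* if it
contains 1 and excludes 0, *partial_drift* otherwise — CI inclusion
rather than a formal slope-=-1 test, mirroring the verbal definitions of
the framework. Classical comparisons use Welch's unequal-variance t
(flavour chosen because it dominates the pooled test when group
variances differ) and the Yates-corrected 2×2 chi-square; p-values are
two-sided and unadjusted.

## Flapping classification

Each 20-s, 1-Hz heave burst is summarised by its **mean peak-to-trough
amplitude**: successive interior local extrema (plateaus collapsed,
endpoints excluded so partial swings do not bias the mean) and the mean
absolute excursion between them. A burst is "flapping" iff the summary
strictly exceeds `flap_threshold_g`. The threshold has no universal
value — in a field deployment it is calibrated against video of tagged
birds — so it is a required config parameter, and the synthetic
generator emits a labelled calibration set instead. Because "amplitude"
admits other readings, RMS-about-mean and max−min variants are available
behind `amplitude_method`. Bursts join the analysis frame at the
bird's nearest retained fix within 90 s.

## Wind-drop days

Crossing birds favour the day the wind collapses after a multi-day
easterly blow. The detector operationalises this: a date is a drop day
iff each of the preceding ≥ 2 days had easterly daily-mean regime with
mean speed above 9 m s⁻¹ (the lower end of the 9–13 m s⁻¹
crossing-restricting band) and its own daily mean falls below half the
previous day's. All three constants are config fields; the rule is a
deliberate formalisation of a qualitative phenomenon, not a published
algorithm.

## Geodesy

Spherical earth, R = 6 371 000 m — error < 0.5 % at sub-50-km strait
scale, far below anything the analysis depends on. Nearest-point
searches against a coastline polyline run in an azimuthal equidistant
tangent plane centred on the query point (radial distances exact,
in-plane segment interpolation sub-metre at this scale); tests pin the
result to a brute-force densification oracle within 2 m. Offshore
islands are excluded simply by supplying island-free polylines.

## The synthetic generator

The generator is the analysis run backwards, with every behavioural
parameter explicit (`BirdSpec`):

* compensation γ ∈ [0, 1]: the bird cancels a fraction γ of the
  crosswind with a perpendicular air-velocity component, so the
  analysis-side drift slope is 1 − γ by construction (γ = 0 full drift,
  γ = 1 full compensation). Defaults: adults 0.9, juveniles 0.1 —
  strongly compensating adults, drifting juveniles.
* preferred airspeed 12 m s⁻¹ with optional linear modulation on target
  tailwind (−0.3) and |crosswind| (+0.3);
* flap probability logistic in |sideways| (intercept −1.5, slope
  0.6 per m s⁻¹); flapping bursts are 1.2 g sinusoids, gliding bursts
  0.08 g noise, plus 0.05 g sensor noise — cleanly separable at the
  default 0.5 g threshold;
* ground-velocity noise 0.5 m s⁻¹ per component, small against the
  9–13 m s⁻¹ winds so recovery tests stay sharp.

Wind follows a scripted regime sequence (10-min records): easterly
episodes draw direction N(90°, 10°) and speed N(11, 1.5) m s⁻¹
truncated at zero, westerly episodes N(270°, 30°) at 5 m s⁻¹, other
days are calm (≈2.5 m s⁻¹, directionless). The record-to-record draws
are what give the crosswind its variance — under a literally constant
wind the drift slope would be unidentifiable. The stylised strait is two
near-parallel shores 14.0 km apart at the narrowest point, widening both
ways; birds depart ~2 km south of the northern shore at random
longitudes and times and are advanced on 10-s steps until they reach
within 500 m of the southern shore, leave the geofence (returned
truncated with an exit flag), or exceed 4 h.

What the generator does **not** emulate: thermalling and altitude
dynamics, GPS positional error, abort-and-return behaviour,
spatially varying wind fields, and state-dependent flap bout structure.
Passing recovery tests therefore demonstrate that the estimator chain is
correct and calibrated under the model's own assumptions, not that real
tracks satisfy those assumptions.

## Problem sizes and numerical choices

Recovery experiments use 20 birds per replicate (100 replicates) for the
drift-slope checks, 8 birds × 200 replicates per γ for the
monotonicity sweep, 30 birds × 40 bursts × 100 replicates for
flap-slope coverage, and 2 000 replicates of a 30-cluster × 30-obs
direct model-frame simulation for Wald calibration — sizes chosen to
keep Monte-Carlo error well below the effects being measured while the
whole suite runs in minutes on one core. The calibration run simulates
model frames directly (crosswind and tailwind drawn per fix, sideways
pure noise) because it tests the inference machinery, and an agent-based
null under steady wind would give a degenerate, variance-free crosswind
design. IRLS converges on relative deviance change < 1e-10 within 100
iterations; rank deficiency is reported with the first aliased column
name; exact-zero east wind components classify as "west" (a
measure-zero tie, assigned to the benign class).

## Known limitations

* The speed-modulation models regress on travel-referenced wind
  components while the generator's airspeed rule (like a bird's
  presumed control law) acts on target-referenced components; the
  nonlinear mapping between the two frames (drift-angle rotation,
  |g − w| convexity under compensation) biases the fitted |crosswind|
  slope upward relative to the generating constant. The tailwind slope
  recovers within its CI; the crosswind slope should be read as a
  qualitative response.
* Cluster-robust inference is anti-conservative below ~30 birds (no
  small-sample correction, by design).
* The drop-day rule and the flapping threshold are operational choices;
  sensitivity to them is exposed through the config rather than explored
  automatically.
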