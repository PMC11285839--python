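# straitcross

Wind-drift compensation and airspeed-modulation analysis for GPS- and
accelerometer-tracked soaring birds crossing a sea strait.

When a soaring bird crosses open water it loses thermal support, and a
strong crosswind — such as the easterly Levanter funnelling through the
Strait of Gibraltar toward the Atlantic — forces a choice: drift
sideways with the wind, or pay the energetic price (often in flapping
flight) to compensate. `straitcross` turns three routine biologging
inputs (GPS fixes, triaxial-acceleration heave bursts, weather-station
wind records) into a quantitative answer per bird group.

## The core decomposition and model

At each fix the horizontal wind triangle `v_ground = v_air + v_wind` is
resolved against a reference bearing — the *target bearing* toward the
nearest point of the destination coast, or the bird's own *travel
bearing*. This yields tailwind and signed crosswind components, the
bird's *sideways speed* (ground-velocity component perpendicular to the
target bearing) and its airspeed `|v_ground − v_wind|`.

Drift behaviour is the crosswind slope β₁ of the cluster-robust
regression (GEE, independence working correlation, birds as clusters)

    sideways ~ β₀ + β₁ · crosswind + β₂ · tailwind        (Gaussian)

Full drift is β₁ = 1, full compensation is β₁ ≈ 0; the verdict is read
from the robust 95 % CI. Companion models relate flapping probability
to |sideways| (binomial-logit) and air/ground speed to travel-referenced
wind components. Classical comparisons (Welch t, Yates χ²) cover
crossing-timing and departure-geometry differences between age classes.

A synthetic module generates the complete input bundle — scripted wind
regimes, a stylised 14-km strait, agent-based tracks with a known
compensation coefficient γ (so the true drift slope is 1 − γ), and
labelled heave bursts — making every stage testable end to end.

## Worked example

Simulate a small cohort (juveniles drift, γ = 0.1; adults compensate,
γ = 0.9), run the pipeline, and fit the model suite:

```sh
straitcross simulate --seed 42 --n-juv 6 --n-adult 6 --out data
straitcross ingest --fixes data/fixes.csv --ages data/ages.csv \
    --wind data/wind.csv --coast data/coastlines.geojson --out frame.csv
straitcross fit --frame frame.csv --bursts data/bursts.csv \
    --wind data/wind.csv --out results
straitcross report --results results
```

prints

```
drift_adult_east: slope=0.276 [0.213, 0.340] -> partial_drift
drift_adult_west: slope=0.024 [-0.031, 0.079] -> compensation
drift_juvenile_east: insufficient data (drift model for age=juvenile regime=east: 1 clusters < 3)
drift_juvenile_west: slope=1.039 [0.984, 1.094] -> full_drift
...
crossings: 12 birds (4 east / 8 west)
```

Read: adult birds (γ = 0.9) show slopes near 0 — crosswind barely moves
them sideways — while juveniles (γ = 0.1) carry a slope ≈ 1, drifting in
direct proportion to the crosswind; strata with too few birds return an
explicit marker instead of a fit. The same machinery is available as a
library:

```python
>>> from straitcross import chisq_2x2_yates
>>> from straitcross.synthetic import drift_recovery_experiment
>>> chisq_2x2_yates(26, 6, 18, 12)        # drop-day crossings, adults vs juveniles
(2.440548716329966, 0.11823486004609805)
>>> r = drift_recovery_experiment(0.0, n_birds=20, seed=7)   # zero compensation
>>> round(r["slope"], 3), (round(r["lo95"], 3), round(r["hi95"], 3))
(1.003, (0.891, 1.114))
```

The χ² of 2.44 (p = 0.12) says adult and juvenile drop-day crossing
proportions do not differ significantly; the recovery experiment shows
the pipeline returning the definitional full-drift slope of 1 from raw
simulated tracks.

## Layout

```
src/straitcross/
  geo.py         spherical geodesy, coastline nearest-point, GeoJSON I/O
  ingest.py      CSV readers, geofence/buffer clipping, subsampling, wind annotation
  wind.py        met-convention vectors, east/west regime classification
  kinematics.py  ground velocity, wind-triangle decompositions, analysis frame
  flapping.py    heave-amplitude burst classification
  stats.py       GEE-independence + cluster sandwich, partial effects, ACF, t/χ²
  analysis.py    model suite, drift verdicts, drop days, age comparisons
  synthetic.py   wind scripts, stylised strait, agent-based simulator
  cli.py         simulate / ingest / fit / report subcommands
docs/methods.md  model assumptions, conventions, parameter defaults, limitations
```
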