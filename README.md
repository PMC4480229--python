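# pleuston

Individual-based drift modelling for pleustonic organisms — animals such as
the Portuguese Man-of-War (*Physalia physalis*) that live at the air–sea
interface and are carried simultaneously by surface currents and by the
wind acting on their sail-like float.

The package is aimed at coastal ecologists and physical oceanographers who
want to ask questions like: *given a winter of anomalously persistent
westerlies, where do open-ocean colonies end up, which beaches receive
them, in what order, and where did a mass stranding originate?* It
provides the full chain needed to study such events on idealized,
fully synthetic domains: scenario generation (a Gulf-of-Cadiz/Alboran-like
two-basin domain joined by a narrow strait, gyre basins, open coasts),
depth-band seeding, the drift model itself, beaching detection and
statistics, backward source localization and wind diagnostics.

## The model

Each colony is an inert surface drifter. Its velocity is

```
dx/dt = u_c(x, t) + α · R(±θ_eff(|w|)) · w(x, t)
```

where `u_c` is the surface current, `w` the 10-m wind, and `α = 0.10` the
windage (leeway) coefficient: colonies are transported downwind at 10% of
the wind speed. `R` is an optional rotation for the two mirror-image
("left"/"right") colony morphologies, whose sail drives them at an angle
`θ_eff` of 10–15° to the left or right of the wind; the angle tapers
linearly to zero for winds stronger than a threshold (default 10 m/s),
since the sail flattens under intense wind. By default handedness is off
and colonies drift dead downwind.

Trajectories are integrated with fixed-step RK4 (default `dt` = 30 min) in
geographic coordinates; velocity fields are sampled bilinearly in space
(land cells carry zero weight) and linearly in time. A colony strands —
permanently — when its stepped position enters a land cell; the crossing
point and time are recorded and assigned to the nearest beach segment.
Backward integration (negated velocities, time reversed, beaching
disabled) turns an observed arrival segment and window into an estimate of
where the arriving population sat a given lookback earlier.

## Worked example

A 2,000-colony population seeded on the western shelf (20–200 m depth) of
the two-basin domain, driven for 60 days by steady 8 m/s westerlies with a
slight onshore component plus a 1 m/s eastward strait jet:

```python
import numpy as np
import pleuston as pl

grid = pl.GridSpec(-10, 0, 34, 38, 200, 100, ["2010-01-15", "2010-03-30"])
sc = pl.make_scenario("two_basin_strait", grid)
currents = pl.make_current_field(sc, "strait_jet", speed=1.0)
wg = pl.GridSpec(-10, 0, 34, 38, 2, 2, ["2010-01-01"])
winds = pl.make_wind_field(wg, [("2010-01-01", "2010-05-01", 8.0, 0.5)])
env = pl.Environment(sc, currents, winds)

pop = pl.seed_depth_band(sc, 20, 200, 2000, rng_seed=7, bbox=(-9.5, -8.0, 36.0, 38.0))
traj, records = pl.run_simulation(pop, env, pl.DriftConfig(), "2010-01-26", "2010-03-27")
print(pop.status_counts())

counts, first, unassigned = pl.count_per_beach(records, sc.beaches, sc)
table = pl.density_per_100m(counts, sc.beaches, first)
print(table.table[table.table["count"] > 0].head())
```

This prints

```
{'active': 0, 'stranded': 1367, 'exited': 633}
   beach_id       lon        lat  ...  count  density_per_100m       first_arrival
3       B03 -9.396985  37.434343  ...      9          0.018440 2010-01-26 12:46:13
5       B05 -8.793970  37.434343  ...     54          0.110642 2010-01-26 12:46:01
7       B07 -8.190955  37.434343  ...    100          0.204893 2010-01-26 13:29:14
9       B09 -7.587940  37.434343  ...    114          0.233578 2010-01-26 14:55:02
11      B11 -6.984925  37.434343  ...    120          0.245872 2010-01-27 05:09:51
```

Densities scale with the seeded population size; the spatial pattern and
the arrival ordering, not the absolute magnitudes, are the meaningful
outputs.

Over two thirds of the strandings occur east of the strait — the synthetic
analog of an Atlantic population being pushed into the Mediterranean — and
the mean stranding time per beach increases monotonically from west to
east (Spearman ρ = 1.0 in this run).

A thin CLI wraps the same functions for shell use
(`pleuston make-env | seed | simulate | backtrack | windstats`); see
`pleuston --help`.

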