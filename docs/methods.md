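# Methods

## Drift rule

A colony is modelled as an inert drifter at the sea surface. Its velocity
is the vector sum of the local surface current and a windage term,

    v(x, t) = u_c(x, t) + α · R(s·θ_eff(|w|)) · w(x, t),

with `α` the windage coefficient (default 0.10: drift at 10% of the 10-m
wind speed, in the wind direction), `w` the 10-m wind, and `R` a rotation
applied only in the handedness variant. Handedness sign convention:
"right" colonies deviate clockwise (to the right of the wind when looking
downwind, `s = −1`), "left" counterclockwise (`s = +1`). The sailing
angle is

    θ_eff(|w|) = θ_max · clip(1 − (|w| − w_t)/w_t, 0, 1),

i.e. the full configured angle `θ_max` (default 12.5°, admissible 10–15°)
up to the taper wind speed `w_t` (default 10 m/s), decaying linearly to
zero at `2·w_t`. Only the direction of the taper is empirically
constrained (the sail angle decreases under intense winds); the linear
form and the factor-of-two endpoint are this package's choice, exposed as
parameters. The main configuration has handedness off: colonies drift
dead downwind, which is also why the mirror-symmetry and mix-sensitivity
suites treat the variant as a perturbation of the baseline.

Whether the windage should act on 10-m winds or on surface-stress
equivalents is unresolved observationally; 10-m winds are assumed.

## Coordinates and metrics

All positions are geographic degrees. Metric conversions use a local
equirectangular approximation: one degree of latitude is `R_E·π/180 ≈
111.19 km` and one degree of longitude carries a `cos(lat)` factor. For
domains spanning < 10° of latitude the induced error is far below the
grid resolution, and the same formula is used consistently for field
construction, integration, beach lengths and distances, so internal
comparisons are exact.

## Time stepping

Fixed-step RK4 (default `dt = 1800 s`) on the degree-space ODE; a forward
Euler option exists for oracle comparisons. The advection scheme and step
of the original tool chain behind the study this emulates are not
documented; RK4 was chosen because it makes the integrator error
negligible at desk cost (uniform-flow displacement matches `u·t` to 1e-6
relative; a solid-body gyre orbit conserves its radius to well under 2%
over 30 days). A CFL-like guard emits a warning (never an error) when a
particle crosses more than one grid cell in a single step.

Velocity sampling is bilinear in space and linear in time. Land nodes
carry zero velocity and zero interpolation weight; the remaining weights
are renormalized over ocean nodes, which keeps near-coast speeds
continuous and avoids a spurious onshore pull. A field with a single time
node is steady and covers every instant.

## Beaching

A particle strands when its stepped position lands in a land cell (cells
are node-centred; the land test uses the nearest node). The coastline
crossing is located by bisection along the sub-step chord (the recorded
point lies in the boundary land cell), the crossing time by linear
interpolation of the step interval, and the event is assigned to the
nearest beach segment. Stranding is terminal: no tidal re-floating is
modelled. Particles stepping outside the grid become `exited` and also
never move again, so `n_seeded = n_active + n_stranded + n_exited` holds
exactly after every step.

## Synthetic environments

The generator produces the geographic elements the drift analysis needs,
not a hindcast of any real circulation:

* **two_basin_strait** — land bands on the northern and southern edges
  and a central landmass rising from the southern band toward the
  northern coast, leaving a single strait gap that hugs the northern
  shelf (as the real Gibraltar passage hugs the Iberian side). Default
  proportions: coast bands 15% of the domain height, strait 6% of the
  width, gap 15% of the height. Construction fails if the strait or its
  gap resolves to fewer than two cells.
* **open_coast** — land along the northern edge only.
* **single_gyre_basin** — a closed land ring for retention experiments.

Bathymetry follows an exponential offshore profile computed from the
distance-to-land transform: 20 m one cell offshore, 200 m at a
configurable offshore distance (default 12 cells), saturating at 1000 m.
This guarantees the 20–200 m seeding band exists along every coast by
construction. Beach segments are maximal straight runs of coastal land
nodes grouped by facing direction, split into chunks of at most
`beach_max_cells` (default 12) nodes and labelled west to east, which
makes alongshore orderings well-defined.

Current kinds: `uniform`; `gyre` (solid-body speed `peak·r/R` inside
radius `R`, exponential decay outside, anticyclonic = clockwise, tapered
to zero within a few cells of the coast so normal flow vanishes at the
basin boundary); `strait_jet` (eastward Gaussian jet centred on the strait
gap, decaying into both basins); `slope_current` (along-isobath flow
peaked at a target depth, coast-on-left by default, the analog of the
slope current feeding the strait inflow); and `composite` (exact sum of
parts). Winds are piecewise-constant episodes of stated (u, v) on their
own — usually very coarse — grid; values at grid times inside an episode
window equal the episode vector, zero outside. Note that with linear time
interpolation an episode edge is only sharp if the wind grid carries time
nodes near it.

All generators are deterministic: regeneration from the same parameters
is bit-identical.

### What the generator does not emulate

No mesoscale turbulence, no tides, no Stokes drift, no realistic 2010
circulation. Passing tests therefore demonstrate the correctness and the
qualitative behaviour of the method (transport through the strait,
west-to-east arrivals, retention in gyres), not a quantitative hindcast of
any observed stranding densities, which would require reanalysis winds
and a realistic hydrodynamic model supplied by the user.

## Seeding

`seed_depth_band` draws positions uniformly over the area between two
isobaths (default 20–200 m, the shelf band where an overwintering
population sits when onshore winds arrive) by rejection sampling on the
bounding box with a `cos(lat)` area correction; depth at a candidate is
bilinear in the bathymetry, consistent with velocity interpolation. The
reference population size is 25,000 colonies. Handedness labels are
assigned in exact largest-remainder proportion to the requested mix
(default 100% `none`) and shuffled by the seeded RNG. An optional
bounding box confines the seeded region, used by experiments that start
from a localized offshore population. Whether a real pre-stranding
population is uniform over the band is unknown; uniform is assumed.

## Backward source localization

`localize_origin` releases `n` virtual colonies one grid cell seaward of
the arrival segment (jittered uniformly along it; pushed up to three
cells out at concave corners), at release times uniform over the arrival
window snapped to the step grid, and integrates all of them backward to
the common origin epoch `t_start − lookback`. The endpoint cloud is thus
a snapshot of the estimated source population at one earlier instant —
the natural reading of "where was this population a month earlier" — and
its convex hull (excluding any boundary-clamped endpoints, whose fraction
is reported) is the origin estimate. Backward mode disables beaching and
exit so an origin region is always produced; backward beaching would be
physically meaningless.

Release geometry and ensemble size are not observationally constrained;
the defaults above are this package's protocol. Round-trip experiments
(forward run from a seed patch, then localization from the most-hit
segment) recover the seed region with Jaccard overlap ≈ 0.3–0.5 at desk
scale; recovery is systematically better under steady forcing than under
strongly unsteady forcing, because the release protocol pairs positions
and times randomly rather than as the forward flow did.

## Stranding statistics

Counts are aggregated per beach segment (records farther than 2 grid
cells from any segment are kept and reported as unassigned), and the
density is `100·count/length` in colonies per 100 m of coastline, with
zero-count beaches retained. Simulated and observed tables are compared
by Spearman rank correlation of densities (the headline statistic:
pattern similarity is the claim of interest, and sparse resampling of
real beaches makes magnitudes unreliable), the RMS difference of log10
densities over beaches nonzero in both, and the west-to-east
first-arrival concordance of each table. Rank ties use the average-rank
method; repeated survey dates on a beach are summed over the analysis
window. No significance test is attached to the comparison.

## Wind diagnostics

The monthly zonal-wind climatology is the `cos(lat)`-weighted spatial
mean of `u` over a box, averaged per calendar month across the requested
years (daily source fields are assumed; the function accepts any time
sampling). Anomaly ratios divide a target winter's monthly means by the
climatology, flagging months where the climatology is zero or
sign-opposed rather than returning infinities. Kinematic wind stress uses
the standard bulk form `τ/ρ = C_d·|w|·w` with constant `C_d = 1.3e-3`
(exposed as a parameter; the original analysis did not state its
formula), sampled at the nearest grid node and averaged per day.
Reproducing a real winter's anomaly magnitudes requires user-supplied
reanalysis winds; the shipped tests exercise the diagnostics on synthetic
fields with known answers.

## Problem sizes and defaults used in the shipped experiments

The test-suite experiments run on 200×100 grids (≈ 4.5 km cells, of the
same order as the 2-km hindcast the study conditions assume) with 300 to
2,000 particles over 14 to 60 simulated days, and the full 25,000-colony
initialization is exercised for seeding itself. These sizes make every
qualitative behaviour (strait transport, west-to-east progression,
round-trip recovery, mix insensitivity) measurable in seconds to tens of
seconds while remaining faithful to the configuration of the full-scale
analysis.

## Known limitations

* Beaching resolution is one grid cell; sub-cell coastline geometry is
  not represented, and a fast particle can step across a thin land
  feature (the CFL guard warns).
* The equirectangular metric degrades poleward of ~60° and for domains
  much wider than 10°.
* Backward localization inverts only the deterministic drift; it cannot
  represent diffusion or the loss of information at the coast, so hulls
  should be read as cores of the plausible origin region, not confidence
  regions.
* Episodic winds are spatially uniform unless a latitude gradient is
  supplied; no synoptic structure is generated.
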