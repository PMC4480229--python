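"""The drift rule and its time stepping: windage, handedness, beaching."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pleuston as pl
from pleuston.seeding import STATUS_ACTIVE, STATUS_EXITED, STATUS_STRANDED

from conftest import bounds_of, steady_wind

T = "2010-01-15"


def _env(scenario, cur_kind="uniform", cur_params=None, wind_uv=(0.0, 0.0)):
    cur = pl.make_current_field(scenario, cur_kind, **(cur_params or {"u": 0.0, "v": 0.0}))
    wind = steady_wind(bounds_of(scenario.grid), *wind_uv)
    return pl.Environment(scenario, cur, wind)


# ---------------------------------------------------------------------------
# drift_velocity
# ---------------------------------------------------------------------------

def test_windage_is_ten_percent_of_wind(coast_scenario):
    env = _env(coast_scenario, wind_uv=(5.0, 0.0))
    u, v = pl.drift_velocity((2.0, 34.5), T, env.currents, env.winds)
    assert (u, v) == pytest.approx((0.5, 0.0), abs=1e-12)


def test_current_only_drift(coast_scenario):
    env = _env(coast_scenario, cur_params={"u": 0.2, "v": 0.0})
    u, v = pl.drift_velocity((2.0, 34.5), T, env.currents, env.winds)
    assert (u, v) == pytest.approx((0.2, 0.0), abs=1e-12)


def test_right_handed_colony_rotates_windage_clockwise(coast_scenario):
    # 10 m/s wind at the taper threshold: theta_eff = theta_max = 15 deg,
    # windage = 1 m/s rotated 15 deg clockwise of the wind
    env = _env(coast_scenario, wind_uv=(10.0, 0.0))
    cfg = pl.DriftConfig(handedness_enabled=True, theta_max_deg=15.0, theta_taper_wind=10.0)
    u, v = pl.drift_velocity((2.0, 34.5), T, env.currents, env.winds, "right", cfg)
    assert u == pytest.approx(np.cos(np.radians(15.0)), abs=1e-3)     # ~0.966
    assert v == pytest.approx(-np.sin(np.radians(15.0)), abs=1e-3)    # ~-0.259
    ul, vl = pl.drift_velocity((2.0, 34.5), T, env.currents, env.winds, "left", cfg)
    assert vl == pytest.approx(-v, abs=1e-12)


def test_sail_angle_tapers_to_zero_under_storm_winds():
    cfg = pl.DriftConfig(handedness_enabled=True, theta_max_deg=12.5, theta_taper_wind=10.0)
    assert pl.effective_sail_angle_deg(5.0, cfg) == pytest.approx(12.5)
    assert pl.effective_sail_angle_deg(10.0, cfg) == pytest.approx(12.5)
    assert pl.effective_sail_angle_deg(15.0, cfg) == pytest.approx(6.25)
    assert pl.effective_sail_angle_deg(20.0, cfg) == pytest.approx(0.0)
    assert pl.effective_sail_angle_deg(35.0, cfg) == pytest.approx(0.0)


def test_drift_velocity_rejects_land_and_uncovered_times(coast_scenario):
    env = _env(coast_scenario)
    with pytest.raises(ValueError, match="land"):
        pl.drift_velocity((2.0, 35.99), T, env.currents, env.winds)
    times = np.arange(np.datetime64("2010-01-01"), np.datetime64("2010-01-05"))
    g = pl.GridSpec(*bounds_of(coast_scenario.grid), 3, 3, times)
    short_wind = pl.make_wind_field(g, [])
    with pytest.raises(ValueError, match="span"):
        pl.drift_velocity((2.0, 34.5), "2010-02-01", env.currents, short_wind)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(uw=st.floats(-20, 20), vw=st.floats(-20, 20),
       lon=st.floats(0.5, 3.5), lat=st.floats(34.2, 35.2))
def test_wind_only_drift_speed_is_windage_fraction(coast_scenario, uw, vw, lon, lat):
    env = _env(coast_scenario, wind_uv=(uw, vw))
    u, v = pl.drift_velocity((lon, lat), T, env.currents, env.winds)
    assert np.hypot(u, v) == pytest.approx(0.1 * np.hypot(uw, vw), rel=1e-12, abs=1e-13)


# ---------------------------------------------------------------------------
# advance_population / run_simulation
# ---------------------------------------------------------------------------

def test_zero_fields_leave_positions_unchanged(still_coast_env):
    pop = pl.population_from_positions([1.0, 2.0, 3.0], [34.5, 34.8, 35.0])
    lon0, lat0 = pop.lon.copy(), pop.lat.copy()
    t = np.datetime64("2010-01-15T00:00:00", "s")
    for _ in range(20):
        pop, recs = pl.advance_population(pop, t, still_coast_env, pl.DriftConfig())
        assert recs == []
    assert np.array_equal(pop.lon, lon0) and np.array_equal(pop.lat, lat0)


def test_uniform_current_displacement_closed_form(coast_scenario):
    # 0.1 m/s east for one day = 8640 m of eastward displacement
    env = _env(coast_scenario, cur_params={"u": 0.1, "v": 0.0})
    pop = pl.population_from_positions([1.0], [34.5])
    traj, recs = pl.run_simulation(pop, env, pl.DriftConfig(), "2010-01-15", "2010-01-16")
    mz, _ = pl.meters_per_degree(34.5)
    disp = (pop.lon[0] - 1.0) * mz
    assert disp == pytest.approx(8640.0, rel=1e-6)
    assert pop.lat[0] == pytest.approx(34.5, abs=1e-12)


def test_onshore_flow_strands_in_expected_step_count(coast_scenario):
    sc = coast_scenario
    env = _env(sc, cur_params={"u": 0.0, "v": 0.5})
    coast_row = np.flatnonzero(sc.land_mask.any(axis=1)).min()
    coast_lat = sc.grid.lats[coast_row]
    # start 4 cells south of the first land row
    lat0 = coast_lat - 4 * sc.grid.dlat
    pop = pl.population_from_positions([2.0], [lat0])
    cfg = pl.DriftConfig(dt=600.0)
    t = np.datetime64("2010-01-15T00:00:00", "s")
    steps = 0
    while pop.status[0] == STATUS_ACTIVE and steps < 100:
        pop, recs = pl.advance_population(pop, t, env, cfg)
        t += np.timedelta64(600, "s")
        steps += 1
    # land test is at the nearest node, so the boundary sits half a cell
    # south of the first land row: transit = 3.5 cells / (v * dt)
    mz, mm = pl.meters_per_degree(lat0)
    expected = 3.5 * sc.grid.dlat * mm / (0.5 * 600.0)
    assert pop.status[0] == STATUS_STRANDED
    assert abs(steps - expected) <= 1
    assert len(recs) == 1
    assert recs[0].segment_id in {b.id for b in sc.beaches}
    assert not np.isnat(pop.strand_time[0])


def test_outward_flow_exits_without_record(coast_scenario):
    env = _env(coast_scenario, cur_params={"u": 0.0, "v": -0.5})
    pop = pl.population_from_positions([2.0], [34.01])
    traj, recs = pl.run_simulation(pop, env, pl.DriftConfig(dt=600), "2010-01-15", "2010-01-16")
    assert pop.status[0] == STATUS_EXITED
    assert recs == []


def test_conservation_of_particles_every_step(coast_scenario):
    env = _env(coast_scenario, cur_params={"u": 0.0, "v": 0.3}, wind_uv=(3.0, 1.0))
    pop = pl.seed_depth_band(coast_scenario, 20, 200, 200, rng_seed=5)
    t = np.datetime64("2010-01-15T00:00:00", "s")
    cfg = pl.DriftConfig(dt=1800)
    for _ in range(60):
        pop, _ = pl.advance_population(pop, t, env, cfg)
        t += np.timedelta64(1800, "s")
        c = pop.status_counts()
        assert c["active"] + c["stranded"] + c["exited"] == 200


def test_stranded_particles_never_move_again(coast_scenario):
    env = _env(coast_scenario, cur_params={"u": 0.0, "v": 0.5})
    pop = pl.population_from_positions([2.0], [35.3])
    traj, recs = pl.run_simulation(pop, env, pl.DriftConfig(dt=600), "2010-01-15", "2010-01-17")
    assert pop.status[0] == STATUS_STRANDED
    lon_s, lat_s = pop.lon[0], pop.lat[0]
    t = np.datetime64("2010-01-17T00:00:00", "s")
    pop, _ = pl.advance_population(pop, t, env, pl.DriftConfig(dt=600))
    assert (pop.lon[0], pop.lat[0]) == (lon_s, lat_s)


def test_forward_backward_reversal_on_steady_gyre(gyre_scenario):
    env = _env(gyre_scenario, cur_kind="gyre",
               cur_params={"center": (-6.0, 36.0), "peak": 0.5, "radius_km": 60.0})
    start_lon, start_lat = -6.3, 36.1
    pop = pl.population_from_positions([start_lon], [start_lat])
    pl.run_simulation(pop, env, pl.DriftConfig(), "2010-01-15", "2010-01-20")
    back_cfg = pl.DriftConfig(direction="backward")
    pl.run_simulation(pop, env, back_cfg, "2010-01-20", "2010-01-15")
    g = gyre_scenario.grid
    assert abs(pop.lon[0] - start_lon) < 1e-3 * g.dlon
    assert abs(pop.lat[0] - start_lat) < 1e-3 * g.dlat


def test_backward_mode_never_beaches(coast_scenario):
    # onshore flow reversed in backward mode pulls particles offshore;
    # offshore flow reversed pushes them to the coast, where they must
    # clamp rather than strand
    env = _env(coast_scenario, cur_params={"u": 0.0, "v": -0.5})
    pop = pl.population_from_positions([2.0], [35.3])
    cfg = pl.DriftConfig(direction="backward", dt=600)
    traj, recs = pl.run_simulation(pop, env, cfg, "2010-01-17", "2010-01-15")
    assert recs == []
    assert pop.status[0] == STATUS_ACTIVE


def test_cfl_warning_on_oversized_steps(coast_scenario):
    env = _env(coast_scenario, cur_params={"u": 2.0, "v": 0.0})
    pop = pl.population_from_positions([1.0], [34.3])
    with pytest.warns(pl.CFLWarning):
        pl.advance_population(pop, np.datetime64(T, "s"), env, pl.DriftConfig(dt=7200))


def test_trajectories_end_at_first_stranding(coast_scenario):
    env = _env(coast_scenario, cur_params={"u": 0.0, "v": 0.4})
    pop = pl.seed_depth_band(coast_scenario, 20, 100, 20, rng_seed=8)
    cfg = pl.DriftConfig(dt=1800, output_stride=4)
    traj, recs = pl.run_simulation(pop, env, cfg, "2010-01-15", "2010-01-17")
    assert traj.lon.shape[0] == traj.times.size
    stranded = np.flatnonzero(pop.status == STATUS_STRANDED)
    assert stranded.size > 0
    # once NaN, always NaN afterwards
    for p in stranded:
        nan_frames = np.isnan(traj.lon[:, p])
        if nan_frames.any():
            first = nan_frames.argmax()
            assert nan_frames[first:].all()


def test_run_requires_consistent_direction_and_coverage(coast_scenario, still_coast_env):
    pop = pl.population_from_positions([2.0], [34.5])
    with pytest.raises(ValueError, match="forward"):
        pl.run_simulation(pop, still_coast_env, pl.DriftConfig(), "2010-01-16", "2010-01-15")
    times = np.arange(np.datetime64("2010-01-01"), np.datetime64("2010-01-05"))
    g = pl.GridSpec(*bounds_of(coast_scenario.grid), 3, 3, times)
    env = pl.Environment(coast_scenario,
                         pl.make_current_field(coast_scenario, "uniform", u=0, v=0),
                         pl.make_wind_field(g, []))
    with pytest.raises(ValueError, match="cover"):
        pl.run_simulation(pop, env, pl.DriftConfig(), "2010-01-02", "2010-02-01")


def test_config_validation():
    with pytest.raises(ValueError):
        pl.DriftConfig(windage_coeff=1.5)
    with pytest.raises(ValueError):
        pl.DriftConfig(handedness_enabled=True, theta_max_deg=20.0)
    with pytest.raises(ValueError):
        pl.DriftConfig(dt=-1)
    with pytest.raises(ValueError):
        pl.DriftConfig(integrator="rk2")
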