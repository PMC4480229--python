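"""Backward-trajectory source localization.

Given a beach segment where arrivals were observed and the arrival time
window, virtual colonies are released just offshore of the segment at times
spread uniformly over the window and integrated backward (negated
velocities, time in reverse, beaching disabled) for a fixed lookback.  The
cloud of backward endpoints, and its convex hull, estimate where the
arriving population sat a lookback earlier — the construction used to place
an open-ocean population off southwestern Portugal one month before a mass
stranding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from shapely.geometry import MultiPoint, Polygon

from .drift import DriftConfig, Environment, _step
from .environment import as_datetime64, meters_per_degree
from .seeding import HANDEDNESS_CODES

SECOND = np.timedelta64(1, "s")


@dataclass(eq=False)
class OriginEstimate:
    """Backward endpoints and their convex hull for one arrival segment."""

    points: np.ndarray              # (n, 2) lon/lat endpoints (all releases)
    hull: Polygon                   # convex hull of non-clamped endpoints
    lookback: np.timedelta64
    clamped_fraction: float
    provenance: dict = field(default_factory=dict)

    def hull_to_geojson(self, path):
        import json
        coords = [[float(x), float(y)] for x, y in np.asarray(self.hull.exterior.coords)]
        feat = {"type": "Feature", "geometry": {"type": "Polygon", "coordinates": [coords]},
                "properties": {"lookback_s": float(self.lookback / SECOND),
                               "clamped_fraction": self.clamped_fraction}}
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": [feat]}, fh)


def _release_positions(env: Environment, segment, n: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Release points jittered along the segment, offset one cell seaward.

    The seaward direction comes from the segment's exposure bearing; if the
    offset point still sits on land (concave corners) it is pushed outward
    up to three cells.
    """
    g = env.scenario.grid
    v = segment.vertices
    seg_len = np.hypot(np.diff(v[:, 0]), np.diff(v[:, 1]))
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    s = rng.uniform(0.0, cum[-1], n)
    k = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(seg_len) - 1)
    f = (s - cum[k]) / np.where(seg_len[k] > 0, seg_len[k], 1.0)
    lon = v[k, 0] + f * np.diff(v[:, 0])[k]
    lat = v[k, 1] + f * np.diff(v[:, 1])[k]

    b = np.radians(segment.exposure_deg)
    ndir = np.array([np.sin(b), np.cos(b)])    # east, north unit components
    out_lon = np.full(n, np.nan)
    out_lat = np.full(n, np.nan)
    for cells in (1.0, 2.0, 3.0):
        mz, mm = meters_per_degree(lat)
        cand_lon = lon + cells * g.dlon * ndir[0]
        cand_lat = lat + cells * g.dlat * ndir[1]
        need = np.isnan(out_lon)
        ok = need & g.in_bounds(cand_lon, cand_lat) & ~env.scenario.is_land(cand_lon, cand_lat)
        out_lon[ok] = cand_lon[ok]
        out_lat[ok] = cand_lat[ok]
    if np.isnan(out_lon).any():
        raise ValueError(f"could not place offshore release points for segment {segment.id}")
    return out_lon, out_lat


def localize_origin(segment_id: str, arrival_window: tuple, n_virtual: int,
                    env: Environment, config: DriftConfig, lookback,
                    rng_seed: int = 0) -> OriginEstimate:
    """Estimate the origin region of arrivals on one beach segment.

    ``arrival_window = (t_start, t_end)`` and ``lookback`` (timedelta64 or
    seconds) define the reconstruction: each virtual colony is released at a
    time uniform over the window (snapped to the step grid anchored at the
    window end) and integrated backward to the common origin epoch
    ``t_start - lookback``, so the endpoint cloud is a snapshot of the
    estimated population one lookback before the arrivals began.  Endpoints
    clamped at the open boundary are excluded from the hull and reported as
    a fraction.
    """
    segment = env.scenario.beach_by_id(segment_id)
    t_start = as_datetime64(arrival_window[0])
    t_end = as_datetime64(arrival_window[1])
    if t_end < t_start:
        raise ValueError("arrival window must satisfy t_start <= t_end")
    lb = lookback if isinstance(lookback, np.timedelta64) else np.timedelta64(int(lookback), "s")
    lb_s = float(lb / SECOND)
    if lb_s <= 0:
        raise ValueError("lookback must be positive")
    earliest = t_start - lb
    if not (env.currents.covers(earliest) and env.winds.covers(earliest)
            and env.currents.covers(t_end) and env.winds.covers(t_end)):
        raise ValueError("lookback exceeds the environment's time coverage")

    cfg = DriftConfig(**{**config.asdict(), "direction": "backward"})
    rng = np.random.default_rng(rng_seed)
    lon, lat = _release_positions(env, segment, n_virtual, rng)

    # snap release times to the dt grid anchored at the window end; all
    # particles march back to the common origin epoch t_start - lookback
    window_s = float((t_end - t_start) / SECOND)
    k_max = int(np.floor(window_s / cfg.dt))
    k_release = rng.integers(0, k_max + 1, n_virtual)       # release at t_end - k*dt
    span_s = window_s + lb_s                                 # t_end -> origin epoch
    total_steps = int(np.ceil(span_s / cfg.dt - 1e-9))

    g = env.scenario.grid
    clamped = np.zeros(n_virtual, bool)
    hand = np.full(n_virtual, HANDEDNESS_CODES["none"], np.int8)
    elapsed = 0.0
    for step in range(total_steps):
        t = t_end - np.timedelta64(int(round(elapsed)), "s")
        h = min(cfg.dt, span_s - elapsed)
        active = k_release * cfg.dt <= elapsed + 1e-9
        elapsed += h
        if not active.any():
            continue
        sub = np.flatnonzero(active)
        nlon, nlat = _step(lon[sub], lat[sub], t, float(h), env, hand[sub], cfg, -1.0, -1.0)
        clamped[sub] |= ~g.in_bounds(nlon, nlat)
        lon[sub] = np.clip(nlon, g.lon_min, g.lon_max)
        lat[sub] = np.clip(nlat, g.lat_min, g.lat_max)

    points = np.column_stack([lon, lat])
    keep = points[~clamped] if (~clamped).sum() >= 3 else points
    hull = MultiPoint([tuple(p) for p in keep]).convex_hull
    if hull.geom_type != "Polygon":            # degenerate (collinear) endpoint sets
        hull = hull.buffer(1e-9)
    return OriginEstimate(
        points=points, hull=hull, lookback=lb,
        clamped_fraction=float(clamped.mean()),
        provenance={"segment_id": segment_id, "arrival_window": [str(t_start), str(t_end)],
                    "n_virtual": int(n_virtual), "rng_seed": int(rng_seed),
                    "config": config.asdict(), "lookback_s": lb_s},
    )
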