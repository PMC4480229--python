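"""Idealized coastal domains and synthetic forcing fields.

Everything downstream of this module (seeding, drift integration, beaching
statistics) operates on three objects defined here:

* :class:`GridSpec` — a rectangular lon/lat grid with a time axis;
* :class:`GriddedVectorField` — a time-varying (u, v) vector field on that
  grid, serving both surface currents and 10-m winds;
* :class:`DomainScenario` — a land mask, shelf bathymetry and the ordered
  list of beach segments traced along the land–ocean boundary.

The scenario presets emulate the geographic elements of the Gulf of Cadiz /
Alboran Sea system at reduced complexity: a two-basin domain joined by a
narrow strait hugging the northern coast (Gibraltar analog), a closed basin
hosting an anticyclonic gyre (Alboran analog), and a plain open coast.
Current generators provide uniform flow, solid-body gyres, a through-strait
jet and a slope current following the isobaths; winds are piecewise-constant
episodes of stated (u, v).

Coordinates are geographic degrees.  Metric conversions use a local
equirectangular approximation with a cos(latitude) zonal scaling, which is
accurate to well below the grid resolution for domains spanning less than
~10 degrees of latitude.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import xarray as xr
from scipy import ndimage

logger = logging.getLogger("pleuston")

EARTH_RADIUS_M = 6_371_000.0
#: metres per degree of latitude (and of longitude at the equator)
M_PER_DEG = EARTH_RADIUS_M * np.pi / 180.0

SCENARIO_PRESETS = ("two_basin_strait", "open_coast", "single_gyre_basin")
CURRENT_KINDS = ("uniform", "gyre", "strait_jet", "slope_current", "composite")


def meters_per_degree(lat_deg):
    """Return (zonal, meridional) metres per degree at the given latitude.

    The meridional factor is the constant ``M_PER_DEG``; the zonal factor
    carries the cos(latitude) scaling of the equirectangular approximation.
    """
    lat = np.asarray(lat_deg, dtype=float)
    return M_PER_DEG * np.cos(np.radians(lat)), M_PER_DEG


def as_datetime64(value) -> np.datetime64:
    """Coerce an ISO string / datetime / datetime64 to datetime64[s]."""
    return np.datetime64(value, "s")


def _as_time_array(times) -> np.ndarray:
    arr = np.asarray([as_datetime64(t) for t in np.atleast_1d(times)], dtype="datetime64[s]")
    return arr


# ---------------------------------------------------------------------------
# Grid
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class GridSpec:
    """Rectangular lon/lat grid (node-registered) with a UTC time axis.

    ``nx``/``ny`` count grid nodes along longitude/latitude; each node owns a
    cell of size ``dlon`` × ``dlat`` centred on it, which is the unit used by
    land/ocean tests and beaching detection.
    """

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    nx: int
    ny: int
    times: np.ndarray

    def __post_init__(self):
        if not (self.lon_min < self.lon_max and self.lat_min < self.lat_max):
            raise ValueError("grid bounds must be strictly increasing")
        if self.nx < 2 or self.ny < 2:
            raise ValueError("nx and ny must both be >= 2")
        self.times = _as_time_array(self.times)
        if self.times.size == 0:
            raise ValueError("at least one time is required")
        if self.times.size > 1 and not np.all(np.diff(self.times).astype(int) > 0):
            raise ValueError("times must be strictly increasing")
        self.lons = np.linspace(self.lon_min, self.lon_max, self.nx)
        self.lats = np.linspace(self.lat_min, self.lat_max, self.ny)
        self.dlon = (self.lon_max - self.lon_min) / (self.nx - 1)
        self.dlat = (self.lat_max - self.lat_min) / (self.ny - 1)

    @property
    def shape(self):
        return (self.ny, self.nx)

    def cell_size_m(self) -> float:
        """Smallest metric cell edge in the domain (used by CFL-type guards)."""
        mz, mm = meters_per_degree(max(abs(self.lat_min), abs(self.lat_max)))
        return float(min(self.dlon * mz, self.dlat * mm))

    def nearest_index(self, lon, lat):
        """Indices (j, i) of the grid node whose cell contains the position."""
        i = np.clip(np.rint((np.asarray(lon, float) - self.lon_min) / self.dlon), 0, self.nx - 1).astype(int)
        j = np.clip(np.rint((np.asarray(lat, float) - self.lat_min) / self.dlat), 0, self.ny - 1).astype(int)
        return j, i

    def in_bounds(self, lon, lat):
        lon = np.asarray(lon, float)
        lat = np.asarray(lat, float)
        return (lon >= self.lon_min) & (lon <= self.lon_max) & (lat >= self.lat_min) & (lat <= self.lat_max)

    def with_times(self, times) -> "GridSpec":
        return GridSpec(self.lon_min, self.lon_max, self.lat_min, self.lat_max,
                        self.nx, self.ny, _as_time_array(times))


def _bilinear_setup(grid: GridSpec, lon, lat):
    """Cell indices and fractional offsets for bilinear interpolation.

    Positions outside the grid are clipped to the boundary for sampling
    purposes; boundary handling (exit/clamp) is the integrator's concern.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    x = (lon - grid.lon_min) / grid.dlon
    y = (lat - grid.lat_min) / grid.dlat
    ix = np.clip(np.floor(x).astype(int), 0, grid.nx - 2)
    iy = np.clip(np.floor(y).astype(int), 0, grid.ny - 2)
    fx = np.clip(x - ix, 0.0, 1.0)
    fy = np.clip(y - iy, 0.0, 1.0)
    return ix, iy, fx, fy


# ---------------------------------------------------------------------------
# Vector field
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class GriddedVectorField:
    """Time-varying (u, v) field on a :class:`GridSpec`, in m/s.

    ``mask`` flags land nodes; u and v are identically zero there.  Spatial
    sampling is bilinear with land nodes carrying zero weight and the
    remaining weights renormalized over ocean nodes, so near-coast speeds
    stay continuous without spurious onshore pull.  Temporal sampling is
    linear; a single-time field is steady and covers every instant.
    """

    grid: GridSpec
    u: np.ndarray
    v: np.ndarray
    mask: np.ndarray
    attrs: dict = field(default_factory=dict)

    def __post_init__(self):
        nt = self.grid.times.size
        expected = (nt, self.grid.ny, self.grid.nx)
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.u.shape != expected or self.v.shape != expected:
            raise ValueError(f"u/v must have shape {expected}, got {self.u.shape}/{self.v.shape}")
        if self.mask.shape != (self.grid.ny, self.grid.nx):
            raise ValueError("mask shape inconsistent with grid")
        self.u[:, self.mask] = 0.0
        self.v[:, self.mask] = 0.0
        ocean = ~self.mask
        if not (np.all(np.isfinite(self.u[:, ocean])) and np.all(np.isfinite(self.v[:, ocean]))):
            raise ValueError("non-finite velocity on ocean cells")
        self._times_i = self.grid.times.astype("int64")
        self._ocean_w = ocean.astype(float)

    # -- time handling -----------------------------------------------------
    @property
    def steady(self) -> bool:
        return self.grid.times.size == 1

    def covers(self, t) -> bool:
        if self.steady:
            return True
        t = as_datetime64(t)
        return self.grid.times[0] <= t <= self.grid.times[-1]

    def _time_bracket(self, t):
        if self.steady:
            return 0, 0, 0.0
        ti = as_datetime64(t).astype("int64")
        k = int(np.clip(np.searchsorted(self._times_i, ti, side="right") - 1, 0, self._times_i.size - 2))
        span = self._times_i[k + 1] - self._times_i[k]
        w = float(np.clip((ti - self._times_i[k]) / span, 0.0, 1.0))
        return k, k + 1, w

    # -- sampling ----------------------------------------------------------
    def sample(self, lon, lat, t):
        """Sample (u, v) at positions ``lon, lat`` (arrays) and scalar time ``t``."""
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        ix, iy, fx, fy = _bilinear_setup(self.grid, lon, lat)
        w00 = (1.0 - fx) * (1.0 - fy)
        w10 = fx * (1.0 - fy)
        w01 = (1.0 - fx) * fy
        w11 = fx * fy
        ow = self._ocean_w
        a00 = w00 * ow[iy, ix]
        a10 = w10 * ow[iy, ix + 1]
        a01 = w01 * ow[iy + 1, ix]
        a11 = w11 * ow[iy + 1, ix + 1]
        wsum = a00 + a10 + a01 + a11
        safe = np.where(wsum > 0, wsum, 1.0)

        k0, k1, wt = self._time_bracket(t)

        def _interp(comp):
            def one(k):
                c = comp[k]
                num = (a00 * c[iy, ix] + a10 * c[iy, ix + 1]
                       + a01 * c[iy + 1, ix] + a11 * c[iy + 1, ix + 1])
                return np.where(wsum > 0, num / safe, 0.0)
            if k0 == k1:
                return one(k0)
            return (1.0 - wt) * one(k0) + wt * one(k1)

        return _interp(self.u), _interp(self.v)

    # -- serialization -----------------------------------------------------
    def to_dataset(self) -> xr.Dataset:
        g = self.grid
        ds = xr.Dataset(
            {
                "u": (("time", "lat", "lon"), self.u, {"units": "m s-1", "long_name": "eastward velocity"}),
                "v": (("time", "lat", "lon"), self.v, {"units": "m s-1", "long_name": "northward velocity"}),
                "mask": (("lat", "lon"), self.mask.astype(np.int8), {"long_name": "land mask", "flag_values": "0 ocean, 1 land"}),
            },
            coords={"time": g.times, "lat": ("lat", g.lats, {"units": "degrees_north"}),
                    "lon": ("lon", g.lons, {"units": "degrees_east"})},
            attrs={"Conventions": "CF-1.8", **{k: str(v) for k, v in self.attrs.items()}},
        )
        return ds

    def to_netcdf(self, path):
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "GriddedVectorField":
        lons = ds["lon"].values
        lats = ds["lat"].values
        times = ds["time"].values.astype("datetime64[s]")
        grid = GridSpec(float(lons[0]), float(lons[-1]), float(lats[0]), float(lats[-1]),
                        lons.size, lats.size, times)
        mask = ds["mask"].values.astype(bool) if "mask" in ds else np.zeros(grid.shape, bool)
        return cls(grid, ds["u"].values.astype(float), ds["v"].values.astype(float), mask)

    @classmethod
    def from_netcdf(cls, path) -> "GriddedVectorField":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls.from_dataset(ds.load())


# ---------------------------------------------------------------------------
# Beaches
# ---------------------------------------------------------------------------

_FACING_BEARING = {"N": 0.0, "E": 90.0, "S": 180.0, "W": 270.0}


@dataclass(eq=False)
class BeachSegment:
    """A straight stretch of the land–ocean boundary.

    ``vertices`` is a polyline of (lon, lat) node coordinates; ``exposure``
    is the compass bearing of the outward (seaward) normal.
    """

    id: str
    vertices: np.ndarray
    length_m: float
    exposure_deg: float

    @property
    def min_lon(self) -> float:
        return float(self.vertices[:, 0].min())

    @property
    def midpoint(self):
        """Midpoint along the polyline (lon, lat)."""
        v = self.vertices
        mid = (v.shape[0] - 1) / 2
        k = int(mid)
        f = mid - k
        if k + 1 < v.shape[0]:
            return tuple(v[k] * (1 - f) + v[k + 1] * f)
        return tuple(v[k])


def polyline_length_m(vertices: np.ndarray) -> float:
    """Equirectangular length of a lon/lat polyline in metres."""
    v = np.asarray(vertices, float)
    if v.shape[0] < 2:
        return 0.0
    mid_lat = 0.5 * (v[:-1, 1] + v[1:, 1])
    dx = np.diff(v[:, 0]) * M_PER_DEG * np.cos(np.radians(mid_lat))
    dy = np.diff(v[:, 1]) * M_PER_DEG
    return float(np.sum(np.hypot(dx, dy)))


def _derive_beaches(grid: GridSpec, land: np.ndarray, max_cells: int = 12) -> list[BeachSegment]:
    """Trace beach segments as maximal straight runs of coastal land nodes.

    Coastal land nodes are grouped by the direction they face (the side on
    which an ocean node sits); each same-row/column run is split into chunks
    of at most ``max_cells`` nodes.  Segments are labelled west to east
    (ties broken south to north), which makes alongshore orderings such as
    "arrivals progressed from west to east" well-defined.
    """
    ocean = ~land
    raw: list[tuple[float, float, str, np.ndarray]] = []

    def shifted_ocean(dj, di):
        out = np.zeros_like(ocean)
        js = slice(max(dj, 0), land.shape[0] + min(dj, 0))
        jd = slice(max(-dj, 0), land.shape[0] + min(-dj, 0))
        is_ = slice(max(di, 0), land.shape[1] + min(di, 0))
        id_ = slice(max(-di, 0), land.shape[1] + min(-di, 0))
        out[jd, id_] = ocean[js, is_]
        return out

    # (facing, ocean-neighbour offset (dj, di), run axis: 0 = along lon)
    specs = [("N", (1, 0), 0), ("S", (-1, 0), 0), ("E", (0, 1), 1), ("W", (0, -1), 1)]
    for facing, (dj, di), axis in specs:
        coastal = land & shifted_ocean(dj, di)
        lines = coastal if axis == 0 else coastal.T
        for row in range(lines.shape[0]):
            idx = np.flatnonzero(lines[row])
            if idx.size < 2:
                continue
            breaks = np.flatnonzero(np.diff(idx) > 1)
            for run in np.split(idx, breaks + 1):
                if run.size < 2:
                    continue
                for s in range(0, run.size, max_cells):
                    chunk = run[s:s + max_cells]
                    if chunk.size == 1:  # merge singleton tail into previous chunk
                        chunk = run[s - 1:s + 1]
                    if axis == 0:
                        verts = np.column_stack([grid.lons[chunk], np.full(chunk.size, grid.lats[row])])
                    else:
                        verts = np.column_stack([np.full(chunk.size, grid.lons[row]), grid.lats[chunk]])
                    raw.append((verts[:, 0].min(), verts[:, 1].min(), facing, verts))

    raw.sort(key=lambda r: (r[0], r[1], r[2]))
    beaches = []
    for k, (_, _, facing, verts) in enumerate(raw):
        beaches.append(BeachSegment(id=f"B{k:02d}", vertices=verts,
                                    length_m=polyline_length_m(verts),
                                    exposure_deg=_FACING_BEARING[facing]))
    return beaches


def point_to_segment_distance_m(lons, lats, segment: BeachSegment) -> np.ndarray:
    """Distance (m) from points to a beach polyline, equirectangular metric."""
    lons = np.atleast_1d(np.asarray(lons, float))
    lats = np.atleast_1d(np.asarray(lats, float))
    cosz = np.cos(np.radians(lats))
    px = lons * M_PER_DEG * cosz
    py = lats * M_PER_DEG
    v = segment.vertices
    best = np.full(lons.shape, np.inf)
    for k in range(v.shape[0] - 1):
        ax = v[k, 0] * M_PER_DEG * cosz
        ay = v[k, 1] * M_PER_DEG
        bx = v[k + 1, 0] * M_PER_DEG * cosz
        by = v[k + 1, 1] * M_PER_DEG
        dx, dy = bx - ax, by - ay
        denom = dx * dx + dy * dy
        tpar = np.where(denom > 0, ((px - ax) * dx + (py - ay) * dy) / np.where(denom > 0, denom, 1.0), 0.0)
        tpar = np.clip(tpar, 0.0, 1.0)
        d = np.hypot(px - (ax + tpar * dx), py - (ay + tpar * dy))
        best = np.minimum(best, d)
    return best


def nearest_segment(lon, lat, beaches: Sequence[BeachSegment]):
    """Nearest beach segment to a point; ties broken by lower id.

    Returns (segment, distance_m).
    """
    dists = [(float(point_to_segment_distance_m(lon, lat, b)[0]), b.id, b) for b in beaches]
    dists.sort(key=lambda r: (round(r[0], 6), r[1]))
    d, _, b = dists[0]
    return b, d


# ---------------------------------------------------------------------------
# Scenario
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class DomainScenario:
    """Bathymetry, land mask and beach segments for an idealized domain."""

    grid: GridSpec
    bathymetry: np.ndarray
    land_mask: np.ndarray
    beaches: list[BeachSegment]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.bathymetry = np.asarray(self.bathymetry, float)
        self.land_mask = np.asarray(self.land_mask, bool)
        if self.bathymetry.shape != self.grid.shape or self.land_mask.shape != self.grid.shape:
            raise ValueError("bathymetry/land_mask shape inconsistent with grid")
        if np.any(self.bathymetry[self.land_mask] > 0):
            raise ValueError("land cells must have depth <= 0")
        ids = [b.id for b in self.beaches]
        if len(ids) != len(set(ids)):
            raise ValueError("beach segment ids must be unique")

    def is_land(self, lon, lat):
        """Land/ocean test at the nearest grid node."""
        j, i = self.grid.nearest_index(lon, lat)
        return self.land_mask[j, i]

    def depth_at(self, lon, lat):
        """Bilinearly interpolated depth (m, positive down) at positions."""
        ix, iy, fx, fy = _bilinear_setup(self.grid, lon, lat)
        b = self.bathymetry
        return ((1 - fx) * (1 - fy) * b[iy, ix] + fx * (1 - fy) * b[iy, ix + 1]
                + (1 - fx) * fy * b[iy + 1, ix] + fx * fy * b[iy + 1, ix + 1])

    def beach_by_id(self, segment_id: str) -> BeachSegment:
        for b in self.beaches:
            if b.id == segment_id:
                return b
        raise KeyError(f"no beach segment with id {segment_id!r}")

    # -- serialization -----------------------------------------------------
    def to_netcdf(self, path):
        g = self.grid
        ds = xr.Dataset(
            {
                "depth": (("lat", "lon"), self.bathymetry, {"units": "m", "positive": "down"}),
                "mask": (("lat", "lon"), self.land_mask.astype(np.int8), {"flag_values": "0 ocean, 1 land"}),
            },
            coords={"time": g.times, "lat": ("lat", g.lats, {"units": "degrees_north"}),
                    "lon": ("lon", g.lons, {"units": "degrees_east"})},
            attrs={"Conventions": "CF-1.8", "provenance": json.dumps(self.provenance, default=str)},
        )
        ds.to_netcdf(path, engine="scipy")

    def beaches_to_geojson(self, path):
        features = []
        for b in self.beaches:
            features.append({
                "type": "Feature",
                "geometry": {"type": "LineString", "coordinates": [[float(x), float(y)] for x, y in b.vertices]},
                "properties": {"id": b.id, "length_m": b.length_m, "exposure_deg": b.exposure_deg},
            })
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)

    @classmethod
    def from_netcdf(cls, path, beaches_path=None) -> "DomainScenario":
        with xr.open_dataset(path, engine="scipy") as ds:
            ds = ds.load()
        lons, lats = ds["lon"].values, ds["lat"].values
        times = ds["time"].values.astype("datetime64[s]")
        grid = GridSpec(float(lons[0]), float(lons[-1]), float(lats[0]), float(lats[-1]),
                        lons.size, lats.size, times)
        land = ds["mask"].values.astype(bool)
        prov = json.loads(ds.attrs.get("provenance", "{}"))
        if beaches_path is not None:
            beaches = beaches_from_geojson(beaches_path)
        else:
            beaches = _derive_beaches(grid, land, max_cells=prov.get("beach_max_cells", 12))
        return cls(grid, ds["depth"].values.astype(float), land, beaches, prov)


def beaches_from_geojson(path) -> list[BeachSegment]:
    with open(path) as fh:
        gj = json.load(fh)
    beaches = []
    for feat in gj["features"]:
        verts = np.asarray(feat["geometry"]["coordinates"], float)
        p = feat["properties"]
        beaches.append(BeachSegment(id=p["id"], vertices=verts,
                                    length_m=float(p["length_m"]),
                                    exposure_deg=float(p["exposure_deg"])))
    return beaches


# ---------------------------------------------------------------------------
# Scenario presets
# ---------------------------------------------------------------------------

def _bathymetry_from_mask(land: np.ndarray, shelf_depth_m=20.0, slope_depth_m=200.0,
                          slope_cells=12, depth_max_m=1000.0) -> np.ndarray:
    """Exponential offshore depth profile from the distance-to-land transform.

    Depth is ``shelf_depth_m`` one cell offshore and ``slope_depth_m`` at
    ``slope_cells`` cells offshore, saturating at ``depth_max_m``; land cells
    read zero.  This guarantees the 20–200 m seeding band exists adjacent to
    every coast by construction.
    """
    dist = ndimage.distance_transform_edt(~land)
    k = np.log(slope_depth_m / shelf_depth_m) / max(slope_cells - 1, 1)
    depth = np.where(land, 0.0, np.minimum(shelf_depth_m * np.exp(k * (dist - 1.0)), depth_max_m))
    return depth


def make_scenario(preset: str, grid_spec: GridSpec, *, coast_frac=0.15,
                  strait_lon_frac=0.5, strait_width_frac=0.06, strait_gap_frac=0.15,
                  wall_cells=2, shelf_depth_m=20.0, slope_depth_m=200.0,
                  slope_cells=12, depth_max_m=1000.0, beach_max_cells=12) -> DomainScenario:
    """Build an idealized :class:`DomainScenario` from a named preset.

    Presets:

    * ``open_coast`` — land along the northern edge only; a straight
      east–west shelf coastline.
    * ``single_gyre_basin`` — a closed rectangular basin (land ring) for
      gyre-retention experiments.
    * ``two_basin_strait`` — land bands along the northern and southern
      edges and a central landmass rising from the southern band, leaving a
      single narrow strait gap along the northern coast that joins the
      western and eastern basins.
    """
    if preset not in SCENARIO_PRESETS:
        raise ValueError(f"unknown preset {preset!r}; valid presets: {', '.join(SCENARIO_PRESETS)}")
    g = grid_spec
    land = np.zeros(g.shape, dtype=bool)
    lat_span = g.lat_max - g.lat_min
    lon_span = g.lon_max - g.lon_min
    prov: dict = {"preset": preset, "coast_frac": coast_frac, "beach_max_cells": beach_max_cells,
                  "shelf_depth_m": shelf_depth_m, "slope_depth_m": slope_depth_m,
                  "slope_cells": slope_cells, "depth_max_m": depth_max_m}

    n_coast = max(2, int(round(coast_frac * g.ny)))
    if preset == "open_coast":
        land[-n_coast:, :] = True
    elif preset == "single_gyre_basin":
        w = max(2, wall_cells)
        land[:w, :] = land[-w:, :] = True
        land[:, :w] = land[:, -w:] = True
    else:  # two_basin_strait
        land[-n_coast:, :] = True            # northern coast (Iberia analog)
        land[:n_coast, :] = True             # southern coast (Africa analog)
        lon_c = g.lon_min + strait_lon_frac * lon_span
        half_w = 0.5 * strait_width_frac * lon_span
        in_strait = (g.lons >= lon_c - half_w) & (g.lons <= lon_c + half_w)
        if in_strait.sum() < 2:
            raise ValueError("strait unresolvable: central landmass narrower than 2 cells")
        north_coast_lat = g.lats[g.ny - n_coast]      # first land row of the north band
        gap_bottom = north_coast_lat - strait_gap_frac * lat_span
        gap_rows = (g.lats >= gap_bottom) & (g.lats < north_coast_lat)
        if gap_rows.sum() < 2:
            raise ValueError("strait unresolvable: gap narrower than 2 cells")
        # central landmass: northward protrusion of the southern band up to the gap
        wall_rows = g.lats < gap_bottom
        land[np.ix_(wall_rows, in_strait)] = True
        if not np.any(~land[:, in_strait].all(axis=0)):
            raise ValueError("strait unresolvable: no open gap remains")
        prov.update({
            "strait_lon_center": float(lon_c), "strait_half_width_deg": float(half_w),
            "gap_lat_bottom": float(gap_bottom), "gap_lat_top": float(north_coast_lat),
        })

    depth = _bathymetry_from_mask(land, shelf_depth_m, slope_depth_m, slope_cells, depth_max_m)
    beaches = _derive_beaches(g, land, max_cells=beach_max_cells)
    return DomainScenario(g, depth, land, beaches, prov)


def mirror_scenario(scenario: DomainScenario) -> DomainScenario:
    """Reflect a scenario about the domain's zonal midline (lat -> -lat order).

    Requires a latitude axis symmetric about its midpoint (always true for
    the evenly spaced grids built here).  Beaches are re-derived from the
    flipped mask, preserving the west-to-east labelling.
    """
    land = scenario.land_mask[::-1].copy()
    depth = scenario.bathymetry[::-1].copy()
    beaches = _derive_beaches(scenario.grid, land,
                              max_cells=scenario.provenance.get("beach_max_cells", 12))
    prov = dict(scenario.provenance)
    prov["mirrored"] = not prov.get("mirrored", False)
    return DomainScenario(scenario.grid, depth, land, beaches, prov)


def mirror_field(fld: GriddedVectorField) -> GriddedVectorField:
    """Reflect a vector field about the zonal midline: flip lat, negate v."""
    return GriddedVectorField(fld.grid, fld.u[:, ::-1, :].copy(),
                              -fld.v[:, ::-1, :].copy(), fld.mask[::-1].copy(),
                              dict(fld.attrs))


# ---------------------------------------------------------------------------
# Current generators
# ---------------------------------------------------------------------------

def _metric_offsets(grid: GridSpec, lon0: float, lat0: float):
    """(dx, dy) metres of every grid node from (lon0, lat0), equirectangular."""
    cos0 = np.cos(np.radians(lat0))
    dx = (grid.lons[None, :] - lon0) * M_PER_DEG * cos0
    dy = (grid.lats[:, None] - lat0) * M_PER_DEG
    return np.broadcast_to(dx, grid.shape), np.broadcast_to(dy, grid.shape)


def _coastal_taper(land: np.ndarray, taper_cells: float = 4.0) -> np.ndarray:
    """Factor ramping 0 at coastal ocean nodes to 1 beyond ``taper_cells``.

    Used by closed-circulation kinds (gyre) to suppress normal flow at the
    basin boundary.
    """
    dist = ndimage.distance_transform_edt(~land)
    return np.clip((dist - 1.0) / max(taper_cells - 1.0, 1.0), 0.0, 1.0)


def _single_kind_field(scenario: DomainScenario, kind: str, params: dict) -> tuple[np.ndarray, np.ndarray]:
    g = scenario.grid
    land = scenario.land_mask
    if kind == "uniform":
        u0 = float(params.get("u", 0.0))
        v0 = float(params.get("v", 0.0))
        _check_speed(np.hypot(u0, v0))
        u = np.full(g.shape, u0)
        v = np.full(g.shape, v0)
    elif kind == "gyre":
        lon0, lat0 = params["center"]
        peak = float(params.get("peak", 0.5))
        _check_speed(peak)
        R = float(params.get("radius_km", 30.0)) * 1000.0
        decay = float(params.get("decay_km", R / 2000.0)) * 1000.0
        sense = params.get("sense", "anticyclonic")
        if scenario.is_land(lon0, lat0):
            raise ValueError("gyre center lies on land")
        dx, dy = _metric_offsets(g, lon0, lat0)
        r = np.hypot(dx, dy)
        speed = np.where(r <= R, peak * r / R, peak * np.exp(-(r - R) / decay))
        rsafe = np.where(r > 0, r, 1.0)
        if sense == "anticyclonic":      # clockwise in the northern hemisphere
            tu, tv = dy / rsafe, -dx / rsafe
        elif sense == "cyclonic":
            tu, tv = -dy / rsafe, dx / rsafe
        else:
            raise ValueError("gyre sense must be 'anticyclonic' or 'cyclonic'")
        taper = _coastal_taper(land, float(params.get("taper_cells", 4.0)))
        u = speed * tu * taper
        v = speed * tv * taper
    elif kind == "strait_jet":
        prov = scenario.provenance
        speed = float(params.get("speed", 1.0))
        _check_speed(abs(speed))
        lon_c = float(params.get("lon_center", prov.get("strait_lon_center", 0.5 * (g.lon_min + g.lon_max))))
        gap_bottom = float(params.get("gap_lat_bottom", prov.get("gap_lat_bottom", g.lat_min)))
        gap_top = float(params.get("gap_lat_top", prov.get("gap_lat_top", g.lat_max)))
        lat_c = 0.5 * (gap_bottom + gap_top)
        sigma_lat = float(params.get("sigma_lat", max((gap_top - gap_bottom) / 3.0, g.dlat)))
        sigma_lon = float(params.get("sigma_lon", max(4.0 * prov.get("strait_half_width_deg", g.dlon), g.dlon)))
        half_w = float(prov.get("strait_half_width_deg", g.dlon))
        dlat = g.lats[:, None] - lat_c
        dlon = np.abs(g.lons[None, :] - lon_c)
        lon_decay = np.where(dlon <= half_w, 1.0, np.exp(-0.5 * ((dlon - half_w) / sigma_lon) ** 2))
        amp = speed * np.exp(-0.5 * (dlat / sigma_lat) ** 2) * lon_decay
        u = np.broadcast_to(amp, g.shape).copy() if amp.shape != g.shape else amp
        v = np.zeros(g.shape)
    elif kind == "slope_current":
        speed = float(params.get("speed", 0.3))
        _check_speed(abs(speed))
        d0 = float(params.get("depth_center_m", 150.0))
        sigma_d = float(params.get("depth_sigma_m", 80.0))
        sense = params.get("sense", "coast_left")
        depth = scenario.bathymetry
        gy, gx = np.gradient(depth)          # cell-index gradient; only direction matters
        norm = np.hypot(gx, gy)
        nsafe = np.where(norm > 0, norm, 1.0)
        # 90 deg CCW rotation of the offshore (deepening) direction keeps the coast on the left
        tu, tv = -gy / nsafe, gx / nsafe
        if sense == "coast_right":
            tu, tv = -tu, -tv
        elif sense != "coast_left":
            raise ValueError("slope_current sense must be 'coast_left' or 'coast_right'")
        amp = speed * np.exp(-0.5 * ((depth - d0) / sigma_d) ** 2) * (norm > 0)
        u = amp * tu
        v = amp * tv
    else:
        raise ValueError(f"unknown current kind {kind!r}; valid kinds: {', '.join(CURRENT_KINDS)}")
    u = np.where(land, 0.0, u)
    v = np.where(land, 0.0, v)
    return u, v


def _check_speed(s):
    if s > 3.0:
        raise ValueError("current speeds are limited to 3 m/s")


def make_current_field(scenario: DomainScenario, kind: str, **params) -> GriddedVectorField:
    """Generate an analytic surface-current field on the scenario grid.

    ``composite`` sums constituent fields given as
    ``parts=[(kind, params_dict), ...]``; all other kinds are documented on
    :func:`_single_kind_field`.  Fields are steady in time (replicated over
    the grid's time axis) and exactly zero on land.
    """
    g = scenario.grid
    if kind == "composite":
        parts = params.get("parts", [])
        u = np.zeros(g.shape)
        v = np.zeros(g.shape)
        for part_kind, part_params in parts:
            pu, pv = _single_kind_field(scenario, part_kind, part_params)
            u = u + pu
            v = v + pv
    else:
        u, v = _single_kind_field(scenario, kind, params)
    nt = g.times.size
    U = np.broadcast_to(u, (nt, *g.shape)).copy()
    V = np.broadcast_to(v, (nt, *g.shape)).copy()
    return GriddedVectorField(g, U, V, scenario.land_mask.copy(),
                              {"kind": kind, **{k: v for k, v in params.items() if k != "parts"}})


# ---------------------------------------------------------------------------
# Wind generator
# ---------------------------------------------------------------------------

def make_wind_field(grid_spec: GridSpec, episodes: Iterable, *, lat_gradient=None) -> GriddedVectorField:
    """Build a 10-m wind field from piecewise-constant episodes.

    ``episodes`` is an iterable of ``(start, end, u, v)`` with non-overlapping
    ``[start, end)`` windows; the field equals the episode vector at grid
    times inside a window and zero outside.  Winds are spatially uniform
    unless ``lat_gradient=(du_dlat, dv_dlat)`` (per degree) is given.  The
    wind grid carries no land mask: windage acts everywhere.
    """
    g = grid_spec
    eps = []
    for (start, end, u, v) in episodes:
        s, e = as_datetime64(start), as_datetime64(end)
        if not s < e:
            raise ValueError("episode start must precede its end")
        if np.hypot(u, v) > 40.0:
            raise ValueError("wind speeds are limited to 40 m/s")
        eps.append((s, e, float(u), float(v)))
    eps.sort(key=lambda r: r[0])
    for a, b in zip(eps, eps[1:]):
        if b[0] < a[1]:
            raise ValueError(f"overlapping wind episodes: {a[0]}–{a[1]} and {b[0]}–{b[1]}")

    nt = g.times.size
    u = np.zeros((nt, g.ny, g.nx))
    v = np.zeros((nt, g.ny, g.nx))
    for k, t in enumerate(g.times):
        for (s, e, eu, ev) in eps:
            if s <= t < e:
                u[k, :, :] = eu
                v[k, :, :] = ev
                break
    if lat_gradient is not None:
        gu, gv = lat_gradient
        dlat = (g.lats - 0.5 * (g.lat_min + g.lat_max))[None, :, None]
        u = u + gu * dlat
        v = v + gv * dlat
    mask = np.zeros(g.shape, dtype=bool)
    return GriddedVectorField(g, u, v, mask, {"kind": "episodic_wind", "n_episodes": len(eps)})
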