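"""Wind-forcing diagnostics: zonal climatology, winter anomalies, stress.

Three diagnostics characterize the wind conditions behind a drift event:

* a monthly climatology of the zonal (U) wind averaged over a lon/lat box
  and a range of years, the long-term baseline;
* the ratio of one target winter's monthly means to that climatology (the
  2009–2010 winter read 1.5–4x its 1979–2012 baseline over the NE
  Atlantic box 29–51N, 20–10W);
* the daily kinematic wind stress tau/rho = C_d |w| (w_x, w_y) at a point,
  bulk formula with constant drag coefficient C_d = 1.3e-3 by default,
  used to identify persistently westerly episodes.

The diagnostics run on any wind field in this package's gridded form,
synthetic or read from a CF-style NetCDF file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import xarray as xr

from .environment import GriddedVectorField

DEFAULT_DRAG_COEFF = 1.3e-3

MONTH_LABELS = ["Jan", "Feb", "Mar", "Apr", "May", "Jun",
                "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"]


@dataclass(eq=False)
class ZonalWindClimatology:
    """Monthly means of the zonal wind over a box, averaged across years."""

    mean_u: np.ndarray              # (12,), m/s, NaN for months with no data
    years_used: tuple
    box: tuple                      # (lon_min, lon_max, lat_min, lat_max)

    @property
    def months(self) -> list[str]:
        return list(MONTH_LABELS)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"month": MONTH_LABELS, "mean_u": self.mean_u})


@dataclass(eq=False)
class StressSeries:
    """Daily kinematic wind stress (m^2/s^2) at a fixed location."""

    times: np.ndarray
    tau_x: np.ndarray
    tau_y: np.ndarray
    location: tuple
    drag_coeff: float = DEFAULT_DRAG_COEFF

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "tau_x": self.tau_x, "tau_y": self.tau_y})


def _wind_dataarray(winds: GriddedVectorField, component: str) -> xr.DataArray:
    g = winds.grid
    data = winds.u if component == "u" else winds.v
    return xr.DataArray(data, coords={"time": g.times, "lat": g.lats, "lon": g.lons},
                        dims=("time", "lat", "lon"))


def monthly_zonal_climatology(winds: GriddedVectorField, box: tuple,
                              years: range | tuple | list) -> ZonalWindClimatology:
    """Area-weighted monthly climatology of the zonal wind over a box.

    ``box = (lon_min, lon_max, lat_min, lat_max)`` must lie inside the wind
    grid.  Per calendar month, the cos(latitude)-weighted spatial mean of u
    over the box is averaged across all samples from the requested years.
    """
    g = winds.grid
    lon_lo, lon_hi, lat_lo, lat_hi = box
    if lon_lo < g.lon_min or lon_hi > g.lon_max or lat_lo < g.lat_min or lat_hi > g.lat_max:
        raise ValueError("climatology box extends outside the wind grid")
    da = _wind_dataarray(winds, "u").sel(lon=slice(lon_lo, lon_hi), lat=slice(lat_lo, lat_hi))
    if da.sizes["lon"] == 0 or da.sizes["lat"] == 0:
        raise ValueError("climatology box contains no grid nodes")
    weights = np.cos(np.radians(da["lat"]))
    spatial = da.weighted(weights).mean(dim=("lat", "lon"))
    years = tuple(int(y) for y in years)
    spatial = spatial.sel(time=spatial["time.year"].isin(list(years)))
    if spatial.sizes["time"] == 0:
        raise ValueError("no wind samples in the requested years")
    monthly = spatial.groupby("time.month").mean()
    mean_u = np.full(12, np.nan)
    mean_u[np.asarray(monthly["month"]) - 1] = monthly.values
    return ZonalWindClimatology(mean_u=mean_u, years_used=years, box=tuple(box))


def anomaly_ratio(target: Mapping | np.ndarray | pd.Series,
                  clim: ZonalWindClimatology) -> pd.DataFrame:
    """Per-month ratio of a target winter's means to the climatology.

    ``target`` maps month number (1-12) to the target mean, or is a
    12-vector.  Where the climatology mean is zero, or the two means have
    opposite signs, the ratio is undefined: it is reported as NaN and
    flagged rather than returned as an infinity or a misleading negative.
    """
    if isinstance(target, Mapping):
        months = sorted(int(m) for m in target)
        tvals = np.array([float(target[m]) for m in months])
    else:
        arr = np.asarray(target, float)
        if arr.size != 12:
            raise ValueError("a target vector must have 12 monthly entries")
        months = list(range(1, 13))
        tvals = arr
    cvals = clim.mean_u[np.asarray(months) - 1]
    undefined = (cvals == 0) | (tvals * cvals < 0) | ~np.isfinite(cvals)
    ratio = np.where(undefined, np.nan, tvals / np.where(cvals == 0, 1.0, cvals))
    return pd.DataFrame({"month": months, "target_u": tvals, "climatology_u": cvals,
                         "ratio": ratio, "undefined": undefined})


def kinematic_wind_stress(winds: GriddedVectorField, location: tuple,
                          drag_coeff: float = DEFAULT_DRAG_COEFF) -> StressSeries:
    """Daily mean kinematic wind stress at a point, bulk formula.

    tau/rho = C_d * |w| * (w_x, w_y), evaluated at the grid node nearest
    ``location = (lon, lat)`` for every wind sample, then averaged per day.
    """
    if drag_coeff <= 0:
        raise ValueError("drag coefficient must be positive")
    lon, lat = location
    g = winds.grid
    if not bool(g.in_bounds(lon, lat)):
        raise ValueError("stress location lies outside the wind grid")
    j, i = g.nearest_index(lon, lat)
    u = winds.u[:, j, i]
    v = winds.v[:, j, i]
    speed = np.hypot(u, v)
    df = pd.DataFrame({"tau_x": drag_coeff * speed * u, "tau_y": drag_coeff * speed * v},
                      index=pd.DatetimeIndex(g.times))
    daily = df.resample("D").mean().dropna()
    return StressSeries(times=daily.index.values.astype("datetime64[s]"),
                        tau_x=daily["tau_x"].to_numpy(),
                        tau_y=daily["tau_y"].to_numpy(),
                        location=(float(lon), float(lat)),
                        drag_coeff=float(drag_coeff))


def plot_climatology(clim: ZonalWindClimatology, target=None, path=None):
    """Line plot of the monthly climatology, optionally with a target winter."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 3))
    ax.plot(range(1, 13), clim.mean_u, "k-o", label=f"climatology {clim.years_used[0]}-{clim.years_used[-1]}")
    if target is not None:
        months = sorted(int(m) for m in target)
        ax.plot(months, [target[m] for m in months], "r-o", label="target winter")
    ax.set_xticks(range(1, 13), MONTH_LABELS, fontsize=7)
    ax.set_ylabel("zonal wind (m/s)")
    ax.axhline(0, color="0.7", lw=0.5)
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
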