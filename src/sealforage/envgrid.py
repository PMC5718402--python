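"""Gridded environmental covariates and per-dive extraction.

Three covariates are attached to each geolocated dive: bathymetry (m,
positive down), sea-ice fraction, and sea surface temperature (C).
Bathymetry and ice come from gridded rasters; SST comes from the shallowest
point of CTD profiles transmitted by the tag, with time-linear interpolation
between profiles when a dive has no profile close in time.

Rasters are held as :class:`xarray.DataArray` objects with ``lon``/``lat``
axes and an optional ``time`` axis; any NetCDF raster with those axes can be
loaded with :func:`load_grid`.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import xarray as xr

logger = logging.getLogger(__name__)

GRID_VARIABLES = ("bathymetry_m", "ice_fraction", "sst_C")


class EnvGrid:
    """A gridded environmental field with nearest/bilinear point lookup."""

    def __init__(self, data: xr.DataArray, variable: str):
        if variable not in GRID_VARIABLES:
            raise ValueError(f"unknown variable {variable!r}")
        for axis in ("lon", "lat"):
            vals = data[axis].values
            if not (np.all(np.diff(vals) > 0) or np.all(np.diff(vals) < 0)):
                raise ValueError(f"{axis} axis must be strictly monotone")
        self.data = data
        self.variable = variable

    @property
    def has_time(self) -> bool:
        return "time" in self.data.dims

    def nearest_fast(self, lon: float, lat: float, time=None) -> float:
        """Scalar nearest-cell lookup via searchsorted (hot-loop path)."""
        da = self.data
        lons = da.lon.values
        lats = da.lat.values
        i = int(np.clip(np.searchsorted(lons, lon), 1, len(lons) - 1))
        i = i if abs(lons[i] - lon) < abs(lons[i - 1] - lon) else i - 1
        j = int(np.clip(np.searchsorted(lats, lat), 1, len(lats) - 1))
        j = j if abs(lats[j] - lat) < abs(lats[j - 1] - lat) else j - 1
        if self.has_time:
            tv = da.time.values
            t64 = np.datetime64(time)
            k = int(np.clip(np.searchsorted(tv, t64), 1, len(tv) - 1))
            k = k if abs(tv[k] - t64) < abs(tv[k - 1] - t64) else k - 1
            return float(da.values[k, j, i])
        return float(da.values[j, i])

    def lookup(self, lon, lat, time=None, method: str = "nearest"):
        """Value(s) at (lon, lat[, time]).

        Out-of-bounds queries return NaN and are logged.  ``method`` is
        ``"nearest"`` (default) or ``"bilinear"``; the time axis, when
        present, is always matched to the nearest available date.
        """
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        da = self.data
        if self.has_time:
            if time is None:
                raise ValueError(f"{self.variable} grid has a time axis; pass time")
            t = pd.to_datetime(np.atleast_1d(time))
            if len(t) == 1 and len(lon) > 1:
                t = t.repeat(len(lon))
        lo, hi = sorted((float(da.lon.min()), float(da.lon.max())))
        la, ha = sorted((float(da.lat.min()), float(da.lat.max())))
        inb = (lon >= lo) & (lon <= hi) & (lat >= la) & (lat <= ha)
        if not inb.all():
            logger.warning("%d/%d lookups out of grid bounds -> NaN",
                           int((~inb).sum()), inb.size)
        out = np.full(lon.shape, np.nan)
        if inb.any():
            kw = dict(lon=xr.DataArray(lon[inb], dims="pt"),
                      lat=xr.DataArray(lat[inb], dims="pt"))
            if self.has_time:
                kw["time"] = xr.DataArray(t[inb], dims="pt")
            if method == "nearest":
                vals = da.sel(**kw, method="nearest").values
            elif method == "bilinear":
                if self.has_time:
                    da2 = da.sel(time=kw.pop("time"), method="nearest")
                    vals = da2.interp(**kw).values
                else:
                    vals = da.interp(**kw).values
            else:
                raise ValueError(f"unknown lookup method {method!r}")
            out[inb] = vals
        return out if out.size > 1 else float(out[0])


def load_grid(path, variable: str) -> EnvGrid:
    """Load a NetCDF raster (lon/lat[/time] axes) as an EnvGrid."""
    ds = xr.open_dataset(path, engine="scipy")
    name = variable if variable in ds else list(ds.data_vars)[0]
    return EnvGrid(ds[name].load(), variable)


def save_grid(grid: EnvGrid, path) -> None:
    grid.data.to_dataset(name=grid.variable).to_netcdf(path, engine="scipy")


def sst_per_dive(dives: pd.DataFrame, ctd: pd.DataFrame,
                 max_gap_hr: float = 3.0) -> pd.DataFrame:
    """Assign an SST to each dive from CTD shallowest-point temperatures.

    A dive within ``max_gap_hr`` of a profile takes that profile's
    shallowest-point temperature (source ``"ctd"``); otherwise the value is
    time-linearly interpolated between the bracketing profiles (source
    ``"interpolated"``); beyond the first/last profile the nearest profile's
    value is used and flagged ``"extrapolated"``.

    ``ctd`` must carry one row per (profile, depth point) with columns
    animal_id, time, depth_m, temp_C.
    """
    out = []
    shallowest = (ctd.sort_values("depth_m")
                  .groupby(["animal_id", "time"], as_index=False).first()
                  [["animal_id", "time", "temp_C"]])
    for animal, dv in dives.groupby("animal_id", sort=False):
        prof = shallowest[shallowest.animal_id == animal].sort_values("time")
        res = dv.copy()
        if prof.empty:
            res["sst_C"] = np.nan
            res["sst_source"] = "missing"
            out.append(res)
            continue
        pt = prof.time.values.astype("datetime64[ns]").astype("int64") / 1e9
        pv = prof.temp_C.to_numpy()
        dt_dive = dv.start_time.values.astype("datetime64[ns]").astype("int64") / 1e9
        nearest_idx = np.clip(np.searchsorted(pt, dt_dive), 0, len(pt) - 1)
        left = np.clip(nearest_idx - 1, 0, len(pt) - 1)
        gap_right = np.abs(pt[nearest_idx] - dt_dive)
        gap_left = np.abs(pt[left] - dt_dive)
        nearest = np.where(gap_left < gap_right, left, nearest_idx)
        gap_hr = np.minimum(gap_left, gap_right) / 3600.0

        interp = np.interp(dt_dive, pt, pv)
        sst = np.where(gap_hr <= max_gap_hr, pv[nearest], interp)
        source = np.where(gap_hr <= max_gap_hr, "ctd", "interpolated")
        outside = (dt_dive < pt[0]) | (dt_dive > pt[-1])
        source = np.where(outside & (gap_hr > max_gap_hr), "extrapolated", source)
        res["sst_C"] = sst
        res["sst_source"] = source
        out.append(res)
    return pd.concat(out, ignore_index=True)


def attach_dive_env(dives: pd.DataFrame, bathy: EnvGrid, ice: EnvGrid,
                    ctd: pd.DataFrame, max_gap_hr: float = 3.0,
                    method: str = "nearest") -> pd.DataFrame:
    """Per-dive environmental table: bathymetry, ice fraction, SST."""
    env = sst_per_dive(dives, ctd, max_gap_hr=max_gap_hr)
    env["bathymetry_m"] = bathy.lookup(env.lon.to_numpy(), env.lat.to_numpy(),
                                       method=method)
    env["ice_fraction"] = ice.lookup(env.lon.to_numpy(), env.lat.to_numpy(),
                                     time=env.start_time, method=method)
    return env


def daily_env(dive_env: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic daily (UTC calendar day) means per animal of each covariate."""
    df = dive_env.copy()
    df["day"] = df.start_time.dt.floor("D")
    agg = (df.groupby(["animal_id", "day"], as_index=False)
             [["bathymetry_m", "ice_fraction", "sst_C"]].mean())
    return agg
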