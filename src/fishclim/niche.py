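"""Environmental niche model: from gridded fields to carrying capacity.

The carrying capacity of the stock model (mdSSB, written K) is obtained from
three habitat-suitability responses combined multiplicatively:

* a thermal response — an asymmetric Gaussian around an optimum SST, with
  different standard deviations below and above the optimum;
* a bathymetric response — a trapezoid over depth with four breakpoints;
* a trophic response — a daily 0/1 indicator that is 1 only on days belonging
  to a run of at least ``window_days`` consecutive days with chlorophyll-a at
  or above ``chl_min``.

The product of the three is a daily gridded suitability in [0, 1]; annual
K maps are March–October means of the daily field, and the regional K series
is the unweighted mean over grid cells inside a bounding box.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

logger = logging.getLogger(__name__)

#: Months of the productive season used for the annual average (March–October).
DEFAULT_MONTHS = frozenset(range(3, 11))

#: North Sea bounding box (lat_min, lat_max, lon_min, lon_max), degrees.
NORTH_SEA_BBOX = (51.0, 62.0, -3.0, 9.5)


@dataclass(frozen=True)
class NicheParameters:
    """Constants of the three-dimensional environmental niche.

    Defaults are the North Sea cod parameterisation: thermal optimum 5.4 °C
    with lower/upper spreads 5.7/4 °C, depth trapezoid (0, 1e-4, 200, 600) m,
    and a trophic rule of chlorophyll >= 0.05 mg m^-3 sustained for 15 days.
    """

    y_opt: float = 5.4
    t1: float = 5.7
    t2: float = 4.0
    c: float = 1.0
    theta1: float = 0.0
    theta2: float = 1e-4
    theta3: float = 200.0
    theta4: float = 600.0
    chl_min: float = 0.05
    window_days: int = 15

    def __post_init__(self) -> None:
        if not (self.t1 > 0 and self.t2 > 0):
            raise ValueError("thermal spreads t1, t2 must be positive")
        if not (0 < self.c <= 1):
            raise ValueError("maximum suitability c must be in (0, 1]")
        if not (self.theta1 <= self.theta2 <= self.theta3 <= self.theta4):
            raise ValueError("trapezoid breakpoints must be non-decreasing")
        if self.chl_min < 0:
            raise ValueError("chl_min must be non-negative")
        if self.window_days < 1:
            raise ValueError("window_days must be >= 1")


@dataclass
class EnvironmentalFields:
    """Gridded SST, daily chlorophyll and bathymetry on a common grid.

    ``sst`` may be monthly or daily (dims time, latitude, longitude, °C),
    ``chl`` is daily (same dims, mg m^-3), ``depth`` is time-invariant
    (latitude, longitude; metres, positive down; negative values are land).
    Missing values are NaN.
    """

    sst: xr.DataArray
    chl: xr.DataArray
    depth: xr.DataArray

    def __post_init__(self) -> None:
        for name, da, dims in (
            ("sst", self.sst, ("time", "latitude", "longitude")),
            ("chl", self.chl, ("time", "latitude", "longitude")),
            ("depth", self.depth, ("latitude", "longitude")),
        ):
            missing = set(dims) - set(da.dims)
            if missing:
                raise ValueError(f"{name} lacks dimension(s) {sorted(missing)}")
        for axis in ("latitude", "longitude"):
            for name, da in (("sst", self.sst), ("chl", self.chl), ("depth", self.depth)):
                vals = np.asarray(da[axis])
                d = np.diff(vals)
                if not (np.all(d > 0) or np.all(d < 0)):
                    raise ValueError(f"{name}: axis {axis!r} not strictly monotonic")
                ref = np.asarray(self.depth[axis])
                if vals.shape != ref.shape or not np.allclose(vals, ref):
                    raise ValueError(f"grid mismatch between {name} and depth on axis {axis!r}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            if np.nanmin(self.chl.values) < 0:
                raise ValueError("chlorophyll must be non-negative where defined")


@dataclass
class CarryingCapacitySeries:
    """Annual regional carrying capacity K_t (dimensionless, 0–1)."""

    years: np.ndarray
    values: np.ndarray
    region: tuple[float, float, float, float] = field(default=NORTH_SEA_BBOX)

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.years.shape != self.values.shape:
            raise ValueError("years and values must have the same length")
        if len(self.years) > 1 and not np.all(np.diff(self.years) == 1):
            raise ValueError("years must be contiguous")
        finite = np.isfinite(self.values)
        if np.any((self.values[finite] < 0) | (self.values[finite] > 1)):
            raise ValueError("K values must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "k": self.values})


def thermal_suitability(y, params: NicheParameters = NicheParameters()):
    """Asymmetric Gaussian suitability U1 of SST ``y`` (°C).

    Equal to ``c`` at the optimum; Gaussian with spread ``t1`` below the
    optimum and ``t2`` above it. Non-finite temperatures yield NaN.
    """
    y = np.asarray(y, dtype=float)
    dev = y - params.y_opt
    spread = np.where(dev <= 0, params.t1, params.t2)
    with np.errstate(invalid="ignore"):
        out = params.c * np.exp(-(dev**2) / (2.0 * spread**2))
    out = np.where(np.isfinite(y), out, np.nan)
    return out if out.ndim else float(out)


def bathymetric_suitability(z, params: NicheParameters = NicheParameters()):
    """Trapezoidal suitability U2 of depth ``z`` (m, positive down).

    Zero at or beyond the outer breakpoints, ``c`` on the plateau, linear on
    the flanks. Land (negative depth) falls in the z <= theta1 branch.
    Zero-width flanks behave as step edges.
    """
    z = np.asarray(z, dtype=float)
    t1, t2, t3, t4, c = params.theta1, params.theta2, params.theta3, params.theta4, params.c
    out = np.zeros_like(z)
    if t2 > t1:
        ramp_up = (t1 < z) & (z <= t2)
        out = np.where(ramp_up, (z - t1) / (t2 - t1) * c, out)
    plateau = (t2 < z) & (z < t3)
    out = np.where(plateau, c, out)
    if t4 > t3:
        ramp_down = (t3 <= z) & (z < t4)
        out = np.where(ramp_down, (t4 - z) / (t4 - t3) * c, out)
    out = np.where(np.isfinite(z), out, np.nan)
    return out if out.ndim else float(out)


def trophic_suitability(chl_series, params: NicheParameters = NicheParameters(), axis: int = 0):
    """Run-length threshold suitability U3 of a daily chlorophyll series.

    A day scores 1 iff it belongs to a run of at least ``window_days``
    consecutive days with chlorophyll >= ``chl_min``; 0 otherwise. NaN days
    break runs and map to NaN in the output. Works along ``axis`` for
    gridded arrays.
    """
    chl = np.asarray(chl_series, dtype=float)
    if chl.shape[axis] < params.window_days:
        logger.warning(
            "chlorophyll series of length %d shorter than window_days=%d: all zeros",
            chl.shape[axis], params.window_days,
        )
    chl = np.moveaxis(chl, axis, 0)
    above = np.where(np.isnan(chl), False, chl >= params.chl_min)
    n = above.shape[0]
    # running length of the current run of True, per trailing cell
    run = np.zeros_like(above, dtype=int)
    acc = np.zeros(above.shape[1:], dtype=int)
    for d in range(n):
        acc = np.where(above[d], acc + 1, 0)
        run[d] = acc
    # propagate qualification backwards: a day is in a qualifying run iff the
    # run it belongs to ever reaches window_days
    member = np.zeros(above.shape, dtype=float)
    qual = np.zeros(above.shape[1:], dtype=bool)
    for d in range(n - 1, -1, -1):
        qual = np.where(above[d], qual | (run[d] >= params.window_days), False)
        member[d] = np.where(qual, 1.0, 0.0)
    member = np.where(np.isnan(chl), np.nan, member)
    member = np.moveaxis(member, 0, axis)
    return member if member.ndim else float(member)


def combine_suitabilities(components):
    """Product of suitability components (multiplicative niche combination).

    Zero if any component is zero; NaN propagates.
    """
    if len(components) == 0:
        raise ValueError("need at least one suitability component")
    out = np.asarray(components[0], dtype=float)
    for comp in components[1:]:
        out = out * np.asarray(comp, dtype=float)
    return out if np.ndim(out) else float(out)


def _broadcast_sst_to_days(sst: xr.DataArray, days: pd.DatetimeIndex,
                           interp: str = "hold") -> xr.DataArray:
    """Expand an SST field to a daily time axis.

    ``hold`` repeats each monthly value over the days of its month;
    ``linear`` interpolates linearly in time between monthly values.
    If SST is already on the daily axis it is returned unchanged.
    """
    sst_times = pd.DatetimeIndex(sst["time"].values)
    if len(sst_times) == len(days) and (sst_times == days).all():
        return sst
    if interp == "linear":
        return sst.interp(time=days, kwargs={"fill_value": "extrapolate"})
    if interp != "hold":
        raise ValueError(f"unknown SST interpolation {interp!r}")
    key = sst_times.year * 100 + sst_times.month
    lookup = {k: i for i, k in enumerate(key)}
    idx = []
    for d in days:
        k = d.year * 100 + d.month
        if k not in lookup:
            raise ValueError(f"no SST value covering {d.date()}")
        idx.append(lookup[k])
    out = sst.isel(time=idx)
    return out.assign_coords(time=days)


def mdssb_daily(env: EnvironmentalFields, params: NicheParameters = NicheParameters(),
                sst_interp: str = "hold") -> xr.DataArray:
    """Daily gridded carrying capacity K = U1(sst) · U2(depth) · U3(chl).

    SST coarser than daily is broadcast to the chlorophyll time axis
    (``sst_interp``: "hold" or "linear"). Missing inputs give missing K.
    """
    days = pd.DatetimeIndex(env.chl["time"].values)
    sst_daily = _broadcast_sst_to_days(env.sst, days, interp=sst_interp)
    u1 = xr.apply_ufunc(thermal_suitability, sst_daily, kwargs={"params": params})
    u2 = xr.apply_ufunc(bathymetric_suitability, env.depth, kwargs={"params": params})
    u3_vals = trophic_suitability(env.chl.values, params,
                                  axis=env.chl.dims.index("time"))
    u3 = env.chl.copy(data=u3_vals)
    k = u1 * u2 * u3
    k.name = "k"
    k.attrs["long_name"] = "maximum standardised spawning stock biomass (mdSSB)"
    return k


def annualize(daily_k: xr.DataArray, months=DEFAULT_MONTHS) -> xr.DataArray:
    """Annual mean of daily K over the selected months (default March–October).

    A cell-year with no valid day is NaN.
    """
    months = sorted(months)
    sel = daily_k.sel(time=daily_k["time"].dt.month.isin(months))
    if sel.sizes["time"] == 0:
        raise ValueError(f"no days fall in months {months}")
    annual = sel.groupby("time.year").mean("time", skipna=True)
    annual.name = "k"
    return annual


def regional_series(annual_k: xr.DataArray,
                    bbox: tuple[float, float, float, float] = NORTH_SEA_BBOX
                    ) -> CarryingCapacitySeries:
    """Unweighted mean K over cells whose centres fall inside the closed bbox."""
    lat_min, lat_max, lon_min, lon_max = bbox
    lat = annual_k["latitude"]
    lon = annual_k["longitude"]
    sub = annual_k.where(
        (lat >= lat_min) & (lat <= lat_max) & (lon >= lon_min) & (lon <= lon_max),
        drop=True,
    )
    if sub.sizes.get("latitude", 0) == 0 or sub.sizes.get("longitude", 0) == 0:
        raise ValueError(f"bounding box {bbox} does not intersect the grid")
    series = sub.mean(("latitude", "longitude"), skipna=True)
    return CarryingCapacitySeries(
        years=np.asarray(series["year"]), values=series.values, region=tuple(bbox)
    )


def climatology_map(annual_k: xr.DataArray, year_range: tuple[int, int] | None = None
                    ) -> xr.DataArray:
    """Per-cell temporal mean of annual K over ``year_range`` (inclusive)."""
    if year_range is not None:
        y0, y1 = year_range
        annual_k = annual_k.sel(year=(annual_k["year"] >= y0) & (annual_k["year"] <= y1))
    if annual_k.sizes.get("year", 0) == 0:
        raise ValueError("empty year range")
    out = annual_k.mean("year", skipna=True)
    out.attrs["n_years"] = int(annual_k.sizes["year"])
    out.name = "k"
    return out
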