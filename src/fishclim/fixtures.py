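"""Deterministic synthetic environmental grids and stock series.

The generator emulates the features the niche and dynamics modules respond
to — a latitudinal SST gradient with seasonality and a linear warming trend,
a spring chlorophyll bloom that exceeds the trophic threshold for a known
number of days, a shelf bathymetry spanning the whole depth trapezoid, and a
stock series simulated under a known fishing-intensity schedule and exported
in the disguised units an assessment agency would publish (decimal-log SSB
plus a fishing-effort series). Because the truth is known, every estimator
in the package can be checked end to end without external data.

All randomness flows from one integer seed through a single
``numpy.random.Generator`` consumed in a fixed order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .dynamics import DynamicsConfig, simulate
from .niche import EnvironmentalFields

__all__ = ["FixtureConfig", "make_environment", "make_stock_series",
           "default_alpha_schedule", "StockFixture"]


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for the synthetic data.

    Defaults: a 20 x 20 cell grid at 0.25° resolution centred on the North
    Sea, 60 years (1963 onward), SST near the thermal optimum with a mild
    poleward gradient, seasonal cycle and a warming trend, and a spring
    bloom comfortably above the 0.05 mg m^-3 trophic threshold.
    """

    seed: int = 0
    n_lat: int = 20
    n_lon: int = 20
    resolution: float = 0.25
    lat0: float = 53.125
    lon0: float = 0.125
    year_start: int = 1963
    n_years: int = 60
    # SST: cell mean at the grid centre, poleward cooling (°C per degree lat),
    # seasonal half-amplitude, linear trend (°C per year), observation noise.
    sst_mean: float = 7.0
    sst_lat_gradient: float = 0.5
    sst_seasonal_amp: float = 3.0
    sst_trend: float = 0.01
    sst_noise: float = 0.1
    # chlorophyll: background below threshold, bloom level, bloom run length
    # (days) and start day-of-year.
    chl_background: float = 0.04
    chl_bloom_level: float = 0.3
    chl_bloom_days: int = 200
    chl_bloom_start: int = 60
    # bathymetry: shelf deepening across longitude from coast to off-shelf.
    depth_min: float = 20.0
    depth_max: float = 700.0
    # stock series
    r: float = 0.5
    x0: float = 0.2
    obs_noise: float = 0.0

    def __post_init__(self):
        if self.n_lat < 2 or self.n_lon < 2:
            raise ValueError("grid must be at least 2 x 2")
        if self.n_years < 2:
            raise ValueError("need at least two years")
        if self.chl_background >= 0.05:
            raise ValueError("background chlorophyll must sit below the trophic threshold")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_start + self.n_years)


def _axes(config: FixtureConfig):
    lat = config.lat0 + config.resolution * np.arange(config.n_lat)
    lon = config.lon0 + config.resolution * np.arange(config.n_lon)
    return lat, lon


def make_environment(config: FixtureConfig = FixtureConfig(),
                     daily_sst: bool = False) -> EnvironmentalFields:
    """Build synthetic gridded SST (monthly by default), daily chlorophyll
    and bathymetry, bit-reproducible from the seed."""
    rng = np.random.default_rng(config.seed)
    lat, lon = _axes(config)
    years = config.years
    days = pd.date_range(f"{years[0]}-01-01", f"{years[-1]}-12-31", freq="D")
    # drop Feb 29 so every year has 365 days and run lengths are exact
    days = days[~((days.month == 2) & (days.day == 29))]

    if daily_sst:
        sst_times = days
    else:
        sst_times = pd.date_range(f"{years[0]}-01-01", f"{years[-1]}-12-01", freq="MS") \
            + pd.Timedelta(days=14)
    doy = sst_times.dayofyear.values
    yr = sst_times.year.values
    seasonal = config.sst_seasonal_amp * np.sin(2 * np.pi * (doy - 105) / 365.0)
    trend = config.sst_trend * (yr - years[0])
    lat_term = -config.sst_lat_gradient * (lat - lat.mean())
    sst = (config.sst_mean
           + seasonal[:, None, None]
           + trend[:, None, None]
           + lat_term[None, :, None]
           + np.zeros((1, 1, len(lon))))
    sst = sst + config.sst_noise * rng.standard_normal(sst.shape)
    sst = np.clip(sst, -2.0, 35.0)
    sst_da = xr.DataArray(sst, coords={"time": sst_times, "latitude": lat,
                                       "longitude": lon},
                          dims=("time", "latitude", "longitude"), name="sst",
                          attrs={"units": "degC"})

    # day index within the (Feb-29-free) 365-day year, so the bloom covers
    # the same run of days every year
    dd = np.tile(np.arange(1, 366), len(years))
    in_bloom = (dd >= config.chl_bloom_start) & \
               (dd < config.chl_bloom_start + config.chl_bloom_days)
    chl = np.where(in_bloom, config.chl_bloom_level, config.chl_background)
    chl = np.broadcast_to(chl[:, None, None], (len(days), len(lat), len(lon))).copy()
    chl_da = xr.DataArray(chl, coords={"time": days, "latitude": lat,
                                       "longitude": lon},
                          dims=("time", "latitude", "longitude"), name="chl",
                          attrs={"units": "mg m-3"})

    depth_profile = np.linspace(config.depth_min, config.depth_max, len(lon))
    depth = np.broadcast_to(depth_profile[None, :], (len(lat), len(lon))).copy()
    depth_da = xr.DataArray(depth, coords={"latitude": lat, "longitude": lon},
                            dims=("latitude", "longitude"), name="depth",
                            attrs={"units": "m", "positive": "down"})
    return EnvironmentalFields(sst=sst_da, chl=chl_da, depth=depth_da)


def default_alpha_schedule(n_years: int) -> np.ndarray:
    """A smooth rise-and-fall fishing-intensity history in [0.03, 0.38]:
    low early, a sustained high-exploitation middle, managed decline late."""
    t = np.linspace(0, 1, n_years)
    hump = np.exp(-((t - 0.55) ** 2) / (2 * 0.22**2))
    return 0.03 + 0.35 * hump


@dataclass
class StockFixture:
    """Published-style stock table plus the generating truth."""

    table: pd.DataFrame = field(repr=False)
    x_true: np.ndarray = field(repr=False)
    alpha_true: np.ndarray = field(repr=False)
    k_series: np.ndarray = field(repr=False)
    scale_true: float = 1.0
    offset_true: float = 0.0
    r: float = 0.5


def make_stock_series(config: FixtureConfig, k_series,
                      alpha_schedule=None,
                      disguise: tuple[float, float] = (0.25, 0.02)
                      ) -> StockFixture:
    """Simulate a stock under a known alpha schedule and export it the way
    an assessment would publish it.

    The truth x is hidden behind an affine decimal-log series
    L = (x - offset) / scale so that x = scale * L + offset is recoverable;
    effort F equals the true alpha plus optional observation noise.
    """
    rng = np.random.default_rng(config.seed + 1)
    k = np.asarray(k_series, dtype=float)
    n = len(k)
    if alpha_schedule is None:
        alpha_schedule = default_alpha_schedule(n)
    alpha = np.asarray(alpha_schedule, dtype=float)
    if len(alpha) != n:
        raise ValueError("alpha schedule misaligned with k series")
    traj = simulate(config.x0, k, alpha, config.r,
                    DynamicsConfig(extirpation_rule_enabled=False),
                    years=config.years[:n])
    scale, offset = disguise
    log_ssb = (traj.x - offset) / scale
    effort = alpha + config.obs_noise * rng.standard_normal(n)
    table = pd.DataFrame({
        "year": traj.years,
        "ssb_log10": log_ssb,
        "recruitment_log10": np.log10(np.maximum(traj.x * k, 1e-6)) + 3.0,
        "effort_f": effort,
    })
    return StockFixture(table=table, x_true=traj.x, alpha_true=alpha,
                        k_series=k, scale_true=scale, offset_true=offset,
                        r=config.r)
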