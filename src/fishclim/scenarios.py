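"""Gridded stock projections under management policies.

Each grid cell carries its own annual carrying-capacity series (from the
niche module, typically driven by climate projections). Three harvest
policies are supported:

* constant intensity — a fixed fraction of biomass removed each year;
* constant catch — a fixed standardised removal each year;
* dynamic MSY — intensity alpha_MSY,t = r (1 - X_MSY,t / K_t) chosen so the
  stock is held at X_MSY,t; with the conventional X_MSY = K/2 this is the
  constant r/2.

Projections run with the extirpation rule on (a cell whose biomass reaches
the threshold is extirpated for good), producing per-cell extirpation-year
and cumulative ("pooled") standardised catch maps, which scenario
comparisons reduce to difference histograms and medians over a bounding box.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xarray as xr

from .dynamics import DynamicsConfig, StockTrajectory, equilibrium, simulate, \
    simulate_constant_catch
from .niche import NORTH_SEA_BBOX

__all__ = [
    "ConstantAlphaPolicy",
    "ConstantCatchPolicy",
    "MSYPolicy",
    "ScenarioComparison",
    "msy_alpha",
    "project_cell",
    "extirpation_year_map",
    "pooled_catch_map",
    "compare_scenarios",
]

PROJECTION_CONFIG = DynamicsConfig(extirpation_rule_enabled=True)


@dataclass(frozen=True)
class ConstantAlphaPolicy:
    """Fishing intensity fixed in space and time (no adjustment to CIEC)."""

    alpha: float = 0.04

    def __post_init__(self):
        if not (0 <= self.alpha <= 1):
            raise ValueError("alpha must be in [0, 1]")


@dataclass(frozen=True)
class ConstantCatchPolicy:
    """Fixed annual standardised removal."""

    catch: float = 0.03

    def __post_init__(self):
        if self.catch < 0:
            raise ValueError("catch must be non-negative")


@dataclass(frozen=True)
class MSYPolicy:
    """Dynamic maximum-sustainable-yield rule holding the stock at X_MSY.

    With X_MSY = x_msy_fraction * K, the implied intensity is the constant
    r (1 - x_msy_fraction), i.e. r/2 at the default fraction of one half.
    """

    x_msy_fraction: float = 0.5

    def __post_init__(self):
        if not (0 < self.x_msy_fraction <= 1):
            raise ValueError("x_msy_fraction must be in (0, 1]")


Policy = ConstantAlphaPolicy | ConstantCatchPolicy | MSYPolicy


def msy_alpha(k_t: float, r: float, x_msy_fraction: float = 0.5) -> float:
    """Intensity holding the stock at X_MSY = fraction * K_t.

    alpha_MSY = r (1 - X_MSY / K) = r (1 - fraction); independent of K_t
    because the target scales with it, but K_t must be positive for the rule
    to be meaningful.
    """
    if not (0 < x_msy_fraction <= 1):
        raise ValueError("x_msy_fraction must be in (0, 1]")
    if k_t <= 0:
        raise ValueError("k_t must be positive")
    return r * (1.0 - x_msy_fraction)


def _initial_state(k0: float, policy: Policy, r: float, x0_rule) -> float:
    """Initial dSSB for a projection; the spin-up state is not observable,
    so by default the stock starts at equilibrium with the first year's
    forcing."""
    if isinstance(x0_rule, (int, float)):
        return float(x0_rule)
    if x0_rule == "half_k":
        return 0.5 * k0
    if x0_rule == "k":
        return float(k0)
    if x0_rule != "equilibrium":
        raise ValueError(f"unknown x0 rule {x0_rule!r}")
    if k0 <= 0:
        return 0.0
    if isinstance(policy, ConstantCatchPolicy):
        # upper root of r x (1 - x/k) = catch, if sustainable
        disc = 1.0 - 4.0 * policy.catch / (r * k0)
        if disc < 0:
            return 0.5 * k0
        return 0.5 * k0 * (1.0 + np.sqrt(disc))
    if isinstance(policy, MSYPolicy):
        return equilibrium(k0, r, r * (1.0 - policy.x_msy_fraction))
    return equilibrium(k0, r, policy.alpha)


def project_cell(k_series, policy: Policy, r: float = 0.5,
                 x0_rule="equilibrium",
                 config: DynamicsConfig = PROJECTION_CONFIG,
                 years=None) -> tuple[StockTrajectory, np.ndarray]:
    """Project one cell under a policy; returns (trajectory, annual catch).

    Catch is booked on pre-step biomass (alpha_t * x_t, or the fixed catch
    while the stock persists) and is zero after extirpation.
    """
    k = np.asarray(k_series, dtype=float)
    x0 = _initial_state(k[0], policy, r, x0_rule)
    if x0 <= 0 or (config.extirpation_rule_enabled
                   and x0 <= config.extirpation_threshold):
        traj = StockTrajectory(x=np.zeros(len(k)), k=k,
                               alpha=np.zeros(len(k)), r=r, years=years)
        traj.extirpated_year = int(traj.years[0])
        return traj, np.zeros(len(k))
    if isinstance(policy, ConstantCatchPolicy):
        traj = simulate_constant_catch(x0, k, policy.catch, r, config, years=years)
        catch = np.where(traj.x > 0, np.minimum(policy.catch, traj.x), 0.0)
        return traj, catch
    if isinstance(policy, MSYPolicy):
        alpha = r * (1.0 - policy.x_msy_fraction)
    else:
        alpha = policy.alpha
    traj = simulate(x0, k, alpha, r, config, years=years)
    return traj, traj.alpha * traj.x


def _per_cell(k_grid_series: xr.DataArray, func):
    lat = k_grid_series["latitude"].values
    lon = k_grid_series["longitude"].values
    out = np.full((len(lat), len(lon)), np.nan)
    for i in range(len(lat)):
        for j in range(len(lon)):
            k_cell = k_grid_series.isel(latitude=i, longitude=j).values
            out[i, j] = func(k_cell)
    return xr.DataArray(out, coords={"latitude": lat, "longitude": lon},
                        dims=("latitude", "longitude"))


def extirpation_year_map(k_grid_series: xr.DataArray, policy: Policy,
                         r: float = 0.5, x0_rule="equilibrium",
                         config: DynamicsConfig = PROJECTION_CONFIG) -> xr.DataArray:
    """Per-cell year of extirpation (NaN where the stock persists).

    ``k_grid_series`` has dims (year, latitude, longitude).
    """
    years = k_grid_series["year"].values

    def one(k_cell):
        if np.isnan(k_cell).all():
            return np.nan
        traj, _ = project_cell(np.nan_to_num(k_cell), policy, r, x0_rule,
                               config, years=years)
        return np.nan if traj.extirpated_year is None else float(traj.extirpated_year)

    out = _per_cell(k_grid_series, one)
    out.name = "extirpation_year"
    return out


def pooled_catch_map(k_grid_series: xr.DataArray, policy: Policy,
                     r: float = 0.5, x0_rule="equilibrium",
                     config: DynamicsConfig = PROJECTION_CONFIG) -> xr.DataArray:
    """Per-cell cumulative standardised catch over the projection years."""
    years = k_grid_series["year"].values

    def one(k_cell):
        if np.isnan(k_cell).all():
            return np.nan
        _, catch = project_cell(np.nan_to_num(k_cell), policy, r, x0_rule,
                                config, years=years)
        return float(catch.sum())

    out = _per_cell(k_grid_series, one)
    out.name = "pooled_catch"
    return out


@dataclass
class ScenarioComparison:
    """Cellwise difference of two scenario maps, summarised over a bbox."""

    map_a: xr.DataArray
    map_b: xr.DataArray
    differences: np.ndarray
    e_median: float
    mode: str
    bbox: tuple[float, float, float, float] = field(default=NORTH_SEA_BBOX)
    n_cells: int = 0


def compare_scenarios(map_a: xr.DataArray, map_b: xr.DataArray,
                      bbox=NORTH_SEA_BBOX, mode: str = "years",
                      censoring: str = "exclude",
                      horizon_year: float | None = None) -> ScenarioComparison:
    """Median difference E between two scenario maps over bbox cells.

    ``mode='years'`` reports a - b in years of extirpation; cells without an
    extirpation year on either side are excluded by default, or imputed as
    ``horizon_year + 1`` with ``censoring='impute'``. ``mode='catch'``
    reports the percentage reduction 100 (a - b) / a in pooled catch.
    """
    if (map_a["latitude"].shape != map_b["latitude"].shape
            or not np.allclose(map_a["latitude"], map_b["latitude"])
            or not np.allclose(map_a["longitude"], map_b["longitude"])):
        raise ValueError("scenario maps are on different grids")
    lat_min, lat_max, lon_min, lon_max = bbox
    in_box = ((map_a["latitude"] >= lat_min) & (map_a["latitude"] <= lat_max)
              & (map_a["longitude"] >= lon_min) & (map_a["longitude"] <= lon_max))
    a = map_a.where(in_box).values
    b = map_b.where(in_box).values
    if mode == "years":
        if censoring == "impute":
            if horizon_year is None:
                raise ValueError("censoring='impute' requires horizon_year")
            a = np.where(np.isnan(a) & ~np.isnan(b), horizon_year + 1, a)
            b = np.where(np.isnan(b) & ~np.isnan(a), horizon_year + 1, b)
        valid = ~np.isnan(a) & ~np.isnan(b)
        diffs = (a - b)[valid]
    elif mode == "catch":
        valid = ~np.isnan(a) & ~np.isnan(b) & (a != 0)
        diffs = 100.0 * (a - b)[valid] / a[valid]
    else:
        raise ValueError(f"unknown comparison mode {mode!r}")
    med = float(np.median(diffs)) if diffs.size else np.nan
    return ScenarioComparison(map_a=map_a, map_b=map_b, differences=diffs,
                              e_median=med, mode=mode, bbox=tuple(bbox),
                              n_cells=int(diffs.size))
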