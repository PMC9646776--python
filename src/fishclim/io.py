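"""Readers/writers for the NetCDF grid and CSV series dialects, run
configuration, and the end-to-end analysis orchestrator.

Grids travel as CF-style NetCDF (dims ``time``/``latitude``/``longitude``;
written with xarray's NETCDF3 backend), series and tables as plain CSV.
Units are normalised at the boundary: SST in kelvin is converted to °C and
chlorophyll in kg m^-3 (the CMIP6 convention) to mg m^-3; longitudes on a
0–360 axis are rewrapped to -180..180.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from . import dynamics, fixtures, inference, niche, scenarios
from .niche import NORTH_SEA_BBOX

logger = logging.getLogger(__name__)

_DIM_ALIASES = {"lat": "latitude", "lon": "longitude", "y": "latitude",
                "x": "longitude", "t": "time"}


def _normalise(da: xr.DataArray, variable: str) -> xr.DataArray:
    rename = {d: _DIM_ALIASES[d] for d in da.dims if d in _DIM_ALIASES}
    if rename:
        da = da.rename(rename)
    for axis in ("latitude", "longitude"):
        if axis not in da.dims:
            raise ValueError(f"variable {variable!r} lacks dimension {axis!r}")
    lon = np.asarray(da["longitude"])
    if lon.max() > 180:
        wrapped = ((lon + 180) % 360) - 180
        da = da.assign_coords(longitude=wrapped).sortby("longitude")
        logger.info("longitude axis rewrapped from 0..360 to -180..180")
    for axis in ("latitude", "longitude"):
        vals = np.asarray(da[axis])
        if np.any(np.diff(vals) < 0):
            da = da.sortby(axis)
        if np.any(np.diff(np.asarray(da[axis])) <= 0):
            raise ValueError(f"axis {axis!r} is not strictly monotonic")
    units = str(da.attrs.get("units", "")).lower()
    if units in {"k", "kelvin"} or (units == "" and float(da.max()) > 200):
        da = da - 273.15
        da.attrs["units"] = "degC"
        logger.info("SST-like variable converted from kelvin to degC")
    if units in {"kg m-3", "kg/m3", "kg m^-3", "kg.m-3"}:
        da = da * 1e6
        da.attrs["units"] = "mg m-3"
        logger.info("chlorophyll converted from kg m-3 to mg m-3")
    return da


def read_grid(path, variable: str) -> xr.DataArray:
    """Read one gridded variable from NetCDF with axis/unit normalisation."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ds = xr.open_dataset(path, engine="scipy")
    if variable not in ds:
        raise ValueError(f"variable {variable!r} not found in {path}; "
                         f"available: {sorted(ds.data_vars)}")
    return _normalise(ds[variable].load(), variable)


def write_grid(da: xr.DataArray, path, name: str | None = None) -> None:
    """Write a DataArray to CF-style NetCDF (NETCDF3 via the scipy engine)."""
    if name:
        da = da.rename(name)
    da = da.astype("float64")
    da.to_dataset(name=da.name or "data").to_netcdf(path, engine="scipy")


def write_series(series: niche.CarryingCapacitySeries, path) -> None:
    series.to_frame().to_csv(path, index=False)


def read_series(path) -> niche.CarryingCapacitySeries:
    df = pd.read_csv(path)
    return niche.CarryingCapacitySeries(years=df["year"].values,
                                        values=df["k"].values)


def read_stock_table(path) -> pd.DataFrame:
    """Read a stock assessment table (year + named columns), validated.

    Years must be unique and contiguous; unknown columns are preserved with
    a warning.
    """
    df = pd.read_csv(path)
    if "year" not in df.columns:
        raise ValueError("stock table must have a 'year' column")
    years = df["year"].values
    dup = df["year"][df["year"].duplicated()].tolist()
    if dup:
        raise ValueError(f"duplicate years in stock table: {dup}")
    gaps = sorted(set(range(int(years.min()), int(years.max()) + 1)) - set(years))
    if gaps:
        raise ValueError(f"stock table has gaps; missing years: {gaps}")
    known = {"year", "ssb_log10", "recruitment_log10", "effort_f"}
    extra = set(df.columns) - known
    if extra:
        logger.warning("stock table has unknown column(s) %s: preserved", sorted(extra))
    return df.sort_values("year").reset_index(drop=True)


def write_trajectory(traj: dynamics.StockTrajectory, path) -> None:
    traj.to_frame().to_csv(path, index=False)


def read_trajectory(path) -> dynamics.StockTrajectory:
    df = pd.read_csv(path)
    ext = df.loc[df["extirpated"] == 1, "year"]
    traj = dynamics.StockTrajectory(
        x=df["x"].values, k=df["k"].values, alpha=df["alpha"].values,
        r=float("nan"), years=df["year"].values,
        extirpated_year=int(ext.iloc[0]) if len(ext) else None)
    return traj


@dataclass
class RunConfig:
    """Serialisable configuration of a full analysis run."""

    seed: int = 0
    r: float = 0.5
    bbox: tuple[float, float, float, float] = field(default=NORTH_SEA_BBOX)
    periods: int = 7
    projection_years: int = 81
    projection_alpha: float = 0.04
    projection_k_decline: float = 0.8  # fractional K loss by the horizon
    out_dir: str = "fishclim_out"
    fixture: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "bbox" in data:
            data["bbox"] = tuple(data["bbox"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["bbox"] = list(d["bbox"])
        return d

    @property
    def config_hash(self) -> str:
        # hash the scientific parameters only: where the output lands must
        # not change what the run computes
        d = self.to_dict()
        d.pop("out_dir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_analysis(config: RunConfig) -> dict:
    """Full synthetic-data pipeline: environment -> K -> inference ->
    attribution -> recovery table -> scenario projection medians.

    Deterministic given the config (and its seed); writes all artefacts
    under ``config.out_dir`` plus a machine-readable ``summary.json``
    embedding the config and its hash, and returns the summary dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fx = fixtures.FixtureConfig(seed=config.seed, r=config.r,
                                **config.fixture)
    logger.info("stage: environment and carrying capacity")
    env = fixtures.make_environment(fx)
    daily_k = niche.mdssb_daily(env)
    annual_k = niche.annualize(daily_k)
    write_grid(annual_k, out / "annual_k.nc", name="k")
    grid_bbox = (float(env.depth["latitude"].min()), float(env.depth["latitude"].max()),
                 float(env.depth["longitude"].min()), float(env.depth["longitude"].max()))
    k_series = niche.regional_series(annual_k, grid_bbox)
    write_series(k_series, out / "k_series.csv")

    logger.info("stage: stock series, standardisation and alpha estimation")
    stock = fixtures.make_stock_series(fx, k_series.values)
    stock.table.to_csv(out / "stock_table.csv", index=False)
    mapping, x_obs = inference.standardise_ssb(
        stock.table["ssb_log10"].values, k_series.values,
        stock.table["effort_f"].values, r=config.r)
    alpha_hat = inference.estimate_alpha(x_obs, k_series.values, r=config.r)
    pd.DataFrame({"year": k_series.years[:-1], "alpha_hat": alpha_hat}).to_csv(
        out / "alpha_hat.csv", index=False)

    logger.info("stage: counterfactual reconstruction and attribution")
    alpha_full = np.clip(np.append(alpha_hat, alpha_hat[-1]), 0.0, 1.0)
    cf = inference.reconstruct_counterfactuals(
        x_obs[0], k_series.values, alpha_full, r=config.r,
        years=k_series.years)
    fishing_inf, env_inf = inference.influence_series(cf)
    matrix = np.column_stack([cf.full.x, fishing_inf, env_inf])
    periods = inference.identify_periods(matrix, k_groups=config.periods,
                                         years=k_series.years)
    rows = []
    for p in periods + [(int(k_series.years[0]), int(k_series.years[-1]))]:
        if p[1] - p[0] + 1 < 3:
            continue
        res = inference.influence_index(cf, p)
        rows.append({"period_start": p[0], "period_end": p[1],
                     "epsilon_mean": res.jackknife_mean,
                     "epsilon_min": res.jackknife_min,
                     "epsilon_max": res.jackknife_max})
    attribution = pd.DataFrame(rows)
    attribution.to_csv(out / "attribution.csv", index=False)

    logger.info("stage: recovery table")
    recovery = {
        f"r={r_}_K={k_}": round(dynamics.recovery_time(k_, r_), 1)
        for r_ in (0.25, 0.5, 0.75) for k_ in (1.0, 0.401)
    }

    logger.info("stage: scenario projection")
    clim = niche.climatology_map(annual_k)
    proj_years = np.arange(2020, 2020 + config.projection_years)
    fade = np.linspace(1.0, 1.0 - config.projection_k_decline,
                       config.projection_years)
    k_proj = xr.concat([clim * f for f in fade],
                       dim=pd.Index(proj_years, name="year"))
    const = scenarios.ConstantAlphaPolicy(alpha=config.projection_alpha)
    msy = scenarios.MSYPolicy()
    ext_const = scenarios.extirpation_year_map(k_proj, const, r=config.r)
    ext_msy = scenarios.extirpation_year_map(k_proj, msy, r=config.r)
    catch_const = scenarios.pooled_catch_map(k_proj, const, r=config.r)
    catch_msy = scenarios.pooled_catch_map(k_proj, msy, r=config.r)
    for da, nm in ((ext_const, "extirpation_const.nc"), (ext_msy, "extirpation_msy.nc"),
                   (catch_const, "catch_const.nc"), (catch_msy, "catch_msy.nc")):
        write_grid(da, out / nm)
    cmp_ext = scenarios.compare_scenarios(ext_msy, ext_const, grid_bbox, mode="years")
    cmp_catch = scenarios.compare_scenarios(catch_msy, catch_const, grid_bbox,
                                            mode="catch")

    summary = {
        "config": config.to_dict(),
        "config_hash": config.config_hash,
        "standardisation": {"scale": mapping.scale, "offset": mapping.offset,
                            "objective": mapping.objective},
        "attribution": rows,
        "recovery_years": recovery,
        "scenarios": {
            "extirpation_delay_median_years": cmp_ext.e_median,
            "extirpation_cells_compared": cmp_ext.n_cells,
            "catch_reduction_median_percent": cmp_catch.e_median,
        },
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
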