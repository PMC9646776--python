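"""Harvested logistic stock dynamics.

The state variable X_t is spawning stock biomass standardised to a 0–1 scale
(dSSB). One year of dynamics is

    X_{t+1} = X_t + r X_t (1 - X_t / K_t) - alpha_t X_t

with r the population growth rate, K_t the environmentally driven carrying
capacity (mdSSB) and alpha_t the fishing intensity (fraction of dSSB removed
per year). X may be transiently above K after an adverse shift in K; the map
never caps X at K. Extirpation is an absorbing state triggered when X reaches
a small threshold, and stock collapse is X at or below a fraction (default
10%) of the unfished biomass K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DynamicsConfig",
    "StockTrajectory",
    "step",
    "simulate",
    "simulate_constant_catch",
    "equilibrium",
    "recovery_time",
    "is_collapsed",
]


@dataclass(frozen=True)
class DynamicsConfig:
    """Policy knobs for simulation: extirpation, collapse, clamping.

    The extirpation rule is intended for modelled and projected series; for
    historical reconstruction it is normally disabled so that low observed
    biomass is not forced to zero.
    """

    extirpation_threshold: float = 0.1
    extirpation_rule_enabled: bool = True
    collapse_fraction: float = 0.1
    clamp_negative: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.extirpation_threshold < 1):
            raise ValueError("extirpation_threshold must be in (0, 1)")
        if not (0 < self.collapse_fraction < 1):
            raise ValueError("collapse_fraction must be in (0, 1)")


@dataclass
class StockTrajectory:
    """A simulated dSSB trajectory with the forcing that produced it."""

    x: np.ndarray
    k: np.ndarray
    alpha: np.ndarray
    r: float
    years: np.ndarray | None = None
    extirpated_year: int | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.k = np.asarray(self.k, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        if not (len(self.x) == len(self.k) == len(self.alpha)):
            raise ValueError("x, k and alpha must share length")
        if self.years is None:
            self.years = np.arange(len(self.x))
        else:
            self.years = np.asarray(self.years, dtype=int)
            if len(self.years) != len(self.x):
                raise ValueError("years misaligned with x")

    def to_frame(self) -> pd.DataFrame:
        ext = np.zeros(len(self.x), dtype=int)
        if self.extirpated_year is not None:
            ext[self.years >= self.extirpated_year] = 1
        return pd.DataFrame(
            {"year": self.years, "k": self.k, "alpha": self.alpha,
             "x": self.x, "extirpated": ext}
        )


def _validate_r(r: float) -> None:
    if not (0 < r <= 1):
        raise ValueError("population growth rate r must be in (0, 1]")


def step(x: float, k: float, r: float, alpha: float = 0.0) -> float:
    """One year of the harvested logistic map (no clamping applied).

    When k = 0 the growth term is taken as its limit 0 and only removal acts.
    """
    if k == 0:
        return x - alpha * x
    return x + r * x * (1.0 - x / k) - alpha * x


def _iterate(x0, k_series, removal, r, config, constant_catch):
    """Shared iteration core for intensity- and catch-driven simulation."""
    k_series = np.asarray(k_series, dtype=float)
    removal = np.asarray(removal, dtype=float)
    if removal.ndim == 0:
        removal = np.full(len(k_series), float(removal))
    if len(removal) != len(k_series):
        raise ValueError("forcing series misaligned with k series")
    n = len(k_series)
    x = np.empty(n)
    x[0] = x0
    extirpated = None
    if config.extirpation_rule_enabled and x[0] <= config.extirpation_threshold:
        extirpated = 0
        x[:] = 0.0
    for t in range(n - 1):
        if extirpated is not None:
            x[t + 1] = 0.0
            continue
        if constant_catch:
            growth = 0.0 if k_series[t] == 0 else r * x[t] * (1 - x[t] / k_series[t])
            nxt = x[t] + growth - removal[t]
        else:
            nxt = step(x[t], k_series[t], r, removal[t])
        if config.clamp_negative and nxt < 0:
            nxt = 0.0
        if config.extirpation_rule_enabled and nxt <= config.extirpation_threshold:
            extirpated = t + 1
            nxt = 0.0
        x[t + 1] = nxt
    return x, extirpated


def simulate(x0: float, k_series, alpha_series, r: float = 0.5,
             config: DynamicsConfig = DynamicsConfig(),
             years=None) -> StockTrajectory:
    """Iterate the harvested logistic map over aligned K and alpha series.

    ``alpha_series`` may be a scalar (held constant). With the extirpation
    rule on, the first year X falls to or below the threshold zeroes the
    stock permanently and is recorded.
    """
    _validate_r(r)
    if x0 <= 0:
        raise ValueError("initial dSSB x0 must be positive")
    k_series = np.asarray(k_series, dtype=float)
    alpha = np.asarray(alpha_series, dtype=float)
    if alpha.ndim == 0:
        alpha = np.full(len(k_series), float(alpha))
    if np.any((alpha < 0) | (alpha > 1)):
        raise ValueError("fishing intensity alpha must be in [0, 1]")
    x, ext_idx = _iterate(x0, k_series, alpha, r, config, constant_catch=False)
    yrs = np.arange(len(x)) if years is None else np.asarray(years, dtype=int)
    ext_year = None if ext_idx is None else int(yrs[ext_idx])
    return StockTrajectory(x=x, k=k_series, alpha=alpha, r=r, years=yrs,
                           extirpated_year=ext_year)


def simulate_constant_catch(x0: float, k_series, catch: float, r: float = 0.5,
                            config: DynamicsConfig = DynamicsConfig(),
                            years=None) -> StockTrajectory:
    """Iterate the map with a fixed annual removal (standardised catch)."""
    _validate_r(r)
    if catch < 0:
        raise ValueError("catch must be non-negative")
    k_series = np.asarray(k_series, dtype=float)
    x, ext_idx = _iterate(x0, k_series, catch, r, config, constant_catch=True)
    # report the implied per-year intensity where biomass is positive
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_implied = np.where(x > 0, np.minimum(catch / np.where(x > 0, x, 1.0), 1.0), 0.0)
    yrs = np.arange(len(x)) if years is None else np.asarray(years, dtype=int)
    ext_year = None if ext_idx is None else int(yrs[ext_idx])
    return StockTrajectory(x=x, k=k_series, alpha=alpha_implied, r=r, years=yrs,
                           extirpated_year=ext_year)


def equilibrium(k: float, r: float, alpha: float = 0.0) -> float:
    """Closed-form fixed point of the harvested logistic map, floored at 0."""
    if r <= 0:
        raise ValueError("r must be positive")
    return max(0.0, k * (1.0 - alpha / r))


def recovery_time(k: float, r: float, target: float = 0.4, x0: float = 0.1,
                  max_steps: int = 100_000) -> float:
    """Years to rebuild from a post-collapse state under a moratorium.

    Iterates the unfished map from ``x0`` until the stock first reaches
    ``target``; returns the linearly interpolated fractional crossing step
    plus one counted starting year. Returns ``inf`` when the carrying
    capacity does not exceed the target (rebuilding impossible).
    """
    _validate_r(r)
    if x0 <= 0:
        raise ValueError("x0 must be positive")
    if k <= target:
        return math.inf
    if x0 >= target:
        return 1.0
    prev = x0
    for n in range(1, max_steps + 1):
        cur = step(prev, k, r, 0.0)
        if cur >= target:
            frac = (target - prev) / (cur - prev)
            return (n - 1) + frac + 1.0
        prev = cur
    return math.inf


def is_collapsed(x: float, k: float,
                 config: DynamicsConfig = DynamicsConfig()) -> bool:
    """Collapse test: dSSB at or below ``collapse_fraction`` of mdSSB."""
    if k < 0:
        raise ValueError("k must be non-negative")
    return bool(x <= config.collapse_fraction * k)
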