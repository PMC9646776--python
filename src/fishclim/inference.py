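"""Inverse estimation of fishing intensity and fishing-vs-environment attribution.

Rearranging the harvested logistic map gives the fishing intensity implied by
two consecutive observations of standardised biomass,

    alpha_t = 1 + r (1 - X_t / K_t) - X_{t+1} / X_t ,

which is an exact algebraic inverse of the forward step. An external
assessment SSB series (decimal log) is brought onto the model's 0–1 scale by
an affine map chosen, under the feasibility constraint 0 < X_t < min_t(K_t),
to maximise the correlation between the implied intensity and an independent
fishing-effort series.

Attribution contrasts the fully forced reconstruction with four
counterfactuals (fishing frozen at its observed extremes; environment frozen
at its observed extremes). The fishing-influence index is

    epsilon = 100 * gamma / (gamma + delta)

where gamma measures departure from the minimal-fishing counterfactual and
delta departure from the best-environment counterfactual; a jackknife over
years gives its range. Regimes (periods) are cut from an average-linkage
clustering of the year-by-year profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .dynamics import DynamicsConfig, StockTrajectory, simulate
from .stats import minmax_standardise

__all__ = [
    "StandardisationMap",
    "CounterfactualSet",
    "AttributionResult",
    "estimate_alpha",
    "standardise_ssb",
    "reconstruct_counterfactuals",
    "influence_series",
    "influence_index",
    "jackknife_epsilon",
    "identify_periods",
]

#: DynamicsConfig used for historical reconstruction (extirpation rule off).
RECONSTRUCTION_CONFIG = DynamicsConfig(extirpation_rule_enabled=False)


@dataclass(frozen=True)
class StandardisationMap:
    """Affine map x = scale * log10(SSB) + offset onto the model scale."""

    scale: float
    offset: float
    feasible: bool
    objective: float

    def apply(self, log_ssb) -> np.ndarray:
        return self.scale * np.asarray(log_ssb, dtype=float) + self.offset


@dataclass
class CounterfactualSet:
    """The fully forced reconstruction and its four frozen-forcing variants."""

    full: StockTrajectory
    alpha_min_fixed: StockTrajectory
    alpha_max_fixed: StockTrajectory
    k_min_fixed: StockTrajectory
    k_max_fixed: StockTrajectory

    @property
    def years(self) -> np.ndarray:
        return self.full.years


@dataclass
class AttributionResult:
    """Fishing-influence index with jackknife range for one period."""

    period: tuple[int, int]
    gamma: float
    delta: float
    epsilon: float
    jackknife_mean: float
    jackknife_min: float
    jackknife_max: float

    @property
    def environment_percent(self) -> float:
        return 100.0 - self.epsilon


def estimate_alpha(x_series, k_series, r: float = 0.5) -> np.ndarray:
    """Fishing intensity implied by consecutive dSSB observations.

    Returns n-1 values for an n-year series (the last year has no successor).
    Values outside [0, 1] are returned as computed; they signal inconsistent
    inputs rather than being clipped.
    """
    x = np.asarray(x_series, dtype=float)
    k = np.asarray(k_series, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least two observations")
    if len(k) != len(x):
        raise ValueError("x and k series misaligned")
    if np.any(x <= 0):
        raise ValueError("dSSB must be strictly positive for inversion")
    return 1.0 + r * (1.0 - x[:-1] / k[:-1]) - x[1:] / x[:-1]


def _objective(x, k, effort, r):
    alpha_hat = estimate_alpha(x, k, r)
    f = np.asarray(effort, dtype=float)[: len(alpha_hat)]
    if np.std(alpha_hat) == 0 or np.std(f) == 0:
        return np.nan
    return float(np.corrcoef(alpha_hat, f)[0, 1])


def _objective_batch(x_batch, k, effort, r):
    """Correlation objective for a (n_maps, n_years) batch of candidate
    standardised series (all strictly positive by construction)."""
    xa, xb = x_batch[:, :-1], x_batch[:, 1:]
    alpha = 1.0 + r * (1.0 - xa / k[None, :-1]) - xb / xa
    f = effort[: alpha.shape[1]]
    a_c = alpha - alpha.mean(axis=1, keepdims=True)
    f_c = f - f.mean()
    denom = np.sqrt((a_c**2).sum(axis=1) * (f_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return (a_c @ f_c) / denom


def standardise_ssb(log_ssb, k_series, effort, r: float = 0.5,
                    grid: int = 200) -> tuple[StandardisationMap, np.ndarray]:
    """Choose the affine standardisation of log10 SSB that best matches effort.

    Grid-searches (scale, offset) over maps keeping every mapped value
    strictly inside (0, min_t K_t), maximising the Pearson correlation
    between the implied fishing intensity and the effort series; the grid is
    refined once around the optimum. Ties break toward mid-range placement
    of the mapped series.
    """
    log_ssb = np.asarray(log_ssb, dtype=float)
    k = np.asarray(k_series, dtype=float)
    effort = np.asarray(effort, dtype=float)
    if not (len(log_ssb) == len(k)):
        raise ValueError("series misaligned")
    if np.ptp(log_ssb) == 0:
        raise ValueError("log SSB series is constant: standardisation infeasible")
    kmin = float(np.min(k))
    if kmin <= 0:
        raise ValueError("min(K) must be positive for a feasible standardisation")
    lo, hi = float(np.min(log_ssb)), float(np.max(log_ssb))
    span = hi - lo
    mid_target = kmin / 2.0

    def search(scales, n_off):
        best = None
        for s in scales:
            # strict feasibility: 0 < s*L + o < kmin for all L in [lo, hi]
            o_lo, o_hi = -s * lo, kmin - s * hi
            if o_hi <= o_lo:
                continue
            eps = (o_hi - o_lo) * 1e-6
            offs = np.linspace(o_lo + eps, o_hi - eps, n_off)
            x_batch = s * log_ssb[None, :] + offs[:, None]
            objs = _objective_batch(x_batch, k, effort, r)
            midness = -np.abs(x_batch.mean(axis=1) - mid_target)  # tie-break
            ok = ~np.isnan(objs)
            if not ok.any():
                continue
            objs = np.where(ok, objs, -np.inf)
            idx = np.lexsort((midness, objs))[-1]
            cand = (float(objs[idx]), float(midness[idx]), float(s), float(offs[idx]))
            if best is None or cand[:2] > best[:2]:
                best = cand
        return best

    s_max = kmin / span
    scales = np.linspace(s_max / grid, s_max * (1 - 1.0 / grid), grid)
    best = search(scales, grid)
    if best is None:
        raise ValueError("no feasible standardisation map found")
    # one refinement pass around the optimum
    ds = scales[1] - scales[0]
    s0 = best[2]
    fine = np.linspace(max(s0 - ds, s_max / (10 * grid)), min(s0 + ds, s_max * (1 - 1e-6)), grid)
    best2 = search(fine, grid)
    if best2 is not None and best2[:2] > best[:2]:
        best = best2
    obj, _, s, o = best
    mapping = StandardisationMap(scale=float(s), offset=float(o),
                                 feasible=True, objective=obj)
    return mapping, mapping.apply(log_ssb)


def reconstruct_counterfactuals(x0: float, k_series, alpha_series,
                                r: float = 0.5, years=None) -> CounterfactualSet:
    """Simulate the full reconstruction and the four frozen-forcing scenarios.

    Fishing counterfactuals freeze alpha at its observed minimum and maximum;
    environmental counterfactuals freeze K at its observed minimum and
    maximum. The extirpation rule is off (historical reconstruction).
    """
    k = np.asarray(k_series, dtype=float)
    a = np.asarray(alpha_series, dtype=float)
    if len(k) != len(a):
        raise ValueError("k and alpha series misaligned")
    cfg = RECONSTRUCTION_CONFIG
    run = lambda kk, aa: simulate(x0, kk, aa, r, cfg, years=years)
    return CounterfactualSet(
        full=run(k, a),
        alpha_min_fixed=run(k, np.full_like(a, a.min())),
        alpha_max_fixed=run(k, np.full_like(a, a.max())),
        k_min_fixed=run(np.full_like(k, k.min()), a),
        k_max_fixed=run(np.full_like(k, k.max()), a),
    )


def influence_series(cf: CounterfactualSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-year residual influence of fishing and of the environment.

    The fishing influence is the departure of the full reconstruction from
    the mean of the two frozen-environment runs; the environmental influence
    its departure from the mean of the two frozen-fishing runs. Signs are
    retained.
    """
    fishing = cf.full.x - 0.5 * (cf.k_min_fixed.x + cf.k_max_fixed.x)
    env = cf.full.x - 0.5 * (cf.alpha_min_fixed.x + cf.alpha_max_fixed.x)
    return fishing, env


def _period_mask(years: np.ndarray, period) -> np.ndarray:
    y0, y1 = period
    mask = (years >= y0) & (years <= y1)
    if not mask.any():
        raise ValueError(f"period {period} outside the series")
    return mask


def _gamma_delta(cf: CounterfactualSet, mask: np.ndarray,
                 strategy: str) -> tuple[float, float]:
    res_fishing = np.abs(cf.full.x - cf.alpha_min_fixed.x)[mask]
    res_env = np.abs(cf.full.x - cf.k_max_fixed.x)[mask]
    if strategy == "default":
        return float(res_fishing.mean()), float(res_env.mean())
    if strategy == "literal":
        # alternative reading: roles of the two curves swapped
        return float(res_env.mean()), float(res_fishing.mean())
    raise ValueError(f"unknown attribution strategy {strategy!r}")


def influence_index(cf: CounterfactualSet, period=None,
                    strategy: str = "default") -> AttributionResult:
    """Fishing-influence index epsilon over a period, with jackknife range.

    gamma is the mean absolute departure of the full reconstruction from the
    minimal-fishing counterfactual (what fishing cost the stock); delta the
    mean absolute departure from the best-environment counterfactual (what
    the environment cost). epsilon = 100 gamma / (gamma + delta); epsilon
    above 50 means fishing dominated. ``strategy='literal'`` computes the
    swapped reading.
    """
    years = cf.years
    if period is None:
        period = (int(years[0]), int(years[-1]))
    mask = _period_mask(years, period)
    gamma, delta = _gamma_delta(cf, mask, strategy)
    if gamma + delta == 0:
        eps = np.nan
    else:
        eps = 100.0 * gamma / (gamma + delta)
    jk_mean, jk_min, jk_max = jackknife_epsilon(cf, period, strategy=strategy) \
        if mask.sum() >= 3 else (eps, eps, eps)
    return AttributionResult(period=tuple(period), gamma=gamma, delta=delta,
                             epsilon=eps, jackknife_mean=jk_mean,
                             jackknife_min=jk_min, jackknife_max=jk_max)


def jackknife_epsilon(cf: CounterfactualSet, period,
                      strategy: str = "default") -> tuple[float, float, float]:
    """Leave-one-year-out resampling of epsilon: (mean, min, max)."""
    years = cf.years
    mask = _period_mask(years, period)
    idx = np.flatnonzero(mask)
    if len(idx) < 3:
        raise ValueError("jackknife needs a period of at least 3 years")
    eps_vals = []
    for leave in idx:
        sub = mask.copy()
        sub[leave] = False
        gamma, delta = _gamma_delta(cf, sub, strategy)
        if gamma + delta == 0:
            continue
        eps_vals.append(100.0 * gamma / (gamma + delta))
    if not eps_vals:
        return (np.nan,) * 3
    eps_vals = np.asarray(eps_vals)
    return float(eps_vals.mean()), float(eps_vals.min()), float(eps_vals.max())


def identify_periods(series_matrix, k_groups: int = 7,
                     years=None) -> list[tuple[int, int]]:
    """Segment years into contiguous regimes by average-linkage clustering.

    Each column of ``series_matrix`` (years x variables) is min-max
    standardised to [0, 1]; years are clustered on Euclidean distance with
    average linkage, the tree is cut at ``k_groups``, and labels are split
    into contiguous periods wherever the label changes from one year to the
    next (so the number of periods can exceed ``k_groups``).
    """
    m = np.asarray(series_matrix, dtype=float)
    if m.ndim == 1:
        m = m[:, None]
    n = m.shape[0]
    if k_groups < 1 or k_groups > n:
        raise ValueError("k_groups must be between 1 and the number of years")
    if years is None:
        years = np.arange(n)
    years = np.asarray(years, dtype=int)
    std = np.column_stack([minmax_standardise(m[:, j]) for j in range(m.shape[1])])
    if k_groups == 1:
        labels = np.ones(n, dtype=int)
    elif k_groups == n:
        labels = np.arange(1, n + 1)
    else:
        z = linkage(pdist(std, metric="euclidean"), method="average")
        labels = fcluster(z, t=k_groups, criterion="maxclust")
    periods = []
    start = 0
    for i in range(1, n):
        if labels[i] != labels[i - 1]:
            periods.append((int(years[start]), int(years[i - 1])))
            start = i
    periods.append((int(years[start]), int(years[-1])))
    return periods
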