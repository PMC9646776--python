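# fishclim

Separating the influence of fishing from climate-induced environmental
change (CIEC) on an exploited fish stock.

Fisheries debates often stall on a dichotomy — did the stock decline because
of fishing or because the environment turned against it? `fishclim`
implements a coupled model that makes the question quantitative. It is aimed
at fisheries and climate-change ecologists working with standard gridded
environmental products (SST, chlorophyll-a, bathymetry) and stock-assessment
time series (SSB, fishing effort), with North Sea Atlantic cod as the
reference parameterisation.

## The model

**Carrying capacity from the environmental niche.** The maximum standardised
spawning stock biomass an environment can support (mdSSB, written *K*,
0–1) is the product of three habitat-suitability responses evaluated per
grid cell and day:

- thermal: an asymmetric Gaussian `U1(y) = c·exp(−(y−y_opt)²/(2t²))` with
  spread `t1 = 5.7 °C` below the optimum `y_opt = 5.4 °C` and `t2 = 4 °C`
  above it;
- bathymetric: a trapezoid over depth with breakpoints
  `θ = (0, 10⁻⁴, 200, 600) m`;
- trophic: a 0/1 indicator marking days inside a run of ≥ 15 consecutive
  days with chlorophyll-a ≥ 0.05 mg m⁻³.

Daily `K = U1·U2·U3` is averaged over March–October to an annual grid, and
over a bounding box (default North Sea, 51–62°N, 3°W–9.5°E) to a regional
series `K_t`.

**Harvested logistic dynamics.** The standardised stock `X_t` (dSSB, 0–1)
evolves as

```
X_{t+1} = X_t + r·X_t·(1 − X_t/K_t) − α_t·X_t
```

with growth rate `r` (0.5 by default) and fishing intensity `α_t` (fraction
of dSSB removed per year). A stock reaching `X = 0.1` in projections is
treated as extirpated (absorbing); collapse is `X ≤ 0.1·K`.

**Inference and attribution.** Inverting the map gives the fishing intensity
implied by observed biomass, `α_t = 1 + r(1 − X_t/K_t) − X_{t+1}/X_t`; an
assessment SSB series (log₁₀) is brought onto the model scale by the affine
map that maximises the correlation of implied α with independent fishing
effort, under the constraint `0 < X_t < min(K_t)`. Counterfactual
reconstructions with fishing or environment frozen at their observed
extremes yield the fishing-influence index `ε = 100·γ/(γ+δ)` with a
leave-one-year-out jackknife, per regime period cut from an average-linkage
clustering of the years.

Also included: a dynamic MSY harvest rule (`α_MSY = r(1 − X_MSY/K)`, with
`X_MSY = K/2` giving `α = r/2`), extirpation-year and pooled-catch
projection maps, a sensitivity surface of equilibrium dSSB over (α, K),
moratorium recovery times, and an autocorrelation-corrected (effective
degrees of freedom) correlation test.

## Worked example

How long does a collapsed stock (dSSB 0.1) need to rebuild to 0.4 under a
fishing moratorium?

```
$ fishclim recovery --k 1.0 --r 0.5
5.1
$ fishclim recovery --k 0.401 --r 0.5
12.9
$ fishclim recovery --k 0.4 --r 0.5
inf
```

At a healthy carrying capacity (`K = 1`) the rebuild takes 5.1 years; with
the environment degraded to just above the target (`K = 0.401`) it takes
12.9 years; at `K ≤ 0.4` the target is unreachable — recovery time diverges
as the environment approaches the rebuild target.

The full synthetic-data pipeline (environment → carrying capacity → stock →
α estimation → attribution → projections) runs end to end:

```python
from fishclim import io

summary = io.run_analysis(io.RunConfig(seed=1, out_dir="demo_out",
                                       projection_years=40,
                                       fixture=dict(n_lat=6, n_lon=6,
                                                    n_years=30)))
print(summary["standardisation"])
# {'scale': 0.24923786651001653, 'offset': 0.02030281891566002,
#  'objective': 0.9999998231927956}
```

The generator hides a known truth behind the published-style series (scale
0.25, offset 0.02); the standardisation search recovers it with an
α-vs-effort correlation of 0.99999+. `demo_out/` then contains the annual
`K` grid (NetCDF), the regional series, estimated α, the per-period
attribution table and scenario maps, plus `summary.json` with a
configuration hash for provenance.

## Command-line interface

`fishclim` subcommands: `niche-map`, `niche-series`, `simulate`, `recovery`,
`estimate-alpha`, `reconstruct`, `attribute`, `project`, `sensitivity`,
`fixtures`, `run`. See `fishclim <cmd> --help`.

See `docs/methods.md` for the modelling assumptions, parameter meanings,
numerical conventions and known limitations.
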