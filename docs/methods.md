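# Methods

## Model overview

`fishclim` couples two components. An environmental niche model converts
gridded sea-surface temperature, daily chlorophyll-a and bathymetry into a
carrying-capacity surface: the maximum standardised spawning stock biomass
(mdSSB, `K`, dimensionless on 0–1) a cell can support in the absence of
fishing. A harvested logistic map then drives the standardised stock `X`
(dSSB) through `K_t` and the fishing intensity `α_t`:

    X_{t+1} = X_t + r X_t (1 − X_t/K_t) − α_t X_t

The growth term absorbs natural mortality implicitly (no explicit M); there
is no age/size structure, no migration, and no process noise — the map is
deterministic, and all environmental influence flows through `K_t`. `X` is
not capped at `K`: after an adverse environmental shift the stock can sit
transiently above the new carrying capacity and the growth term then pulls
it down.

## Niche component

The three suitabilities are multiplied (`K = U1·U2·U3`), so any single
unsuitable dimension forces `K = 0` — the multiplicative nil rule, preferred
over an additive combination precisely because one hostile variable should
suffice to exclude the species.

- Thermal `U1`: asymmetric Gaussian, optimum `y_opt = 5.4 °C`, standard
  deviations `t1 = 5.7 °C` (cold side) and `t2 = 4 °C` (warm side), maximum
  `c = 1`. The narrower warm side encodes the sharper decline of cod
  habitat under warming.
- Bathymetric `U2`: trapezoid with breakpoints `θ1..θ4 = 0, 10⁻⁴, 200,
  600 m` (depth positive down). The near-zero `θ2` makes the ascending ramp
  effectively a step at the coastline; land (negative depth) falls in the
  `z ≤ θ1` branch and scores 0. Zero-width ramps are treated as steps.
- Trophic `U3`: a day scores 1 iff it belongs to a run of at least
  `window_days = 15` consecutive days with chlorophyll ≥ `chl_min =
  0.05 mg m⁻³`. Run *membership* (rather than a window ending on the day)
  is the adopted convention; the comparison is inclusive (≥), since at
  exact equality measurement precision dominates any modelling argument.
  Both choices are isolated in `trophic_suitability` so a variant can be
  swapped in.

Monthly SST is broadcast uniformly over the days of its month by default
(`sst_interp="hold"`); linear interpolation in time is available. Annual
`K` is the mean of daily `K` over March–October, the productive season;
regional series are unweighted means over cells whose centres fall inside a
closed bounding box (default North Sea, 51–62°N, 3°W–9.5°E). Missing inputs
propagate to missing `K` (never silently to 0), so data gaps are not
confounded with unsuitable habitat.

## Dynamics conventions

- `r` is constant in space and time, default 0.5, restricted to (0, 1] so
  the unfished map is monotone (no overshoot of `K`).
- Negative intermediate `X` is clamped to 0.
- Extirpation: in projections, the first year `X ≤ 0.1` zeroes the stock
  permanently (absorbing). The rule is off for historical reconstruction,
  where low observed biomass must not be forced to zero. Note that when the
  fished equilibrium `K(1 − α/r)` equals the threshold exactly, the decline
  is geometric and the threshold is an asymptote — extirpation in finite
  time requires the equilibrium strictly below it.
- Collapse is `X ≤ 0.1·K` (10% of unfished biomass), the common assessment
  convention.
- `K = 0` cells: the growth term takes its limit value 0; removal still
  applies.

**Recovery time.** The moratorium experiment iterates the unfished map from
the post-collapse state `X0 = 0.1` until `X` first reaches the rebuild
target 0.4, interpolates the crossing linearly within the final step, and
adds one counted starting year; results are reported to 0.1 year. This
convention reproduces the six reference values (3.9/5.1/8.6 years at
`K = 1` and 8.0/12.9/27.2 years at `K = 0.401` for `r` = 0.75/0.5/0.25) and
was verified against an independent plain-loop iteration before being
frozen. Recovery is impossible when `K ≤` target (the function returns
infinity); times diverge as `K` approaches the target from above.

## Inference and attribution

`estimate_alpha` is the exact algebraic inverse of the forward step; on any
trajectory without clamping events it recovers the generating α to
floating-point accuracy (≤ 1e−12), which the test suite asserts over random
draws.

**Standardisation.** An assessment SSB series (decimal log) enters the
model through an affine map `x = s·log₁₀(SSB) + o`. Feasible maps keep
every `x_t` strictly inside `(0, min_t K_t)`; among them the grid search
(200 × 200 in scale × offset, refined once around the optimum) maximises
the Pearson correlation between the implied α and the independent effort
series, breaking ties toward mid-range placement. Infeasibility (constant
series, or `min K ≤ 0`) raises an explicit error.

**Counterfactuals.** Five trajectories share `x0` (the first observed
dSSB), `r` and years: the fully forced reconstruction, fishing frozen at
its observed minimum and maximum, and `K` frozen at its observed minimum
and maximum (extirpation rule off). The per-year influence series are
`full − mean(K-frozen runs)` (fishing side) and `full − mean(α-frozen
runs)` (environment side); by construction the fishing side vanishes
identically when `K` is constant and the environment side when α is
constant.

**Fishing-influence index.** Over a period, `γ` is the mean absolute
departure of the full run from the minimal-fishing counterfactual (what
fishing cost the stock) and `δ` the mean absolute departure from the
best-environment counterfactual (what the environment cost);
`ε = 100·γ/(γ+δ)`. This mapping makes low fishing plus a degraded
environment yield `ε < 50` and heavy fishing in a near-best environment
yield `ε > 50`, the directionality all period-wise interpretations rely
on. The component-to-curve mapping was genuinely open; the swapped reading
is available via `strategy="literal"`. Aggregation by mean absolute
residual is a design choice (a scalar per period was needed); `ε` is
invariant to common rescaling of `γ` and `δ`. The jackknife recomputes `ε`
leaving each year of the period out once and reports mean/min/max
(periods must span ≥ 3 years).

**Periods.** Years are clustered on the Euclidean distances between
year-profiles of (reconstructed dSSB, fishing influence, environmental
influence), each min-max standardised to [0, 1] so the three series weigh
equally; average linkage (UPGMA), tree cut at `k_groups` (default 7), and
cluster labels split into contiguous periods at every label change — so
the number of reported periods can exceed the cut level.

## Scenario projections

Per grid cell, the annual `K` series drives a projection with the
extirpation rule on. Policies: constant intensity (default 0.04), constant
standardised catch (default 0.03), and dynamic MSY
(`α_MSY,t = r(1 − X_MSY,t/K_t)`, `X_MSY = K/2` ⇒ `α = r/2`). The initial
2020 state is not observable; the default initialises each cell at
equilibrium under the first year's `K` and the policy (alternatives: `K/2`,
`K`, or a number). Catch is booked on pre-step biomass (`α_t·x_t`, or the
fixed catch), zero after extirpation; pooled catch is its sum over the
horizon.

Because the map is monotone in α, a lighter constant intensity always keeps
the stock pointwise higher than the heavier MSY rate (`r/2 = 0.25` vs
0.04), so MSY never delays extirpation relative to light constant fishing —
what it buys is yield (MSY out-harvests the light policy severalfold).
Scenario comparisons should therefore be read as persistence-vs-yield
trade-offs, not dominance.

Comparisons reduce two maps to a cellwise difference (years of extirpation)
or percentage reduction `100(a−b)/a` (pooled catch), a histogram, and the
median over bounding-box cells. Cells that never extirpate on one side are
excluded from year medians by default (censoring); imputing `horizon + 1`
is available. Multi-member climate ensembles are averaged into one `K`
series before projection; member-wise projection remains possible by
calling the projection per member.

## Sensitivity surface

Equilibrium dSSB `X(α, K) = max(0, K(1 − α/r))` is evaluated on regular
grids α ∈ [0, 0.5], K ∈ [0, 1], step θ = 0.001 (a transient-horizon
alternative exists behind a switch; equilibrium was chosen for
determinism). Central differences along each axis give
`ζ = |∂X/∂α| (= K/r)` and `η = |∂X/∂K| (= 1 − α/r)` on the unfloored
sheet; because the surface is piecewise linear the differences are exact
there to rounding. At the kink `α = r`, where the floor engages, nodes
whose stencil straddles the kink use the one-sided difference on their own
side, avoiding a spurious spike. The joint index is the elementwise sum
`I = ζ + η`, min-max standardised to `I*` ∈ [0, 1]; boundary nodes (no
central stencil) are NaN and excluded from the standardisation.

## Statistics

- Corrected correlation: Pyper–Peterman effective degrees of freedom,
  `1/N* = 1/N + (2/N) Σ ρxx(j)ρyy(j)`, plain sample autocorrelations, lags
  1..⌊N/5⌋, sum truncated at the first negative cross-product (so the
  correction never inflates the sample size); two-sided t test with
  `N* − 2` (possibly fractional) df; the corrected p is floored at the
  uncorrected p. On AR(1) pairs with coefficient 0.8 and n = 60 the
  corrected test holds its nominal 5% level (empirically ~6% over 2000
  replicates) where the naive test rejects > 30%.
- Moving average: "first order" = centred 3-point window, truncated at the
  series ends.
- Standardised PCA index: columns z-scored, correlation matrix
  eigen-decomposed, PC1 scores returned with the first loading forced
  non-negative for a reproducible sign.
- UPGMA: scipy average-linkage on Euclidean distances; merge heights are
  checked non-decreasing per run.

## Synthetic data

The generator produces the study conditions every estimator is tested
under: a 20 × 20 grid at 0.25°, 60 years from 1963; SST with a poleward
gradient (0.5 °C per degree latitude), seasonal cycle (±3 °C), a linear
warming trend of 0.01 °C yr⁻¹ and small observation noise around a 7 °C
mean — near enough to the thermal optimum that habitat is good but
degrading; a spring bloom of 200 days from day 60 at 0.3 mg m⁻³ over a
0.04 background (run lengths are exact because day-of-year is indexed
within a 365-day year, Feb 29 dropped); a shelf deepening from 20 to 700 m
across the grid, spanning plateau, ramp and exclusion zone of the depth
trapezoid. The stock series starts at `x0 = 0.2` — below the minimum
regional `K`, so the generated truth satisfies the feasibility constraint
the standardisation search imposes — under a smooth rise-and-fall fishing
history (0.03–0.38), and is published as an affine-disguised log-SSB plus
an effort series equal to the true α (plus optional noise). All randomness
comes from one `numpy.random.Generator` per seed, consumed in a fixed
order, so outputs are bit-reproducible.

What the generator does not emulate: spatial heterogeneity of chlorophyll,
cloud gaps and sensor error, interannual bloom-timing variability,
regime-like jumps in the forcing, assessment-model error in SSB, or any
feedback of the stock on its environment. Passing tests therefore show the
estimators are correct under the model's own assumptions, not that the
model captures any particular real stock.

## Numerical and interface notes

- Grid files are CF-style NetCDF read/written through xarray's NETCDF3
  (scipy) backend; dims `time/latitude/longitude` (aliases lat/lon
  accepted), longitudes on 0–360 rewrapped to −180..180, SST in kelvin
  auto-converted to °C, chlorophyll in kg m⁻³ converted to mg m⁻³.
- Series and tables are plain CSV; stock tables require unique, contiguous
  years and preserve unknown columns with a warning.
- `run_analysis` writes every artefact plus a `summary.json` embedding the
  configuration and a hash of its scientific parameters (output paths
  excluded), so equal hashes imply identical summaries.
- Default problem sizes in the orchestrator and test suite (grids of 5–8
  cells a side, 20–30 years, 30–40 projection years) keep a full run in
  seconds while exercising every code path; production-scale grids only
  change array sizes, not logic.

## Known limitations

- No age/size structure, explicit natural mortality, migration, or process
  noise; `r` constant in space and time.
- The niche is fixed from literature parameters, not fitted to occurrence
  data; no regridding beyond nearest/linear interpolation.
- Attribution depends on the counterfactual envelope actually spanning the
  observed forcing range; degenerate periods (zero residuals) leave ε
  undefined and are reported as such.
- The equilibrium-based sensitivity surface ignores transient dynamics; the
  `transient` mode exists for cross-checks.
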