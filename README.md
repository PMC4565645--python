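# urbansami

Scale-adjusted metrics for urban indicators: allometric power-law fits,
residual-based city performance measures, their lagged dynamics, and
cross-indicator forecasting of the next census.

## The problem

Aggregate urban indicators — homicides, illiteracy, unemployment, income,
age- and sex-specific populations — scale with city population as power laws,

    Y_i = 10^A_i · N^β_i,

with exponents β_i that are usually not 1.  Per-capita values Y_i/N then
retain a factor N^(β_i − 1): superlinear indicators (β > 1) look worse in
large cities and sublinear ones (β < 1) look worse in small cities, purely
because of size.  The **scale-adjusted metric** removes this bias: it is the
log-residual of a city around the fitted allometry,

    D_i(t) = log10 Y_i(t) − [A_i(t) + β_i(t) · log10 N(t)],

so D > 0 flags a city above the law *for its size* and D < 0 below it.
Because both axes of the log–log scatter carry comparable error, the line is
fitted by **major-axis (orthogonal-distance) regression** — the closed-form
slope that minimizes summed squared perpendicular distances.

The package then models the residual dynamics across censuses:

* a one-lag memory model `D(t+Δt) = A + α·D(t)` (OLS), whose continuous
  limit `dD/dt = A + (α−1)D` relaxes toward the law with characteristic
  time 1/(1−α) when α < 1;
* an eight-predictor linear model
  `D_i(t+Δt) = C₀ + Σ_k C_k·D_k(t) + η_i` per indicator and census
  interval, averaged over intervals and used to forecast the next census;
* group trend summaries (cities above vs below the law at a baseline
  census, with percentile-bootstrap CIs), residual diagnostics
  (Cramér–von Mises normality, windowed SDs), and a geographic bubble map
  of predicted changes.

It is written for quantitative urban-science / public-health researchers
working with census panels (e.g. Brazilian municipal data with eight
indicators over the 1991/2000/2010 censuses), and ships a synthetic
city-system generator with exactly known ground truth so that every stage
has an end-to-end parameter-recovery test without downloading anything.

## Worked example

```python
from urbansami import (default_config, generate_panel, fit_allometry,
                       compute_sami, fit_memory, per_capita_bias)
from urbansami.allometry import fit_all_allometries
from urbansami.memory import characteristic_time

config = default_config(seed=1)              # 1605 cities, 3 censuses
panel, truth, coords = generate_panel(config)

fit = fit_allometry(panel, "homicides", 1991, seed=2)
print(f"homicides 1991: A = {fit.intercept:.2f} ({fit.se_intercept:.2f}), "
      f"beta = {fit.exponent:.2f} ({fit.se_exponent:.2f}), rho = {fit.rho:.3f}")
bias, label = per_capita_bias(fit)
print(f"per-capita bias exponent: {bias:.2f} ({label})")

fits = fit_all_allometries(panel, seed=2, n_boot=200)
table = compute_sami(panel, fits)
mem = fit_memory(table, "homicides", (1991, 2000))
print(f"memory slope alpha = {mem.slope:.2f} ({mem.se_slope:.2f}), rho = {mem.rho:.2f}")
print(f"characteristic time = {characteristic_time(mem.slope):.1f} census intervals")
```

Output:

```
homicides 1991: A = -5.48 (0.12), beta = 1.37 (0.03), rho = 0.771
per-capita bias exponent: 0.37 (superlinear)
memory slope alpha = 0.71 (0.02), rho = 0.70
characteristic time = 3.4 census intervals
```

The exponent 1.37 ± 0.03 says homicides grow ~37% faster than population,
so raw per-capita homicide rates are biased against large cities; the
memory slope α ≈ 0.71 < 1 says cities above/below the law drift back toward
it, losing a fraction 1 − α of their excess per census interval.

The full chain (fits → residuals → groups → memory → forecast → map) runs
as one command and writes every table, plot, GeoJSON map and a hashed
manifest:

```sh
urbansami report --out results_dir --seed 1          # reference synthetic scenario
urbansami report --panel my_panel.csv --coords my_coords.csv --out results_dir
```

For real data, `read_census_panel` expects a wide CSV with columns
`city_id, city_name, state, year, population` plus one column per indicator
(city ids are kept as strings, preserving leading zeros); a precomputed-metrics
spreadsheet of precomputed metrics can be loaded with `read_sami_table`
(CSV/XLSX, with a user-supplied column map).

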