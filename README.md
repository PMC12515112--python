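# cesdemog

Demographic analysis of constant-effort bird-ringing data: which matters
more for year-to-year population change in breeding songbirds — adult
survival or productivity?

## The scientific problem

Constant-effort ringing schemes operate networks of mist-netting sites
with a fixed protocol (same nets, same places, a fixed visit schedule)
so that captures are comparable across years. From the resulting
capture histories, three annual demographic quantities can be estimated
for each species within each national scheme:

* **apparent adult survival** `phi_t` between breeding seasons, from a
  Cormack–Jolly–Seber (CJS) mark–recapture model extended with a
  residency probability `tau` — newly captured adults are a mixture of
  residents and transients that are never available for recapture, and
  ignoring this biases survival low;
* **productivity** `rho_t`, the juvenile share of captures, from a
  quasi-binomial GLM on site and year;
* an **adult abundance index** `x_t` from a quasi-Poisson GLM of
  distinct adults captured per site-year.

The analysis then proceeds in three steps:

1. estimate the annual quantities above, per species and scheme, and
   apply explicit data-quality filters (recapture probability within
   [0.10, 0.90], survival SE strictly inside (0.01, 0.25), dispersion
   below 4);
2. for each population, regress the annual growth rate
   `r_t = log(x_{t+1} / x_t)` on z-scaled survival and productivity,
   weighting years by the inverse squared mean of the three standard
   errors — the two slopes measure how strongly each demographic rate
   drives population change;
3. stack the slopes from all populations (two rows per population:
   survival and productivity) and compare them with weighted linear
   mixed models (rows weighted `1/SE^2`, random intercepts for species
   and scheme, Satterthwaite degrees of freedom): overall (model A),
   along the schemes' temperature gradient (model B), and by migratory
   strategy and breeding habitat (model C).

The package implements all three steps, a seeded synthetic-data
generator with known truth for validating them, a pipeline that runs
the whole chain from one configuration, and a sensitivity sweep over
filter settings.

## Worked example

Simulate one 30-site, 12-year scheme with known truth
(`phi = 0.55`, `tau = 0.7`) and fit the transient-CJS model:

```python
from cesdemog import build_histories, fit_cjs_transient
from cesdemog.simulate import (
    SchemeConfig, SimulationConfig, SpeciesConfig, simulate_scheme,
)

config = SimulationConfig(
    schemes=[SchemeConfig("X", n_sites=30, n_years=12, p_sites=(0.3, 0.6))],
    species=[SpeciesConfig("SP", phi=0.55, tau=0.7, rho=0.55, mean_new_adults=10)],
    seed=1,
)
table, truth = simulate_scheme(config, "X")
fit = fit_cjs_transient(build_histories(table, "SP", "X"), n_starts=3, seed=1)
print(f"tau = {fit.tau_hat:.3f} +- {fit.tau_se:.3f}")
print(f"phi (first interval) = {fit.phi_hat[0]:.3f} +- {fit.phi_se[0]:.3f}")
```

Output:

```
tau = 0.735 +- 0.038
phi (first interval) = 0.585 +- 0.060
```

Both estimates cover the truth. The full chain — selection, survival,
indices, growth regression, meta-models — runs from one configuration:

```python
from cesdemog import PipelineConfig, run_pipeline

results = run_pipeline(PipelineConfig(simulation=config, seed=1))
```

or from the command line with a YAML configuration:

```bash
cesdemog run --config config.yaml --out output/
cesdemog sweep --config config.yaml --out sweep.csv
```

The scripts in `examples/` walk through each stage with printed,
interpreted output; `examples/06_full_pipeline.py` produces, on a
two-scheme, three-species simulation:

```
stage counts:
  input: {'records': 15445}
  selection: {'records_in': 15445, 'records_retained': 15445, 'exclusions': 0, 'populations': 6}
  step1: {'populations_attempted': 6, 'survival_fits': 6, 'index_series': 6}
  step2: {'populations_with_coefficients': 6}
  step3: {'coefficient_rows': 12, 'models_fitted': ['A', 'B', 'C']}
model A: measure effect +0.0193 +- 0.0377 (p = 0.623)
```

With only six populations the measure effect is (correctly) not
significant; `examples/05_meta_models.py` shows the same model on a
240-row coefficient table recovering a simulated survival effect of
+0.019 with p = 0.004.

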