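"""Run the full three-step pipeline from one configuration.

Simulates a two-scheme, three-species dataset, runs selection, the
transient-CJS survival model, the index GLMs, the per-population growth
regressions and the three meta-models, writes all outputs to
``pipeline_output/``, and reruns a sensitivity sweep over the
survival-SE filter bound.
"""

from cesdemog import PipelineConfig, run_pipeline, sensitivity_sweep
from cesdemog.simulate import SchemeConfig, SimulationConfig, SpeciesConfig

simulation = SimulationConfig(
    schemes=[
        SchemeConfig("FIN", n_sites=10, n_years=9, mean_temp_c=8.0),
        SchemeConfig("ESP", n_sites=10, n_years=9, mean_temp_c=16.0),
    ],
    species=[
        SpeciesConfig("ACR", phi=0.55, tau=0.7, rho=0.55, mean_new_adults=9,
                      migration="long-distance", habitat="reed"),
        SpeciesConfig("PAR", phi=0.50, tau=0.8, rho=0.60, mean_new_adults=9,
                      migration="short/resident", habitat="forest"),
        SpeciesConfig("SYL", phi=0.52, tau=0.75, rho=0.50, mean_new_adults=9,
                      migration="long-distance", habitat="forest"),
    ],
    seed=11,
)

config = PipelineConfig(simulation=simulation, seed=11, out_dir="pipeline_output")
results = run_pipeline(config)

print("stage counts:")
for stage, counts in results.report.stages.items():
    print(f"  {stage}: {counts}")

for model, fit in results.meta_fits.items():
    effect = fit["measure[survival]"]
    print(f"model {model}: measure effect {effect['estimate']:+.4f} "
          f"+- {effect['se']:.4f} (p = {effect['p']:.3f})")

print("\nsensitivity sweep over the survival-SE upper bound:")
sweep = sensitivity_sweep(
    config, {f"se<{u}": {"survival_se_upper": u} for u in (0.20, 0.25, 0.30)}
)
effect_rows = sweep[sweep["parameter"] == "measure[survival]"]
print(effect_rows.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print("interpretation: the measure effect should keep its sign as the "
      "filter bound varies; outputs are in pipeline_output/.")
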