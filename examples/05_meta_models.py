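"""Step 3: weighted mixed-model comparison of survival vs productivity.

Simulates a stacked coefficient table (two rows per scheme-species
population) with a known positive survival effect, then fits the three
weighted LMMs:

* model A — which measure matters more overall,
* model B — does the answer change along the temperature gradient,
* model C — does it differ by migratory strategy or habitat.
"""

import numpy as np

from cesdemog import fit_weighted_lmm, temperature_gradient_prediction
from cesdemog.simulate import CoefficientTruth, simulate_coefficient_table

truth = CoefficientTruth(
    intercept=0.061, survival_effect=0.019, temp_interaction=0.002
)
table = simulate_coefficient_table(truth, n_species=20, n_schemes=6, seed=2)
print(f"{len(table)} coefficient rows "
      f"({table['species'].nunique()} species x {table['scheme'].nunique()} schemes x 2 measures)")

for model in ("A", "B", "C"):
    fit = fit_weighted_lmm(table, model=model)
    effect = fit["measure[survival]"]
    print(f"\nmodel {model}: measure effect {effect['estimate']:+.4f} "
          f"+- {effect['se']:.4f}, df = {effect['df']:.1f}, p = {effect['p']:.4f}")
    print(f"  variance components: "
          + ", ".join(f"{k} = {v:.2e}" for k, v in fit.varcomps.items()))

fit_b = fit_weighted_lmm(table, model="B")
grid = np.linspace(*fit_b.temp_range, 3)
pred = temperature_gradient_prediction(fit_b, grid)
print("\nmodel B predictions along the temperature gradient:")
print(pred.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print("interpretation: the survival-productivity gap widens with "
      "temperature when the interaction term is positive.")
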