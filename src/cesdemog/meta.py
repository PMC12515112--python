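"""Step 3: weighted mixed-model comparison of demographic measures.

The per-population survival and productivity coefficients from step 2
are stacked into one long table (two rows per population) and analyzed
with three weighted Gaussian LMMs, each weighting rows by the inverse
squared standard error of the coefficient:

* **Model A** — coefficient ~ measure, random intercepts for species
  and scheme. The measure effect (survival vs. the productivity
  reference) tests which demographic measure matters more for annual
  population change.
* **Model B** — coefficient ~ measure * mean breeding-season
  temperature, random intercept for species only (temperature is
  already scheme-specific).
* **Model C** — coefficient ~ measure * migratory strategy +
  measure * breeding habitat, random intercepts for species and scheme.

Reference levels: productivity (measure), long-distance (migration),
forest (habitat).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from cesdemog.errors import DataError
from cesdemog.growth import GrowthCoefficients
from cesdemog.lmm import WeightedLMMResult, fit_weighted_lmm_core

logger = logging.getLogger(__name__)

MEASURE_REF = "productivity"
MIGRATION_REF = "long-distance"
HABITAT_REF = "forest"

META_COLUMNS = [
    "scheme",
    "species",
    "measure",
    "coefficient",
    "se",
    "mean_temp_c",
    "migration",
    "habitat",
]


def stack_coefficients(
    growth: list[GrowthCoefficients] | pd.DataFrame,
    traits: pd.DataFrame,
    temperatures: pd.DataFrame,
) -> pd.DataFrame:
    """Assemble the long-format meta-analysis table.

    ``traits`` must have columns (species, migration, habitat) and
    ``temperatures`` (scheme, mean_temp_c). Populations dropped in
    step 2 simply contribute no rows; no imputation is done.
    """
    if isinstance(growth, pd.DataFrame):
        long = growth.copy()
    else:
        rows: list[dict] = []
        for g in growth:
            rows.extend(g.to_rows())
        long = pd.DataFrame(rows)
    if len(long) == 0:
        raise DataError("no step-2 coefficients to stack")
    trait_map = traits.set_index("species")
    missing = sorted(set(long["species"]) - set(trait_map.index))
    if missing:
        raise KeyError(f"species missing from trait table: {missing}")
    temp_map = temperatures.set_index("scheme")["mean_temp_c"]
    missing_t = sorted(set(long["scheme"]) - set(temp_map.index))
    if missing_t:
        raise KeyError(f"schemes missing from temperature table: {missing_t}")
    long = long.copy()
    long["migration"] = long["species"].map(trait_map["migration"]).astype(str)
    long["habitat"] = long["species"].map(trait_map["habitat"]).astype(str)
    long["mean_temp_c"] = long["scheme"].map(temp_map).astype(float)
    bad_se = long["se"] <= 0
    if bad_se.any():
        raise DataError(f"{int(bad_se.sum())} coefficient rows have non-positive SE")
    return long[META_COLUMNS].reset_index(drop=True)


def _fixed_design(table: pd.DataFrame, model: str) -> tuple[np.ndarray, list[str]]:
    is_surv = (table["measure"] == "survival").to_numpy(dtype=float)
    cols = [np.ones(len(table))]
    names = ["(Intercept)"]
    cols.append(is_surv)
    names.append("measure[survival]")
    if model == "B":
        temp = table["mean_temp_c"].to_numpy(dtype=float)
        cols.append(temp)
        names.append("mean_temp")
        cols.append(is_surv * temp)
        names.append("measure[survival]:mean_temp")
    elif model == "C":
        is_short = (table["migration"] != MIGRATION_REF).to_numpy(dtype=float)
        is_reed = (table["habitat"] != HABITAT_REF).to_numpy(dtype=float)
        cols.extend([is_short, is_reed, is_surv * is_short, is_surv * is_reed])
        names.extend(
            [
                "migration[short/resident]",
                "habitat[reed]",
                "measure[survival]:migration[short/resident]",
                "measure[survival]:habitat[reed]",
            ]
        )
    elif model != "A":
        raise ValueError(f"unknown model {model!r}; expected 'A', 'B' or 'C'")
    return np.column_stack(cols), names


@dataclass
class MetaFit:
    """Fitted weighted LMM for one of the three meta-models."""

    model: str
    result: WeightedLMMResult
    n: int
    temp_range: tuple[float, float] | None = None

    @property
    def params(self) -> pd.DataFrame:
        r = self.result
        return pd.DataFrame(
            {
                "model": self.model,
                "parameter": r.fixed_names,
                "estimate": r.beta,
                "se": r.se,
                "df": r.df,
                "t": r.tvalues,
                "p": r.pvalues,
            }
        )

    @property
    def varcomps(self) -> dict[str, float]:
        out = dict(self.result.varcomps)
        out["residual"] = self.result.sigma2
        return out

    def __getitem__(self, term: str) -> dict[str, float]:
        i = self.result.fixed_names.index(term)
        r = self.result
        return {
            "estimate": float(r.beta[i]),
            "se": float(r.se[i]),
            "df": float(r.df[i]),
            "t": float(r.tvalues[i]),
            "p": float(r.pvalues[i]),
        }


_RANDOM_FACTORS = {"A": ("species", "scheme"), "B": ("species",), "C": ("species", "scheme")}


def fit_weighted_lmm(
    table: pd.DataFrame,
    model: str = "A",
    reml: bool = True,
    force_zero_random_effects: bool = False,
) -> MetaFit:
    """Fit meta-model A, B or C on a stacked coefficient table.

    Rows are weighted by ``1 / se**2``. Random intercepts follow the
    model definition (species and scheme for A and C, species only for
    B). Pairwise Pearson correlations between the fixed predictors are
    logged as a collinearity screen but nothing is dropped.
    """
    if not reml:
        raise NotImplementedError("only REML estimation is provided")
    needed = {"measure", "coefficient", "se"}
    if not needed.issubset(table.columns):
        raise DataError(f"meta table needs columns {sorted(needed)}")
    X, names = _fixed_design(table, model)
    y = table["coefficient"].to_numpy(dtype=float)
    w = 1.0 / table["se"].to_numpy(dtype=float) ** 2

    if X.shape[1] > 2:
        corr = np.corrcoef(X[:, 1:], rowvar=False)
        hi = np.abs(corr[np.triu_indices_from(corr, k=1)])
        if np.any(hi > 0.7):
            logger.warning(
                "model %s: strong pairwise predictor correlation (max |r| = %.2f)",
                model,
                float(hi.max()),
            )

    factors = {}
    for name in _RANDOM_FACTORS[model]:
        codes, _levels = pd.factorize(table[name], sort=True)
        factors[name] = codes
    result = fit_weighted_lmm_core(
        y,
        X,
        w,
        factors,
        fixed_names=names,
        force_zero_random_effects=force_zero_random_effects,
    )
    temp_range = None
    if model == "B":
        temps = table["mean_temp_c"].to_numpy(dtype=float)
        temp_range = (float(temps.min()), float(temps.max()))
    return MetaFit(model=model, result=result, n=len(table), temp_range=temp_range)


def temperature_gradient_prediction(
    fit: MetaFit, temp_grid
) -> pd.DataFrame:
    """Predicted coefficient of each demographic measure over temperature.

    Model B fixed-effect predictions with pointwise SEs; rows outside
    the fitted temperature range trigger an extrapolation warning.
    """
    if fit.model != "B":
        raise ValueError("temperature predictions require a model-B fit")
    grid = np.asarray(temp_grid, dtype=float)
    lo, hi = fit.temp_range
    if np.any((grid < lo) | (grid > hi)):
        warnings.warn(
            f"temperature grid extends beyond the observed range ({lo:.1f}, {hi:.1f})",
            stacklevel=2,
        )
    r = fit.result
    rows = []
    for measure, is_surv in (("productivity", 0.0), ("survival", 1.0)):
        L = np.column_stack(
            [np.ones_like(grid), np.full_like(grid, is_surv), grid, is_surv * grid]
        )
        pred = L @ r.beta
        se = np.sqrt(np.einsum("ij,jk,ik->i", L, r.cov_beta, L))
        for g, mu, s in zip(grid, pred, se):
            rows.append(
                {"measure": measure, "mean_temp_c": float(g), "predicted": float(mu), "se": float(s)}
            )
    return pd.DataFrame(rows)


def metafits_to_frame(fits: list[MetaFit]) -> pd.DataFrame:
    """Concatenate fitted meta-models into one results table."""
    return pd.concat([f.params for f in fits], ignore_index=True)
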