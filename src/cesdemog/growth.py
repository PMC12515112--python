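"""Step 2: weighted regression of annual population growth on demography.

For each species-scheme population, the annual growth rate

    r_t = log(1 + (x_{t+1} - x_t) / x_t) = log(x_{t+1} / x_t)

is regressed on the z-scaled annual adult survival (interval
``t -> t + 1``) and z-scaled productivity (year ``t``), with weights
``1 / mean(SE_phi, SE_rho, SE_x)**2`` per year so that better-estimated
years carry more influence. The two slopes — one per demographic
measure — are the population-level coefficients carried to step 3.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from cesdemog.errors import DataError

logger = logging.getLogger(__name__)


def growth_rate(x_t: float, x_next: float) -> float:
    """Annual population growth rate ``log(1 + (x_next - x_t) / x_t)``.

    Algebraically identical to ``log(x_next / x_t)``; antisymmetric in
    its arguments.
    """
    if x_t <= 0 or x_next <= 0:
        raise ValueError(f"abundances must be positive, got ({x_t}, {x_next})")
    return math.log1p((x_next - x_t) / x_t)


def zscale(values) -> np.ndarray:
    """Center to mean 0 and scale to sample SD 1 (n - 1 denominator)."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("zscale needs a 1-d vector of length >= 2")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot z-scale a constant series (zero variance)")
    return (v - v.mean()) / sd


def combine_step2_weights(se_phi: float, se_rho: float, se_x: float) -> float:
    """Inverse squared mean of the three standard errors.

    ``w = 1 / ((se_phi + se_rho + se_x) / 3)**2``. Individual SEs may
    be 0 (the abundance reference year has SE 0 by construction) but
    their mean must be positive.
    """
    ses = (se_phi, se_rho, se_x)
    if any(s < 0 or not math.isfinite(s) for s in ses):
        raise ValueError(f"standard errors must be finite and non-negative, got {ses}")
    mean_se = sum(ses) / 3.0
    if mean_se <= 0:
        raise ValueError("mean standard error must be positive")
    return 1.0 / mean_se**2


@dataclass
class DemographicSeries:
    """Aligned annual demography for one population.

    Each entry covers one growth interval ``years[i] -> years[i] + 1``:
    survival over that interval, productivity of the starting year,
    and the abundance index at both endpoints. Only years surviving
    every upstream filter (with both interval endpoints retained)
    should be present.
    """

    scheme: str
    species: str
    years: np.ndarray  # start year of each interval
    phi: np.ndarray
    phi_se: np.ndarray
    rho: np.ndarray
    rho_se: np.ndarray
    x_start: np.ndarray
    x_start_se: np.ndarray
    x_end: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.years)
        for name in ("phi", "phi_se", "rho", "rho_se", "x_start", "x_start_se", "x_end"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have length {n}")
            setattr(self, name, arr)

    def __len__(self) -> int:
        return len(self.years)


@dataclass
class GrowthCoefficients:
    """Per-population regression output of step 2."""

    scheme: str
    species: str
    beta_survival: float
    beta_survival_se: float
    beta_productivity: float
    beta_productivity_se: float
    intercept: float
    n_years: int
    r_squared: float

    def to_rows(self) -> list[dict]:
        """Long format: one row per demographic measure."""
        return [
            {
                "scheme": self.scheme,
                "species": self.species,
                "measure": "survival",
                "coefficient": self.beta_survival,
                "se": self.beta_survival_se,
                "n_years": self.n_years,
            },
            {
                "scheme": self.scheme,
                "species": self.species,
                "measure": "productivity",
                "coefficient": self.beta_productivity,
                "se": self.beta_productivity_se,
                "n_years": self.n_years,
            },
        ]


def fit_growth_lm(series: DemographicSeries, min_pairs: int = 4) -> GrowthCoefficients:
    """Weighted least squares of growth rate on z-scaled demography.

    Requires at least ``min_pairs`` aligned year-pairs so slope SEs
    exist with at least one residual degree of freedom.
    """
    n = len(series)
    if n < min_pairs:
        raise DataError(
            f"{series.scheme}/{series.species}: {n} usable year-pairs < {min_pairs}"
        )
    r = np.array(
        [growth_rate(a, b) for a, b in zip(series.x_start, series.x_end)]
    )
    z_phi = zscale(series.phi)
    z_rho = zscale(series.rho)
    if abs(np.corrcoef(z_phi, z_rho)[0, 1]) >= 1.0 - 1e-12:
        raise DataError(
            f"{series.scheme}/{series.species}: survival and productivity are collinear"
        )
    w = np.array(
        [
            combine_step2_weights(sp, sr, sx)
            for sp, sr, sx in zip(series.phi_se, series.rho_se, series.x_start_se)
        ]
    )
    X = sm.add_constant(np.column_stack([z_phi, z_rho]))
    res = sm.WLS(r, X, weights=w).fit()
    return GrowthCoefficients(
        scheme=series.scheme,
        species=series.species,
        beta_survival=float(res.params[1]),
        beta_survival_se=float(res.bse[1]),
        beta_productivity=float(res.params[2]),
        beta_productivity_se=float(res.bse[2]),
        intercept=float(res.params[0]),
        n_years=n,
        r_squared=float(res.rsquared),
    )


def coefficients_to_frame(coefs: list[GrowthCoefficients]) -> pd.DataFrame:
    """Stack per-population coefficients into the long CSV format."""
    rows: list[dict] = []
    for c in coefs:
        rows.extend(c.to_rows())
    return pd.DataFrame(
        rows, columns=["scheme", "species", "measure", "coefficient", "se", "n_years"]
    )
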