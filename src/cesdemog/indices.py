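"""Annual productivity and adult-abundance indices via quasi-likelihood GLMs.

Productivity is the juvenile share of captures: per site-year, the
number of juvenile captures is treated as successes out of all
captures, modeled with a logit-link binomial GLM on site and year
(both categorical) and a quasi-binomial dispersion. The annual
estimate is the back-transformed year effect evaluated at the mean
site effect.

Adult abundance is modeled as a log-link Poisson GLM of the distinct
adults captured per site-year on site and year, with quasi-Poisson
dispersion. The annual index is ``exp(gamma_t)`` with the first year
as reference (``x_1 = 1``); growth rates depend only on ratios, so the
reference is immaterial for downstream use, but standard errors are
reference-dependent (SE of the first year is 0 by construction).

Species whose dispersion statistic (Pearson chi-square over residual
df) is 4 or more in either model are flagged as poorly fitted and
dropped from the scheme.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from cesdemog.data import AGE_ADULT, AGE_JUVENILE, CaptureTable
from cesdemog.errors import DataError

logger = logging.getLogger(__name__)

_SEPARATION_ETA = 15.0  # |linear predictor| beyond this means separation


@dataclass
class SiteYearCounts:
    """Distinct adults and juveniles captured per site-year."""

    species: str
    scheme: str
    df: pd.DataFrame  # columns: site, year, adults, juveniles

    @property
    def n_sites(self) -> int:
        return self.df["site"].nunique()

    @property
    def years(self) -> np.ndarray:
        return np.array(sorted(self.df["year"].unique()))


@dataclass
class IndexSeries:
    """Annual estimates of one demographic index with uncertainty."""

    kind: str  # "productivity" or "abundance"
    species: str
    scheme: str
    years: np.ndarray
    estimate: np.ndarray
    se: np.ndarray
    dispersion: float
    df_resid: int
    flags: dict[int, str] = field(default_factory=dict)
    note: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scheme": self.scheme,
                "species": self.species,
                "year": self.years,
                "kind": self.kind,
                "estimate": self.estimate,
                "se": self.se,
            }
        )


def tabulate_counts(table: CaptureTable, species: str, scheme: str) -> SiteYearCounts:
    """Count distinct individuals per site-year and age class.

    Every site-year present in the (scheme, species) slice of the table
    is retained, including those where one age class is absent.
    """
    df = table.df
    sub = df[(df["species"] == species) & (df["scheme"] == scheme)]
    counts = (
        sub.groupby(["site", "year", "age_class"])["ring_id"]
        .nunique()
        .unstack("age_class", fill_value=0)
    )
    for age in (AGE_ADULT, AGE_JUVENILE):
        if age not in counts.columns:
            counts[age] = 0
    out = counts.reset_index().rename(columns={AGE_ADULT: "adults", AGE_JUVENILE: "juveniles"})
    out = out[["site", "year", "adults", "juveniles"]].sort_values(["site", "year"])
    return SiteYearCounts(species=species, scheme=scheme, df=out.reset_index(drop=True))


def _glm_design(counts: SiteYearCounts) -> tuple[pd.DataFrame, str]:
    df = counts.df.copy()
    n_sites = df["site"].nunique()
    n_years = df["year"].nunique()
    if n_sites < 2 and n_years < 2:
        raise DataError("need at least two sites or two years to fit an index GLM")
    terms = []
    if n_sites >= 2:
        terms.append("C(site)")
    if n_years >= 2:
        terms.append("C(year)")
    return df, " + ".join(terms) if terms else "1"


def pearson_dispersion(result) -> float:
    """Pearson chi-square over residual degrees of freedom.

    The quasi-likelihood dispersion statistic; values near 1 indicate a
    well-calibrated binomial/Poisson variance, values >= 4 a poor fit.
    """
    if result.df_resid <= 0:
        raise DataError("dispersion undefined: residual degrees of freedom is 0")
    return float(result.pearson_chi2 / result.df_resid)


def _annual_linear_predictors(
    result, df: pd.DataFrame, years: np.ndarray, average_site: bool
) -> tuple[np.ndarray, np.ndarray]:
    """Linear predictor per year (optionally at the mean site effect)
    and its SE from the scaled covariance."""
    names = list(result.model.exog_names)
    beta = np.asarray(result.params)
    cov = np.asarray(result.cov_params())
    sites = sorted(df["site"].unique())
    n_sites = len(sites)
    L = np.zeros((len(years), len(names)))
    for i, name in enumerate(names):
        if name == "Intercept":
            L[:, i] = 1.0
        elif name.startswith("C(site)") and average_site:
            # each non-reference site dummy gets weight 1/S in the site average
            L[:, i] = 1.0 / n_sites
        elif name.startswith("C(year)"):
            level = name.split("[T.")[1].rstrip("]")
            for j, y in enumerate(years):
                if str(y) == level or (str(float(y)) == level):
                    L[j, i] = 1.0
    eta = L @ beta
    var = np.einsum("ij,jk,ik->i", L, cov, L)
    return eta, np.sqrt(np.maximum(var, 0.0))


def fit_productivity_glm(counts: SiteYearCounts) -> IndexSeries:
    """Quasi-binomial GLM of the juvenile share of captures.

    Each capture is a trial; a juvenile capture is a success. The
    annual productivity estimate is the inverse-logit of (intercept +
    mean site effect + year effect); its SE follows by the delta
    method with the Pearson-dispersion-scaled covariance.

    Years with complete separation (all-juvenile or all-adult captures
    across every site) are flagged and get no SE.
    """
    df, rhs = _glm_design(counts)
    df = df[(df["adults"] + df["juveniles"]) > 0]
    if len(df) == 0:
        raise DataError("no captures to model")
    years = np.array(sorted(df["year"].unique()))
    model = smf.glm(
        f"juveniles + adults ~ {rhs}", data=df, family=sm.families.Binomial()
    )
    # two-pass quasi-binomial: statsmodels' scale="X2" mis-scales the
    # covariance for two-column binomial responses (it divides the
    # Pearson statistic by proportion-scale residuals, losing the trial
    # counts), so compute the dispersion from pearson_chi2 explicitly
    # and refit with that fixed scale
    with np.errstate(all="ignore"):
        result = model.fit(scale=1.0)
    df_resid = int(result.df_resid)
    dispersion = float(result.pearson_chi2 / df_resid) if df_resid > 0 else float("nan")
    if df_resid > 0 and np.isfinite(dispersion) and dispersion > 0:
        with np.errstate(all="ignore"):
            result = model.fit(scale=dispersion)

    eta, se_eta = _annual_linear_predictors(result, df, years, average_site=True)
    est = 1.0 / (1.0 + np.exp(-eta))
    se = est * (1 - est) * se_eta
    flags: dict[int, str] = {}
    for j, y in enumerate(years):
        if abs(eta[j]) > _SEPARATION_ETA:
            flags[int(y)] = "complete separation"
            se[j] = np.nan
            logger.warning("%s/%s productivity: year %s separated", counts.scheme, counts.species, y)
    return IndexSeries(
        kind="productivity",
        species=counts.species,
        scheme=counts.scheme,
        years=years,
        estimate=est,
        se=se,
        dispersion=dispersion,
        df_resid=df_resid,
        flags=flags,
        note="estimate at mean site effect; quasi-binomial scale",
    )


def fit_abundance_glm(counts: SiteYearCounts) -> IndexSeries:
    """Quasi-Poisson GLM of distinct adults captured per site-year.

    The annual index is ``exp(gamma_t)`` with the first year as the
    reference (index 1, SE 0). A year with zero adults at every site
    sits on the likelihood boundary (index 0) and is flagged.
    """
    df, rhs = _glm_design(counts)
    years = np.array(sorted(df["year"].unique()))
    model = smf.glm(f"adults ~ {rhs}", data=df, family=sm.families.Poisson())
    with np.errstate(all="ignore"):
        result = model.fit(scale="X2" if len(df) > model.exog.shape[1] else 1.0)
    df_resid = int(result.df_resid)
    dispersion = float(result.pearson_chi2 / df_resid) if df_resid > 0 else float("nan")

    # gamma_1 = 0 by treatment coding; gamma_t and its SE come straight
    # from the year-dummy coefficient and its covariance
    names = list(result.model.exog_names)
    cov = np.asarray(result.cov_params())
    beta = np.asarray(result.params)
    gamma = np.zeros(len(years))
    se_gamma = np.zeros(len(years))
    for i, name in enumerate(names):
        if name.startswith("C(year)"):
            level = name.split("[T.")[1].rstrip("]")
            for j, y in enumerate(years):
                if str(y) == level or (str(float(y)) == level):
                    gamma[j] = beta[i]
                    se_gamma[j] = np.sqrt(max(cov[i, i], 0.0))
    est = np.exp(gamma)
    se = est * se_gamma
    flags: dict[int, str] = {}
    zero_years = set(
        int(y)
        for y, total in df.groupby("year")["adults"].sum().items()
        if total == 0
    )
    for j, y in enumerate(years):
        if int(y) in zero_years:
            flags[int(y)] = "zero adults across sites (boundary)"
            est[j] = 0.0
            se[j] = np.nan
            logger.warning("%s/%s abundance: year %s has zero adults", counts.scheme, counts.species, y)
    return IndexSeries(
        kind="abundance",
        species=counts.species,
        scheme=counts.scheme,
        years=years,
        estimate=est,
        se=se,
        dispersion=dispersion,
        df_resid=df_resid,
        flags=flags,
        note="index relative to first year (x_1 = 1, SE 0); quasi-Poisson scale",
    )


def filter_by_dispersion(series: IndexSeries, threshold: float = 4.0) -> bool:
    """Keep decision for one index series: True when dispersion < threshold.

    The rule is strict: a dispersion exactly at the threshold drops the
    species. An undefined dispersion (no residual df) is treated as
    passing, since the model is then saturated rather than overdispersed.
    """
    c_hat = series.dispersion
    if np.isnan(c_hat):
        return True
    keep = c_hat < threshold
    if not keep:
        logger.info(
            "%s/%s %s: dispersion %.3f >= %.1f, species dropped",
            series.scheme,
            series.species,
            series.kind,
            c_hat,
            threshold,
        )
    return keep
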