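"""Synthetic constant-effort capture data with known demographic truth.

The generator mirrors the data-generating process the survival and
index models assume: at each site and year a Poisson number of
never-before-captured adults is ringed; each of them is a *resident*
with probability ``tau`` or a transient that never reappears; residents
survive each annual interval with probability ``phi_t`` (shared across
sites within a scheme) and, while alive, are recaptured at their site
with site-specific probability ``p_s``. Juvenile captures are drawn so
that the juvenile share of captures has expectation ``rho_t``.

Alongside the capture table the generator keeps a truth record: the
parameter values actually used, plus the expected number of adult
captures per site-year (new captures + recaptures of marked
residents), which is the quantity the quasi-Poisson abundance index
estimates.

A second, direct generator (:func:`simulate_coefficient_table`)
produces stacked survival/productivity coefficient tables with known
fixed effects, random-intercept SDs and per-row standard errors, for
testing the meta-models in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from cesdemog.data import AGE_ADULT, AGE_JUVENILE, CAPTURE_COLUMNS, CaptureTable
from cesdemog.errors import ConfigError

MIGRATION_LEVELS = ("long-distance", "short/resident")
HABITAT_LEVELS = ("forest", "reed")


def _as_vector(value, length: int, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        arr = np.full(length, float(arr))
    if arr.shape != (length,):
        raise ConfigError(f"{name} must be scalar or length {length}, got shape {arr.shape}")
    return arr


def _check_prob(arr: np.ndarray, name: str, closed_top: bool = False) -> None:
    hi_ok = arr <= 1 if closed_top else arr < 1
    if not np.all((arr > 0) & hi_ok):
        raise ConfigError(f"{name} must lie in (0, 1{']' if closed_top else ')'}): got {arr}")


@dataclass
class SpeciesConfig:
    """True demographic parameters of one simulated species.

    ``phi`` (length ``T - 1``) is annual apparent survival of resident
    adults, ``tau`` the residency probability of a newly captured
    adult, ``rho`` (length ``T``) the expected juvenile share of
    captures, and ``mean_new_adults`` the expected number of
    newly captured adults per site-year before site/year effects.
    """

    code: str
    phi: float | Sequence[float] = 0.5
    tau: float = 0.7
    rho: float | Sequence[float] = 0.55
    mean_new_adults: float = 10.0
    log_site_sd: float = 0.3
    log_year_effects: float | Sequence[float] = 0.0
    migration: str = "short/resident"
    habitat: str = "forest"

    def __post_init__(self) -> None:
        if self.migration not in MIGRATION_LEVELS:
            raise ConfigError(f"migration must be one of {MIGRATION_LEVELS}")
        if self.habitat not in HABITAT_LEVELS:
            raise ConfigError(f"habitat must be one of {HABITAT_LEVELS}")
        if self.mean_new_adults <= 0:
            raise ConfigError("mean_new_adults must be positive")
        if self.log_site_sd < 0:
            raise ConfigError("log_site_sd must be non-negative")


@dataclass
class SchemeConfig:
    """One simulated ringing scheme: a set of sites run for ``n_years``."""

    code: str
    n_sites: int = 10
    n_years: int = 10
    mean_temp_c: float = 10.0
    p_sites: float | Sequence[float] | tuple[float, float] = (0.3, 0.6)
    n_visits: int = 12

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ConfigError("n_sites must be >= 1")
        if self.n_years < 5:
            raise ConfigError("n_years must be >= 5")
        if self.n_visits < 2:
            raise ConfigError("n_visits must be >= 2")

    def recapture_probs(self, rng: np.random.Generator) -> np.ndarray:
        p = np.asarray(self.p_sites, dtype=float)
        if p.ndim == 0:
            p = np.full(self.n_sites, float(p))
        elif p.shape == (2,) and self.n_sites != 2:
            p = rng.uniform(p[0], p[1], size=self.n_sites)
        if p.shape != (self.n_sites,):
            raise ConfigError(
                f"p_sites must be scalar, (lo, hi) range or length {self.n_sites}"
            )
        _check_prob(p, "p_sites")
        return p


@dataclass
class SimulationConfig:
    """Full multi-scheme, multi-species simulation design."""

    schemes: list[SchemeConfig] = field(default_factory=list)
    species: list[SpeciesConfig] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        codes = [s.code for s in self.schemes]
        if len(set(codes)) != len(codes):
            raise ConfigError(f"duplicate scheme codes in {codes}")
        sp = [s.code for s in self.species]
        if len(set(sp)) != len(sp):
            raise ConfigError(f"duplicate species codes in {sp}")


@dataclass
class TruthRecord:
    """Realized true parameters for one species-scheme series."""

    scheme: str
    species: str
    years: list[int]
    phi: list[float]
    tau: float
    rho: list[float]
    p_sites: dict[str, float]
    lam: list[list[float]]  # expected new adult captures, (site, year)
    expected_adult_captures: list[list[float]]  # new + expected recaptures
    mean_temp_c: float

    def to_dict(self) -> dict:
        return {
            "scheme": self.scheme,
            "species": self.species,
            "years": self.years,
            "phi": self.phi,
            "tau": self.tau,
            "rho": self.rho,
            "p_sites": self.p_sites,
            "lam": self.lam,
            "expected_adult_captures": self.expected_adult_captures,
            "mean_temp_c": self.mean_temp_c,
        }


def expected_adult_captures(
    lam: np.ndarray, phi: np.ndarray, tau: float, p: np.ndarray
) -> np.ndarray:
    """Expected adult captures per site-year: new birds plus recaptures.

    With ``M_{s,t}`` the expected number of marked residents alive at
    site ``s`` in year ``t`` (``M_{s,1} = 0``,
    ``M_{s,t+1} = (M_{s,t} + tau * lam_{s,t}) * phi_t``), the expected
    capture count is ``lam_{s,t} + p_s * M_{s,t}``.
    """
    S, T = lam.shape
    M = np.zeros((S, T))
    for t in range(T - 1):
        M[:, t + 1] = (M[:, t] + tau * lam[:, t]) * phi[t]
    return lam + p[:, None] * M


def _simulate_species_at_scheme(
    rng: np.random.Generator,
    scheme: SchemeConfig,
    sp: SpeciesConfig,
    years: np.ndarray,
    p: np.ndarray,
    ring_counter: list[int],
) -> tuple[list[tuple], TruthRecord]:
    T = scheme.n_years
    S = scheme.n_sites
    phi = _as_vector(sp.phi, T - 1, "phi")
    _check_prob(phi, "phi")
    rho = _as_vector(sp.rho, T, "rho")
    _check_prob(rho, "rho")
    if not 0 < sp.tau <= 1:
        raise ConfigError(f"tau must lie in (0, 1], got {sp.tau}")
    gyear = _as_vector(sp.log_year_effects, T, "log_year_effects")
    asite = rng.normal(0.0, sp.log_site_sd, size=S)
    lam = np.exp(np.log(sp.mean_new_adults) + asite[:, None] + gyear[None, :])

    site_codes = [f"{scheme.code}-S{j + 1:02d}" for j in range(S)]
    rows: list[tuple] = []

    def new_ring() -> str:
        ring_counter[0] += 1
        return f"R{ring_counter[0]:07d}"

    def capture(ring: str, site: str, year: int, age: str) -> None:
        visit = int(rng.integers(1, scheme.n_visits + 1))
        rows.append((ring, sp.code, scheme.code, site, int(year), visit, age))

    for s in range(S):
        site = site_codes[s]
        for t in range(T):
            n_new = rng.poisson(lam[s, t])
            for _ in range(n_new):
                ring = new_ring()
                capture(ring, site, years[t], AGE_ADULT)
                if rng.random() >= sp.tau:
                    continue  # transient: never seen again
                alive_at = t
                for u in range(t, T - 1):
                    if rng.random() >= phi[u]:
                        break
                    alive_at = u + 1
                    if rng.random() < p[s]:
                        capture(ring, site, years[alive_at], AGE_ADULT)
    # juveniles: independent Poisson draws with mean rho/(1-rho) times the
    # *expected* adult captures per site-year. Independence from the
    # realized adult count matters: two independent Poissons make the
    # juvenile share of the total exactly binomial given the total, so
    # the quasi-binomial productivity model sees unit dispersion.
    ec = expected_adult_captures(lam, phi, sp.tau, p)
    for s in range(S):
        site = site_codes[s]
        for t in range(T):
            mean_j = ec[s, t] * rho[t] / (1.0 - rho[t])
            n_juv = rng.poisson(mean_j) if mean_j > 0 else 0
            for _ in range(n_juv):
                capture(new_ring(), site, years[t], AGE_JUVENILE)

    truth = TruthRecord(
        scheme=scheme.code,
        species=sp.code,
        years=[int(y) for y in years],
        phi=phi.tolist(),
        tau=float(sp.tau),
        rho=rho.tolist(),
        p_sites={site_codes[s]: float(p[s]) for s in range(S)},
        lam=lam.tolist(),
        expected_adult_captures=expected_adult_captures(lam, phi, sp.tau, p).tolist(),
        mean_temp_c=scheme.mean_temp_c,
    )
    return rows, truth


def simulate_scheme(
    config: SimulationConfig, scheme_code: str
) -> tuple[CaptureTable, list[TruthRecord]]:
    """Simulate all species for one scheme.

    The RNG stream is seeded as ``config.seed + scheme index`` so a
    single scheme can be regenerated without rerunning the others.
    """
    idx = [s.code for s in config.schemes].index(scheme_code)
    scheme = config.schemes[idx]
    rng = np.random.default_rng(config.seed + idx)
    years = np.arange(2000, 2000 + scheme.n_years)
    p = scheme.recapture_probs(rng)
    ring_counter = [idx * 10_000_000]
    rows: list[tuple] = []
    truths: list[TruthRecord] = []
    for sp in config.species:
        sp_rows, truth = _simulate_species_at_scheme(rng, scheme, sp, years, p, ring_counter)
        rows.extend(sp_rows)
        truths.append(truth)
    df = pd.DataFrame(rows, columns=list(CAPTURE_COLUMNS))
    table = CaptureTable(df, provenance=f"simulate_scheme(seed={config.seed}, scheme={scheme_code})")
    return table, truths


def simulate_multischeme(
    config: SimulationConfig,
) -> tuple[CaptureTable, pd.DataFrame, pd.DataFrame, list[TruthRecord]]:
    """Simulate all schemes; returns captures, traits, temperatures, truth."""
    if len(config.schemes) < 1:
        raise ConfigError("at least one scheme required")
    parts: list[pd.DataFrame] = []
    truths: list[TruthRecord] = []
    for scheme in config.schemes:
        table, t = simulate_scheme(config, scheme.code)
        parts.append(table.df)
        truths.extend(t)
    df = pd.concat(parts, ignore_index=True)
    traits = pd.DataFrame(
        {
            "species": [s.code for s in config.species],
            "migration": [s.migration for s in config.species],
            "habitat": [s.habitat for s in config.species],
        }
    )
    temps = pd.DataFrame(
        {
            "scheme": [s.code for s in config.schemes],
            "mean_temp_c": [s.mean_temp_c for s in config.schemes],
        }
    )
    table = CaptureTable(df, provenance=f"simulate_multischeme(seed={config.seed})")
    return table, traits, temps, truths


@dataclass
class CoefficientTruth:
    """Fixed-effect truth for directly simulated coefficient tables.

    The linear predictor for a row with measure ``m`` (productivity is
    the reference level), scheme temperature ``temp`` (centered),
    migration ``mig`` and habitat ``hab`` is::

        mu = intercept
             + survival_effect * [m == survival]
             + temp_effect * temp + temp_interaction * temp * [m == survival]
             + migration_effect * [mig == short/resident]
             + habitat_effect * [hab == reed]
             + migration_interaction * [m == survival][mig == short/resident]
             + habitat_interaction * [m == survival][hab == reed]
    """

    intercept: float = 0.061
    survival_effect: float = 0.019
    temp_effect: float = 0.0
    temp_interaction: float = 0.0
    migration_effect: float = 0.0
    habitat_effect: float = 0.0
    migration_interaction: float = 0.0
    habitat_interaction: float = 0.0


def simulate_coefficient_table(
    truth: CoefficientTruth,
    n_species: int = 20,
    n_schemes: int = 6,
    species_sd: float = 0.02,
    scheme_sd: float = 0.02,
    residual_sd: float = 1.0,
    se_range: tuple[float, float] = (0.03, 0.07),
    temp_range: tuple[float, float] = (7.0, 17.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Directly simulate a stacked coefficient table with known truth.

    Each (scheme, species) pair yields two rows (productivity and
    survival). Row ``k`` gets a standard error ``SE_k`` drawn uniformly
    from ``se_range`` and a residual ``residual_sd * SE_k * N(0, 1)``,
    so that a meta-model weighting rows by ``1 / SE_k**2`` has unit
    (times ``residual_sd**2``) residual variance.
    """
    if n_species * n_schemes * 2 < 20:
        raise ConfigError("need at least 20 rows (n_species * n_schemes * 2)")
    for name, sd in (("species_sd", species_sd), ("scheme_sd", scheme_sd), ("residual_sd", residual_sd)):
        if sd < 0:
            raise ConfigError(f"{name} must be non-negative")
    rng = np.random.default_rng(seed)
    species = [f"SP{j + 1:02d}" for j in range(n_species)]
    schemes = [f"SCH{q + 1:02d}" for q in range(n_schemes)]
    migration = {
        sp: MIGRATION_LEVELS[j % 2] for j, sp in enumerate(species)
    }
    habitat = {sp: HABITAT_LEVELS[(j // 2) % 2] for j, sp in enumerate(species)}
    temps = dict(zip(schemes, np.linspace(*temp_range, n_schemes)))
    temp_center = float(np.mean(list(temps.values())))

    b_species = dict(zip(species, rng.normal(0.0, species_sd, n_species)))
    b_scheme = dict(zip(schemes, rng.normal(0.0, scheme_sd, n_schemes)))

    rows = []
    for scheme in schemes:
        for sp in species:
            for measure in ("productivity", "survival"):
                is_surv = 1.0 if measure == "survival" else 0.0
                is_short = 1.0 if migration[sp] == "short/resident" else 0.0
                is_reed = 1.0 if habitat[sp] == "reed" else 0.0
                temp_c = temps[scheme] - temp_center
                mu = (
                    truth.intercept
                    + truth.survival_effect * is_surv
                    + truth.temp_effect * temp_c
                    + truth.temp_interaction * temp_c * is_surv
                    + truth.migration_effect * is_short
                    + truth.habitat_effect * is_reed
                    + truth.migration_interaction * is_surv * is_short
                    + truth.habitat_interaction * is_surv * is_reed
                )
                se = rng.uniform(*se_range)
                y = mu + b_species[sp] + b_scheme[scheme] + residual_sd * se * rng.normal()
                rows.append(
                    {
                        "scheme": scheme,
                        "species": sp,
                        "measure": measure,
                        "coefficient": y,
                        "se": se,
                        "mean_temp_c": temps[scheme],
                        "migration": migration[sp],
                        "habitat": habitat[sp],
                    }
                )
    return pd.DataFrame(rows)
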