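"""Capture-record data model, I/O and the data-selection filters.

Constant-effort ringing data arrive as one row per capture event:
ring number, species, scheme (national ringing organization), site,
calendar year, within-season visit index and age class (adult ``A`` =
older than first calendar year, juvenile ``J`` = first calendar year).

Selection proceeds in three nested passes before any model is fitted:

* site-years must have been covered well enough (at least a fraction of
  the scheme's modal maximum visit number overall, and a smaller
  fraction in each half of the season), and sites must have at least
  five retained years;
* per species, a site-year must hold at least two adults and two
  juveniles (this filter is species-specific, so a site can contribute
  to one species but not another);
* per scheme, a species must average at least 50 distinct individuals
  captured per year across the scheme's retained site-years.

The surviving records are turned into annual capture histories of
adults for the survival analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from cesdemog.errors import DataError, SchemaError

logger = logging.getLogger(__name__)

AGE_ADULT = "A"
AGE_JUVENILE = "J"

CAPTURE_COLUMNS = ("ring_id", "species", "scheme", "site", "year", "visit", "age_class")


@dataclass
class CaptureTable:
    """A validated collection of capture events.

    Attributes
    ----------
    df
        One row per capture event with the columns in
        :data:`CAPTURE_COLUMNS`.
    provenance
        Free-form origin note (source path or simulation seed).
    """

    df: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        self.df = validate_capture_frame(self.df)

    def __len__(self) -> int:
        return len(self.df)

    def schemes(self) -> list[str]:
        return sorted(self.df["scheme"].unique())

    def species(self) -> list[str]:
        return sorted(self.df["species"].unique())


def validate_capture_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a raw capture-event frame.

    Raises
    ------
    SchemaError
        If a required column is missing.
    ValueError
        If a row violates a field invariant; the message names the
        offending row numbers.
    """
    missing = [c for c in CAPTURE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"capture table is missing columns: {missing}")
    df = df.loc[:, list(CAPTURE_COLUMNS)].copy()
    if len(df) == 0:
        logger.warning("capture table is empty")
        return df.astype({"year": "int64", "visit": "int64"})
    for col in ("ring_id", "species", "scheme", "site", "age_class"):
        df[col] = df[col].astype(str)

    bad_age = ~df["age_class"].isin([AGE_ADULT, AGE_JUVENILE])
    if bad_age.any():
        rows = df.index[bad_age].tolist()[:10]
        values = sorted(df.loc[bad_age, "age_class"].unique())
        raise ValueError(
            f"unknown age_class value(s) {values} in row(s) {rows}; "
            f"expected '{AGE_ADULT}' (adult) or '{AGE_JUVENILE}' (juvenile)"
        )
    df["year"] = pd.to_numeric(df["year"]).astype("int64")
    df["visit"] = pd.to_numeric(df["visit"]).astype("int64")
    bad_visit = df["visit"] < 1
    if bad_visit.any():
        rows = df.index[bad_visit].tolist()[:10]
        raise ValueError(f"visit index must be >= 1; bad row(s) {rows}")

    # a site belongs to exactly one scheme
    per_site = df.groupby("site")["scheme"].nunique()
    multi = per_site[per_site > 1]
    if len(multi):
        raise ValueError(
            f"site(s) {multi.index.tolist()} appear under more than one scheme"
        )
    return df


def read_capture_table(path: str | Path, format: str = "csv") -> CaptureTable:
    """Read a capture table from disk.

    Only the CSV dialect is supported: comma-separated UTF-8 with the
    header ``ring_id,species,scheme,site,year,visit,age_class``.
    """
    if format != "csv":
        raise ValueError(f"unsupported format {format!r}; only 'csv' is supported")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str)
    return CaptureTable(df, provenance=str(path))


def write_capture_table(table: CaptureTable, path: str | Path) -> None:
    """Write a capture table to CSV (lossless round-trip)."""
    table.df.to_csv(path, index=False)


@dataclass(frozen=True)
class SelectionCriteria:
    """Thresholds governing site-, species- and scheme-level selection.

    Fractional thresholds are applied to the scheme's modal maximum
    visit number and rounded *up* to whole visits.
    """

    min_site_years: int = 5
    visit_fraction: Fraction | float = Fraction(2, 3)
    half_season_fraction: Fraction | float = Fraction(1, 4)
    min_adults_per_species_year: int = 2
    min_young_per_species_year: int = 2
    min_mean_individuals_per_year: float = 50.0

    def __post_init__(self) -> None:
        if self.min_site_years <= 0:
            raise ValueError("min_site_years must be positive")
        for name in ("visit_fraction", "half_season_fraction"):
            f = float(getattr(self, name))
            if not 0 < f <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.min_adults_per_species_year <= 0 or self.min_young_per_species_year <= 0:
            raise ValueError("per-species count thresholds must be positive")
        if self.min_mean_individuals_per_year <= 0:
            raise ValueError("min_mean_individuals_per_year must be positive")


@dataclass
class SelectionReport:
    """Exclusion log accumulated across the selection passes.

    Each entry records the level at which the rule fired
    (``site``/``site_year``/``species_site_year``/``species``), an
    identifier and the triggering rule.
    """

    entries: list[dict] = field(default_factory=list)
    input_records: int = 0
    retained_records: int = 0

    def add(self, level: str, identifier: str, rule: str) -> None:
        self.entries.append({"level": level, "identifier": identifier, "rule": rule})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["level", "identifier", "rule"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def modal_max_visits(table: CaptureTable, scheme: str) -> int:
    """Modal number of distinct visits per site-year within a scheme.

    Ties between equally frequent visit counts are broken toward the
    larger count, which makes the downstream coverage rule stricter.
    """
    sub = table.df[table.df["scheme"] == scheme]
    if len(sub) == 0:
        raise KeyError(f"scheme {scheme!r} not present in capture table")
    counts = sub.groupby(["site", "year"])["visit"].nunique()
    freq = counts.value_counts()
    top = freq[freq == freq.max()]
    return int(max(top.index))


def _ceil_frac(fraction: Fraction | float, total: int) -> int:
    if isinstance(fraction, Fraction):
        return int(math.ceil(fraction * total))
    return int(math.ceil(float(fraction) * total))


def select_site_years(
    table: CaptureTable, criteria: SelectionCriteria = SelectionCriteria()
) -> tuple[CaptureTable, SelectionReport]:
    """Apply the visit-coverage and site-longevity filters.

    Per scheme, with modal maximum visit number ``V``:

    * a site-year is retained when it has at least ``ceil(2/3 * V)``
      distinct visits overall and at least ``ceil(1/4 * V)`` distinct
      visits in each half of the season (first half = visit indices
      ``1..ceil(V/2)``);
    * a site is retained when it keeps at least five retained years.
    """
    df = table.df
    report = SelectionReport(input_records=len(df))
    keep_parts: list[pd.DataFrame] = []
    for scheme, sub in df.groupby("scheme", sort=True):
        v_max = modal_max_visits(table, scheme)
        need_total = _ceil_frac(criteria.visit_fraction, v_max)
        need_half = _ceil_frac(criteria.half_season_fraction, v_max)
        split = math.ceil(v_max / 2)  # first half = visits 1..split

        grp = sub.groupby(["site", "year"])
        n_total = grp["visit"].nunique()
        n_first = grp["visit"].agg(lambda v: v[v <= split].nunique())
        n_second = grp["visit"].agg(lambda v: v[v > split].nunique())
        ok = (n_total >= need_total) & (n_first >= need_half) & (n_second >= need_half)
        for (site, year), good in ok.items():
            if not good:
                if n_total.loc[(site, year)] < need_total:
                    rule = f"visits {n_total.loc[(site, year)]} < {need_total} (2/3 of {v_max})"
                else:
                    rule = (
                        f"half-season visits ({n_first.loc[(site, year)]}, "
                        f"{n_second.loc[(site, year)]}) < {need_half} (1/4 of {v_max})"
                    )
                report.add("site_year", f"{scheme}/{site}/{year}", rule)
        retained_sy = ok[ok].index
        years_per_site = pd.Series(
            [y for (_s, y) in retained_sy], index=[s for (s, _y) in retained_sy]
        ).groupby(level=0).nunique()
        good_sites = set(years_per_site[years_per_site >= criteria.min_site_years].index)
        for site, n_years in years_per_site.items():
            if site not in good_sites:
                report.add(
                    "site",
                    f"{scheme}/{site}",
                    f"retained years {n_years} < {criteria.min_site_years}",
                )
        sy_keep = {(s, y) for (s, y) in retained_sy if s in good_sites}
        mask = [(s, y) in sy_keep for s, y in zip(sub["site"], sub["year"])]
        keep_parts.append(sub[mask])
    kept = (
        pd.concat(keep_parts, ignore_index=True)
        if keep_parts
        else df.iloc[0:0].copy()
    )
    if len(kept) == 0:
        logger.warning("site-year selection removed every record")
    report.retained_records = len(kept)
    out = CaptureTable(kept, provenance=table.provenance)
    return out, report


def select_species_site_years(
    table: CaptureTable,
    criteria: SelectionCriteria = SelectionCriteria(),
    report: SelectionReport | None = None,
) -> CaptureTable:
    """Drop species-site-years with too few adults or juveniles.

    A site-year is dropped *for one species only* when fewer than two
    distinct adults or fewer than two distinct juveniles of that species
    were captured there; other species at the same site-year are
    unaffected.
    """
    df = table.df
    if len(df) == 0:
        return table
    counts = (
        df.groupby(["scheme", "species", "site", "year", "age_class"])["ring_id"]
        .nunique()
        .unstack("age_class", fill_value=0)
    )
    for age in (AGE_ADULT, AGE_JUVENILE):
        if age not in counts.columns:
            counts[age] = 0
    ok = (counts[AGE_ADULT] >= criteria.min_adults_per_species_year) & (
        counts[AGE_JUVENILE] >= criteria.min_young_per_species_year
    )
    if report is not None:
        for (scheme, species, site, year), good in ok.items():
            if not good:
                a = counts.loc[(scheme, species, site, year), AGE_ADULT]
                j = counts.loc[(scheme, species, site, year), AGE_JUVENILE]
                report.add(
                    "species_site_year",
                    f"{scheme}/{species}/{site}/{year}",
                    f"adults {a} or juveniles {j} below "
                    f"({criteria.min_adults_per_species_year}, "
                    f"{criteria.min_young_per_species_year})",
                )
    good_keys = set(ok[ok].index)
    key = list(zip(df["scheme"], df["species"], df["site"], df["year"]))
    mask = [k in good_keys for k in key]
    return CaptureTable(df[mask].reset_index(drop=True), provenance=table.provenance)


def select_species(
    table: CaptureTable,
    criteria: SelectionCriteria = SelectionCriteria(),
    report: SelectionReport | None = None,
) -> list[tuple[str, str]]:
    """Retain (scheme, species) pairs with enough captures per year.

    The statistic is the mean number of distinct individuals (adults
    plus juveniles) of the species captured per year, averaged over the
    years the scheme was active in the filtered table.
    """
    df = table.df
    retained: list[tuple[str, str]] = []
    for scheme, sub in df.groupby("scheme", sort=True):
        active_years = sub["year"].nunique()
        if active_years == 0:
            continue
        per_species = sub.groupby(["species", "year"])["ring_id"].nunique()
        totals = per_species.groupby(level="species").sum()
        for species, total in totals.sort_index().items():
            mean_per_year = total / active_years
            if mean_per_year >= criteria.min_mean_individuals_per_year:
                retained.append((scheme, str(species)))
            elif report is not None:
                report.add(
                    "species",
                    f"{scheme}/{species}",
                    f"mean individuals/year {mean_per_year:.2f} < "
                    f"{criteria.min_mean_individuals_per_year}",
                )
    return retained


@dataclass
class CaptureHistorySet:
    """Annual adult detection histories for one species-scheme pair.

    Attributes
    ----------
    species, scheme
        Identity of the series.
    years
        Ordered study years (the occasions); interval ``t`` spans
        ``years[t] -> years[t + 1]``.
    detections
        ``(n_individuals, T)`` 0/1 matrix; entry 1 means the individual
        was captured as an adult at least once that year.
    first
        Index of each individual's first adult capture year.
    site_index
        Index into :attr:`site_codes`; the site of first adult capture.
    site_codes
        Ordered site codes.
    ring_ids
        Ring numbers, aligned with the matrix rows.
    multi_site
        True where an individual was also caught at another site later;
        such birds keep their first site (site fidelity convention).
    """

    species: str
    scheme: str
    years: np.ndarray
    detections: np.ndarray
    first: np.ndarray
    site_index: np.ndarray
    site_codes: list[str]
    ring_ids: list[str]
    multi_site: np.ndarray

    @property
    def n_occasions(self) -> int:
        return len(self.years)

    @property
    def n_individuals(self) -> int:
        return self.detections.shape[0]

    @property
    def n_sites(self) -> int:
        return len(self.site_codes)

    def subset_sites(self, keep: Sequence[str]) -> "CaptureHistorySet":
        """Restrict to individuals whose first-capture site is in ``keep``."""
        keep_set = set(keep)
        site_ok = np.array([self.site_codes[i] in keep_set for i in self.site_index])
        codes = [c for c in self.site_codes if c in keep_set]
        remap = {self.site_codes.index(c): i for i, c in enumerate(codes)}
        new_idx = np.array(
            [remap[i] for i in self.site_index[site_ok]], dtype=np.int64
        ) if site_ok.any() else np.empty(0, dtype=np.int64)
        return CaptureHistorySet(
            species=self.species,
            scheme=self.scheme,
            years=self.years,
            detections=self.detections[site_ok],
            first=self.first[site_ok],
            site_index=new_idx,
            site_codes=codes,
            ring_ids=[r for r, ok in zip(self.ring_ids, site_ok) if ok],
            multi_site=self.multi_site[site_ok],
        )


def build_histories(table: CaptureTable, species: str, scheme: str) -> CaptureHistorySet:
    """Collapse adult captures to annual detection histories.

    Multiple captures within a year count as one detection; juvenile
    captures are ignored entirely (a bird ringed as a juvenile enters
    the history in its first *adult* capture year). Individuals caught
    as adults at more than one site are assigned to their first site
    and flagged.

    Raises
    ------
    DataError
        If fewer than three study years remain.
    """
    df = table.df
    sub = df[
        (df["species"] == species)
        & (df["scheme"] == scheme)
        & (df["age_class"] == AGE_ADULT)
    ]
    years = np.array(sorted(df[(df["species"] == species) & (df["scheme"] == scheme)]["year"].unique()))
    if len(years) < 3:
        raise DataError(
            f"{scheme}/{species}: only {len(years)} study years; need >= 3 for survival fitting"
        )
    year_pos = {y: i for i, y in enumerate(years)}
    T = len(years)

    sub = sub.sort_values(["ring_id", "year", "visit"], kind="mergesort")
    ring_ids: list[str] = []
    first_list: list[int] = []
    site_list: list[str] = []
    multi_list: list[bool] = []
    det_rows: list[np.ndarray] = []
    for ring, grp in sub.groupby("ring_id", sort=True):
        det = np.zeros(T, dtype=np.int8)
        for y in grp["year"].unique():
            det[year_pos[int(y)]] = 1
        first_site = grp.iloc[0]["site"]
        multi = grp["site"].nunique() > 1
        if multi:
            logger.info("ring %s caught at multiple sites; assigned to first site %s", ring, first_site)
        ring_ids.append(str(ring))
        first_list.append(int(det.argmax()))
        site_list.append(str(first_site))
        multi_list.append(bool(multi))
        det_rows.append(det)

    site_codes = sorted(set(site_list))
    site_pos = {s: i for i, s in enumerate(site_codes)}
    return CaptureHistorySet(
        species=species,
        scheme=scheme,
        years=years,
        detections=np.array(det_rows, dtype=np.int8).reshape(len(det_rows), T),
        first=np.array(first_list, dtype=np.int64),
        site_index=np.array([site_pos[s] for s in site_list], dtype=np.int64),
        site_codes=site_codes,
        ring_ids=ring_ids,
        multi_site=np.array(multi_list, dtype=bool),
    )
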