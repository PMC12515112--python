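"""End-to-end orchestration of the three analysis steps.

A single :class:`PipelineConfig` drives the full chain: load (or
simulate) capture data, apply the selection filters, fit the
transient-CJS survival model and the two index GLMs per species and
scheme, run the per-population growth regression, and fit the three
weighted meta-models. Every exclusion is logged and counted, outputs
are written as plain CSV/JSON, and the whole run is deterministic
under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from cesdemog._version import __version__ as _version
from cesdemog.cjs import CJSFit, fit_cjs_transient, filter_by_recapture, filter_by_survival_se
from cesdemog.data import (
    CaptureTable,
    SelectionCriteria,
    SelectionReport,
    build_histories,
    read_capture_table,
    select_site_years,
    select_species,
    select_species_site_years,
    write_capture_table,
)
from cesdemog.errors import CesdemogError, ConfigError, ConvergenceError, DataError
from cesdemog.growth import (
    DemographicSeries,
    GrowthCoefficients,
    coefficients_to_frame,
    fit_growth_lm,
)
from cesdemog.indices import (
    IndexSeries,
    filter_by_dispersion,
    fit_abundance_glm,
    fit_productivity_glm,
    tabulate_counts,
)
from cesdemog.meta import MetaFit, fit_weighted_lmm, metafits_to_frame, stack_coefficients
from cesdemog.simulate import SimulationConfig, simulate_multischeme

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one pipeline run.

    Exactly one of ``capture_csv`` and ``simulation`` must be set;
    traits/temperature tables are required for meta-models B and C
    (the simulator provides them itself).
    """

    capture_csv: str | None = None
    traits_csv: str | None = None
    temperature_csv: str | None = None
    simulation: SimulationConfig | None = None
    selection: SelectionCriteria = field(default_factory=SelectionCriteria)
    recapture_lower: float = 0.10
    recapture_upper: float = 0.90
    survival_se_lower: float = 0.01
    survival_se_upper: float = 0.25
    dispersion_threshold: float = 4.0
    min_year_pairs: int = 4
    n_starts: int = 5
    seed: int = 0
    out_dir: str | None = None
    models: tuple[str, ...] = ("A", "B", "C")

    def __post_init__(self) -> None:
        if (self.capture_csv is None) == (self.simulation is None):
            raise ConfigError(
                "provide exactly one of capture_csv (with trait/temperature "
                "tables) or a simulation config"
            )
        if not self.recapture_lower < self.recapture_upper:
            raise ConfigError("recapture bounds must be ordered")
        if not self.survival_se_lower < self.survival_se_upper:
            raise ConfigError("survival SE bounds must be ordered")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "selection" in raw and isinstance(raw["selection"], dict):
            raw["selection"] = SelectionCriteria(**raw["selection"])
        if "simulation" in raw and isinstance(raw["simulation"], dict):
            from cesdemog.simulate import SchemeConfig, SpeciesConfig

            sim = dict(raw["simulation"])
            sim["schemes"] = [SchemeConfig(**s) for s in sim.get("schemes", [])]
            sim["species"] = [SpeciesConfig(**s) for s in sim.get("species", [])]
            raw["simulation"] = SimulationConfig(**sim)
        if "models" in raw:
            raw["models"] = tuple(raw["models"])
        return cls(**raw)

    def echo(self) -> dict:
        """JSON-serializable copy of the configuration."""
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (list, tuple)):
                return [enc(v) for v in obj]
            if isinstance(obj, dict):
                return {k: enc(v) for k, v in obj.items()}
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, (bool, int, float, str)) or obj is None:
                return obj
            if hasattr(obj, "numerator") and hasattr(obj, "denominator"):
                return float(obj)  # Fraction thresholds
            return obj

        return {
            f.name: enc(getattr(self, f.name)) for f in dataclasses.fields(self)
        }


@dataclass
class RunReport:
    """Counts, warnings and provenance for one pipeline run."""

    config: dict = field(default_factory=dict)
    version: str = _version
    stages: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)

    def warn(self, message: str) -> None:
        self.warnings.append(message)
        logger.warning(message)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, default=str)


@dataclass
class PipelineResults:
    """In-memory results of a pipeline run (files are optional)."""

    report: RunReport
    selected: CaptureTable
    selection_report: SelectionReport
    cjs_fits: dict[tuple[str, str], CJSFit]
    retained_intervals: dict[tuple[str, str], np.ndarray]
    indices: dict[tuple[str, str], dict[str, IndexSeries]]
    growth: list[GrowthCoefficients]
    meta_table: pd.DataFrame | None
    meta_fits: dict[str, MetaFit]
    traits: pd.DataFrame | None
    temperatures: pd.DataFrame | None
    truth: list | None


def _fit_seed(base_seed: int, scheme: str, species: str) -> int:
    """Stable per-population optimizer seed below 2**31."""
    h = zlib.crc32(f"{scheme}/{species}".encode())
    return int((base_seed + h) % (2**31 - 1))


def build_demographic_series(
    cjs: CJSFit,
    interval_mask: np.ndarray,
    productivity: IndexSeries,
    abundance: IndexSeries,
) -> DemographicSeries:
    """Align survival intervals with productivity and abundance years.

    Interval ``t -> t + 1`` is usable when its survival estimate passed
    the SE filter, productivity of year ``t`` has a finite SE, and the
    abundance index is positive with finite SE at year ``t`` and
    positive at year ``t + 1``.
    """
    prod = {int(y): (e, s) for y, e, s in zip(productivity.years, productivity.estimate, productivity.se)}
    abund = {int(y): (e, s) for y, e, s in zip(abundance.years, abundance.estimate, abundance.se)}
    years, phi, phi_se, rho, rho_se, x0, x0_se, x1 = ([] for _ in range(8))
    for t in range(len(cjs.years) - 1):
        if not interval_mask[t]:
            continue
        y_start, y_end = int(cjs.years[t]), int(cjs.years[t + 1])
        if y_start not in prod or y_start not in abund or y_end not in abund:
            continue
        p_est, p_se = prod[y_start]
        a0, a0_se = abund[y_start]
        a1, _ = abund[y_end]
        if not (np.isfinite(p_se) and np.isfinite(a0_se)):
            continue
        if a0 <= 0 or a1 <= 0:
            continue
        years.append(y_start)
        phi.append(float(cjs.phi_hat[t]))
        phi_se.append(float(cjs.phi_se[t]))
        rho.append(p_est)
        rho_se.append(p_se)
        x0.append(a0)
        x0_se.append(a0_se)
        x1.append(a1)
    return DemographicSeries(
        scheme=cjs.scheme,
        species=cjs.species,
        years=np.array(years, dtype=int),
        phi=np.array(phi),
        phi_se=np.array(phi_se),
        rho=np.array(rho),
        rho_se=np.array(rho_se),
        x_start=np.array(x0),
        x_start_se=np.array(x0_se),
        x_end=np.array(x1),
    )


def run_pipeline(config: PipelineConfig) -> PipelineResults:
    """Execute selection, step 1, step 2 and step 3 from one config."""
    report = RunReport(config=config.echo())
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    # ------------------------------------------------------------------ input
    truth = None
    traits = temps = None
    if config.simulation is not None:
        table, traits, temps, truth = simulate_multischeme(config.simulation)
    else:
        table = read_capture_table(config.capture_csv)
        if config.traits_csv:
            traits = pd.read_csv(config.traits_csv, dtype={"species": str})
        if config.temperature_csv:
            temps = pd.read_csv(config.temperature_csv, dtype={"scheme": str})
    report.stages["input"] = {"records": len(table)}
    if out_dir and config.simulation is not None:
        write_capture_table(table, out_dir / "captures.csv")
        traits.to_csv(out_dir / "traits.csv", index=False)
        temps.to_csv(out_dir / "temperature.csv", index=False)
        with open(out_dir / "truth.json", "w") as fh:
            json.dump([t.to_dict() for t in truth], fh, indent=2)
        report.outputs += ["captures.csv", "traits.csv", "temperature.csv", "truth.json"]

    # -------------------------------------------------------------- selection
    selected, sel_report = select_site_years(table, config.selection)
    selected = select_species_site_years(selected, config.selection, report=sel_report)
    populations = select_species(selected, config.selection, report=sel_report)
    sel_report.retained_records = len(selected)
    report.stages["selection"] = {
        "records_in": len(table),
        "records_retained": len(selected),
        "exclusions": len(sel_report.entries),
        "populations": len(populations),
    }
    if out_dir:
        sel_report.write(out_dir / "selection_report.csv")
        report.outputs.append("selection_report.csv")

    # ----------------------------------------------------------------- step 1
    cjs_fits: dict[tuple[str, str], CJSFit] = {}
    retained_intervals: dict[tuple[str, str], np.ndarray] = {}
    indices: dict[tuple[str, str], dict[str, IndexSeries]] = {}
    growth_list: list[GrowthCoefficients] = []
    for scheme, species in populations:
        key = (scheme, species)
        seed = _fit_seed(config.seed, scheme, species)
        try:
            hist = build_histories(selected, species, scheme)
            fit = fit_cjs_transient(hist, n_starts=config.n_starts, seed=seed)
            retained_sites = filter_by_recapture(
                fit, config.recapture_lower, config.recapture_upper
            )
            if len(retained_sites) < len(fit.site_codes):
                if not retained_sites:
                    raise DataError("all sites excluded by the recapture filter")
                hist = hist.subset_sites(retained_sites)
                fit = fit_cjs_transient(hist, n_starts=config.n_starts, seed=seed)
            mask = filter_by_survival_se(
                fit, config.survival_se_lower, config.survival_se_upper
            )
        except (CesdemogError, ConvergenceError) as exc:
            report.warn(f"survival {scheme}/{species}: {exc}")
            continue
        cjs_fits[key] = fit
        retained_intervals[key] = mask

        try:
            counts = tabulate_counts(selected, species, scheme)
            prod = fit_productivity_glm(counts)
            abund = fit_abundance_glm(counts)
        except CesdemogError as exc:
            report.warn(f"indices {scheme}/{species}: {exc}")
            continue
        if not (
            filter_by_dispersion(prod, config.dispersion_threshold)
            and filter_by_dispersion(abund, config.dispersion_threshold)
        ):
            report.warn(
                f"{scheme}/{species}: dropped by the dispersion filter "
                f"(productivity {prod.dispersion:.2f}, abundance {abund.dispersion:.2f})"
            )
            continue
        indices[key] = {"productivity": prod, "abundance": abund}

        # ------------------------------------------------------------- step 2
        series = build_demographic_series(fit, mask, prod, abund)
        try:
            growth_list.append(fit_growth_lm(series, min_pairs=config.min_year_pairs))
        except CesdemogError as exc:
            report.warn(f"growth {scheme}/{species}: {exc}")

    report.stages["step1"] = {
        "populations_attempted": len(populations),
        "survival_fits": len(cjs_fits),
        "index_series": len(indices),
    }
    report.stages["step2"] = {"populations_with_coefficients": len(growth_list)}

    # ----------------------------------------------------------------- step 3
    meta_table = None
    meta_fits: dict[str, MetaFit] = {}
    if growth_list and traits is not None and temps is not None:
        try:
            meta_table = stack_coefficients(growth_list, traits, temps)
        except (KeyError, CesdemogError) as exc:
            report.warn(f"step 3 stacking failed: {exc}")
        if meta_table is not None:
            for model in config.models:
                try:
                    meta_fits[model] = fit_weighted_lmm(meta_table, model=model)
                except (CesdemogError, ValueError) as exc:
                    report.warn(f"model {model} not fitted: {exc}")
    elif growth_list:
        report.warn("trait/temperature tables missing: meta-models skipped")
    report.stages["step3"] = {
        "coefficient_rows": 0 if meta_table is None else len(meta_table),
        "models_fitted": sorted(meta_fits),
    }

    # ---------------------------------------------------------------- outputs
    if out_dir:
        _write_outputs(out_dir, report, cjs_fits, retained_intervals, indices, growth_list, meta_table, meta_fits)
        report.write(out_dir / "run_report.json")

    return PipelineResults(
        report=report,
        selected=selected,
        selection_report=sel_report,
        cjs_fits=cjs_fits,
        retained_intervals=retained_intervals,
        indices=indices,
        growth=growth_list,
        meta_table=meta_table,
        meta_fits=meta_fits,
        traits=traits,
        temperatures=temps,
        truth=truth,
    )


def _float_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def _write_outputs(
    out_dir: Path,
    report: RunReport,
    cjs_fits: dict,
    retained_intervals: dict,
    indices: dict,
    growth_list: list[GrowthCoefficients],
    meta_table: pd.DataFrame | None,
    meta_fits: dict[str, MetaFit],
) -> None:
    surv_rows, p_rows, idx_frames, disp_rows = [], [], [], []
    for (scheme, species), fit in cjs_fits.items():
        mask = retained_intervals[(scheme, species)]
        for t in range(len(fit.years) - 1):
            surv_rows.append(
                {
                    "scheme": scheme,
                    "species": species,
                    "year_start": int(fit.years[t]),
                    "year_end": int(fit.years[t + 1]),
                    "estimate": fit.phi_hat[t],
                    "se": fit.phi_se[t],
                    "retained": bool(mask[t]),
                }
            )
        for code, p, se in zip(fit.site_codes, fit.p_hat, fit.p_se):
            p_rows.append(
                {"scheme": scheme, "species": species, "site": code, "p_hat": p, "se": se}
            )
    for (scheme, species), d in indices.items():
        for kind, series in d.items():
            idx_frames.append(series.to_frame())
            disp_rows.append(
                {
                    "scheme": scheme,
                    "species": species,
                    "kind": kind,
                    "dispersion": series.dispersion,
                    "df_resid": series.df_resid,
                }
            )
    _float_csv(pd.DataFrame(surv_rows), out_dir / "survival_estimates.csv")
    _float_csv(pd.DataFrame(p_rows), out_dir / "recapture_estimates.csv")
    if idx_frames:
        _float_csv(pd.concat(idx_frames, ignore_index=True), out_dir / "index_estimates.csv")
    _float_csv(pd.DataFrame(disp_rows), out_dir / "dispersion_report.csv")
    _float_csv(coefficients_to_frame(growth_list), out_dir / "growth_coefficients.csv")
    if meta_table is not None:
        _float_csv(meta_table, out_dir / "meta_table.csv")
    if meta_fits:
        _float_csv(metafits_to_frame(list(meta_fits.values())), out_dir / "meta_models.csv")
    report.outputs += [
        "survival_estimates.csv",
        "recapture_estimates.csv",
        "index_estimates.csv",
        "dispersion_report.csv",
        "growth_coefficients.csv",
        "meta_table.csv",
        "meta_models.csv",
        "run_report.json",
    ]


def sensitivity_sweep(
    config: PipelineConfig, variants: dict[str, dict]
) -> pd.DataFrame:
    """Re-run the pipeline under named configuration variants.

    ``variants`` maps a label to a dict of :class:`PipelineConfig`
    field overrides (``selection`` overrides may be given as a dict of
    :class:`SelectionCriteria` fields). Returns a side-by-side table
    of model-A fixed effects per variant; a failed variant contributes
    an error row and does not stop the sweep.
    """
    if len(variants) < 2:
        raise ConfigError("a sweep needs at least two variants")
    rows = []
    for label, overrides in variants.items():
        raw = config.echo()
        raw.pop("out_dir", None)
        sel = raw.get("selection") or {}
        for key, value in overrides.items():
            if key == "selection":
                sel = {**sel, **value}
            else:
                raw[key] = value
        raw["selection"] = sel
        if config.out_dir:
            raw["out_dir"] = str(Path(config.out_dir) / f"variant_{label}")
        try:
            variant_cfg = PipelineConfig.from_dict(raw)
            results = run_pipeline(variant_cfg)
            fit = results.meta_fits.get("A")
            if fit is None:
                raise DataError("model A not fitted")
            for _, row in fit.params.iterrows():
                rows.append(
                    {
                        "variant": label,
                        "parameter": row["parameter"],
                        "estimate": row["estimate"],
                        "se": row["se"],
                        "p": row["p"],
                        "error": "",
                    }
                )
        except Exception as exc:  # keep sweeping past broken variants
            logger.warning("variant %s failed: %s", label, exc)
            rows.append(
                {
                    "variant": label,
                    "parameter": "",
                    "estimate": np.nan,
                    "se": np.nan,
                    "p": np.nan,
                    "error": str(exc),
                }
            )
    out = pd.DataFrame(rows)
    est = out[(out["parameter"] == "measure[survival]") & (out["error"] == "")]
    if len(est) > 1:
        signs = np.sign(est["estimate"].to_numpy())
        if not np.all(signs == signs[0]):
            logger.warning("sweep: measure-effect sign differs across variants")
    return out
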