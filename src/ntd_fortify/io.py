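"""CSV schemas, packaged fixtures, run configuration and the pipeline driver.

The packaged fixtures transcribe the published country tables verbatim:

``table1_registries.csv``
    Registry NTD case totals, period prevalence and national coverage.
``table2_folate.csv``
    Estimated median serum folate (nmol/L) and log-scale SD per country,
    with borrowing annotations for countries lacking a survey.
``table3_impacts.csv``
    Published per-country impact figures (used for cross-checks and for
    back-computing an approximate births table — never as model input).
``borrowing_map.csv`` / ``direct_prevalence.csv`` / ``eu_membership.csv``
    The footnote rules (who borrows whose prevalence or folate values,
    literature prevalences for Slovakia and Slovenia, EU15/EU28 sets).

Per-registry *annual* case counts were never published, only period totals;
:func:`annualize_registry_table` spreads totals uniformly over each
registry's active years and is therefore approximate — adequate for
integration demos, not a reconstruction of the original microdata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .folate import FolateDistribution, FolateSurvey, default_log_sd
from .impact import BirthsTable, ImpactResult, aggregate_impacts, predict_country_impact, render_report
from .prevalence import (
    CountryPrevalenceSeries,
    RegistryRecord,
    borrow_countries,
    impute_missing_years,
    pool_registries,
)
from .risk import SCENARIO_PRESETS, RiskModelParams, Scenario, intake_to_increment, reduction_for

__all__ = [
    "ValidationError",
    "DEFAULT_WINDOW",
    "load_fixture",
    "read_surveys",
    "annualize_registry_table",
    "folate_distributions",
    "assemble_prevalence",
    "back_computed_births",
    "eu_sets",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger("ntd_fortify")

DEFAULT_WINDOW = (1998, 2017)

_FIXTURE_FILES = {
    "table1": "table1_registries.csv",
    "table2": "table2_folate.csv",
    "table3": "table3_impacts.csv",
    "borrowing_map": "borrowing_map.csv",
    "direct_prevalence": "direct_prevalence.csv",
    "eu_membership": "eu_membership.csv",
}

_FIXTURE_REQUIRED_COLUMNS = {
    "table1": ["country_code", "registry_name", "first_year", "last_year",
               "cases_total", "prevalence_per_1000", "coverage_pct"],
    "table2": ["country_code", "statistic_kind", "median_nmol_l", "log_sd",
               "source_country", "estimated_from_prevalence"],
    "table3": ["country_code", "aggregate", "prevalence_per_1000",
               "pct_reduction_nosupp", "prevented_nosupp",
               "pct_reduction_supp", "prevented_supp"],
    "borrowing_map": ["quantity", "target_country", "source_countries"],
    "direct_prevalence": ["country_code", "prevalence_per_1000"],
    "eu_membership": ["country_code", "eu_1998", "eu_2017"],
}


class ValidationError(ValueError):
    """A fixture or input file violates its schema."""


def _validate(name: str, df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _FIXTURE_REQUIRED_COLUMNS[name] if c not in df.columns]
    if missing:
        raise ValidationError(f"fixture {name}: missing columns {missing}")
    codes = df["country_code"] if "country_code" in df else df["target_country"]
    for i, code in codes.items():
        if not isinstance(code, str) or not (
            (len(code) == 2 and code.isalpha() and code.isupper())
            or code in ("EU15", "EU28")
        ):
            raise ValidationError(f"fixture {name}, row {i}: bad country code {code!r}")
    if name == "table1":
        bad = df[(df["cases_total"] < 0) | (df["first_year"] > df["last_year"])]
        if not bad.empty:
            raise ValidationError(f"fixture table1: invalid rows {list(bad.index)}")
    if name == "table2":
        has_value = df["median_nmol_l"].notna()
        bad = df[has_value & (df["median_nmol_l"] <= 0)]
        if not bad.empty:
            raise ValidationError(f"fixture table2: non-positive medians rows {list(bad.index)}")
        orphans = df[~has_value & df["source_country"].isna()]
        if not orphans.empty:
            raise ValidationError(
                f"fixture table2: rows {list(orphans.index)} have neither a value "
                "nor a source country"
            )
    return df


def load_fixture(name: str) -> pd.DataFrame:
    """Load and validate a packaged fixture table by short name."""
    if name not in _FIXTURE_FILES:
        raise ValidationError(
            f"unknown fixture {name!r}; expected one of {sorted(_FIXTURE_FILES)}"
        )
    ref = resources.files("ntd_fortify") / "data" / _FIXTURE_FILES[name]
    with resources.as_file(ref) as path:
        df = pd.read_csv(path)
    return _validate(name, df)


def read_surveys(frame: pd.DataFrame) -> list[FolateSurvey]:
    """Turn table2-style rows (those with a value) into FolateSurvey objects."""
    surveys = []
    for r in frame.itertuples(index=False):
        if pd.isna(r.median_nmol_l):
            continue
        surveys.append(
            FolateSurvey(
                country_code=r.country_code,
                statistic_kind=r.statistic_kind,
                location_value=float(r.median_nmol_l),
                location_unit="nmol/L",
                log_sd=None if pd.isna(r.log_sd) else float(r.log_sd),
                source_label=str(getattr(r, "source", "")),
                estimated_from_prevalence=bool(r.estimated_from_prevalence),
            )
        )
    return surveys


def annualize_registry_table(frame: pd.DataFrame) -> list[RegistryRecord]:
    """Spread each registry's period totals uniformly over its active years.

    Approximate by construction (annual counts were not published): total
    cases and back-computed covered births (cases / prevalence per 1,000)
    are divided evenly across first..last year, remainders going to the
    earliest years.
    """
    records = []
    for r in frame.itertuples(index=False):
        n_years = int(r.last_year) - int(r.first_year) + 1
        total_cases = int(r.cases_total)
        total_births = int(round(1000.0 * total_cases / float(r.prevalence_per_1000)))
        base_c, extra_c = divmod(total_cases, n_years)
        base_b, extra_b = divmod(total_births, n_years)
        for j, year in enumerate(range(int(r.first_year), int(r.last_year) + 1)):
            records.append(
                RegistryRecord(
                    registry_name=str(r.registry_name),
                    country_code=str(r.country_code),
                    year=year,
                    cases=base_c + (1 if j < extra_c else 0),
                    births_covered=base_b + (1 if j < extra_b else 0),
                )
            )
    return records


def _borrowing(frame: pd.DataFrame, quantity: str) -> dict[str, list[str]]:
    sub = frame[frame["quantity"] == quantity]
    return {
        r.target_country: str(r.source_countries).split(";")
        for r in sub.itertuples(index=False)
    }


def folate_distributions(
    table2: pd.DataFrame | None = None,
    borrowing: Mapping[str, list[str]] | None = None,
    fallback_log_sd: float | None = None,
) -> dict[str, FolateDistribution]:
    """Country folate distributions from the survey table.

    Countries whose survey lacks a log-scale SD receive ``fallback_log_sd``
    (default: the median SD across surveys that have one); countries with
    no survey inherit their source country's distribution per the borrowing
    map.
    """
    if table2 is None:
        table2 = load_fixture("table2")
    if borrowing is None:
        borrowing = _borrowing(load_fixture("borrowing_map"), "folate")
    surveys = read_surveys(table2)
    if fallback_log_sd is None:
        fallback_log_sd = default_log_sd(surveys)
    dists: dict[str, FolateDistribution] = {}
    for s in surveys:
        sigma = s.log_sd if s.log_sd is not None else fallback_log_sd
        if s.log_sd is None:
            logger.info("folate: %s has no log-SD, using default %.2f", s.country_code, fallback_log_sd)
        dists[s.country_code] = FolateDistribution(s.location_nmol_l, sigma)
    for target, sources in borrowing.items():
        if len(sources) != 1:
            raise ValidationError(f"folate borrowing for {target} must name one source")
        if sources[0] not in dists:
            raise KeyError(f"folate borrowing for {target}: missing source {sources[0]}")
        dists[target] = dists[sources[0]]
        logger.info("folate: %s borrows distribution from %s", target, sources[0])
    return dists


def assemble_prevalence(
    registry_records: list[RegistryRecord] | None = None,
    window: tuple[int, int] = DEFAULT_WINDOW,
    borrowing: Mapping[str, list[str]] | None = None,
    direct: pd.DataFrame | None = None,
) -> dict[str, CountryPrevalenceSeries]:
    """Full prevalence assembly: pool, impute, add literature values, borrow."""
    if registry_records is None:
        registry_records = annualize_registry_table(load_fixture("table1"))
    if borrowing is None:
        borrowing = _borrowing(load_fixture("borrowing_map"), "prevalence")
    if direct is None:
        direct = load_fixture("direct_prevalence")
    by_country: dict[str, list[RegistryRecord]] = {}
    for rec in registry_records:
        by_country.setdefault(rec.country_code, []).append(rec)
    series: dict[str, CountryPrevalenceSeries] = {}
    for country, recs in by_country.items():
        pooled = pool_registries(recs, window)
        complete = impute_missing_years(pooled, window)
        for year, prov in sorted(complete.provenance.items()):
            if prov != "observed":
                logger.info("prevalence: %s %d %s = %.3f", country, year, prov, complete.values[year])
        series[country] = complete
    for r in direct.itertuples(index=False):
        lit = CountryPrevalenceSeries(r.country_code)
        for year in range(window[0], window[1] + 1):
            lit.set(year, float(r.prevalence_per_1000), "literature")
        series[r.country_code] = lit
    series = borrow_countries(series, borrowing)
    for target in borrowing:
        logger.info("prevalence: %s borrowed from %s", target, ";".join(borrowing[target]))
    return series


def eu_sets(frame: pd.DataFrame | None = None) -> dict[str, set[str]]:
    """EU15 / EU28 membership sets (plus the non-EU extras)."""
    if frame is None:
        frame = load_fixture("eu_membership")
    return {
        "EU15": set(frame[frame["eu_1998"] == "Y"]["country_code"]),
        "EU28": set(frame[frame["eu_2017"] == "Y"]["country_code"]),
        "non_EU": set(frame[(frame["eu_1998"] == "N") & (frame["eu_2017"] == "N")]["country_code"]),
    }


def back_computed_births(
    window: tuple[int, int] = DEFAULT_WINDOW,
    params: RiskModelParams = RiskModelParams(),
) -> BirthsTable:
    """Approximate national births, back-computed from published impacts.

    Inverts the accounting identity for each country: period births =
    prevented / (prevalence/1000 x reduction), using the unrounded
    quintile-band reduction recomputed from the folate table, spread evenly
    across the window.  Synthetic stand-in for a per-country-year Eurostat
    extract; suitable for integration demos, not for reproducing the
    published absolute counts exactly.
    """
    t3 = load_fixture("table3")
    dists = folate_distributions()
    scenario = SCENARIO_PRESETS["us_1998"]
    delta = intake_to_increment(scenario.added_intake_ug_day, params)
    n_years = window[1] - window[0] + 1
    births: dict[tuple[str, int], float] = {}
    for r in t3.itertuples(index=False):
        if r.aggregate:
            continue
        reduction = reduction_for(dists[r.country_code], delta, "quantile_bands", 5, params)
        period_births = float(r.prevented_nosupp) / (float(r.prevalence_per_1000) / 1000.0 * reduction)
        annual = max(1.0, round(period_births / n_years))
        for year in range(window[0], window[1] + 1):
            births[(r.country_code, year)] = annual
    return BirthsTable(births)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    window: tuple[int, int] = DEFAULT_WINDOW
    scenario: Scenario = SCENARIO_PRESETS["us_1998"]
    params: RiskModelParams = field(default_factory=RiskModelParams)
    births_csv: str | Path | None = None  # default: back-computed fixture
    registries_csv: str | Path | None = None  # default: packaged table
    folate_csv: str | Path | None = None
    fallback_log_sd: float | None = None  # default: median of survey log-SDs
    out_dir: str | Path = "out"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        scenario_raw = raw.pop("scenario", "us_1998")
        if isinstance(scenario_raw, str):
            scenario = SCENARIO_PRESETS[scenario_raw]
        else:
            scenario = Scenario(**scenario_raw)
        if "window" in raw:
            raw["window"] = tuple(raw["window"])
        return cls(scenario=scenario, **raw)


def run_pipeline(config: RunConfig) -> dict[str, pd.DataFrame]:
    """Assemble -> fit folate -> predict -> aggregate -> render.

    Writes ``country_impacts.csv``, ``aggregate_impacts.csv`` and
    ``provenance.log`` under ``config.out_dir`` and returns the frames.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "provenance.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setLevel(logging.INFO)
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        records = None
        if config.registries_csv is not None:
            records = annualize_registry_table(
                _validate("table1", pd.read_csv(config.registries_csv))
            )
        series = assemble_prevalence(records, config.window)
        table2 = None
        if config.folate_csv is not None:
            table2 = _validate("table2", pd.read_csv(config.folate_csv))
        dists = folate_distributions(table2, fallback_log_sd=config.fallback_log_sd)
        if config.births_csv is not None:
            births = BirthsTable.from_frame(pd.read_csv(config.births_csv))
        else:
            births = back_computed_births(config.window, config.params)
        impacts: list[ImpactResult] = []
        for country in sorted(series):
            if country not in dists:
                raise ValidationError(f"no folate distribution for {country}")
            impacts.extend(
                predict_country_impact(
                    series[country], births, dists[country], config.scenario, config.params
                )
            )
        country_table = render_report(impacts, "country_table")
        sets = eu_sets()
        agg_rows = []
        for name in ("EU15", "EU28"):
            subset = [i for i in impacts if i.country_code in sets[name]]
            agg = aggregate_impacts(subset)
            agg_rows.append({"country_set": name, **agg})
        aggregate_table = pd.DataFrame(agg_rows)
        country_table.to_csv(out_dir / "country_impacts.csv", index=False)
        aggregate_table.to_csv(out_dir / "aggregate_impacts.csv", index=False)
    finally:
        logger.removeHandler(handler)
        handler.close()
    return {"country": country_table, "aggregate": aggregate_table}
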