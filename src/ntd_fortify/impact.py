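"""Scenario accounting: prevalence series + folate + births -> prevented cases.

For each country the scenario's folate increment yields one risk-reduction
fraction (the folate surveys carry no time structure, so the reduction is
held constant over the window).  Per year, prevented pregnancies are
births * baseline_prevalence/1000 * effective_reduction, where the
effective reduction scales by the fraction of births not already protected
by supplements.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .folate import FolateDistribution
from .prevalence import CountryPrevalenceSeries
from .risk import (
    RiskModelParams,
    Scenario,
    apply_supplementation,
    intake_to_increment,
    reduction_for,
    round_half_away,
)

__all__ = [
    "BirthsTable",
    "ImpactResult",
    "predict_country_impact",
    "aggregate_impacts",
    "uniform_folate_sensitivity",
    "render_report",
]


class BirthsTable:
    """National annual births, keyed by (country_code, year)."""

    def __init__(self, births: Mapping[tuple[str, int], float]):
        self._births: dict[tuple[str, int], float] = {}
        for (country, year), n in births.items():
            if n <= 0:
                raise ValueError(f"births must be positive ({country}, {year})")
            self._births[(country, int(year))] = float(n)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BirthsTable":
        """Build from a DataFrame with columns country_code, year, births."""
        return cls(
            {
                (str(r.country_code), int(r.year)): float(r.births)
                for r in frame.itertuples(index=False)
            }
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"country_code": c, "year": y, "births": n}
            for (c, y), n in sorted(self._births.items())
        ]
        return pd.DataFrame(rows, columns=["country_code", "year", "births"])

    def get(self, country: str, year: int) -> float:
        return self._births[(country, year)]

    def countries(self) -> list[str]:
        return sorted({c for c, _ in self._births})

    def missing_years(self, country: str, years: Iterable[int]) -> list[int]:
        return [y for y in years if (country, y) not in self._births]

    def total(self, country: str) -> float:
        return sum(n for (c, _), n in self._births.items() if c == country)


@dataclass(frozen=True)
class ImpactResult:
    """One country-year under a fortification scenario.

    Conservation holds by construction:
    baseline cases = counterfactual cases + prevented.
    """

    country_code: str
    year: int
    baseline_prevalence: float  # per 1,000 births
    reduction_fraction: float  # after supplementation adjustment
    counterfactual_prevalence: float  # per 1,000 births
    births: float
    prevented_pregnancies: float

    @property
    def baseline_cases(self) -> float:
        return self.births * self.baseline_prevalence / 1000.0

    @property
    def counterfactual_cases(self) -> float:
        return self.births * self.counterfactual_prevalence / 1000.0


def predict_country_impact(
    series: CountryPrevalenceSeries,
    births: BirthsTable,
    dist: FolateDistribution,
    scenario: Scenario,
    params: RiskModelParams = RiskModelParams(),
) -> list[ImpactResult]:
    """Per-year impact of a scenario on one country.

    The reduction is computed once from the country's folate distribution
    (method and band count per the scenario), adjusted for supplementation
    coverage, then applied to every year of the prevalence series.
    """
    years = series.years()
    if not years:
        raise ValueError(f"{series.country_code}: empty prevalence series")
    gaps = births.missing_years(series.country_code, years)
    if gaps:
        raise KeyError(f"births missing for {series.country_code} years {gaps}")
    delta = intake_to_increment(scenario.added_intake_ug_day, params)
    raw = reduction_for(dist, delta, scenario.method, scenario.n_bands, params)
    eff = apply_supplementation(raw, scenario.supplementation_coverage)
    out = []
    for year in years:
        prev = series.values[year]
        n = births.get(series.country_code, year)
        out.append(
            ImpactResult(
                country_code=series.country_code,
                year=year,
                baseline_prevalence=prev,
                reduction_fraction=eff,
                counterfactual_prevalence=prev * (1.0 - eff),
                births=n,
                prevented_pregnancies=n * prev / 1000.0 * eff,
            )
        )
    return out


def aggregate_impacts(
    impacts: Iterable[ImpactResult],
    country_set: Iterable[str] | None = None,
) -> dict[str, float]:
    """Totals over a set of countries (all, if no set is given).

    Returns total prevented pregnancies, the overall percentage reduction
    (prevented over expected baseline cases), and births-weighted baseline
    and counterfactual pooled prevalences per 1,000.
    """
    impacts = list(impacts)
    if country_set is not None:
        wanted = set(country_set)
        have = {i.country_code for i in impacts}
        missing = sorted(wanted - have)
        if missing:
            raise KeyError(f"no impact results for countries {missing}")
        impacts = [i for i in impacts if i.country_code in wanted]
    if not impacts:
        raise ValueError("no impact results to aggregate")
    births = sum(i.births for i in impacts)
    baseline = sum(i.baseline_cases for i in impacts)
    counterfactual = sum(i.counterfactual_cases for i in impacts)
    prevented = sum(i.prevented_pregnancies for i in impacts)
    return {
        "total_births": births,
        "baseline_cases": baseline,
        "counterfactual_cases": counterfactual,
        "total_prevented": prevented,
        "percent_reduction": 100.0 * prevented / baseline,
        "baseline_prevalence": 1000.0 * baseline / births,
        "counterfactual_prevalence": 1000.0 * counterfactual / births,
    }


def uniform_folate_sensitivity(
    series_by_country: Mapping[str, CountryPrevalenceSeries],
    births: BirthsTable,
    dists: Mapping[str, FolateDistribution],
    pooled_median: float,
    scenario: Scenario,
    params: RiskModelParams = RiskModelParams(),
    sigma_override: float | None = None,
) -> dict[str, float]:
    """Aggregate impact with every country's median set to the pooled median.

    Sensitivity check on the heterogeneous, often thin folate surveys:
    country medians are replaced by the births-weighted European median
    while each country keeps its own log-scale SD (or ``sigma_override``).
    """
    if pooled_median <= 0:
        raise ValueError("pooled median must be positive")
    impacts: list[ImpactResult] = []
    for country, series in series_by_country.items():
        sigma = (
            sigma_override if sigma_override is not None else dists[country].sigma_log
        )
        dist = FolateDistribution(pooled_median, sigma)
        impacts.extend(predict_country_impact(series, births, dist, scenario, params))
    return aggregate_impacts(impacts)


def render_report(
    impacts: Iterable[ImpactResult],
    style: str = "country_table",
    rounding: bool = True,
) -> pd.DataFrame:
    """Tabulate impacts, one row per country (or one aggregate row).

    Columns mirror the reporting convention: baseline prevalence, prevalence
    with fortification, percentage reduction, prevented pregnancies.  With
    ``rounding`` the percentage is rounded half-away-from-zero to a whole
    percent and prevented counts to integers; otherwise full precision.
    """
    impacts = list(impacts)
    if not impacts:
        raise ValueError("no impact results to report")
    if style not in ("country_table", "aggregate"):
        raise ValueError(f"unknown report style {style!r}")

    def row(label: str, subset: list[ImpactResult]) -> dict:
        agg = aggregate_impacts(subset)
        pct = agg["percent_reduction"]
        prevented = agg["total_prevented"]
        return {
            "country_code": label,
            "baseline_prevalence": round(agg["baseline_prevalence"], 2)
            if rounding
            else agg["baseline_prevalence"],
            "fortified_prevalence": round(agg["counterfactual_prevalence"], 2)
            if rounding
            else agg["counterfactual_prevalence"],
            "percent_reduction": round_half_away(pct) if rounding else pct,
            "prevented_pregnancies": round_half_away(prevented)
            if rounding
            else prevented,
        }

    if style == "aggregate":
        rows = [row("ALL", impacts)]
    else:
        countries = sorted({i.country_code for i in impacts})
        rows = [
            row(c, [i for i in impacts if i.country_code == c]) for c in countries
        ]
    return pd.DataFrame(
        rows,
        columns=[
            "country_code",
            "baseline_prevalence",
            "fortified_prevalence",
            "percent_reduction",
            "prevented_pregnancies",
        ],
    )
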