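"""Assembly of per-country annual NTD prevalence from registry observations.

Congenital-anomaly registries cover part of a country's births for part of
the study window.  Per year, registries reporting for the same country are
pooled (total cases over total covered births); missing years are imputed
from the mean of up to three nearest observed years (prevalence has been
flat over the period, so carrying local averages is defensible); countries
with no registry borrow a neighbour's series.  Every filled value carries a
provenance tag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "RegistryRecord",
    "CountryPrevalenceSeries",
    "pool_registries",
    "impute_missing_years",
    "borrow_countries",
    "pooled_prevalence",
]


@dataclass(frozen=True)
class RegistryRecord:
    """One registry's NTD cases and covered births for one calendar year.

    Cases count NTD pregnancies: live births, fetal deaths >= 20 weeks and
    terminations for fetal anomaly, excluding known genetic conditions.
    """

    registry_name: str
    country_code: str
    year: int
    cases: int
    births_covered: int

    def __post_init__(self) -> None:
        if self.cases < 0:
            raise ValueError("cases must be nonnegative")
        if self.births_covered <= 0:
            raise ValueError("births_covered must be positive")
        if self.cases > self.births_covered:
            raise ValueError(
                f"{self.registry_name} {self.year}: cases exceed covered births"
            )


@dataclass
class CountryPrevalenceSeries:
    """Per-year NTD prevalence (per 1,000 births) for one country.

    ``provenance[year]`` is one of ``observed``, ``imputed_prev3``,
    ``imputed_next3`` or ``borrowed:<source>``.
    """

    country_code: str
    values: dict[int, float] = field(default_factory=dict)
    provenance: dict[int, str] = field(default_factory=dict)

    def observed_years(self) -> list[int]:
        return sorted(y for y, p in self.provenance.items() if p == "observed")

    def years(self) -> list[int]:
        return sorted(self.values)

    def set(self, year: int, prevalence: float, provenance: str) -> None:
        if prevalence < 0:
            raise ValueError("prevalence must be nonnegative")
        self.values[year] = float(prevalence)
        self.provenance[year] = provenance

    def mean_prevalence(self) -> float:
        if not self.values:
            raise ValueError(f"{self.country_code}: empty series")
        return float(np.mean(list(self.values.values())))

    def copy_as(self, country_code: str, provenance: str) -> "CountryPrevalenceSeries":
        return CountryPrevalenceSeries(
            country_code,
            dict(self.values),
            {y: provenance for y in self.values},
        )


def pooled_prevalence(total_cases: float, total_births: float) -> float:
    """NTD prevalence per 1,000 births from aggregate counts."""
    if total_births <= 0:
        raise ValueError("total births must be positive")
    if total_cases < 0:
        raise ValueError("cases must be nonnegative")
    return 1000.0 * total_cases / total_births


def pool_registries(
    records: Iterable[RegistryRecord],
    window: tuple[int, int] | None = None,
) -> CountryPrevalenceSeries:
    """Pool same-country registries into an observed annual prevalence series.

    For each year with at least one reporting registry, prevalence is
    1000 * (sum of cases) / (sum of covered births) over the registries
    reporting that year.  Splitting a registry's counts into sub-records
    with the same totals leaves the result unchanged.
    """
    records = list(records)
    if not records:
        return CountryPrevalenceSeries(country_code="")
    countries = {r.country_code for r in records}
    if len(countries) > 1:
        raise ValueError(f"records span multiple countries: {sorted(countries)}")
    series = CountryPrevalenceSeries(country_code=records[0].country_code)
    cases: dict[int, int] = {}
    births: dict[int, int] = {}
    for r in records:
        if window is not None and not (window[0] <= r.year <= window[1]):
            continue
        cases[r.year] = cases.get(r.year, 0) + r.cases
        births[r.year] = births.get(r.year, 0) + r.births_covered
    for year in sorted(cases):
        series.set(year, pooled_prevalence(cases[year], births[year]), "observed")
    return series


def impute_missing_years(
    series: CountryPrevalenceSeries,
    window: tuple[int, int],
) -> CountryPrevalenceSeries:
    """Fill every missing year in the window from nearby years.

    A missing year takes the mean prevalence of up to three nearest
    preceding filled years; years before the first observation take the
    mean of up to three nearest following filled years.  Imputed values may
    feed later imputations (required to bridge multi-year gaps).  Running
    on a complete series is a no-op.
    """
    if not series.values:
        raise ValueError(f"{series.country_code}: no observed years to impute from")
    out = CountryPrevalenceSeries(
        series.country_code, dict(series.values), dict(series.provenance)
    )
    first, last = window
    # Forward pass: interior and trailing gaps from preceding years.
    for year in range(first, last + 1):
        if year in out.values:
            continue
        preceding = sorted(y for y in out.values if y < year)[-3:]
        if preceding:
            out.set(
                year,
                float(np.mean([out.values[y] for y in preceding])),
                "imputed_prev3",
            )
    # Backward pass: leading gap from following years.
    for year in range(last, first - 1, -1):
        if year in out.values:
            continue
        following = sorted(y for y in out.values if y > year)[:3]
        if not following:  # unreachable once the forward pass ran
            raise ValueError(f"{series.country_code}: cannot impute {year}")
        out.set(
            year,
            float(np.mean([out.values[y] for y in following])),
            "imputed_next3",
        )
    return out


def borrow_countries(
    series_by_country: Mapping[str, CountryPrevalenceSeries],
    borrowing_map: Mapping[str, Sequence[str]],
) -> dict[str, CountryPrevalenceSeries]:
    """Give registry-less countries a neighbour's prevalence series.

    Each target receives its single source's series, or the year-wise
    unweighted mean of several sources' series, with provenance marked
    ``borrowed:<sources>``.  Source series must already be complete.
    """
    out = dict(series_by_country)
    for target, sources in borrowing_map.items():
        sources = list(sources)
        missing = [s for s in sources if s not in series_by_country]
        if missing:
            raise KeyError(
                f"borrowing for {target}: source series missing for {missing}"
            )
        tag = "borrowed:" + ";".join(sources)
        if len(sources) == 1:
            out[target] = series_by_country[sources[0]].copy_as(target, tag)
            continue
        year_sets = [set(series_by_country[s].values) for s in sources]
        years = sorted(set.intersection(*year_sets))
        if not years:
            raise KeyError(f"borrowing for {target}: sources share no years")
        borrowed = CountryPrevalenceSeries(target)
        for y in years:
            borrowed.set(
                y,
                float(np.mean([series_by_country[s].values[y] for s in sources])),
                tag,
            )
        out[target] = borrowed
    return out
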