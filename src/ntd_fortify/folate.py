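"""Log-normal serum-folate distributions.

Population serum folate is modelled as log-Gaussian: if F is serum folate
(nmol/L) then ln F ~ Normal(ln m, sigma^2), where m is the population median
and sigma the SD on the natural-log scale.  Published surveys report either
the median directly or an arithmetic mean and SD; the latter are inverted to
(m, sigma) by log-normal moment matching, either in closed form or by
simulation search.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import norm

__all__ = [
    "NMOL_PER_NG_ML",
    "ConfigurationError",
    "ConvergenceError",
    "FolateSurvey",
    "FolateDistribution",
    "convert_units",
    "fit_lognormal_closed_form",
    "fit_lognormal_by_search",
    "fit_survey",
    "default_log_sd",
    "quantile_band_medians",
    "pooled_median",
]

#: nmol/L of serum folate per ng/mL (folic acid molar mass 441.4 g/mol).
NMOL_PER_NG_ML = 2.2655


class ConfigurationError(ValueError):
    """Invalid configuration (unknown unit tag, bad option value)."""


class ConvergenceError(RuntimeError):
    """A moment-matching search failed to reach its tolerance."""


# Canonical unit tags; ng/mL and ug/L denote the same mass concentration.
_UNIT_CANON = {
    "ng/ml": "ng/mL",
    "ug/l": "ng/mL",
    "µg/l": "ng/mL",
    "μg/l": "ng/mL",
    "nmol/l": "nmol/L",
}


def _canon_unit(tag: str) -> str:
    try:
        return _UNIT_CANON[tag.strip().lower()]
    except KeyError:
        raise ConfigurationError(
            f"unknown serum-folate unit {tag!r}; expected one of ng/mL, ug/L, nmol/L"
        ) from None


def convert_units(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a serum-folate concentration between ng/mL (= ug/L) and nmol/L.

    Uses 2.2655 nmol/L per ng/mL, so 1.88 ng/mL = 4.26 nmol/L (3 s.f.),
    the increment produced by US-level fortification.
    """
    if value < 0:
        raise ValueError(f"concentration must be nonnegative, got {value}")
    src, dst = _canon_unit(from_unit), _canon_unit(to_unit)
    if src == dst:
        return float(value)
    if src == "ng/mL":  # -> nmol/L
        return float(value) * NMOL_PER_NG_ML
    return float(value) / NMOL_PER_NG_ML


@dataclass(frozen=True)
class FolateSurvey:
    """One published serum-folate survey summary for a country.

    ``statistic_kind`` says whether ``location_value`` is the population
    median or the arithmetic mean; ``dispersion_value`` is an SD on that
    same (linear) scale while ``log_sd`` is an SD of natural-log folate.
    """

    country_code: str
    statistic_kind: str  # "median" | "arithmetic_mean"
    location_value: float
    location_unit: str = "nmol/L"
    dispersion_value: float | None = None
    log_sd: float | None = None
    source_label: str = ""
    estimated_from_prevalence: bool = False

    def __post_init__(self) -> None:
        if self.statistic_kind not in ("median", "arithmetic_mean"):
            raise ValueError(f"unknown statistic_kind {self.statistic_kind!r}")
        if self.location_value <= 0:
            raise ValueError("location_value must be positive")
        if self.dispersion_value is not None and self.dispersion_value < 0:
            raise ValueError("dispersion_value must be nonnegative")
        if self.log_sd is not None and self.log_sd < 0:
            raise ValueError("log_sd must be nonnegative")
        _canon_unit(self.location_unit)

    @property
    def location_nmol_l(self) -> float:
        return convert_units(self.location_value, self.location_unit, "nmol/L")

    @property
    def dispersion_nmol_l(self) -> float | None:
        if self.dispersion_value is None:
            return None
        return convert_units(self.dispersion_value, self.location_unit, "nmol/L")


@dataclass(frozen=True)
class FolateDistribution:
    """A log-normal serum-folate distribution: median m, log-scale SD sigma."""

    median_nmol_l: float
    sigma_log: float

    def __post_init__(self) -> None:
        if self.median_nmol_l <= 0:
            raise ValueError("median_nmol_l must be positive")
        if self.sigma_log < 0:
            raise ValueError("sigma_log must be nonnegative")

    @property
    def mu_log(self) -> float:
        """Mean of ln(folate)."""
        return math.log(self.median_nmol_l)

    def quantile(self, p):
        """q(p) = m * exp(sigma * Phi^-1(p)); strictly increasing for sigma>0."""
        return self.median_nmol_l * np.exp(self.sigma_log * norm.ppf(p))

    def arithmetic_mean(self) -> float:
        return self.median_nmol_l * math.exp(self.sigma_log**2 / 2)

    def arithmetic_sd(self) -> float:
        s2 = self.sigma_log**2
        return self.arithmetic_mean() * math.sqrt(math.expm1(s2))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return self.median_nmol_l * np.exp(self.sigma_log * rng.standard_normal(n))


def fit_lognormal_closed_form(mean: float, sd: float) -> FolateDistribution:
    """Moment-match a log-normal to an arithmetic mean and SD, exactly.

    With cv = sd/mean:  sigma = sqrt(ln(1 + cv^2)),  median = mean/sqrt(1+cv^2).
    The resulting distribution has arithmetic mean and SD equal to the inputs.
    """
    if mean <= 0:
        raise ValueError(f"arithmetic mean must be positive, got {mean}")
    if sd < 0:
        raise ValueError(f"arithmetic SD must be nonnegative, got {sd}")
    cv2 = (sd / mean) ** 2
    sigma = math.sqrt(math.log1p(cv2))
    median = mean / math.sqrt(1.0 + cv2)
    return FolateDistribution(median, sigma)


def fit_lognormal_by_search(
    mean: float,
    sd: float,
    tolerance: float = 1e-3,
    seed: int = 0,
    n_draws: int = 500_000,
    max_iter: int = 100,
) -> FolateDistribution:
    """Moment-match by simulation search, mirroring fitting-by-simulation.

    Candidate (median, sigma) pairs are scored by the arithmetic mean and SD
    of simulated draws until both match the published values.  Common random
    numbers (antithetic standard normals, fixed by ``seed``) make the search
    deterministic: for draws z, the simulated mean of m*exp(sigma*z) factors
    as m*A(sigma) and the SD as m*B(sigma), so sigma solves
    B(sigma)/A(sigma) = sd/mean (bisection; CV is increasing in sigma) and
    the median then rescales to match the mean.
    """
    if mean <= 0:
        raise ValueError(f"arithmetic mean must be positive, got {mean}")
    if sd < 0:
        raise ValueError(f"arithmetic SD must be nonnegative, got {sd}")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    if sd == 0:
        return FolateDistribution(mean, 0.0)

    rng = np.random.default_rng(seed)
    half = rng.standard_normal(n_draws // 2)
    z = np.concatenate([half, -half])

    def simulated_cv(sigma: float) -> float:
        x = np.exp(sigma * z)
        return float(np.std(x) / np.mean(x))

    target_cv = sd / mean
    lo, hi = 0.0, 1.0
    for _ in range(max_iter):
        if simulated_cv(hi) >= target_cv:
            break
        hi *= 2.0
    else:
        raise ConvergenceError(
            f"could not bracket sigma for mean={mean}, sd={sd}"
        )
    sigma = 0.5 * (lo + hi)
    for _ in range(max_iter):
        sigma = 0.5 * (lo + hi)
        if simulated_cv(sigma) < target_cv:
            lo = sigma
        else:
            hi = sigma
        if hi - lo < 1e-12:
            break
    x = np.exp(sigma * z)
    median = mean / float(np.mean(x))
    sim_mean = median * float(np.mean(x))
    sim_sd = median * float(np.std(x))
    if abs(sim_mean - mean) > tolerance * mean or abs(sim_sd - sd) > tolerance * sd:
        raise ConvergenceError(
            f"simulation search did not match mean={mean}, sd={sd} "
            f"within {tolerance:.1e} (got mean={sim_mean:.6g}, sd={sim_sd:.6g})"
        )
    return FolateDistribution(median, sigma)


def fit_survey(
    survey: FolateSurvey,
    fallback_log_sd: float | None = None,
    method: str = "closed_form",
    **search_kwargs,
) -> FolateDistribution:
    """Turn one survey summary into a FolateDistribution (nmol/L).

    Median-form surveys use the reported median and log-SD (or
    ``fallback_log_sd`` when the survey carries none); mean/SD-form surveys
    are inverted by moment matching.
    """
    if survey.statistic_kind == "median":
        sigma = survey.log_sd
        if sigma is None:
            if fallback_log_sd is None:
                raise ValueError(
                    f"survey for {survey.country_code} has no log-scale SD and "
                    "no fallback was supplied"
                )
            sigma = fallback_log_sd
        return FolateDistribution(survey.location_nmol_l, sigma)
    if survey.dispersion_nmol_l is None:
        raise ValueError(
            f"mean-form survey for {survey.country_code} requires an SD"
        )
    fit = (
        fit_lognormal_closed_form
        if method == "closed_form"
        else fit_lognormal_by_search
    )
    return fit(survey.location_nmol_l, survey.dispersion_nmol_l, **search_kwargs)


def default_log_sd(surveys: Iterable[FolateSurvey]) -> float:
    """Median of the log-scale SDs present across surveys.

    Used to fill in countries whose survey reports a median but no
    dispersion (midpoint rule for an even count).
    """
    sds = [s.log_sd for s in surveys if s.log_sd is not None]
    if not sds:
        raise ValueError("no survey carries a log-scale SD")
    return float(np.median(sds))


def quantile_band_medians(dist: FolateDistribution, k: int) -> np.ndarray:
    """Medians of the k equal-probability bands of the distribution.

    Band i (1-based) covers probability ((i-1)/k, i/k); its median sits at
    p_i = (2i-1)/(2k), so the band medians are m*exp(sigma*Phi^-1(p_i)).
    k=5 gives the quintile medians used to average risk over the folate
    distribution.
    """
    if k < 1:
        raise ValueError(f"number of bands must be >= 1, got {k}")
    p = (2 * np.arange(1, k + 1) - 1) / (2 * k)
    return np.asarray(dist.quantile(p), dtype=float)


def pooled_median(
    dists: Mapping[str, FolateDistribution],
    weights: Mapping[str, float],
) -> float:
    """Weighted median of country medians (weights = births, typically).

    Each country's median enters with its weight; the weighted median uses
    the midpoint rule when the half-weight point falls exactly between two
    values.
    """
    items = []
    for country, w in weights.items():
        if w < 0:
            raise ValueError(f"negative weight for {country}")
        if w == 0:
            continue
        if country not in dists:
            raise KeyError(f"no folate distribution for weighted country {country}")
        items.append((dists[country].median_nmol_l, float(w)))
    if not items:
        raise ValueError("weights are all zero")
    items.sort()
    values = np.array([v for v, _ in items])
    cum = np.cumsum([w for _, w in items])
    half = cum[-1] / 2.0
    idx = int(np.searchsorted(cum, half))
    if math.isclose(cum[idx], half) and idx + 1 < len(values):
        return float((values[idx] + values[idx + 1]) / 2.0)
    return float(values[idx])
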