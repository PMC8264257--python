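"""Scenario accounting: prevented-case arithmetic, aggregation, reports."""

import numpy as np
import pytest

import ntd_fortify as nf
from ntd_fortify.prevalence import CountryPrevalenceSeries


def series_for(country, prevalence, years=range(1998, 2018)):
    s = CountryPrevalenceSeries(country)
    for y in years:
        s.set(y, prevalence, "observed")
    return s


def births_for(countries, annual, years=range(1998, 2018)):
    return nf.BirthsTable({(c, y): annual for c in countries for y in years})


def flat_dist_with_reduction(target_reduction, delta):
    """Median (sigma=0) chosen so the median-method reduction equals target."""
    m = delta / ((1.0 - target_reduction) ** (1.0 / -0.81) - 1.0)
    return nf.FolateDistribution(m, 0.0)


class TestPredictCountryImpact:
    def test_known_reduction_arithmetic(self):
        scenario = nf.Scenario(200.0, method="median")
        delta = nf.intake_to_increment(200.0)
        dist = flat_dist_with_reduction(0.20, delta)
        impacts = nf.predict_country_impact(
            series_for("AA", 1.0, [2000]), births_for(["AA"], 100_000, [2000]),
            dist, scenario,
        )
        assert impacts[0].prevented_pregnancies == pytest.approx(20.0, rel=1e-9)

    def test_supplementation_scales_prevented(self):
        delta = nf.intake_to_increment(200.0)
        dist = flat_dist_with_reduction(0.20, delta)
        scenario = nf.Scenario(200.0, supplementation_coverage=0.25, method="median")
        impacts = nf.predict_country_impact(
            series_for("AA", 1.0, [2000]), births_for(["AA"], 100_000, [2000]),
            dist, scenario,
        )
        assert impacts[0].prevented_pregnancies == pytest.approx(15.0, rel=1e-9)

    def test_denmark_fixture_rounds_to_published_percentages(self, table2_dists):
        births = births_for(["DK"], 60_000)
        for coverage, expected in [(0.0, 28), (0.25, 21)]:
            impacts = nf.predict_country_impact(
                series_for("DK", 1.12), births, table2_dists["DK"],
                nf.Scenario(200.0, supplementation_coverage=coverage),
            )
            pct = nf.round_half_away(100 * impacts[0].reduction_fraction)
            assert pct == expected

    def test_missing_births_year_lists_gaps(self, table2_dists):
        with pytest.raises(KeyError, match="2001"):
            nf.predict_country_impact(
                series_for("DK", 1.12, [2000, 2001]),
                births_for(["DK"], 60_000, [2000]),
                table2_dists["DK"], nf.Scenario(200.0),
            )

    def test_conservation_per_country_year(self, table2_dists):
        impacts = nf.predict_country_impact(
            series_for("IT", 0.57), births_for(["IT"], 500_000),
            table2_dists["IT"], nf.Scenario(200.0, supplementation_coverage=0.25),
        )
        for i in impacts:
            assert i.baseline_cases == pytest.approx(
                i.counterfactual_cases + i.prevented_pregnancies, rel=1e-12
            )
            assert i.counterfactual_prevalence == pytest.approx(
                i.baseline_prevalence * (1 - i.reduction_fraction), rel=1e-12
            )


class TestAggregation:
    def impacts_pair(self, reductions, annual_births=100_000):
        """Two countries with equal baseline cases and the given reductions."""
        delta = nf.intake_to_increment(200.0)
        out = []
        for code, r in zip(("AA", "BB"), reductions):
            dist = flat_dist_with_reduction(r, delta)
            out += nf.predict_country_impact(
                series_for(code, 1.0, [2000]),
                births_for([code], annual_births, [2000]),
                dist, nf.Scenario(200.0, method="median"),
            )
        return out

    def test_single_country_equals_own_reduction(self, table2_dists):
        impacts = nf.predict_country_impact(
            series_for("BE", 0.75), births_for(["BE"], 120_000),
            table2_dists["BE"], nf.Scenario(200.0),
        )
        agg = nf.aggregate_impacts(impacts)
        assert agg["percent_reduction"] == pytest.approx(
            100 * impacts[0].reduction_fraction, rel=1e-12
        )

    def test_equal_case_weights_average_reductions(self):
        agg = nf.aggregate_impacts(self.impacts_pair([0.10, 0.30]))
        assert agg["percent_reduction"] == pytest.approx(20.0, rel=1e-9)

    def test_country_set_filter_and_missing_country(self):
        impacts = self.impacts_pair([0.10, 0.30])
        only_a = nf.aggregate_impacts(impacts, {"AA"})
        assert only_a["percent_reduction"] == pytest.approx(10.0, rel=1e-9)
        with pytest.raises(KeyError):
            nf.aggregate_impacts(impacts, {"AA", "ZZ"})

    def test_scaling_births_scales_prevented_not_percentages(self):
        small = nf.aggregate_impacts(self.impacts_pair([0.10, 0.30], 100_000))
        large = nf.aggregate_impacts(self.impacts_pair([0.10, 0.30], 200_000))
        assert large["total_prevented"] == pytest.approx(
            2 * small["total_prevented"], rel=1e-12
        )
        assert large["percent_reduction"] == pytest.approx(
            small["percent_reduction"], rel=1e-12
        )

    def test_supplementation_linearity_exact(self, table2_dists):
        births = nf.back_computed_births()
        series = nf.assemble_prevalence()
        totals = {}
        for cov in (0.0, 0.25):
            impacts = []
            for c in sorted(series):
                impacts += nf.predict_country_impact(
                    series[c], births, table2_dists[c],
                    nf.Scenario(200.0, supplementation_coverage=cov),
                )
            totals[cov] = nf.aggregate_impacts(impacts)["total_prevented"]
        assert totals[0.25] == pytest.approx(0.75 * totals[0.0], rel=1e-12)

    def test_eu28_aggregate_near_published_range(self, table2_dists):
        """On the approximate back-computed births the EU28 reduction lands
        near the published 21% (no supplements) and 15% (25% coverage)."""
        births = nf.back_computed_births()
        series = nf.assemble_prevalence()
        eu28 = nf.eu_sets()["EU28"]
        for cov, published in [(0.0, 21.0), (0.25, 15.0)]:
            impacts = []
            for c in sorted(eu28):
                impacts += nf.predict_country_impact(
                    series[c], births, table2_dists[c],
                    nf.Scenario(200.0, supplementation_coverage=cov),
                )
            agg = nf.aggregate_impacts(impacts, eu28)
            assert abs(agg["percent_reduction"] - published) < 1.5
        assert agg["baseline_prevalence"] == pytest.approx(0.92, abs=0.01)


class TestChileScenario:
    def test_higher_fortification_prevents_strictly_more_everywhere(
        self, table2_dists
    ):
        births = nf.back_computed_births()
        series = nf.assemble_prevalence()
        us, chile = nf.SCENARIO_PRESETS["us_1998"], nf.SCENARIO_PRESETS["chile"]
        for c in sorted(series):
            a = nf.predict_country_impact(series[c], births, table2_dists[c], us)
            b = nf.predict_country_impact(series[c], births, table2_dists[c], chile)
            assert sum(i.prevented_pregnancies for i in b) > sum(
                i.prevented_pregnancies for i in a
            ), c


class TestUniformFolateSensitivity:
    def test_pooled_median_equal_to_actual_is_identity(self, table2_dists):
        births = births_for(["DK"], 60_000)
        series = {"DK": series_for("DK", 1.12)}
        base = nf.aggregate_impacts(
            nf.predict_country_impact(
                series["DK"], births, table2_dists["DK"], nf.Scenario(200.0)
            )
        )
        sens = nf.uniform_folate_sensitivity(
            series, births, table2_dists, table2_dists["DK"].median_nmol_l,
            nf.Scenario(200.0),
        )
        assert sens["total_prevented"] == pytest.approx(
            base["total_prevented"], rel=1e-12
        )

    def test_european_median_reproduces_published_sensitivity(self, table2_dists):
        """All countries at median 14.1 nmol/L, sigma 0.50: reductions round
        to 20% (no supplements) and 15% (25% coverage)."""
        births = nf.back_computed_births()
        series = nf.assemble_prevalence()
        for cov, expected in [(0.0, 20), (0.25, 15)]:
            sens = nf.uniform_folate_sensitivity(
                series, births, table2_dists, 14.1,
                nf.Scenario(200.0, supplementation_coverage=cov),
                sigma_override=0.50,
            )
            assert nf.round_half_away(sens["percent_reduction"]) == expected

    def test_full_coverage_prevents_nothing(self, table2_dists):
        births = births_for(["DK"], 60_000)
        series = {"DK": series_for("DK", 1.12)}
        sens = nf.uniform_folate_sensitivity(
            series, births, table2_dists, 14.1,
            nf.Scenario(200.0, supplementation_coverage=1.0),
        )
        assert sens["total_prevented"] == 0.0


class TestRenderReport:
    def test_denmark_row_prints_published_percentage(self, table2_dists):
        impacts = nf.predict_country_impact(
            series_for("DK", 1.12), births_for(["DK"], 60_000),
            table2_dists["DK"], nf.Scenario(200.0),
        )
        table = nf.render_report(impacts)
        row = table[table["country_code"] == "DK"].iloc[0]
        assert row["percent_reduction"] == 28
        assert row["baseline_prevalence"] == pytest.approx(1.12)

    def test_empty_impacts_rejected(self):
        with pytest.raises(ValueError):
            nf.render_report([])

    def test_rounding_off_emits_full_precision(self, table2_dists):
        impacts = nf.predict_country_impact(
            series_for("DK", 1.12), births_for(["DK"], 60_000),
            table2_dists["DK"], nf.Scenario(200.0),
        )
        table = nf.render_report(impacts, rounding=False)
        pct = table.iloc[0]["percent_reduction"]
        assert pct != round(pct)  # genuinely unrounded
        assert pct == pytest.approx(28.06, abs=0.05)

    def test_aggregate_style_single_row(self, table2_dists):
        impacts = nf.predict_country_impact(
            series_for("DK", 1.12), births_for(["DK"], 60_000),
            table2_dists["DK"], nf.Scenario(200.0),
        )
        table = nf.render_report(impacts, style="aggregate")
        assert len(table) == 1
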