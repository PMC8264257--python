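# Methods

## Model

The pipeline estimates, per country and year, the NTD pregnancies that
mandatory folic-acid flour fortification would have prevented. It rests on
three empirical inputs: (i) serum folate in women of childbearing age is
log-Gaussian within a population; (ii) serum folate rises linearly with
folic-acid intake at 0.94 ng/mL per 0.1 mg/day; (iii) NTD risk scales with
serum folate as a power law, so the prevalence ratio after an increment Δ at
baseline folate f is ((f+Δ)/f)^−0.81. All three are treated as fixed point
estimates; no uncertainty intervals are propagated.

The effect of fortification is assumed constant over the 1998–2017 window
(the folate surveys carry no time structure, and European NTD prevalence has
been flat over the period), and supplementation is modelled as a fraction of
births that receives no additional benefit — an all-or-nothing
simplification.

## Folate distribution estimation

Surveys report a median (sometimes with a log-scale SD) or an arithmetic
mean and SD. Mean/SD summaries are inverted to the log-normal (median m,
log-SD σ) by moment matching. The default is the closed form
σ = √ln(1+(sd/mean)²), m = mean/√(1+(sd/mean)²), which is exact. A
simulation-search mode is retained for fidelity to fitting-by-simulation
practice: with common antithetic normal draws, the simulated coefficient of
variation is monotone in σ, so σ is found by bisection and m by rescaling;
the two modes agree within twice the search tolerance, and a test asserts
this. Surveys with a median but no SD receive the median of the SDs
observed across surveys (0.50 on the packaged table, configurable);
countries with no survey inherit another country's distribution through an
editable borrowing table rather than hard-coded rules.

Unit handling: ng/mL and μg/L are the same mass concentration; the molar
conversion is fixed at 2.2655 nmol/L per ng/mL (folic acid 441.4 g/mol),
consistent with the 1.88 ng/mL ↔ 4.26 nmol/L pairing of the fortification
increment.

## Averaging risk over the distribution

Because the same increment helps folate-poor women more, the reduction is
averaged over the distribution by the quintile-median method: evaluate the
prevalence ratio at the five band medians m·exp(σ·Φ⁻¹((2i−1)/10)) and take
the unweighted mean (each band holds 20% of women). The band count k is
configurable; as k → ∞ the band mean converges to the exact expectation,
which the tests verify against Gauss–Hermite quadrature (k = 2000 agrees to
≤1e−3). The simpler median-only method is provided and typically agrees to
the nearest percentage point; the quantile-band method is the reporting
default because it reproduces more of the published per-country table. A
third, baseline-risk-weighted band mean (weights ∝ fᵢ^−0.81, i.e. the
reduction in cases rather than in mean individual risk) is available but is
not used for reporting. One published cell (Austria, 25%) matches neither
the band (24.3%) nor the median (22.5%) method at k = 5; we record this as
an unresolved discrepancy of the source table.

Reported percentages are rounded half-away-from-zero to whole percent;
prevented counts are real-valued expectations, reported rounded and
unrounded.

## Prevalence assembly

Within a country, registries reporting in a given year are pooled as
Σcases/Σcovered births — invariant to splitting a registry into
sub-records. Missing years take the mean of up to three nearest preceding
filled years; years before the first observation take the mean of up to
three nearest following years. Preceding years take precedence, interior
gaps use preceding years only, and imputed values may cascade into later
imputations (required to bridge multi-year gaps); every filled year is
tagged with its provenance, and imputation is idempotent on complete
series. Countries without registries either borrow a series (single source,
or the year-wise unweighted mean of several) or carry a literature
prevalence directly. Registry coverage fractions are metadata only; national
births always come from the births table.

## Births and the approximate fixture

National annual births are a user input. For demonstrations the package
back-computes an approximate births table from the published per-country
impact figures by inverting prevented = births × prevalence/1000 ×
reduction, using the unrounded quintile-band reduction, and spreading the
period total evenly across years. This synthetic table reproduces the
published aggregate prevalence (0.92 per 1,000) and the supplementation
scenario's prevented total to within a fraction of a percent, but absolute
headline counts are demonstrated, not asserted: they depend on the original
per-country-year births extract, which is not published. Whether the
original aggregates weighted countries by annual or period-total births is
unknown; we weight by annual births.

## Synthetic data

The generator draws country medians uniformly on [7, 19] nmol/L, log-SDs on
[0.3, 0.8] and prevalences on [0.4, 1.8] per 1,000 — ranges spanning the
observed European tables — with annual births on [20,000, 800,000] and
optional linking of prevalence to the folate median through the same
power law. Registry observations are Poisson in the covered births
(prevalences near 1/1,000 make the binomial distinction negligible, and
Poisson is standard registry practice); surveys report the arithmetic mean
and SD of individual log-normal draws — exactly the publication form the
moment-matching fitters must invert. All randomness flows through one
seeded generator per operation, and seeds are recorded in outputs.

The generator emulates sampling noise only: no secular trends, no
measurement error beyond sampling, no within-country heterogeneity in
supplement use, and registry coverage that is exact rather than estimated.
Passing recovery tests therefore show the pipeline's arithmetic and fitting
are correct under the model's own assumptions, not that the assumptions
hold in real registry data.

End-to-end recovery tests run 50 simulated worlds of 5 countries, 20 years,
full registry coverage and 10⁴-subject surveys, and require the estimated
total of prevented pregnancies to fall within 5% of the analytic ground
truth (Gauss–Hermite quadrature over the true folate density, 201 nodes —
a problem size that keeps the whole suite under a few seconds while leaving
Poisson noise as the dominant error term).

## Numerical choices and degenerate inputs

σ = 0 collapses every method to the median method. Zero added intake or
full supplement coverage gives exactly zero reduction and prevented counts.
The weighted median of country medians uses the midpoint rule when the
half-weight point falls on a boundary. Band representative points are
p = (2i−1)/(2k), the within-band medians. The simulation search brackets σ
by doubling and bisects to 1e−12, raising a convergence error naming its
inputs if the target dispersion cannot be bracketed. Validation rejects
non-positive medians, negative SDs, coverages outside [0, 1], cases
exceeding covered births, and registry files spanning multiple countries.

## Known limitations

Serum-folate surveys are sparse, often single-timepoint and small; several
countries borrow values outright. One country's folate level (flagged
`estimated_from_prevalence` in the fixture) was derived from its NTD
prevalence rather than measured, and the exact reference used for that
inversion is not recoverable; `folate_from_prevalence_ratio` implements the
inversion but reproduction of that cell is not guaranteed. Per-registry
annual case counts were never published; the packaged registry fixture
spreads period totals uniformly over active years and is suitable for
integration demonstrations only. The dose-response parameters are applied
outside the folate range in which they were estimated for the lowest-folate
populations.
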