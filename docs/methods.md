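# Methods

## The model

The unit of analysis is the household of one medical traveler. An
episode of overseas treatment has itemized costs over ten components
(direct medical care; travel in the home country; airfare; travel in
the destination country; entertainment; lodging; food; visa; foreign
exchange; other), each split by payer. Only direct medical care and the
airfare can carry a government subsidy — the benefit package covers
nothing else — so every other component is out-of-pocket by
construction, and the data model enforces this.

All money is held internally as integer US cents, which makes sums
associative and the CSV round trip bit-exact; rendering is USD with two
decimals. No discounting or currency conversion is applied (a single
survey year, all amounts nominal USD).

**Visit total and payer split.** The visit total is the sum over all
components and both payers. Productivity loss is excluded from every
total: it is an income loss, not a payment, and is reported in its own
column. The subsidy share is subsidy / (subsidy + OOP), defined as 0
(and flagged) for a zero-cost visit.

**Per-capita allocation.** Caretakers bear no medical costs. Writing M
for the medical component and G for the non-medical remainder of a
visit with k caretakers, the package splits G equally over the travel
party: caretaker per-capita = G/(k+1), patient per-capita = M + G/(k+1),
so M + (k+1)·(G/(k+1)) recovers the total. The equal split is the
minimal assumption consistent with "caretakers bear no medical costs"
and is a package convention; attributing shared costs differently would
change per-capita levels but not totals.

**Productivity loss.** Loss = (hours lost per day / 8) × days abroad ×
daily income. The three-way product of hours, days and a *daily* wage is
dimensionally ambiguous unless hours are read as a fraction of a working
day; the 8-hour working day is the package's documented convention and
the divisor is configurable.

**Catastrophic expenditure.** The health budget share is monthly OOP
health spending over total monthly household expenditure (health + food
+ other). The episode's own costs are *not* amortized into the month —
no amortization rule is defined for this survey design — and exceedance
is strict (share > z), with a weak (≥) mode for sensitivity analysis.
Headcount H, overshoot O and MPO = O/H are as defined in the README;
the identity z·H + O = (mean share among exceeders)·H is tested
exactly, and H and O are non-increasing in z.

**Extrapolation.** Four strata: patients and caretakers within the
subsidized and the private groups. Annual cost per stratum is
c = a × b computed exactly in cents, a the stratum's median per-capita
cost, b its annual visits. Patient visit counts are secondary-data
inputs and carry no sampling uncertainty; caretaker visits are
round-half-up(mean party size × patient visits). When reproducing the
published four-row table the printed visit counts are taken as direct
inputs, because the published caretaker rows used unrounded means.
Uncertainty in a is propagated by a nonparametric bootstrap (default
B = 1000 resamples of size n with replacement; SD of median × visits
across replicates; SDs combined in quadrature for the total). The
median's bootstrap SE tracks the asymptotic value 1/(2·f(m)·√n) — the
test suite verifies agreement within 15 % on log-normal samples,
averaging over independent samples because a single sample's bootstrap
SE carries ±30 % sampling noise at n ≈ 350.

## Statistical tests

Costs are heavily right-skewed, so all comparisons are nonparametric.

* **Rank-sum** (two groups): mid-ranks for ties; the exact conditional
  permutation distribution for small untied samples, otherwise the
  tie-corrected normal approximation with continuity correction.
  Survey-sized groups always take the asymptotic path. For small
  samples with heavy ties the asymptotic p can deviate from the
  conditional-exact value by up to ~0.1; this regime does not occur in
  the analysis.
* **Chi-square** independence: Pearson statistic without continuity
  correction, df = (r−1)(c−1). (On the published finance ×
  catastrophic 2×2 table this gives p = 0.696; Yates' correction would
  give 0.749.)
* **Trend across ordered groups**: Cuzick's rank test, written in this
  package (no scipy/statsmodels implementation exists): groups scored
  1..k, T = Σ l_i·rank_i, standardized by its exact null mean
  (N+1)/2·Σl and variance (N+1)/12·(N·Σl² − (Σl)²), two-sided normal p.
  With two groups the z-statistic agrees in sign with the rank-sum
  ordering.

All p-values are two-sided; α = 0.05 is reported, never used to drop
rows. Quantiles use numpy's linear-interpolation convention everywhere.

## The synthetic survey generator

No traveler-level microdata is published for this survey type, so the
generator produces data with the moments the analysis consumes. Every
number in `resources/default_survey.yaml` is either a published summary
or a documented convention:

* **Stratum sizes** 344 / 471; categorical fields (sex, age band,
  region, occupation, household-size class, destination, diagnosis
  chapter) are drawn from the published per-stratum counts, used as
  weights and normalized by the loader.
* **Cost components** are log-normal, calibrated from the published
  median/IQR per stratum: μ = ln median, σ = ln(q3/q1)/(2·0.67449).
  This preserves the median exactly and the quartile *ratio* exactly;
  when the printed quartiles are not symmetric about the median on the
  log scale the fitted quartiles are their geometric symmetrization
  m·(q3/q1)^(±1/2). Components whose printed lower quartile is zero are
  zero-inflated (point mass π₀ = 0.3 at zero; the positive log-normal
  is solved so the *mixture's* median and upper quartile hit the
  printed values — solvable for π₀ < 0.5). All-zero components
  ("0 (0–0)") get π₀ = 0.9 with a small log-normal tail, reflecting the
  rare large visa/agent/exchange fees respondents reported. The private
  stratum's airfare (650, IQR 480–900) is chosen so that home travel +
  airfare + destination travel reproduces the published private travel
  aggregate of 1133 (739.5–1804.5).
* **Caretakers**: 1 + Poisson(mean − 1) with stratum means 2.3 / 3.3 —
  a shifted Poisson, since nearly all patients travel accompanied and
  only the means are published.
* **Household budgets**: the health share follows a two-component Beta
  mixture, low = Beta(2, 32) (protected households) and high =
  Beta(3, 6.5) (burdened households). The mixture weight is solved in
  closed form so that P(share > z) equals the configured catastrophic
  target (0.43 at z = 0.10); an unreachable target is a configuration
  error. With these defaults the mean share among exceeders is ≈0.29,
  matching the published pattern of exceeders spending slightly under
  30 % of their budget on health. Total monthly expenditure is
  log-normal (median $1000, IQR 600–1700 — a convention; no budget
  levels are published), health = share × total, and food takes a
  Beta(10,10) fraction of the remainder.
* **Stay length, incomes, daily wages, visits/year** are log-normal or
  shifted-Poisson conventions with medians in the published ranges.
* **Randomness**: one root seed feeds named independent streams
  (numpy `SeedSequence` spawn keys hashed from field names), one per
  field per stratum, so adding a field never perturbs the others and
  generation is a pure function of (config, seed).

**What the generator does not emulate:** dependence between diagnosis
chapter and cost (components are drawn independently of the chapter and
of each other), correlation between household income and budget levels,
within-party cost correlation, and recall/under-reporting error. Sums
of independently drawn components are more dispersed than jointly
reported episode costs, so sample medians of *derived* aggregates
(per-capita totals, stratum annual costs) sit below the published
derived medians even though every component median matches its target.
Passing tests therefore demonstrate correctness of the estimators and
faithful component-level calibration, not distributional realism of
joint features.

## Numerical choices and problem sizes

* Money: integer cents; ties round half-up at the cent.
* Quintiles: sorted-sample cut points at the 20/40/60/80 % boundary
  positions; boundary ties take the lower quintile (stable and
  monotone); identical incomes collapse to quintile 1 with a warning.
* Stay classes: week k covers 7(k−1)+1..7k days, "1 month" = 22–31
  days, ">1 month" above — a ceiling-week convention, since only the
  class labels are published.
* Household-size classes: small ≤5, medium 6–10, large >10, so the
  classes partition (the published labels leave size 5 unassigned).
* ICD-10 chapters: the 22 blocks ship as a plain-text resource; codes
  in inter-block gaps (e.g. D49) fall to the preceding chapter so
  assignment is total; missing codes map to a first-class "missing"
  sentinel, excluded from disease-profile tables alongside the
  health-service-contact (Z) chapter.
* Monte-Carlo test sizes: calibration fidelity at n = 20 000 records;
  bootstrap-vs-asymptotic comparison at n = 344, B = 2000, averaged
  over 24 samples; null rejection rates over 500 simulations per test.
  These sizes keep the full suite under a minute while leaving the
  binomial error bands well below the asserted tolerances.

## Known limitations

* The generator's free dispersion parameters (caretaker and budget
  families, stay length, incomes) are conventions; only their targeted
  summaries are calibrated.
* Subsidy outlay shares computed from synthetic data are aggregate
  (ratio-of-sums) figures and are sensitive to the heavy upper tails of
  the fitted log-normals.
* The catastrophic denominator is the reported monthly budget; whether
  reported monthly health spending includes the episode's own OOP cost
  is a property of the questionnaire, not of this package — both
  interpretations are supported by feeding the appropriate column.
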