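# Methods

## Scope and design

The package implements a relative-validity analysis for a short-item FFQ
against repeated 24-h recalls in children aged 0–3 years, on the common
currency of daily food-group serves. It is organised as an analysis
project: the computation lives in the library (`src/dgival/`), and the
numbered scripts under `analysis/` are thin drivers that run the study on
the default synthetic cohort.

## Serves conversion

An FFQ item contributes `frequency × serves-per-occasion ÷ period-days`
serves/day to its food group; the reference period defaults to a fortnight
(14 days), matching how the instrument frames "usual" intake around the
pay cycle. Recall records arrive already expressed in reference serves;
a child-day's records are summed by group, and days are averaged with the
number of *completed* recalls as divisor, so children with one or two
recalls stay in the analysis. A recall day with no food is a valid
all-zero day rather than a missing one — in food-insecure settings such
days genuinely occur (the fixtures represent them by a zero-serves
placeholder record, or by the breastmilk record alone for breastfed
children). Breastmilk is recorded but never quantified into dairy serves.
Plausibility screening flags group intakes strictly above configurable
ceilings (default 10 serves/day per group) without mutating the data.

Reference serve sizes and recommended daily serves are *configuration*,
not constants: the shipped defaults follow the Australian Dietary
Guidelines age 0–3 bands (e.g. vegetables 2.5 serves/day at 1–2 years,
with a reduced under-12-month column for late-infancy solids), and every
scoring function takes them as input, so no correctness claim rests on the
default table.

## Index scoring

Nine indicators, maxima summing to exactly 90:

| indicator | max | rule |
|---|---|---|
| vegetables, fruit, meat & alternatives, healthy fats | 10 each | `min(intake/recommended, 1) × max` |
| breads & cereals | 5 | same proportional rule |
| wholegrain | 5 | binary: any wholegrain-bread consumption |
| sugar-sweetened beverages | 10 | `max(0, 1 − intake/cutoff) × max`, cutoff 1 serve/day |
| discretionary foods | 20 | same negative rule, cutoff 1 serve/day |
| dietary variety | 10 | System A or B, below |

The total is the sum (/90) and is rescaled ×10/9 to /100 for
comparability with other index variants. Dairy is computed and stored but
never scored; supplying a dairy indicator raises a configuration error by
design. Scores are kept at full precision internally; reports round to
2 dp.

Choices made where the scoring rules left room:

* **Proportional scoring is strictly linear** between zero and the
  recommendation. Stepped band variants exist in older index versions;
  linear interpolation is the simplest rule consistent with "a proportion
  of the possible score" and is what the closed-form tests pin down.
* **Breads & cereals is split 5 + 5**: a /5 quantity indicator plus a /5
  binary wholegrain indicator, mirroring how the two appear as separate
  /5 rows in validation reports of this index family.
* **Negative-indicator cutoffs** (the intake at which points reach zero)
  are not published for this age band; both default to 1 serve/day and are
  configurable. At these ages any habitual soft-drink or discretionary
  intake is far from guideline-compliant, so a 1-serve/day zero point is a
  defensible, deliberately strict default.
* **Variety System A** splits 2 points per scored group across its
  sub-foods (meat uses the published 0.5-point allocation over red meat,
  white meat, fish and eggs; legumes and traditional meat earn no System-A
  points by default); **System B** awards a group's whole 2 points for any
  consumption. No minimum serving applies in either system, because
  recommended amounts for under-threes are small. B ≥ A pointwise under
  the default allocations, a property the tests enforce.
* **Breastfeeding is recorded but unscored**; it feeds the binary
  agreement analysis only.

## Agreement statistics

Differences are always FFQ − recall, so positive bias means FFQ
over-estimation.

* **Lin's CCC** uses the sample-moment form (divisor n). The confidence
  interval back-transforms a normal interval on atanh(ρ_c) with the
  large-sample standard error of the estimator; when a marginal is
  constant or agreement is numerically perfect the interval degenerates to
  the point estimate. The CI method is a documented choice — CCC intervals
  can be constructed several ways and only the estimator itself is pinned
  by a closed-form test.
* **Bland–Altman**: mean difference with a t-based 95% CI, limits of
  agreement mean ± k·SD(d) (k = 1.96 by default, configurable), and
  proportional bias as the OLS slope of differences on pair means with its
  two-sided p. The LOA width identity `upper − lower = 2k·SD(d)` holds
  exactly.
* **Quartile ranking**: each method's scores are quartiled against their
  own distribution (per-method, not pooled — a documented choice), with
  cut-points at the 25th/50th/75th percentiles under linear interpolation
  and ties at a cut-point taking the lower quartile. Agreement is
  summarised as percent same-quartile and weighted Cohen's kappa
  (disagreement weights |i−j|/(K−1), linear by default; quadratic by
  flag), with the large-sample H0 standard error for its p-value. The
  kappa computation is delegated to statsmodels and cross-checked in the
  tests against a brute-force double sum.
* **Paired location tests**: paired t (with the convention that a
  zero-variance, zero-mean difference vector gives t = 0, p = 1), and
  Wilcoxon signed-rank reported as a normal-approximation Z with
  continuity and tie correction — the form small validation studies
  print — checked in tests against exact sign-flip enumeration at n ≤ 10.
  An all-zero difference vector is degenerate: the Wilcoxon reports p = 1
  with a warning rather than failing.
* **Fisher's exact test** (scipy) is verified against exhaustive
  hypergeometric enumeration — two-sided by probability ordering — for
  *every* 2×2 table with total ≤ 30.
* **Percent agreement** is used for the binary breastfeeding and
  wholegrain questions. For near-degenerate binary tables (one discordant
  pair out of 40), kappa is unstable under prevalence imbalance and a
  recomputed kappa can differ wildly from values reported alongside such
  tables; percent agreement is the quantity this package targets and
  tests.
* **Age-band direction analysis** counts, per band, children whose FFQ
  score exceeds their recall score, tests infants (<12 months) against
  older children by Fisher's exact test on the collapsed 2×2, and re-runs
  Bland–Altman excluding infants.

## Synthetic cohort

The generator emulates the structure of a small remote-community infant
feeding validation study. Defaults:

* **Cohort**: 40 children; age bands <12 mo / 1–2 y / >2 y with
  probabilities 0.30 / 0.55 / 0.15; breastfeeding probability 11/12,
  19/22 and 4/6 by band (≈85% overall); session completion 36/40 after
  session 1 and 33/36 after session 2 (monotone dropout, ≈83% completing
  all three).
* **Usual diet**: per-group gamma-distributed usual serves/day (mean e.g.
  vegetables 0.7, breads 2.0, meat 0.9, SSB 0.1; squared CV 0.4) — sparse,
  right-skewed toddler intakes. Infants under 12 months scale intake by
  0.5 (milk-fed, small solids). Each child also has a sub-food repertoire
  (each sub-food kept with probability 0.6, at least one per group) shared
  by both instruments, and a wholegrain-consumer flag (probability 0.7,
  expressed through bread).
* **Recall days**: distinct day types per child in random order; group
  serves = usual × day-type multiplier (pay week 1.25, non-pay week 0.75,
  weekend 1.0 — averaging 1) × mean-one log-normal noise (σ = 0.35); a
  day is zero-intake with probability 0.05 (power outages, food
  insecurity). A day's group intake spreads over the child's whole
  repertoire — children this age graze small amounts of their usual foods.
* **FFQ**: group serves = usual × per-group reporting bias × mean-one
  log-normal noise (σ = 0.30), spread over the repertoire as
  frequencies/fortnight. Default biases encode the over-reporting pattern
  seen when short FFQs are validated against recalls in young children:
  meat 2.5, healthy fats 2.0, breads 1.3, discretionary 1.3, SSB 1.2,
  vegetables 1.1, and fruit 0.9 (the one group reported lower).
* **Instrument discordance on breastfeeding**: the recall-side
  classification flips with probability 0.025, i.e. ≈1 child in 40.

Because the reporting noise is **mean-one** (log-normal with μ = −σ²/2),
expected reported serves equal bias × usual exactly; the
parameter-recovery tests exploit this (the FFQ/recall meat-serves ratio
recovers a 1.5× bias within 3 Monte-Carlo standard errors at n = 500, and
the zero-noise limit reproduces the latent truth to machine precision,
driving CCC = 1, zero mean difference and 100% same-quartile
classification).

What the generator does **not** emulate: real food-composition data or
nutrient intakes (serves are atomic), seasonal or growth trends within the
follow-up window, correlation between food groups beyond the shared
repertoire, energy adjustment, or the reported day-level proportions of
less/more/usual intake (day-type multipliers exist but are not calibrated
to those proportions). Passing tests therefore demonstrate the pipeline's
arithmetic and statistical machinery and its behaviour under a plausible
data-generating process — not the field performance of any instrument.

## Numerical conventions

* Quartile cut-points: linear interpolation between order statistics;
  ties at a cut-point take the lower label.
* Degenerate inputs raise typed errors (`DegenerateInputError`,
  `InsufficientDataError`, `ConfigurationError`) rather than returning
  NaN; the two deliberate exceptions (all-zero Wilcoxon differences,
  constant-difference t) are documented above.
* Fixture CSVs are written with `%.17g` floats and read with
  round-trip parsing, so generate → write → read is lossless and
  re-running a seed is byte-identical.
* All randomness flows from one `numpy.random.Generator` seeded from the
  cohort seed; identical (parameters, seed) give identical cohorts,
  reports and files.

## Problem sizes

The test suite and the acceptance script use cohorts of 25–60 children for
structural checks, 500 for parameter recovery, and 800–2000 for marginal
and dropout calibration; the exhaustive Fisher verification covers all
46,375 tables with total ≤ 30. These sizes give 3-standard-error margins
comfortably below the effects being recovered while keeping the whole
suite to a few minutes.

## Known limitations

* The CCC confidence interval assumes approximate bivariate normality;
  with n = 40 skewed scores it is indicative, not exact.
* The weighted-kappa p-value uses the large-sample H0 standard error,
  which is optimistic for 4×4 tables built from 40 observations.
* Category→frequency mapping for categorical FFQ response options is a
  config hook (`freq_per_period` is continuous here); real instruments
  with banded responses need that mapping supplied.
* The pipeline requires at least 4 children with both instruments and at
  least 3 recalls' worth of variation for the regression-based statistics.
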