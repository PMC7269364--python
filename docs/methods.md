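# Methods

This note documents the models, filters, numerical conventions and design
choices behind `muacdose`, and what the synthetic-data results do and do
not establish about real program data.

## Data model

One patient card is one treatment episode: admission metadata (country,
admitting facility TFP/SFP, age in months, sex) plus date-ordered visits
with MUAC (whole mm), weight (0.1 kg) and, at admission and discharge,
height (0.1 cm). Episodes cannot be linked across cards. Files are UTF-8
CSV with ISO 8601 dates and empty fields for missing values; the reader
reports malformed rows by row number and rejects duplicate
(card, visit-date) pairs rather than guessing which record is real.

Interval observations are indexed by *prior-visit* MUAC throughout: a
change over *d* days is assumed constant across the interval, giving a
MUAC velocity ΔMUAC/(d/7) in mm/week and a proportional weight gain
ΔW·1000/W_prior/d in g/kg/day. An interval contributes one observation
regardless of its length; changes are divided, records are not expanded
into pseudo-weeks.

## Filtering

Filters run in a fixed order and every exclusion is attributed to the
first failing rule, so attrition counts are disjoint and sum to the
total:

1. **Usability**: at least one follow-up visit; age, sex and all visit
   dates present.
2. **Plausibility** (likely measurement or transcription errors):
   retained ranges are WHZ ∈ [−5, 5], WAZ ∈ [−6, 5], HAZ ∈ [−6, 6],
   MUAC ∈ [65, 200] mm; changes of more than 25 g/kg/day weight gain or
   more than 15 mm/week MUAC change in either direction are flagged
   (strict inequalities — exactly 15 mm/week is retained). A card with
   any implausible visit is excluded entirely; z-score rules apply only
   where height and a growth reference are available, and nothing is
   imputed. The weight-change rule is applied to gains only, mirroring
   the asymmetric phrasing of the MUAC rule ("either direction") versus
   the weight rule.
3. **Outcome eligibility**: discharged as recovered, non-negative
   admission-to-discharge MUAC gain, and weight gain of at least 10%
   (TFP/SAM admissions) or 3% (SFP/MAM admissions), thresholds
   inclusive. Restricting to recovered children makes the estimated
   energy needs those of *successful* treatment.
4. **Analysis window**: interval observations with prior MUAC outside
   [100, 140] mm are dropped (closed window), per observation — a card
   may contribute some visits and not others.

Z-scores use the LMS transform z = ((x/M)^L − 1)/(L·S), switching to
ln(x/M)/S for |L| < 1e-7; L, M and S are linearly interpolated between
reference rows, and ages are admission age in months × 30.4375 days plus
elapsed days (card ages are often year-rounded, so day-level age
precision is illusory anyway). The package applies no restricted-range
flag adjustment: the filters test only wide bounds where conventions
agree. The reference table is an input file; the shipped
`synthetic_reference()` is an explicitly synthetic LMS table for tests
and demonstrations, not a published growth standard.

## Smoothing and the trend comparison

Velocities are smoothed against prior MUAC by local polynomial
regression: at grid point *g*, a weighted polynomial fit with kernel
weights K((x−g)/h). Defaults are an Epanechnikov kernel, degree 0, an
integer-mm grid over the window, and a rule-of-thumb bandwidth
h = max(1, 1.06·sd(x)·n^(−1/5)) mm — all configurable, since none is
dictated by the science. Degenerate local designs fall back to the local
mean; grid points with zero kernel mass are missing. Pointwise standard
errors come from the kernel-weighted local residual variance.

The trend comparison asks whether MUAC velocity and proportional weight
gain, each min-max normalized to [0, 1] over a shared grid, diverge
linearly in MUAC. The statistic is the OLS slope of the normalized
difference on grid MUAC. Two numerical facts shape the implementation:

- **Grid spacing.** Estimates at grid points closer than 2h share
  observations and are correlated; a slope test that assumes independent
  residuals is then anti-conservative (measured rejection rates up to
  23% at nominal 5% on a 1-mm grid). The test therefore uses a grid
  spaced at ≥ 2h, where compact-kernel windows are disjoint.
- **Reference distribution.** Min-max normalization pins both curves to
  0 and 1 at their shape-determined extremes and absorbs each curve's
  own linear component, so under the null the slope of the difference is
  structurally suppressed and the textbook F distribution does not apply
  (measured rejection rates of 0.2–0.4% at nominal 5% with independent
  grid points). The reported p-value is therefore computed by parametric
  Monte Carlo: both curves are redrawn from their common estimated
  normalized shape with independent Gaussian noise at each curve's
  pointwise standard error, renormalized, and the slope recomputed
  (default 400 draws; the add-one p-value convention keeps it positive).
  The plain F p-value is retained on the result as a diagnostic
  (`f_pvalue`). With this construction the test's observed size is close
  to nominal: 96–99% non-significant across batches of 100 true-null
  cohorts.

The resampling harness draws, per replicate, a fixed number of visits
(default 1000; configurable to cards) from each country without
replacement, smooths both series, and runs the trend test; defaults are
100 replicates at significance level 0.05. One caveat documented here
because it is easy to trip over: when the pool being subsampled is itself
a single modest cohort, replicates partly detect that cohort's own
sampling deviation from the generating process (a finite-population
effect), so calibration experiments use independently generated cohorts
per replicate.

## Energy model

Per-visit need is maintenance plus tissue cost:

    need [kcal/day] = W_prior·m + (g·W_prior)·c

with maintenance m = 82 kcal/kg/day and tissue cost c = 5 kcal/g by
default. "Current weight" is the prior-visit weight — the same weight
that anchors the proportional gain, so the need is the energy consistent
with the growth observed over that interval. Weight-loss visits
contribute negatively and are never clamped: they occur legitimately in
eligible cards whose overall trajectory still met recovery criteria.

Dosage levels are empirical percentiles (default 95th) of needs within
5-mm bands of prior MUAC, using linear interpolation between closest
ranks (numpy's default, type-7). Subgroup tables split by age group
(6–23 vs 24–59 months), continent (Kenya, Chad, South Sudan → Africa;
Pakistan, Yemen → Asia), or admission MUAC category; the
admission-category comparison is restricted to the MUAC range both
categories actually share during treatment, [110, 125) mm.

## Protocols and performance

The proposed protocol doses by MUAC alone: two sachets (1000 kcal/day)
for visits at MUAC 100–<115 mm aiming at 100% of needs, one sachet
(500 kcal/day) at 115–<125 mm aiming at 50% (the rest from home foods).
Stratum membership uses the visit's prior MUAC, not the admission
category. Comparators: Golden's minimum/intermediate/standard
(135/150/170 kcal/kg/day), Sierra Leone (175 kcal/kg/day below 115 mm,
75 above), and Kenya (200 kcal/kg/day for SAM-program admissions, flat
500 kcal/day for MAM-program admissions). The 92 g ↔ 500 kcal sachet
equivalence is a named constant.

Per visit, the provision ratio is dose/need; a SAM-stratum visit counts
as covered when the ratio ≥ 1.0, a MAM-stratum visit when ≥ 0.5. Visits
with prior MUAC outside [100, 125) have no defined dose under the
proposed protocol and are excluded with a count. The trial simulation
draws 200 visits per country without replacement, 100 times, and
aggregates per stratum and factor level (sex, age group, weight band,
admission type, continent): mean/min/max of the per-replicate n and
coverage fraction, and the mean of per-replicate median provision.
Medians are the standard midpoint convention. The sampling unit defaults
to visits (the strata sizes quoted above are visit counts); cards are
available via configuration because program descriptions are ambiguous
between the two.

## Synthetic cohort generator

The generator emulates the study's card structure so the pipeline can be
exercised end to end. Per card: country (equal card counts by default),
facility mix per country (South Sudan all-TFP, 14–28% TFP elsewhere),
age-group fractions 0.29/0.40/0.18/0.13 over 6–11/12–23/24–35/36–59
months, 54% female, admission MUAC uniform over [100, 115) mm for TFP
and [115, 125) for SFP, admission weight log-normal about age-group
medians 5.4/6.6/8.2/9.6 kg (σ_log = 0.12) so most under-24-month
children sit below 8 kg. Visits advance weekly (TFP) or two-weekly
(SFP), with a 0.1 probability per interval of a missed visit (doubling
the gap) — a modelling choice, as visit irregularity is not otherwise
quantified. Forward simulation:

    MUAC(t+d) = MUAC(t) + v(MUAC(t))·d/7 + ε,  ε ~ N(0, 1 mm)
    W(t+d)    = W(t)·(1 + g(MUAC(t))·d/1000) + ε',  ε' ~ N(0, 0.05 kg)

with recorded values rounded to card precision (whole mm, 0.1 kg; the
`quantize` switch disables rounding for exact noise-free checks).
Rounding acts as a small extra symmetric measurement error. Cards
discharge at MUAC ≥ 125 mm or 24 visits; 10% are censored early
(non-response) and cards are labelled recovered only when the recovery
criteria hold on their recorded values — with rounding, a short SFP
episode can genuinely miss the 3% weight-gain bar, so clean cohorts
contain a small eligible-outcome attrition, as real programs do.

Velocity presets: `band_anchor` interpolates linearly between anchor
means (2.0 mm/week and 3.9 g/kg/day at MUAC 105; 1.0 mm/week and
2.4 g/kg/day at 122.5) and extrapolates flat beyond them — only band
means are published, not a functional form; `linear_slope` is globally
linear with slopes −0.06 mm/week and −0.05 g/kg/day per mm, anchored at
MUAC 105. In both presets the weight-gain function is an affine
transform of the MUAC-velocity function, so the two normalized trends
share one shape: the trend comparison's null is true by construction.

Error injection plants each implausible-record type (MUAC spike
> 15 mm/week, weight jump > 25 g/kg/day, out-of-range MUAC, missing
age/sex/date, no follow-up) independently per card at configured rates
and returns a manifest of every corruption; on an otherwise-clean cohort
the QC-excluded card set equals the manifest exactly.

What the generator does *not* model: oedema dynamics, mortality and
transfers, seasonality, between-country velocity differences,
age-dependent growth rates, and correlation between a child's successive
noise terms. Passing parameter-recovery tests on these cohorts shows the
estimators are correct for data satisfying the model's assumptions, not
that real feeding-program data satisfy them; in particular the energy
percentiles of synthetic cohorts depend on the synthetic weight
distribution and should not be read as field dosage recommendations.

## Problem sizes

Default analyses use cohorts of 400 cards per country (≈ 11 000 interval
observations), 1000 visits per country × 100 replicates for the trend
analysis, and 200 visits per country × 100 replicates for protocol
trials; calibration experiments use 100 independent 200-card-per-country
cohorts. These sizes give Monte-Carlo error well inside the tolerances
asserted in the tests while keeping the full suite fast.

## Known limitations

- WHZ can only be evaluated where height was measured (admission and
  discharge); mid-treatment visits are screened by the change rules and
  age-based z-scores only.
- The MUAC-slope recovery shows a small attenuation (|slope| ≈ 0.058 for
  a generating 0.06) from discharge-boundary selection: intervals
  observed at high MUAC condition on not yet having crossed the
  discharge threshold.
- The trend test's Monte-Carlo null assumes independent Gaussian errors
  at the (disjoint-window) grid points; heavy-tailed measurement error
  would make it approximate.
- Confidence bands on smoothed curves are deliberately out of scope.
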