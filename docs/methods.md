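# Methods

## Schedule model

The default schedule is the Kenyan routine infant schedule: BCG and an OPV
birth dose (OPV0) at day 0; OPV, pentavalent and PCV doses 1–3 at days
42/70/98; measles (MV) at day 274.  Eight doses — BCG, OPV1–3,
pentavalent 1–3, MV — form the FIC basis; OPV0 and PCV are tracked and
tabulated but do not count toward full immunization, and OPV0 is also
exempt from the late-BCG rule (it is co-administered with BCG by design, so
including it would flag essentially every child).  PCV carries a rollout
date (2011-02-01) before which it is treated as not on offer.

Timeliness windows are `[max(0, rec − early), rec + delay]` in whole days:
early margin 4 days for every dose; delay margin 14 days for
BCG/OPV/pentavalent/PCV and 30 days for measles.  "A month" of measles
delay is fixed at 30 days rather than one calendar month so that a dose's
classification does not depend on the calendar month of birth; both
margins are per-dose configuration, not constants.  A secondary
strict-early indicator flags measles more than 14 days before day 274.
The FIC cutoff is 365 days ("by 12 months"), consistent with the day-based
dose ages; it is configurable.

Schedules load from JSON/YAML with full validation: unique labels,
non-negative ages/margins, strictly increasing recommended ages within a
series, symmetric pentavalent↔OPV companion links, unknown fields
rejected.

## Inclusion and classification

A child enters the analysis iff some follow-up visit with the vaccination
card seen falls at an age in `[365, 730)` days; the earliest such visit is
the analysis visit and its calendar year the child's year of visit.  The
window is half-open (12 months inclusive, 24 exclusive) and expressed in
days to avoid calendar-month ambiguity; both bounds are parameters.

Classification is pure per-child date arithmetic (whole days, no time
zones, no hidden state).  FIC requires every basis dose at age ≤ 365;
children with all doses on the card but at least one later are the
"FIC after 12 months" category and are counted with zero missing doses in
the missing-vaccine table.  Sequencing rules compare calendar dates;
"with" means the same day.  By default the comparisons run over doses
received by the cutoff, matching an audit of the first year of life; a
switch evaluates all card events instead.  For the late-BCG rule the
comparator set is every recorded schedule dose except BCG and OPV0 (the
definition "after or with any of the other routine vaccines"); a narrower
reading that compares BCG only against pentavalent and measles is
available as `late_bcg_comparators="penta_mv"`.  Family-only antigen
labels in input files (e.g. "OPV" with a date but no dose number) are
numbered chronologically within the family — the only reproducible rule
when cards omit dose numbers.

## Survival statistics

Ages at vaccination are analyzed as right-censored event times with
administrative censoring at the 365-day horizon: a child without the dose
by the horizon (or with it recorded later) is censored there, which makes
"coverage at 12 months" from the Kaplan–Meier curve agree with the
count-based tables.  The product-limit estimator processes tied events
together and censorings after events at the same time.  The k-sample
log-rank statistic uses the hypergeometric covariance summed over event
times and a pseudo-inverse quadratic form on the first k−1 groups.
Quartiles use linear interpolation between closest ranks; table output is
rounded half-up, full precision is kept internally.  Mood's median test
assigns values equal to the grand median to the "at or below" cell; a
table with an empty side is reported as degenerate with p = 1.  The
Pearson chi-square uses no continuity correction and warns (does not fail)
when an expected cell is below 5.  All p-values come from the χ² upper
tail; no exact or Monte-Carlo options in this version.  Greenwood
confidence bands and regression modelling of determinants are out of
scope.

## Report tables

Every percentage cell stores its numerator and denominator and is
recomputed from them when written, so tables cannot drift from their
counts; rounding is half-up to one decimal.  Yearly tables pool the final
column from counts, never by averaging yearly percentages.  Stratified
tables give children with a missing covariate their own "(missing)"
stratum, excluded from the chi-square.  Out-of-sequence tables use FIC
children as denominators.  PCV rows are tabulated only over children whose
analysis-visit year is at or after the rollout year, with their own
denominators — before rollout the dose could not have been given, and the
usual denominator would understate uptake; this eligibility rule is a
documented package choice.

## Synthetic cohort generator

The generator emulates a four-monthly demographic-surveillance follow-up
of children born over 2006–2013 in two urban informal settlements.  It is
a structural emulation calibrated to headline rates, not a reconstruction
of any real microdata; its purpose is to give every pipeline stage inputs
with known truth.

Per child: date of birth uniform over the recruitment window; a card
available with probability 0.38 (card availability is a child-level trait,
so the included fraction of a large cohort estimates that probability);
visits every 122 days from a uniformly shifted start, so at least one
visit always falls in the 12–23-month window.  Vaccination events:

* **BCG** with probability 0.9715, at a delay with median ≈ 6 days (a
  point mass spread over 0–2 days plus a discretized log-normal, capped at
  35 days); with probability 0.04 BCG is instead deferred to the first
  6-week contact, which is what produces late-BCG flags.  OPV0 with
  probability 0.80, given with BCG when BCG is timely.
* **Contacts 1–3** (pentavalent/OPV/PCV) through a continuation chain:
  attendance probabilities 0.990, 0.9758 and 0.9027 give marginal
  attendance 0.990/0.966/0.872, matching the observed pentavalent
  coverage gradient.  Cumulative contact delays are sums of non-negative
  integer increments (zero-inflated discretized Gamma: P(0) = 0.35, body
  1 + Gamma(shape 1.0, scale 4.5)), which keeps inter-dose gaps at or
  above the 28-day schedule gap by construction; the increment pmf is
  discrete, so the cumulative dose-3 delay has an exact convolution median
  of 9 days (dose-3 age 107; 108 pooled over the site delay shift).  A 3 %
  early-first-contact fraction moves contact 1 ahead by 5–12 days.  OPV is
  missed at the third contact with probability 0.016 (stock-outs), making
  OPV3 coverage 0.858 against pentavalent-3's 0.872.  With a per-contact
  split probability (baseline 0.0425, log-odds +0.907 in the
  higher-pressure site, averaging ≈ 0.065) the OPV dose is given 1–14 days
  after its pentavalent companion — the dominant out-of-sequence source,
  ≈ 18 % of FIC children over three contacts.  PCV is given at attended
  contacts with probability 0.95 once the rollout date has passed.
* **Measles** with probability 0.845, at 274 days plus a discretized
  log-normal delay (median 8 days, σ = 1.477; IQR 3–21, ≈ 3.5 % beyond the
  365-day horizon), a 9 % early fraction 5–27 days ahead, and a 0.8 %
  chance that the third contact is swapped to on-or-after the measles date
  (the penta-with/after-MV rule).

Categorical covariates (site, education, wealth, postnatal care, parity,
ethnicity, maternal age group, sex, delivery place) are drawn
independently from configured frequencies.  A centred log-odds
"engagement" score built from site, education, wealth, postnatal care and
parity shifts third-contact continuation and measles uptake (and the site
level also adds a 2-day delay shift and raises the split probability), so
coverage gradients run in the observed directions while the calibrated
marginals are preserved.  Under these defaults the closed-form product —
P(BCG) × P(attend 3) × P(OPV never missed) × P(MV within the horizon) ≈
0.9715 × 0.872 × 0.984 × 0.82 ≈ 0.68 — puts the FIC rate in the
mid-to-high sixties, within the calibration band of the audit it emulates.

Every latent draw is stored in a `Truth` record whose labels (FIC, split,
late BCG, ...) are computed by separate straight-line code, so classifier
and generator can be audited against each other; an exact analytic FIC
probability (per-child closed form on the discrete delay grid, averaged
over the drawn covariates) serves as a second oracle.  A fixed seed gives
a byte-identical cohort.

What the generator does **not** emulate: correlations between covariates;
recall-based histories (every generated event carries a date, as on a
card); card loss correlated with vaccination behaviour — card availability
is independent of the event process, so inclusion is non-informative,
whereas in real audits excluded children likely differ; catch-up and
booster schedules; seasonality and calendar-time trends other than the PCV
rollout (so yearly tables vary only by sampling noise); events recorded
only up to the analysis visit (all events are written, and classification
ignores those past the cutoff).  Passing tests therefore demonstrate that
the pipeline measures what it claims on data with this structure, not that
real cohorts satisfy these assumptions.

## Test and simulation sizes

Unit and property tests run at hundreds to a few thousand synthetic
children; oracle-equivalence audits use 500–1,000; calibration-band and
recovery checks use one 20,000-child cohort; test calibration uses 1,000
null replicates (type-I error) and 200 alternative replicates (power).
These sizes put Monte-Carlo error well inside the stated tolerances while
keeping the full suite fast.

## Known limitations

* The OS rules are evaluated on recorded dates only; unrecorded doses
  never trigger flags, so OS rates are conditional on card completeness.
* Mood's median test on heavily tied integer ages can be conservative;
  the tie convention is documented above.
* Chi-square p-values are asymptotic; sparse strata only warn.
* The generator's covariate effects are directional calibrations, not
  estimates; stratified tables from synthetic cohorts should not be read
  as predictions for any real population.
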