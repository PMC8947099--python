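# Methods

This note documents the statistical procedures implemented in `aomburden`,
the conventions chosen where the underlying epidemiological definitions
leave room, and what the synthetic-data tests do and do not demonstrate.

## Case identification

A visit is AOM-related if any of its (possibly several, delimiter-separated)
ICD-9-CM codes falls under a configured rubric prefix — default `382`,
matched on dot-stripped strings anchored at position 0, so `382`, `382.00`
and `38200` match while `038.2` and `1382` do not — or if its free-text
diagnosis matches one of the otitis search patterns. Text matching is
token-level: prefix patterns (`oti*`, `om*`) anchor at the start of a
whitespace token, substring patterns (`*oti*`, `*om*`) match anywhere inside
a token. String-level matching would collapse the four patterns into one,
which is why anchoring is defined relative to word starts. Matching is
case-insensitive by default (clinical free text has inconsistent casing).

False positives — strings such as *vomito* that contain `om` but are not
otitis — are removed by an exclusion list matched against the full
normalized text. The packaged list is a small Italian vocabulary standing in
for the manual expert review used in curated databases; it is a reproducible
emulation, not a clinical instrument, and users can supply their own file.

## Episode construction

Same-day duplicate AOM visits merge into one occurrence. The default
`rolling` gap mode starts a new episode when the gap from the *previous*
visit exceeds 14 days; the alternative `anchor_to_first` mode measures gaps
from the episode's first visit. The two readings coincide for 1–2-visit
chains and diverge from three visits on; rolling is the default because the
operative definition of a new episode is phrased in terms of gaps between
consecutive AOM visits. Episodes take the calendar year and the exact age
(and age band) of their onset date even when follow-up visits cross a year
or band boundary; the bands <2, 2–4 and 5–14 are left-closed at the 2nd,
5th and 15th birthdays.

Eligibility is applied per child, all episodes standing or falling together:

* registered at least 6 months (183 days) before the index episode, waived
  below age 1;
* registered at least 12 months (365 days) after the index date, waived when
  registration is still open at study close (`end_date >= study_end`) —
  otherwise every index in the final study year would be dropped and the
  last year's numerator biased down;
* known birth date;
* at least 2 distinct visit dates of any kind (configurable to AOM-only);
  this reads as a data-quality filter on under-observed children.

Month windows use fixed day counts (183/365, i.e. 30.4375 days/month) so the
filters are deterministic across calendars. When several checks fail the
exclusion log records the first in the order missing_age, pre_index,
post_index, min_visits.

## Recurrence classification

Episode *i* is recurrent when (≥3 onsets in the 183 days ending at its
onset, or ≥4 in the 365 days ending there — windows half-open on the left,
closed at and including the current onset) **and** at least one onset falls
strictly before it within the preceding 183 days. The preceding-onset
condition is evaluated strictly before the current onset; otherwise it would
be vacuous whenever the short-window count fires. A first-ever episode is
therefore always simple. By default the label attaches to episodes that
*complete* a qualifying window, keeping classification causal and
streamable; `cluster_labels=True` additionally back-labels the earlier
episodes of each qualifying window, since aggregate recurrent-AOM rates can
be defined either way.

## Person-time and incidence rates

Person-time is exact day arithmetic: the observation interval
[max(registration, birth, study start), min(deregistration, study end, day
before the 15th birthday)], closed on both ends, split at every 1 January
and at band-edge birthdays (the boundary day counting in the later
fragment), each fragment contributing its day count to one (year, band)
cell. Days convert to person-years at 365.25 days/year. Fragment additivity
is asserted exactly at day resolution in the tests.

Rates are IR = 1000·D/PY with the Poisson normal-approximation interval
IR ± z·√D/PY·1000 (z = 1.96), lower bound clipped at zero; this formula
reproduces, after half-up integer rounding, every published rate and
interval pair used as reference values in the acceptance tests. Cells with
zero person-years are reported as empty, never as zero rates. By default all
children contribute denominator person-time while eligibility exclusions
remove numerator episodes only, mirroring the convention of reporting the
full cohort denominator; `denominator="eligible"` removes excluded
children's person-time as well, which is the mode used in the
rate-recovery test so that numerator and denominator describe the same
children.

## Trend analysis

**Mann–Kendall.** S = Σ_{i<j} sgn(x_j − x_i), Var(S) = [n(n−1)(2n+5) −
Σ_t t(t−1)(2t+5)]/18 over tied groups of size t, Z = S/√Var(S) with **no
continuity correction**, two-sided normal p-value. The no-correction choice
is deliberate: on the reference annual series it reproduces the published
p-values (0.0065 and 0.0478) exactly to four decimals, while the corrected
statistic gives 0.0094 and 0.0635. A constant series returns S = 0, p = 1;
fewer than three points is an error.

**Interrupted time series.** Counts per (year × age band × sex) stratum,
offset log PY, log-link count regression with design

log μ = β₀ + β₁(year − t₀) + β₂·1[year ≥ τ] + β₃(year − τ)·1[year ≥ τ] + factors,

breakpoint τ = 2014 (first "late" year), covariate factors entering
additively on the log scale via treatment-coded dummies. Working with
stratified counts is the aggregate analogue of child-level covariate
adjustment; it is a design choice, and annual time is indexed in integer
years so exp(β₁) reads as percent change per year. The negative-binomial
dispersion α is estimated by profiling the full NB2 likelihood over log α
(bounded scalar minimization, tolerance 1e-6 on log α, inner IRLS fits to
1e-10), and a boundary solution at α → 0 is reported as dispersion 0, the
fit then agreeing with Poisson to ~1e-8 in the coefficients. Wald CIs and
p-values throughout; per-period annual rate ratios exp(β₁) and exp(β₁+β₃)
get delta-method intervals from the full covariance. Non-convergence and
non-finite coefficients (separation) raise rather than returning garbage.
With only eight annual points no autocorrelation-robust inference is
attempted.

## Synthetic cohort

The generator emulates a 2010–2017 family-pediatrician panel: births uniform
over the 23-year window that makes age <15 overlap the study; registration
at birth plus an exponential delay (mean ≈ 1 month, `enrollment_hazard` 12
per year), reflecting enrolment with a paediatrician in infancy;
deregistration by an exponential dropout hazard (0.02 per year), with
`end_date` clipped to study end meaning "still registered". Episode onsets
follow a per-child non-homogeneous Poisson process, piecewise constant over
(year × age band) segments: base rates 180/200/48 per 1000 PY for <2, 2–4
and 5–14, a cumulative annual multiplier per period (default 0.94/0.94,
i.e. a 6% yearly decline in both the early and late vaccine-era periods),
and a per-child log-normal frailty (σ = 1.0, normalized to mean 1) inducing
otitis-prone children. The frailty σ was chosen so that recurrent episodes
actually occur at realistic cohort sizes; recurrence in reality is
self-exciting, and a stationary frailty is a documented simplification that
exercises the classifier without reproducing published recurrent-AOM
magnitudes. Episodes emit an index visit plus, with probability 0.5, 1–2
follow-up visits within 14 days (so episodes have 1–3 visits; no
within-episode visit-count distribution is established in the literature,
and this fixture choice is documented rather than claimed). Diagnoses are
ICD-9 382.x with probability 0.6, otherwise otitis free text.

Two background streams make the data-quality filters meaningful: neutral
non-AOM visits (3 per person-year — routine checks, unrelated diagnoses),
without which the ≥2-distinct-visits filter would drop every child whose
only contact was a single AOM visit, and false-positive visits (0.2 per
person-year) whose free text matches the otitis patterns but sits on the
exclusion vocabulary. All randomness flows from one `numpy` generator
seeded by `seed`; identical parameters give byte-identical tables, and
`ground_truth` re-simulates and verifies provenance before returning true
onsets and labels.

Not emulated: seasonality, daycare/sibling/breastfeeding covariate effects,
hospital and ER contacts, true self-excitation, and real coding noise
beyond the false-positive vocabulary. Passing recovery tests therefore shows
the pipeline is internally consistent under the stated generative
assumptions, not that it is robust to every artefact of real EHR data.

## Problem sizes and calibration in the test suite

* Oracle-equivalence checks run 1000 random visit streams (≤20 visits) and
  1000 random onset sets (≤10 episodes) against brute-force evaluators.
* End-to-end rate recovery uses 5000 children with flat rates and zero
  frailty; band estimates are required to sit within 3 standard errors of
  the configured rates, using eligible-child denominators.
* ITS recovery uses aggregate simulated counts at 5000 person-years per
  (year × band × sex) cell. That stratum size was fixed a priori by an
  expected-information (Wald) power analysis: it gives SE(β₂) ≈ 0.025 and
  analytic power ≈ 0.91 for detecting an 8% immediate level drop at
  α = 0.05, comfortably above the 80%-of-replicates acceptance line, while
  100-replicate coverage of the true 0.94 annual trend ratio is checked
  against a 90-of-100 line.

## Known limitations

* The exclusion list is a fixture; real free-text review is richer.
* Whether "fewer than 2 distinct visits" should count all visits or AOM
  visits only, and whether excluded children's person-time belongs in the
  denominator, are genuinely ambiguous conventions; both are configurable
  and the defaults are stated above.
* The label-completion (vs cluster) convention changes recurrent-AOM rate
  magnitudes; the default is the causal convention.
* The ITS operates on aggregate stratified counts; child-level frailty is
  not identifiable from them, and overdispersion absorbs it instead.
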