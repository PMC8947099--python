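# aomburden

Burden-of-disease analysis of **acute otitis media (AOM)** from pediatric
primary-care visit streams — the kind of data produced by family-pediatrician
networks and claims databases.

Given a child table (demographics, registration interval, risk-factor flags)
and a visit table (dates, ICD-9-CM codes, free-text diagnoses), the package:

1. **identifies AOM-related visits** — ICD-9-CM rubric 382.x in any code
   position, or free text matching the otitis patterns `oti*`, `*oti*`,
   `om*`, `*om*` subject to an exclusion list of known false positives;
2. **groups visits into episodes** with a 14-day gap rule (visits within 14
   days are follow-ups; a longer gap opens a new episode), assigns each
   episode to the calendar year of its onset and to an exact-birthday age
   band (<2, 2–4, 5–14 years), and applies cohort eligibility filters
   (≥6 months registered before the index episode — waived under age 1 —
   ≥12 months after it, known birth date, ≥2 distinct visits);
3. **classifies episodes** as *recurrent* (≥3 episode onsets within 6 months
   or ≥4 within 12 months, with ≥1 onset in the preceding 6 months) or
   *simple*;
4. **estimates incidence rates** with day-resolution person-time
   (registration to the earliest of deregistration, study end, or the day
   before the 15th birthday), as episodes per 1000 person-years with Poisson
   normal-approximation confidence intervals

   IR = 1000·D/PY,  IR ± 1.96·√D/PY·1000

   for event count D and person-years PY;
5. **tests trends** across study years with the Mann–Kendall test (statistic
   S = Σ_{i<j} sgn(x_j − x_i), tie-corrected variance, normal approximation
   without continuity correction) and a two-period segmented **interrupted
   time series** negative-binomial regression with offset log PY:

   log μ = β₀ + β₁(year − t₀) + β₂·1[year ≥ τ] + β₃(year − τ)·1[year ≥ τ] + covariates

   where exp(β₁) is the early-period annual rate ratio, exp(β₂) the
   immediate level change at the breakpoint τ, and exp(β₁ + β₃) the
   late-period annual rate ratio. Dispersion is estimated by profile
   likelihood and collapses to Poisson when the data are equidispersed.

A **synthetic cohort generator** emulates the statistical structure such
analyses assume (age-band-specific episode rates, multiplicative annual
trend, recurrence-prone children via log-normal frailty, follow-up visits,
false-positive free text, staggered enrolment and dropout), so the entire
pipeline is testable without access to real patient data.

## Worked example

```python
import aomburden as ab

params = ab.SimulationParams(n_children=2000, seed=42)
children, visits = ab.generate_cohort(params)

definition = ab.CaseDefinition(exclusion_list=ab.load_exclusion_list())
aom = ab.identify_aom_visits(visits, definition)
episodes = ab.assign_attributes(ab.build_episodes(aom), children)
retained, excluded = ab.apply_eligibility(children, visits, episodes,
                                          study_end=params.study_end)
labeled = ab.label_episodes(retained)
labeled["sex"] = labeled["child_id"].map(children.set_index("child_id")["sex"])

pt = ab.person_time_table(children, params.study_start, params.study_end)
print(ab.tabulate(labeled, pt, by=["age_band"])["mean"])

annual = ab.tabulate(labeled, pt)["annual"]
mk = ab.mann_kendall(annual.sort_values("year")["ir"])
its = ab.fit_its(ab.stratum_counts(labeled, pt, ["age_band", "sex"]), ab.ITSSpec())
```

On this cohort the pipeline finds 1396 AOM visits, 780 episodes (770 after
eligibility; 758 simple, 12 recurrent), and mean annual band rates

```
age_band  person_years  events  ir  ci_low  ci_high
     2-4          2004     334 167     149      185
    5-14          5748     250  43      38       49
      <2          1363     186 136     117      156
```

— below the configured 2010 base rates (180/200/48) because the generator's
default 6%-per-year decline and person-year weighting pull the multi-year
means down. The Mann–Kendall test on the overall annual series gives
S = −20, p = 0.0133 (a monotone decline), and the ITS fit estimates early-
and late-period annual rate ratios of 0.92 and 0.94 with dispersion 0 (the
simulated counts are Poisson).

The same run is available from the shell:

```bash
aomburden run --config run.yaml --seed 42 --set simulate.n_children=2000
```

with a YAML config naming either a `simulate:` block or `inputs:` paths; the
output directory receives the episode, exclusion-log, incidence and
trend-result CSVs, a run report (stage-count ledger, config echo), and a
multi-panel figure of observed annual rates with fitted ITS segments.

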