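# Methods

## Scope and model

`bsiepi` derives *episodes* from rows of a blood-culture laboratory
database and classifies them with deterministic window rules against
hospital-administrative contact records. The analytical unit for evaluation
is the physician-anchored reference episode; the computer episode of the
same patient and index date supplies the algorithmic labels. All arithmetic
is calendar-day integer subtraction on ISO dates; there is no time-of-day,
timezone or leap-second handling anywhere, because the source registries
record dates only.

Assumptions inherited from the data model:

- The receipt date is never missing; the draw date may be. The
  best-estimate-date is the draw date when present, else the receipt date.
- Culture rows cannot be grouped into blood-culture *sets* (bottle
  numbering is not interpretable), so dates are the grouping primitive and
  duplicate per-bottle rows are harmless.
- Hospital contacts carry an in-date and out-date and are either inpatient
  or outpatient (ambulatory/emergency); patient identifiers are opaque.
- Comorbidity arrives pre-categorized (Charlson score 0, 1–2, >2); no ICD
  parsing is in scope.

## Windows and parameters

| parameter | default | role |
|---|---|---|
| episode span | 2 days | index date plus the day after |
| contamination screen | 5 days | index date plus 4 following days; repeat commensal growth inside rejects contamination |
| `time_in` retention | ≥ −2 days | drop contacts admitted > 2 days after the culture |
| `time_out` retention | ≤ 30 days | drop contacts discharged > 30 days before the culture |
| HCA window | 30 days | prior contact ending 1–30 days before the index date |
| reference attachment | 30 days | unassessed cultures join the preceding reference episode |
| incident lookback | 365 days | prior positive culture blocks incidence (inclusive boundary) |

All window constants are exposed in `RunConfig` and must be positive; the
defaults are the surveillance rules' published values and are not tuned.

## Interpretations where the rules are under-specified

These are this package's own documented decisions; each is flagged in code
or report metadata.

- **Transfer clause arithmetic.** The same-day-transfer condition is stated
  as "`time_out − time_in` ≥ 2 days", which for a single contact equals
  `indate − outdate` and can never be positive. It is implemented as the
  stay length `outdate − indate ≥ 2` days (≥ 1 day when the minimal
  `time_in` is 1), i.e. the magnitude of the stated difference. Any
  retained contact may satisfy the clause, including the index admission.
- **Minimal `time_in` < 0.** The retention bound keeps contacts admitted up
  to 2 days after the culture date, so the minimal inpatient `time_in` can
  be −1 or −2 — a case the onset rule's two branches do not cover (it
  cannot arise when every culture is drawn during an admission). Such
  episodes are classified community-onset under a distinct provenance
  branch (`admitted_after_culture`).
- **No retained inpatient contact** is likewise classified community-onset,
  with a logged warning (`no_inpatient_contact`).
- **Contamination screen anchoring.** The 5-day repeat-growth screen is
  anchored at the episode index date and evaluated against *all* of the
  patient's cultures, not only episode members, since repeat commensal
  growth shortly after the index date argues against contamination
  regardless of episode windowing.
- **Reference attachment precedence.** An assessed culture always anchors
  or joins an episode by the assessed-date rule; the 30-day attachment
  window applies to unassessed cultures only, and an unassessed culture
  inside two overlapping windows joins the earlier episode. Unassessed
  cultures predating the patient's first assessed date stay unattached.
- **Incident boundary.** "Within 365 days prior" is inclusive: a culture
  exactly 365 days before the index date makes the episode non-incident.
- **Linking.** How reference episodes were matched to computer
  classifications is not specified upstream; this package pairs on equal
  index dates with a fallback to 2-day-window containment, and treats an
  ambiguous match (impossible when both derive from the same records) as a
  hard error.
- **Landis–Koch edges.** Shared band boundaries are assigned to the lower
  band, except 0 which opens the slight band; negative kappa is "poor".
  The convention is embedded in every report's metadata.
- **Mortality.** Death on day 0 through day 30 after the index date counts;
  emigration before day 30 without death removes the episode from the
  denominator and is reported separately. The crude odds ratio uses the
  closed form with a log-normal 95% CI — identical to logistic regression
  with a single binary covariate — and refuses zero cells rather than
  applying a silent continuity correction. Adjusted models and
  Kaplan–Meier estimation are deliberately out of scope; standard
  statistical tooling covers them.
- **Report rounding.** Kappa to 2 decimals and percentages to 1 decimal,
  alongside the raw fractions. When a published table's printed summary
  percentage conflicts with its printed cell counts, the counts are
  treated as authoritative.

## The synthetic cohort generator

The generator emulates the *structure* of two hospital laboratories linked
to a national patient registry: per-organism culture rows duplicated per
bottle (1–4 rows at one site, 1–2 at the other), ~8.8% missing draw dates,
receipt 0–1 days after draw, a commensal/pathogen catalogue including
provisional labels, admissions/transfers/outpatient contacts placed around
culture dates, a lag year of prior cultures, physician assessments with
per-comparison flip rates, and 30-day deaths by true class.

Planting is **constructive**: each episode's contacts are built by
`plant_transfer_scenario` to exercise exactly one onset branch (direct
admission ≥ 2 days before; same-day transfer; ward stay spanning the
culture date; same-day/day-before admission; outpatient-only;
admitted-after), and organisms are chosen so the contamination and
polymicrobial rules provably yield the planted class. Ground truth is
therefore exact, not estimated. Two consequences worth knowing:

- Planted episodes are spaced ≥ 45 days apart so no window of one episode
  touches another; masked draw dates keep `receipt = draw` so the
  best-estimate-date never moves. Real data have neither property — the
  generator validates the rules' implementation, not their clinical
  accuracy on entangled timelines.
- Scenarios that would entangle windows (a second culture date combined
  with a day-before admission, an emergency-room-only contact, or a
  post-culture admission) are planted as single-date episodes, because the
  extra offset pair would genuinely change the rule outcome.

Default rates (20% contamination, 13% polymicrobial, 30% hospital-onset,
40% healthcare-associated among community BSI, ~20% 30-day mortality, 10%
unassessed episodes, 1% lag-year cultures) mirror the shape of a 3-year
two-hospital cohort; the default per-comparison discordance rates (5.4%,
4.9%, 16.9%, 36%) mirror the discrepant shares observed when routine
physician assessments are compared with these algorithms. Under zero
discordance the pipeline recovers 100% of planted labels with kappa 1.00
in all four comparisons; under a flip rate δ the expected percent
agreement is 1 − δ per comparison, which the test suite checks within
three binomial standard errors at ~2,000 episodes. Statistical-fidelity
properties are checked at ~5,000 episodes; the property suites use
1,200-instance randomized brute-force comparisons. These sizes keep the
whole suite in the tens of seconds while leaving binomial bands narrow
enough to be informative.

A nuance on lexicon monotonicity: enlarging the commensal set can only move
*isolated* episodes from BSI toward contamination. When another culture of
the same patient falls inside the 5-day screen window, relabelling its
organism as commensal can newly trigger the repeat-growth clause; the
monotonicity property is therefore asserted on isolated episodes and on
simulated cohorts (whose episode spacing guarantees isolation), not
universally.

## Known limitations

- Commensal classification is purely lexical; no susceptibility data, no
  species-level pathogenicity logic, and the default coagulase-negative
  staphylococcus species list is not exhaustive (it is fully overridable).
- The onset rules presume cultures are drawn in hospital; cohorts with
  substantial primary-care sampling will hit the community-by-convention
  branches often, and the warning counts should be inspected.
- The generator does not model microbial epidemiology, seasonality,
  antibiotic resistance, or site-clustered missingness of draw dates
  (missingness is independent per row).
- Percent agreement and kappa are computed on linked pairs only; reference
  episodes without a computer counterpart (impossible when both derive
  from the same records) are reported, not imputed.
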