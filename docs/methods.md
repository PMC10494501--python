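# Methods

## Design

The package estimates within-cohort changes in hospitalized-fracture
incidence after initiation of an osteoporosis medication. Each cohort's
fracture rate in a risk window is divided by the same cohort's rate in
the 3 months immediately following initiation (the baseline window). The
design assumes (i) individual fracture hazards are piecewise constant on
the scale of the analysis windows, (ii) treatment benefit is negligible
during the baseline window, and (iii) person-level risk factors that do
not change over the ~2-year horizon cancel out of the ratio. Assumption
(ii) is conservative for fast-acting antiresorptives (denosumab lowers
bone resorption within the first month), which biases their estimated
benefit toward the null. Time-varying confounding (e.g. ageing) is not
removed; age-stratified runs are the diagnostic for it.

## Date and interval conventions

All dates are integers (days since 1970-01-01); every interval is
half-open `[start, end)`. A "last covered day" or "death date" printed in
output is `end - 1`. Calendar criteria are fixed day counts so every rule
is testable: 3 months = 91 days, 6 months = 183, 1 year = 365, 2 years =
730, 3 years = 1095. Person-years = person-days / 365.25; rates are per
1000 person-years.

## Treatment episodes

A delivery of `units` packs covers `units x coverage_days_per_unit` days
starting at `max(dispense date, end of current coverage)` — an early
refill stockpiles, extending coverage rather than overlapping it. The
episode continues while each refill arrives within 30 days (grace) after
current coverage ends; otherwise it ends by discontinuation on the last
covered day. Death and end of observation truncate with their own end
reasons, and initiation of a different study drug before the episode's
end censors it as a switch the day before the new drug's first delivery.

The index date is the first delivery in the inclusion window with no
dispensing of the same drug in the prior 365 days; the washout is
class-level for the three oral bisphosphonates, which also share one
episode stream (an alendronate-to-risedronate change is a refill, not a
switch). A delivery after a gap starts a new candidate episode only if it
re-satisfies the washout.

Coverage days per unit are configuration, defaulting to: oral
bisphosphonate and raloxifene 30 d (pack-month), teriparatide 28 d (pen),
denosumab 182 d (half-yearly injection), zoledronic acid 365 d (yearly
infusion). Claims carry no days-supplied field, so these are modelling
choices, not data.

## Eligibility and assignment

A woman is eligible when at least one episode passes all criteria:
female; age ≥ 55 at index; ≥ 1095 days of data before index; ≥ 730 days
of observation window after index (death within 2 years does **not**
disqualify — it censors person-time); episode length ≥ 183 days; no
cancer/Paget-coded stay admitted in the 365 pre-index days; and no second
study drug dispensed on the index date. Exclusion reasons are reported as
the union over a woman's failing episodes (they are not mutually
exclusive). Eligible women are assigned to exactly one cohort by drug
hierarchy — most recently marketed first: denosumab, zoledronic acid,
teriparatide, oral bisphosphonates, raloxifene — and the chosen episode's
index date becomes the woman's index date.

The comorbidity score is a configurable weighted sum of diagnosis-prefix
flags over the 3-year look-back — a deliberate simplification of
claims-adapted Charlson-style indices, reported as "comorbidity score".

## Fracture events

Stays contribute ICD-10 diagnosis codes in principal, related, or
associated position (all three accepted by default) and procedure codes.
The shipped prefix map (S72 hip; S22.0, S32.0, T08 vertebral; S52
wrist/forearm; S42.0 clavicle; other S42 humerus; other S22 ribs; other
S32 pelvis; S82 leg; longest prefix wins) is an editable stand-in for a
full national code list. One raw event per (stay, site), dated at
admission — the standard claims convention, since onset is not recorded.

A same-site recurrence is an independent event only if it falls at least
90 days (inclusive: a day-90 gap qualifies) after the previous
independent same-site event with no other-site fracture strictly between
the two dates. Non-independent events are retained and flagged for audit
but never counted in incidence. Site groups overlap: wrist/forearm events
also belong to the non-hip/nonvertebral group (wrist/forearm, humerus,
clavicle, ribs, pelvis, leg).

## Person-time and censoring

Windows relative to index: baseline [0, 91), months 3–12 [91, 365), 3–18
[91, 548), 3–24 [91, 730). A woman contributes the overlap of each window
with `[index, censor)`; events do not truncate follow-up (incidence
counting, not time-to-first-event), so a baseline fracture does not
remove a woman from later windows. Censoring by mode:

- **as-treated**: episode end (discontinuation, switch, death, end of
  data);
- **intent-to-treat**: end of study period (2018-12-31) or death;
- **virtual exposure**: episode end plus a drug-specific carry-over —
  365 days for bisphosphonates including zoledronic acid, 30 days
  otherwise — capped by death and end of data.

The post-discontinuation window runs from the day after the last covered
day (keeping it disjoint from on-treatment time under the half-open
convention) until the first dispensing of any study drug, death, or end
of data. The post hoc analysis of oral-bisphosphonate early discontinuers
(episode < 183 days, otherwise eligible) compares [91, 183) with baseline,
censoring at reinitiation, death, or end of data — these women are off
treatment for most of the comparison window, so discontinuation itself
does not censor.

## Statistics

Rates carry exact Poisson (Garwood) 95% intervals:
`chi2.ppf(alpha/2, 2k)/2` and `chi2.ppf(1-alpha/2, 2k+2)/2` scaled by
`1000/PY`, lower bound 0 at k = 0. The IRR interval conditions on the
total event count: given n = k_num + k_den, k_num is binomial with
p = PY_num·IRR/(PY_num·IRR + PY_den); a Clopper-Pearson interval on p is
mapped through the monotone transform IRR = p/(1-p) · PY_den/PY_num. With
k_num = 0 the lower bound is 0 and the upper bound finite; with k_den = 0
the point estimate is infinite and the row is flagged undefined (the
finite one-sided bound is still reported). A log-normal Wald option
(`method="lognormal"`) exists for comparison; the method tag is recorded
in every output row. Display rounding (rates to 2 decimals, IRRs to 1–2)
is applied only in rendered tables; machine output keeps full precision.
No multiple-testing adjustment is applied. Forest output is plot-ready
data (log IRR and log bounds, ordered labels, undefined rows omitted with
a count), not rendered graphics.

## Synthetic claims generator

The generator emulates exactly the structure the design assumes. Each
woman receives one drug, an index date uniform on 2014-01-01..2016-12-31,
an age from a normal(72, 9) truncated at 55, observation 2010-01-01 to
2018-12-31, and a planned treatment duration from a per-drug log-normal
(medians 360–520 days) floored at 183 days unless she is a planted early
discontinuer. Refills recur at coverage boundaries with small jitter
(clipped below the grace period, so realized discontinuation equals the
plan). Her fracture process per site group is piecewise-constant Poisson:
baseline hazard h0 on [index, index+91), h0 × on-treatment multiplier on
[index+91, discontinuation), h0 × post-discontinuation multiplier
afterwards. Every event produces one hospital stay admitted that day with
a site-appropriate code, 80% in principal and 20% in associated position.

Default hazards and multipliers are per-drug configuration whose
magnitudes mirror treated postmenopausal cohorts in national claims data
(e.g. baseline vertebral 8.78 ‰PY for denosumab initiators vs 34.75 ‰PY
for teriparatide initiators, on-treatment vertebral multipliers 0.34–0.56,
a denosumab post-discontinuation rebound). They are configuration, not
constants. Because site groups overlap downstream, each group is driven
by a disjoint carrier site (hip, vertebral, wrist/forearm, pelvis); the
observed non-hip/nonvertebral group therefore aggregates the wrist and
pelvis processes and its true rate is the sum of the two configured
rates — planted-IRR recovery studies use the clean hip/vertebral/wrist
processes.

Planted exclusions (`exclusion_fractions`): a pre-index cancer stay, an
index age of 45–55, a second drug dispensed on the index date, and a
planned duration under 183 days (defaults 2%, 2%, 1%, 25%; the short-
treatment fraction is the dominant exclusion in real cohorts). With all
fractions zero, every generated woman passes eligibility; to keep that
invariant exact, death times are drawn exponentially (default 10 ‰PY)
*after* the 183-day qualification point — a simplification: the
generator has no early mortality, no comorbidity-correlated hazards, no
inter-refill gap distribution estimated from real data (none is
published), and no coding noise beyond the diagnosis-position mix. Tests
passing on this generator therefore validate the pipeline's arithmetic
and logic under the design's own assumptions; they say nothing about
coding quality or confounding in real claims.

## Calibration studies and problem sizes

`osteoirr.validation` runs the pipeline in memory for simulation studies.
Parameter recovery uses 20,000 women on one drug with a planted vertebral
on-treatment IRR of 0.5 and post-discontinuation IRR of 2.0 (baseline
40 ‰PY); the estimates land within their own exact intervals and within
0.1 of the truth. Interval coverage uses 200 replicates of 2,000 women.
Exact conditional intervals are conservative by construction: at sparse
counts (~20 events per cell) their measured coverage is ~97.5%, above
nominal, as theory predicts. The coverage study therefore runs in a
moderate-count regime (baseline 120 ‰PY, ~60–90 events per cell), where
measured coverage settles at 94–96.5% — near-nominal behavior is a
property of count magnitude, not of the estimator options. Brute-force
oracles (a day-by-day pill-supply simulation for episodes, a day-count
loop for person-time) are kept in the test layer and agree exactly with
the interval arithmetic on 1,000-woman datasets.

## Known limitations

- The hierarchical assignment and the ≥ 6-month criterion restrict
  generalizability to persistent users; the early-discontinuer post hoc
  path exists precisely because oral-bisphosphonate users discontinue
  early at high rates.
- The default fracture code map is a stand-in; site classification in
  production use requires the jurisdiction's validated code list.
- The exact IRR interval is undefined (flagged, not dropped) when the
  baseline cell has zero events; strata with little person-time will
  produce such rows.
- Reinitiation detection treats any study-drug dispensing after
  discontinuation as reinitiation; it does not distinguish restarting the
  index drug from starting another.
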