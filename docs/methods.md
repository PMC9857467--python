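# Methods

## Model structure

Individual-level state-transition model with six health states — healthy
vision, untreated amblyopia, untreated amblyopia risk factor (strabismus,
anisometropia or media opacity), treated amblyopia, vision loss in the
nonamblyopic eye, dead — over 15 annual cycles from age 3 to 17. A
microsimulation (rather than a cohort matrix) is required because several
pieces of per-child memory are path-dependent: social-assistance status
(gates glasses coverage), the once-only optometric exam, the
glasses-replacement clock, and treatment history. A closed-form cohort
matrix is retained as a validation oracle for the degenerate no-testing
configuration.

Within-cycle event order: **testing → referral → optometrist diagnosis →
treatment adherence → treatment outcome → QALY/cost accrual → progression →
mortality**. Testing is placed at the start of the program year; the QALY
for a cycle reflects the post-treatment state (a child treated at the start
of a year spends that year in the resulting state); progression is skipped
in a treatment cycle; a child dying in a cycle still accrues that cycle.
No half-cycle correction is applied (annual cycles, events at cycle start).

Key structural assumptions:

* Incidence (healthy → risk factor at 0.033/yr; risk factor → amblyopia at
  0.32/yr) operates at ages 3–5 only. After age 5 untreated states persist
  unchanged — undiagnosed impairment is irreversible — except for an annual
  vision-loss hazard (4×10⁻⁵ at ages 5–15, 5×10⁻⁵ at 16–18) while amblyopia
  remains untreated.
* Treatment resolves within its cycle: a treated risk factor always returns
  to healthy vision; treated amblyopia succeeds with an age-declining
  probability (0.89/0.76/0.65 at 3/4/5), success splitting 0.472/0.528
  between full recovery and a residual treated-amblyopia state (utility
  0.99). Failures remain untreated and can be re-detected at later screens
  (ages ≤ 5). Treated amblyopia is absorbing — no relapse.
* The optometrist classifies the true state correctly with probability
  0.95; misclassification in either direction yields "no condition", so
  healthy children are never falsely treated but always incur the
  diagnostic-exam fee when they attend.
* Unilateral impairment only; no refractive error without amblyopia risk;
  no demographic covariates.

## Costs

2019 CAD, public-payer perspective, discounted at 1.5%/yr beyond year one
(as are QALYs). Unit costs: well-child visit 41.34 (charged whenever a
visit occurs in the reference strategy — visits happen with probability
0.84/yr at ages 3–5 whether or not the physician screens), primary-care
screen 11.50 (probability 0.61 given a visit), school screen 10.00 plus
0.01 per-child screener training, optometric diagnostic exam 42.50 (every
attendee), one follow-up visit 25.15 in each treatment cycle, and glasses
120.70 for social-assistance recipients (4% of the cohort) at treatment
start and every 3 years while impaired. USD figures are a reporting-time
conversion at 1.3268 CAD/USD, never an internal unit.

Because the recurring optometrist follow-up schedule for children under
care is not fully specifiable from the available description, this model
books exactly one follow-up visit per treatment course. This is the main
known driver of comparator-strategy cost levels and is flagged as a
limitation below.

## Testing pathways

A screen first resolves *inconclusive* with a condition-specific
probability (interpreted as a marginal probability; sensitivity and
specificity then apply to the conclusive remainder). Conclusive results are
positive with the condition-specific sensitivity for diseased children and
with 1 − specificity otherwise (a treated child screens like a healthy
one). Referral and adherence probabilities depend on strategy, age and
result type. The optometric strategy has no screening step — attendance
(0.88) implies direct diagnosis — and its single exam is placed at age 3,
the earliest-benefit choice; the age is configurable
(`optometric_exam_age`) for sensitivity exploration.

## Probabilistic analysis

Outer loop over parameter draws; within each iteration one cohort and one
block of per-child, per-cycle, per-decision uniform variates are shared by
all three strategies (common random numbers). Distribution families:

* **beta** for probabilities with published uncertainty, method-of-moments
  with an effective sample size of 100 pseudo-observations (mean exact,
  spread comparable to the published interval widths);
* **log-normal** for treatment success and vision-loss hazards, median at
  the reference value, 97.5th percentile 1.2× the median, truncated at 1;
* **normal** for social-assistance receipt, SD 10% of the mean, truncated
  to [0, 1];
* **point** for everything else (including the life table, incidence rates,
  the success split, optometrist accuracy and all unit costs).

The published dispersions are not available, so these defaults are declared
rather than estimated; each is overridable per key.

Two levels of summary are produced. *Iteration level*: cohort means per
draw, for second-order uncertainty. *Trial level*: per-child paired
differences pooled across iterations, used for the cost-effectiveness-plane
quadrants, the "on the y-axis" share (pairs with exactly zero QALY
difference — meaningful only because of common random numbers), and the
acceptability curves. The paired corrections (+0.0001 CAD to each
incremental cost, −0.0001 to each incremental QALY) push exact ties into
the northwest quadrant, i.e. against the comparator. A comparator trial
counts as cost-effective at willingness-to-pay λ iff it lands in the
southeast quadrant or in the northeast with ICER < λ; southwest trials
(savings without benefit) never count. The acceptability curve is the
proportion of such trials per λ (pairwise, reference takes the complement);
a multiway net-monetary-benefit variant (`cea.ceac_nmb`, ties to the
reference) is provided for completeness.

Seeding: a single user seed feeds a `SeedSequence` tree (parameter stream,
one stream per iteration for cohort + uniforms), so every output is
bit-reproducible given the manifest.

## Synthetic cohort

The generator *is* the stated world: 25 000 children, entry states drawn
from (0.058, 0.202, 0.740), social assistance 4%, no other covariates. It
emulates none of the features of a real administrative cohort — no
clustering by school or clinic, no correlation between uptake and disease
risk, no migration in or out. A green test therefore establishes internal
consistency of the model and its statistics, not external validity.

## Numerical choices

* Probabilities sampled outside [0, 1] are truncated (relevant only to the
  log-normal and normal families).
* Degenerate beta means (0 or 1) are carried as point masses.
* A zero mean QALY difference yields the explicit ICER label `UNDEFINED`,
  never a division.
* Quadrant boundary ties (Δcost = 0) count as "cost ≥ 0", against the
  comparator.
* All accumulations are in float64; paired equality of QALY streams under
  common random numbers is exact, not approximate.

## Known limitations

* The comparator strategies' optometrist utilisation is likely understated:
  with a single follow-up per treatment course, school screening and the
  optometric exam cost roughly 31 and 43 CAD per child — their published
  counterparts are about twice that, while the reference strategy (≈140)
  matches its published level. Incremental savings are correspondingly
  overstated. Recurring follow-up schedules were explored analytically and
  no single faithful schedule reconciles both comparators at once.
* With the untreated amblyopia and risk-factor utilities raised to 1.00,
  treating additional children becomes a small net QALY loss (treated
  amblyopia carries 0.99), so the optometric strategy loses dominance in
  that scenario under this structure.
* 15-year horizon; lifetime extrapolation is out of scope, as are family
  out-of-pocket costs (e.g. patches).
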