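# Methods

## Model structure

`graftcea` evaluates two strategies for acetabular impaction bone grafting
during revision hip arthroplasty — decellularised allograft (intervention)
versus fresh-frozen allograft (comparator) — with a decision-tree entry into
a three-state Markov cohort model (`post_revision`, `re_revision`, `death`)
run in one-year cycles.

**Year 0 (decision-tree entry).** The whole cohort undergoes its first
revision: it incurs the full per-surgery cost (base procedure cost plus
graft price × heads used) and accrues the revision-year utility (0.397),
undiscounted. Because a revision year — first or repeat — carries the same
surgery cost, utility and perioperative mortality, year 0 is modelled as
occupancy of the `re_revision` state; the transition out of year 0 therefore
uses the perioperative-blended death probability, which is how the elevated
first-year mortality (0.047 at age 71) acts on the initial cohort in a
memoryless chain. The alternative convention (no year-0 utility accrual,
`year0_utility=False`) is implemented; printed lifetime totals cannot
distinguish the two, and the default is the package's choice, with the
difference being a constant 0.397 QALYs in both arms (it cancels from every
incremental quantity).

**Cycles 1..H.** Occupancy propagates through year-specific 3×3 matrices.
From `post_revision`: re-revision with the strategy's annual probability,
death at background mortality, remainder stays. From `re_revision`: the same
re-revision probability, death at the perioperative-blended rate, remainder
returns to `post_revision` (the state has no memory beyond one year). Death
is absorbing. A year whose death probability is 1 is fully absorbing; any
other parameter combination that would drive a row negative raises an error
naming the year. Rewards: `post_revision` accrues the annual care cost
(£54.19) and utility 0.685; `re_revision` accrues the full surgery cost of
its arm and utility 0.397. Both are discounted by 1/(1+r)^year, r = 3.5%/yr
for costs and effects alike. No half-cycle correction is applied by default
(transitions at cycle end, rewards on the state occupied during the cycle);
a trapezoidal half-cycle correction is available behind a flag for
comparison.

**Horizon.** The cohort's age during cycle k is `floor(starting_age + k − 1)`.
By default the model runs until that age exceeds 100 — 30 cycles for the
base-case starting age of 71.7, visiting ages 71..100 inclusive, so the
background death schedule spans 0.0195 to 0.364 — after which death is
certain and the model terminates. An explicit `horizon_years` overrides
this; years beyond age 100 are then fully absorbing.

## Mortality

Background mortality is a national-style life table `qx` by single year of
age (unisex, unstratified). Revision-state years use a **replacement**
convention for perioperative risk: the 90-day surgical window replaces
background mortality for its duration,

    1 − q_rev = (1 − p90) · (1 − q_bg)^(275/365).

The replacement (rather than additive) convention is required for a blended
probability to fall *below* background at high ages, as the year-29 pair
(0.306 vs 0.364) does. The window length is configurable.

The 90-day surgical mortality `p90` is not published as such. The two
published blended endpoints invert to p90 ≈ 0.0327 at age 71 and ≈ 0.0239
at age 100 — inconsistent with a constant — so the default is linear
interpolation in age between those two derived anchors (constant outside
71–100). A user-supplied constant, per-year vector or age function can
replace it.

## Synthetic inputs

No input data ship with the package; everything is generated.

**Life table.** A Gompertz–Makeham hazard μ(x) = λ + αe^(βx) with a small
fixed accident floor λ = 5×10⁻⁴/yr; α and β are solved in closed form so
that q(71) = 0.0195 and q(100) = 0.364 exactly. Ages 0–105. The shape
between and outside the anchors is synthetic (pure exponential-hazard
growth); it reproduces no real national table, but is monotone above age 40
and log-linear between the anchors, which is the behaviour the model is
sensitive to. Passing tests therefore show correctness of the machinery and
of the anchored mortality levels, not agreement with any particular
country-year table.

**Base case.** Published point values: utilities 0.397/0.685; decellularised
price £10,040.72 per head (its structural build-up from the seven production
components under a 50% sales-and-distribution fraction and 19.4% operating
margin gives £10,044.44, a 0.04% residual attributed to per-component
rounding; the printed price is used); fresh-frozen price £709.71 (the tissue
retrieval cost); 2.43 heads per surgery; care cost £54.19/yr; discount 3.5%;
starting age 71.7 (the alternative printed value 71 is accepted as an
override). The base surgery cost £14,618.05 is back-computed from the
published per-surgery totals (£39,017 − 2.43 × £10,040.72; cross-checked
against the fresh-frozen total within £0.40) — a derived default,
overridable.

**Fresh-frozen re-revision probability (calibrated).** The comparator's
revision evidence is unpublished. The packaged default is a cumulative
fraction of 0.2238 over a 10-year follow-up, i.e. 0.02502/yr after the
constant-hazard conversion, calibrated once so the deterministic model
reproduces the published incremental QALY gain of 0.077. With that single
calibrated input the model also lands within 1% of the published incremental
cost (£20,970 vs £20,834), base-case ICER (£272,390 vs £270,059) and
same-rate incremental cost (£28,809 vs £28,783), and within 7% of the
per-arm QALY totals (7.38/7.31 vs 6.93/6.86) — emergent agreement, not
additional fitting. The value is an estimate standing in for real study
data and is overridable through the `evidence` config section.

**PSA distributions.** Families follow the conventional health-economics
assignment by support: beta for utilities and probabilities (moment
matched), gamma for costs, normal for age (truncated to 40–100 by
rejection). Published spreads: age 71.7 ± 11.16 (one-SD points 60.54 and
82.86). Unpublished spreads are chosen once: utilities SD 0.05; care cost
gamma SD £61.50, sized so its mass spans the published £0–£301 extreme
scenarios; graft prices SD = mean/2; base surgery cost SD £2,923.60
(mean/5, sampled once and shared by both arms); re-revision probabilities
SD = 0.75 × mean. Parameters are sampled independently (nothing indicates
correlation); each draw uses its own deterministic sub-stream
(`default_rng([seed, draw])`), so draw *i* is invariant to the total number
of draws. Draws producing an infeasible transition row are rejected and
counted, never clipped.

## Cost-effectiveness statistics

ICER = ΔC/ΔE with dominance labels covering all sign patterns; the ratio is
undefined (reported as a dash) at ΔE = 0. The published base-case table row
divides *rounded* operands (20,834/0.077 = 270,571 vs the printed 270,059);
the package carries full precision internally and rounds only in reports,
so no attempt is made to reproduce that rounding artefact. Net monetary
benefit NMB = WTP·ΔE − ΔC underpins the acceptability curves; a tie
(NMB = 0) counts for the comparator. "Favoured" strategy in scenario tables
is decided at £30,000/QALY by default.

Threshold searches invert the full model by bracketed Brent root-finding:
the decellularised price (ICER decreasing in price; bracket 0 to current
price) or the decellularised re-revision probability (ICER increasing;
bracket 0 to the comparator's probability) at which the ICER equals the
willingness to pay, converged to within £1/QALY on re-evaluation. A bracket
without a sign change raises a diagnostic error — at the full graft price no
re-revision rate reaches £30,000/QALY, which is why the CLI `threshold`
command first finds the break-even price and then the break-even rate *at
that price* (recovering ≈ 64 re-revisions per 10,000 patients per year with
the packaged bundle).

## Numerical choices and verification scale

Probability conversions use `log1p`/`expm1`, making the one-year round trip
exact to machine precision. Transition rows are validated to sum to 1 within
1e-12; trace occupancy conserves mass within 1e-10. The cohort engine is
cross-checked against an independent individual-level Monte-Carlo
microsimulation (100,000 patients on a 5-year toy model, agreement within 3
Monte-Carlo standard errors). The test suite exercises PSAs at 50–1,000
draws and moment-recovery sampling at 10,000 draws; the CLI default is
10,000 model draws (~10 s on one CPU). Threshold bisection is verified
against an exhaustive 1e-5-resolution grid search on a two-cycle model.

## Limitations

* The comparator's re-revision evidence and all unpublished PSA spreads are
  reconstructions; absolute cost/QALY levels inherit that uncertainty, and
  the published base-case ICER is matched only approximately (~1%).
* The life table is an endpoint-calibrated synthetic stand-in, unisex and
  unstratified; no cohort projection.
* The intervention's effectiveness rests on a single demineralised-bone
  proxy study, as in the underlying evidence base.
* No memory beyond the one-year re-revision state (no tunnel states), no
  currency conversion or inflation machinery, no value-of-information
  analysis, and only two strategies (no extended dominance).
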