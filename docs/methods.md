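# Methods

## The decision problem

Metabolic and bariatric surgery (MBS; Roux-en-Y gastric bypass or sleeve
gastrectomy) is compared with usual medical care (UC) for adults with
obesity and comorbid, poorly controlled type 2 diabetes, from a public
health-system perspective.  Outcomes are lifetime discounted costs
(2022/23 AUD) and quality-adjusted life years (QALYs), summarized as the
incremental cost-effectiveness ratio (ICER) with dominance labelling and
the net monetary benefit (NMB) at a willingness-to-pay threshold of
A$64,000 per QALY.

## Model structure

A Markov cohort model with five mutually exclusive states: overweight
(OW, BMI 25–29.9 kg/m²), obesity classes I–III (OB1 30–34.9, OB2
35–39.9, OB3 40+), and an absorbing dead state.  Cycles are annual;
the default horizon is 40 cycles.  Rewards (costs, utilities) accrue on
start-of-cycle occupancy and are discounted at 5% per year with cycle 0
undiscounted.  There is no half-cycle correction by default (a flag
enables one).

The base cohort enters at age 52.4 distributed 0.5% / 20.0% / 79.5%
across OB1/OB2/OB3.

**Surgery arm.** A fixed 12-month class-change matrix (e.g. 34% of OB3
entrants reach OW, 23% OB1, 19% OB2, 24% remain) is applied once, by
default at model entry, so cycle-0 occupancy and utilities already
reflect the post-surgery distribution — quality-of-life gains begin in
the year of surgery, while management-cost savings begin the year
after, because cycle 0 is charged the micro-costed first-year surgery
cost instead.  Surgical mortality (0.5%) combines with first-year
background mortality as independent competing risks,
1 − (1 − p_surg)(1 − q).  Thereafter the cohort drifts up one BMI class
with probability 1.8%/year.

**Usual-care arm.** A two-sided annual drift: up 6.03%, down 5.57% per
year.  At the boundaries (OW cannot move down, OB3 cannot move up) the
blocked mass stays put.

**Mortality.** Background mortality comes from an annual life table; the
diabetic fraction of the cohort faces the population hazard scaled by a
risk ratio of 1.54 (capped at probability 1):
q = f·min(1, qx·RR) + (1−f)·qx.  Mortality is folded into each cycle's
transition matrix ahead of BMI drift; the order is a convention (it is
not identifiable from annual data) and is fixed and documented.  The age
used in cycle t is entry age + t.

**Diabetes.** The model does not split states by diabetes status;
instead a static diabetic fraction f acts as a cohort-level mixing
weight on mortality, utility and cost.  UC: f = 1 for life (entry
required poorly controlled diabetes; no remission is assumed).
Surgery: f = 1 in cycle 0 and 0.101 from cycle 1 on (the 12-month
post-surgery proportion with diabetes, insulin use as proxy, static
thereafter).  The alternative reading of the 12-month figure — 10.1%
*in remission*, i.e. f = 0.899 — is available as a config override
(`diabetes_fraction_surgery: 0.899`); see "Fidelity" below.

**Utilities.** Per-state weights (OW 0.782, OB1 0.730, OB2 0.599, OB3
0.550) measured at cohort entry, applied in both arms.  Each year of
age beyond the *entry* age subtracts 0.003 (entry-anchored because the
baseline weights are entry measurements; scenarios re-anchor at their
own entry age), and diabetes subtracts 0.116·f.  Utilities floor at 0;
dead contributes 0.  The narrative diabetes disutility of 0.05 that
circulates alongside the tabulated 0.116 can be set via
`disutility_diabetes`.

**Costs.** Annual management costs per state: OW $6,762, OB1 $7,574,
OB2/OB3 pooled $8,926.  The 5% (OB2) and 10% (OB3) "cost inflators" are
interpreted by default as *static class-cost differentials* — OB2 costs
1.05× and OB3 1.10× the pooled value in every cycle
(`class_inflator_mode: differential`) — because they are described as
deliberately smaller than the 18% cross-sectional OB2/3-vs-OB1
differential in the underlying costing study, and because annual
compounding (1.10³⁹ ≈ 41×) produces lifetime totals several-fold larger
than the published ones.  `class_inflator_mode: compound` applies them
as c·(1+g)^cycle instead.  Diabetes management adds $3,997·f per year,
compounding at 5% per year of diabetes by default
(`compound_diabetes_cost`).  First-year surgery costs ($15,734 for
OB1/OB2 entrants, $18,242 for OB3) replace the cycle-0 management cost
by default, since the micro-costing covers the six months before and
twelve months after surgery (`surgery_cost_replaces_management`).

## Life table

Only two anchor death probabilities are available (0.00053 at age 30,
0.15277 at age 90, male/female-weighted).  Adult all-cause mortality is
approximately log-linear in age, so the packaged table interpolates a
Gompertz hazard q(x) = a·e^{bx} through the anchors (b =
ln(q₉₀/q₃₀)/60 ≈ 0.0944), tabulated for ages 18–90; lookups clamp to
the age-90 rate beyond the table, matching the "modelled to age 90"
horizon.  Lookups at fractional ages interpolate log-linearly.  Users
can substitute an empirical table via a two-column CSV (age, qx).  The
Gompertz approximation understates the curvature of a real national
life table in mid-life, which shifts absolute survival slightly; both
arms share the table, so increments are less sensitive.

## Probabilistic sensitivity analysis

Every parameter with published uncertainty is sampled independently per
draw: Beta and Gamma distributions are parameterized from the printed
mean and standard deviation by the method of moments (the standard PSA
convention when only two moments are reported); initial age is
Triangular(28.1, 52.4, 65) with the base value as mode, rounded to one
decimal, with the horizon kept at 40 cycles.  The 12-month surgery
transition matrix is fixed, as published.  Each parameter owns a
counter-based random sub-stream keyed by (seed, parameter index) in a
canonical order, so identical seeds are bit-reproducible and appending
a new parameter does not perturb existing draws.  Infeasible joint
draws (e.g. up + down drift > 1) are resampled with a capped retry
count (never observed at the published standard deviations).  Default
10,000 draws (Monte-Carlo SE on a proportion near 0.8 is ≈ 0.4 pp).
An optional rejection filter enforcing monotone state utilities is off
by default because only marginal distributions are published.

Summaries: proportions of draws in the cost-saving & QALY-gaining (SE)
quadrant, in NE below the threshold, in SW, and the composite
below-threshold proportion; SW counts as below the threshold to match
the published composite (a stricter positive-NMB rule is available via
`sw_below_wtp: nmb`).  Boundary points (ΔC = 0, ΔQ = 0) deterministically
join the cost-saving / QALY-gaining side (measure-zero under PSA).  The
95% credible ellipse uses the sample mean, sample covariance and the
χ²(2) 0.95 quantile (≈ 5.991) under a bivariate-normal approximation.

## One-way sensitivity analysis

Per the published protocol: transition/drift probabilities ±50% of base
(clamped to [0, 1]); utility and disutility weights ±1 SD (clamped);
costs from 70% of base to base + 1 SD (costs are highly right-skewed);
structural parameters (discount rate 3–7%, horizon 25–55 cycles,
mortality risk ratio 1.33–1.78, post-surgery diabetes fraction 5–15%,
class inflators, initial age 28–65) over their printed pairs.  Each bar
records NMB at both ends with all other parameters at base; entries are
sorted by descending width with alphabetical tie-break.  One bar per
published cost row (pooled parameters such as the OB2/OB3 management
cost move together).  The initial BMI-class shares are not varied
one-at-a-time (perturbing a single share breaks normalization); the
class-restriction question is covered by the scenario grid instead.

## Scenarios

The grid crosses entry ages {30, 40, 50, 60} with pure entry cohorts
{OB2, OB3}.  Each scenario re-anchors the age-utility decrement at its
own entry age, picks the surgery cost by entry class, and keeps the
40-cycle horizon (life-table clamping at 90 absorbs the difference for
older cohorts; a `horizon_mode: to-age-90` flag runs round(90 − a₀)
cycles instead, e.g. 60 for age 30).

## Synthetic data and the microsimulation oracle

The package needs no external data: the life table is generated from
the two printed anchors, and named fixtures (`table1_base`,
`no_mortality`, `no_discount`, `degenerate_psa`,
`two_cycle_hand_case`) provide deterministic test inputs, including a
two-cycle configuration whose totals are verified against pencil-and-
paper arithmetic.

An individual-level microsimulation re-implements the model patient by
patient with the same per-cycle probabilities, costs, utilities and
timing as the cohort engine, and serves as a brute-force estimate of
the cohort expectations (agreement within 3 Monte-Carlo SE at n = 10⁵
is asserted for both arms).  Each patient's diabetes indicator is
redrawn Bernoulli(f) every cycle rather than fixed at entry: mortality,
cost and utility are all linear in the indicator, so redrawing makes
the microsimulation exactly unbiased for the cohort's static mixing
fraction, whereas a persistent indicator interacts with the mortality
risk ratio (diabetic patients die faster, so the surviving diabetic
share drifts below f) and would bias the check by an amount comparable
to its own tolerance.  What the microsimulation therefore validates is
the Markov bookkeeping — transitions, accrual, discounting, timing —
not the clinical realism of the static-fraction assumption itself.

## Numerical choices

- Row-stochasticity is validated to 1e-12 on every built matrix;
  occupancy conservation to 1e-9 per cycle.
- Configuration validation reports the offending key and constraint.
- Currency values are kept at full precision internally; rounding is
  presentation-only.
- Beta feasibility requires sd² < mean(1−mean); infeasible moment pairs
  raise a dedicated error rather than clipping.
- Degenerate inputs: equal life-table anchors give a constant table;
  zero drift is the identity on alive states; q = 1 absorbs the cohort
  in one cycle; a degenerate PSA (all point masses) reproduces the base
  case exactly.

## Fidelity to the published results

The published *incremental* structure is reproduced under the default
conventions: surgery strictly dominates UC in the base case and in all
eight scenarios; the tornado's two widest bars are the OB3 utility
weight and the pooled OB2/OB3 management cost; and the PSA proportions
(SE quadrant, composite below-threshold, cost-saving) land within a few
percentage points of the published 75.8 / 93.5 / 80.7%.

The published *absolute* base-case totals, however, cannot be derived
from the printed input table under any configuration of the documented
convention flags, and the test suite records this honestly rather than
calibrating toward it:

- UC arm: with per-cycle cost = state management + $3,997 diabetes cost
  (≈ $13.8k) and per-cycle utility ≈ 0.44 (after the 0.116 diabetes
  disutility), the cost:QALY ratio per discounted survivor-year is
  fixed ≈ 33% above what the published pair ($138,821, 5.942) implies —
  independent of the mortality level or discounting convention, since
  both totals scale with the same survival annuity.  This implementation
  matches the published UC QALYs (within ~3%) and therefore exceeds the
  published UC cost.
- Surgery arm: the published total ($90,154) implies a post-year-1
  management cost of ≈ $5.3k per discounted survivor-year, below the
  cheapest state's printed cost ($6,762 for OW) — infeasible even with
  the whole cohort in OW and zero diabetes cost.
- The published incremental QALYs (1.080, and scenario values *rising*
  with entry age) imply a survival-driven gain with a small utility
  gap, which no reading of the printed per-state utilities reproduces;
  the printed abstract itself reports a different gain (2.5 QALYs) than
  the results table (1.080).

Under the `diabetes_fraction_surgery: 0.899` override (the "10.1% in
remission" reading) the incremental QALYs move close to the published
scenario values but the cost increments and PSA proportions degrade;
the default keeps the tabulated 10.1%-with-diabetes reading.

## Limitations

- The cohort's diabetic share is a static mixing weight; remission
  dynamics, complication sub-states and time-in-state-dependent costs
  are out of scope of this model structure.
- Parameters are sampled independently in PSA; no correlation structure
  between state utilities or costs is published or imposed, so draws
  can invert the cost or utility gradient across classes.
- The packaged life table is a two-anchor Gompertz approximation, not a
  national life table.
- All costs are taken as printed in 2022/23 AUD; no currency or
  inflation machinery is included.
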