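# Methods

This note documents the model implemented by `cvdprev`, its assumptions,
parameter conventions, numerical choices, and the limits of what the
synthetic test data can demonstrate.

## Decision problem

Two discrete-time Markov cohort models — CVD risk without diabetes and CVD
risk with diabetes — are run for four absolute-risk index cohorts (low,
moderate, high, very high, in the sense of the WHO risk prediction charts).
For each (model, risk level) cell a universe of drug strategies (subsets of
nine drug classes) is compared with no treatment on expected discounted
lifetime cost (US$) and DALYs averted, and ranked by incremental
cost-effectiveness.  Cohort-level simulation only; no patient-level
microsimulation.

## State space (a reconstruction)

The published state diagram was not available; the implemented state space
is the minimal structure supporting every reported quantity:

```
well → acute MI → post-MI
well → acute stroke (mild | moderate | severe) → post-stroke
post-stroke → acute stroke (subsequent, same severity split)
any alive state → dead
```

* Acute states are strict one-cycle tunnels: their occupants exit to the
  post state or to dead (via age- and sex-specific case fatality) every
  cycle, even when case fatality is zero.  Consequently the
  "all-parameters-zero" transition matrix is the identity on the well,
  post and dead rows while tunnels still route acute → post.
* `post_stroke` forgets severity; it carries a constant subsequent-stroke
  probability (constant after the second event) whose realizations re-enter
  the acute severity split.
* Cross-event transitions (post-MI → stroke and post-stroke → MI) are
  disabled by default: the available description did not specify them, and
  enabling them would require unavailable conditional risks.  This is a
  reconstruction choice, recorded here prominently.
* Death is absorbing; background (non-CVD) mortality is the life table's
  all-cause probability times one minus the CVD-attributable fraction, so
  CVD deaths are generated only by the model's explicit event pathways.
  Post-event states additionally carry a constant excess mortality.

Cycle length is one year; the horizon runs from the index age to age 100 or
cohort extinction (live occupancy below 1e-9).  No half-cycle correction is
applied in the base case (an `half_cycle_correction` flag exists for
exploration); deaths occurring within a cycle credit half of that cycle's
YLD (`half_cycle_death_yld`, on by default, togglable).

## Event risks

Ten-year risks of a first coronary event and a first stroke come from
Framingham-style Weibull accelerated-failure-time equations

    p(t) = 1 − exp(−exp((ln t − μ)/σ)),

with μ linear in ln(age), ln(SBP), ln(TC/HDL), smoking, diabetes and LVH
(sex-specific age terms) and σ log-linear in the same predictor.  The
coronary coefficient set is the published Anderson-1991 total-CHD equation,
shipped as `data/coronary_aft_anderson1991.csv`.  A separate published
stroke coefficient table could not be sourced; the stroke endpoint uses
`data/stroke_aft_synthetic.csv`, a clearly-labelled synthetic calibration
of the same functional form (stronger blood-pressure, LVH and diabetes
dependence, weaker cholesterol dependence, plausible absolute risks — about
2% ten-year stroke risk for a normotensive 50-year-old man, about 16% for a
hypertensive 60-year-old male smoker).  Results driven by the stroke file
do not reproduce any published risk score.  LVH exists in the profile only
because the stroke equation requires it; all packaged index cohorts set it
false.

Equation validity is ages 30–74; outside ages are clamped with a logged
warning.  Ten-year risks convert to the annual cycle under a constant
hazard, `p₁ = 1 − (1 − p₁₀)^(1/10)` (the standard decision-modelling
convention; the conversion used originally was unstated).  MI and stroke
are competing first events within a cycle: their annual probabilities are
mutually exclusive exits from the well state and an error is raised if
their sum exceeds one.  Annual probabilities may also be given directly,
bypassing the equations (`directly_specified` source), which is how the
synthetic generator operates by default.

Units: blood pressure mmHg; cholesterol mmol/L internally (the WHO chart
convention), with an mg/dL converter (÷38.67) at the I/O boundary only.

## Treatment effects

Per-drug relative risks on the two endpoints combine multiplicatively,
RR = Π RRᵢ; the empty strategy has RR 1 exactly.  Default endpoint mapping:
anti-hypertensives (ACEI, ARB, BB, CCB, Diu) and the statin affect both
endpoints; aspirin affects MI only; the oral hypoglycemics (Big, Sulf)
affect both via glycaemic control.  The mapping is fully overridable
through the effect table.  Effects apply to first events only (well-state
exits), are constant across ages and risk strata, and assume perfect
adherence; an adherence multiplier a scales the risk reduction
(RR_eff = 1 − a(1 − RR)) and defaults to 1.

Strategy universes per cell are generated from constraint rules because the
full published combination list was unavailable: up to three
anti-hypertensive classes (no triples at moderate risk, where triple
anti-hypertensive therapy was considered clinically irrelevant), the statin
optional everywhere, aspirin restricted to very-high risk, zero to two oral
hypoglycemics in the diabetes model only, and no-treatment always included.
These universes are supersets of every strategy in the packaged published
table.

## Outcomes and costs

DALY = YLD + YLL, discounted at the effect rate with the first cycle
undiscounted (discount factor (1+r)^(−t), t = 0, 1, …).

* YLD: start-of-cycle occupancy × state disability weight × cycle length.
  Weights: acute MI 0.422; mild/moderate/severe acute stroke
  0.021/0.076/0.539; dead 1.0 (used only for YLL, never YLD).  The chronic
  post-stroke state forgets severity and carries a single configurable
  weight, defaulting to the moderate-stroke value 0.076.  MI leaves no
  chronic disability by default (the 0.422 weight describes the acute
  episode); `post_mi` defaults to 0 and is configurable.  Acute weights are
  applied for the full one-cycle tunnel occupancy — a simplification of
  episode-length weighting inherent to an annual-cycle model.
* YLL: each death credits the discounted annuity of remaining sex-specific
  life expectancy at the age of death, A = (1 − (1+r)^(−L))/r, degenerating
  to L at r = 0 (GBD-consistent practice).

Costs carry provider and patient components throughout.  Prevention costs
(per-drug annual provider cost + flat annual monitoring cost + flat annual
patient access cost) accrue to the well state only — a primary-prevention
regimen; after an event the cohort moves onto treatment costs.  Acute event
costs are charged once at the event inflow; post-event states accrue an
annual chronic-care cost (provider + patient).  The base case is a narrow
societal perspective (provider + patient); the provider perspective zeroes
patient components only, leaving the data intact.  Costs discount at the
cost rate, 3% in the base case, non-differentially with health.

## Cost-effectiveness conventions

* Frontier: sort by cost; remove strictly dominated strategies (weakly more
  costly, no more effective, one inequality strict); iteratively remove
  extended dominance until ICERs strictly increase along survivors; ICERs
  are computed against the preceding surviving strategy.
* Exact ties in cost and effect keep the lexicographically smaller label.
* Display ICERs round half-up to whole US$; internal arithmetic is
  unrounded.
* A willingness-to-pay threshold adopts at equality (ICER ≤ λ), matching
  net-monetary-benefit maximization with ties resolved toward the more
  effective strategy.  Where a narrative recommendation prefers a simpler
  regimen even though an add-on's ICER lies below the threshold, the
  package follows the net-benefit rule.

## Uncertainty analysis

* One-way DSA: each parameter set to its low/high bound with all else at
  base; the outcome is the ICER of a named strategy pair.  Ranges come from
  reported 95% CIs or standard errors where available, otherwise ±15%
  around base (probabilities truncated to [0, 1]).  Parameters contributing
  less than 1% of the summed absolute swings are omitted from the default
  report — the share is taken of the total swing because the original
  denominator was undefined — and the cutoff is configurable.
* PSA: all distributed parameters drawn jointly and independently (no
  correlation information was available); every strategy runs on the same
  draw.  Distribution families follow the conventional support-respecting
  choices — beta for probabilities, gamma for costs, lognormal (base as
  median) for relative risks — moment-matched reading the range as an
  approximate 95% interval (sd = (high − low)/3.92), with a uniform
  fallback when matching is infeasible.  Per-parameter random streams are
  derived from the shared seed via a CRC-keyed spawn, so adding a parameter
  never perturbs the other parameters' draws.  Invalid joint draws are
  resampled (capped at 100 attempts, then an error).  The default sample
  size is configurable; no published sample size was stated.
* CEAF: at each λ the strategy maximizing expected NMB, with the fraction
  of samples in which it attains the per-sample maximum; each sample has
  exactly one winner so probabilities sum to 1 across strategies.
* EVPI per person: E[maxₛ NMB] − maxₛ E[NMB] (≥ 0 by Jensen); population
  EVPI multiplies by Σ_{t=1..Y} P/(1+r)^(t−1) — first year undiscounted, a
  documented choice where the timing convention was unstated.  Defaults:
  P = 1000 patients/year, r = 3%, Y = 10 years (multiplier 8786.11).
* Default λ grid: 0–3000 US$/DALY in steps of 10.

## Scenarios

Scenarios are pure parameter transformations (no scenario-specific engine
code): perspective switch, differential discounting of health (effect rate
0.015 or 0 with costs at 3%), and an index-cohort gender swap.  They are
idempotent and composable, and the base-case spec is the identity.
Directional guarantees tested: a lower effect discount rate never raises a
frontier ICER, and the provider perspective changes prevention costs by
exactly the patient component.

## Synthetic data: what it does and does not emulate

The generator stands in for undeposited parameter tables.  It emulates the
*structure* of the inputs — per-level annual MI probability bands
(low 0.2–0.5%, moderate 0.5–1.5%, high 1.5–3%, very high 3–6%; stroke at
0.6× those bands; diabetes raising both within-band), case fatalities
rising with age from a 20–45% base, relative risks in (0.5, 1), per-drug
annual costs of a few tens of US$ (generic formulations), a patient access
cost of US$123/year with chronic treatment 57.5% higher, a Gompertz life
table with internally consistent life expectancy, ±15% ranges and
moment-matched distributions — all deterministically from a seed.  It does
not emulate the actual magnitudes of the original inputs, so model outputs
on synthetic data are illustrative: passing tests demonstrate the engine's
arithmetic, invariants and orderings, not the published cost and effect
levels.  The published base-case table itself is packaged verbatim
(`table3_base_case.csv`), and its internal arithmetic (ICER = IC/IE on
every row, and frontier recomputation from absolute costs and effects) is
reproduced exactly.

Index cohorts are synthetic stand-ins chosen so derived risks order
strictly across levels: a female cohort for low risk and male cohorts for
moderate to very-high risk (ages 50–60, SBP 125–170 mmHg, TC 4.5–6.8
mmol/L, smoking from high risk upward); the diabetes model flips the
diabetic flag on the same profiles.

## Numerical choices

* Occupancy mass is conserved to better than 1e-9 per cycle (observed
  ~1e-15); transition rows are validated to sum to 1 within 1e-12.
* Extinction threshold 1e-9 of live occupancy; severity splits must sum to
  1 within 1e-12.
* The cohort engine agrees with the closed-form geometric series for
  discounted life-years on a constant-rate reduction to 1e-8 (observed
  ~1e-14).
* Test and acceptance problem sizes: 1000 random parameter sets for the
  conservation sweep, 1000 random instances for the frontier oracle,
  10,000-sample synthetic PSAs for the value-of-information properties, and
  a few hundred Markov-backed PSA samples in the end-to-end pipeline —
  sizes chosen to exercise the asymptotics while keeping the default suite
  fast.

## Known limitations

* The stroke risk equation is a synthetic calibration, not a published
  score; absolute stroke risks are plausible but not validated.
* Acute disability weights apply for a whole one-year tunnel cycle.
* No evidence synthesis (indirect/mixed treatment comparisons) behind the
  relative risks; no non-adherence modelling; no time-varying treatment
  effects; no budget-impact analysis or EVPPI.
* Cross-event chronic transitions are disabled (see State space).
* Extended dominance assumes strategies are divisible/mixable in the usual
  frontier sense.
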