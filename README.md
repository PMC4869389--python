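# cvdprev

Markov cohort cost-effectiveness analysis of **medical primary prevention of
cardiovascular disease (CVD)** in a low-income setting, following the WHO
absolute-risk approach.  Two cohort models — *CVD risk without diabetes* and
*CVD risk with diabetes* — are evaluated across four absolute-risk levels
(low, moderate, high, very high) for combinations of nine drug classes
(ACE inhibitor, angiotensin-receptor blocker, beta blocker, calcium-channel
blocker, thiazide diuretic, statin, aspirin, metformin, glibenclamide).

The package is aimed at health economists and modellers who want a tested,
scriptable implementation of the full analysis chain:

* **Risk engine** — 10-year first-MI and first-stroke risks from
  Framingham-style Weibull accelerated-failure-time equations,
  `p(t) = 1 − exp(−exp((ln t − μ)/σ))`, annualized under a constant hazard,
  `p₁ = 1 − (1 − p₁₀)^(1/10)`.
* **Cohort engine** — an 8-state annual-cycle Markov model
  (well, acute MI, post-MI, acute stroke in three severities, post-stroke,
  dead) with case fatality, subsequent strokes, life-table background
  mortality net of the CVD-attributable share, and excess post-event
  mortality.  Outcomes are DALYs: YLD from GBD-2010 disability weights
  (acute MI 0.422; mild/moderate/severe stroke 0.021/0.076/0.539) plus YLL
  as the discounted annuity of remaining life expectancy at death.  Costs
  (prevention, acute events, chronic care) carry provider and patient
  components; base case is a narrow societal perspective with 3% annual
  discounting of costs and health.
* **Treatment effects** — per-drug relative risks combined multiplicatively
  (RR₁ × RR₂ × … × RRₙ), perfect adherence in the base case.
* **CEA** — strict and extended dominance elimination, ICERs against the
  preceding non-dominated strategy, and willingness-to-pay decisions
  equivalent to net-monetary-benefit maximization (λ·E − C).
* **Uncertainty** — one-way tornado analysis (±15% default ranges),
  probabilistic sensitivity analysis with beta/gamma/lognormal
  moment-matched distributions, cost-effectiveness acceptability frontiers,
  and per-person / population expected value of perfect information.
* **Synthetic data** — the original analysis' primary parameter tables were
  never deposited, so a first-class generator produces complete, valid,
  reproducible stand-in parameter sets; the published base-case table is
  packaged verbatim as a fixture.

## Worked example

```python
from cvdprev import (RiskLevel, Strategy, SyntheticSpec, frontier,
                     generate_parameter_set, optimal_at_wtp, run_cohort,
                     effectiveness_vs_baseline)
from cvdprev.cea import results_to_frame

params = generate_parameter_set(
    SyntheticSpec(seed=1, model="cvd", risk_level=RiskLevel.very_high))
labels = ["No treatment", "ACEI_Diu", "ACEI_CCB_Diu",
          "ACEI_CCB_Diu_Sta", "ACEI_CCB_Diu_ASA"]
nt = run_cohort(params, Strategy.no_treatment())
triples = []
for lab in labels:
    s = Strategy.from_label(lab)
    tr = nt if s.is_no_treatment else run_cohort(params, s)
    triples.append((lab, tr.total_cost, effectiveness_vs_baseline(tr, nt)))
res = frontier(triples)
print(results_to_frame(res).round(2).to_string(index=False))
print("optimal at WTP 610 :", optimal_at_wtp(res, 610.0))
print("optimal at WTP 1500:", optimal_at_wtp(res, 1500.0))
```

prints

```
        strategy  cost_usd  incremental_cost_usd  effect_dalys_averted  incremental_effect  icer_usd_per_daly               status
    No treatment   1651.43                   NaN                  0.00                 NaN                NaN         nondominated
        ACEI_Diu   3071.24                   NaN                  0.88                 NaN                NaN extendedly_dominated
    ACEI_CCB_Diu   3542.58                   NaN                  1.32                 NaN                NaN extendedly_dominated
ACEI_CCB_Diu_Sta   3853.65               2202.22                  1.69                1.69             1301.0         nondominated
ACEI_CCB_Diu_ASA   3913.09                   NaN                  1.45                 NaN                NaN            dominated
optimal at WTP 610 : No treatment
optimal at WTP 1500: ACEI_CCB_Diu_Sta
```

Reading the table: under this synthetic parameter set the no-treatment
cohort already costs US$1651 in discounted lifetime event and chronic-care
costs.  Adding the quadruple regimen averts 1.69 DALYs per person at an
incremental US$2202, an ICER of US$1301 per DALY averted; the intermediate
regimens are removed by extended dominance (their ICERs exceed that of the
next step up), and the aspirin variant is strictly dominated here because
aspirin only affects the MI endpoint.  At a willingness to pay of US$610
per DALY averted no treatment is optimal; at US$1500 the statin-containing
quadruple therapy is.

Note: synthetic parameter magnitudes stand in for undeposited source
tables, so absolute costs and effects are illustrative; the published
base-case table is available unchanged via
`cvdprev.synthetic.table3_fixture()`.

A CLI covers the same pipeline: `cvdprev run|dsa|psa|evpi|synth|fixtures`
(see `cvdprev --help`); every run writes CSV outputs plus a JSON manifest
(config hash, seed, version) for byte-identical reproduction.

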