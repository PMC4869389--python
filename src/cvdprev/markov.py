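"""Discrete-time Markov cohort engine.

State space (a reconstruction; the minimal structure supporting every
reported quantity):

    well -> {acute MI, acute stroke (mild/moderate/severe), dead(background)}
    acute states are one-cycle tunnels emptying into their post state or dead
    post-stroke carries a constant subsequent-stroke probability that
    re-enters the acute severity split; post states carry excess mortality
    on top of background mortality; dead is absorbing.

Cycles are one year, run from the index age to age 100 or cohort
extinction.  Treatment scales the well-state first-event exits by the
strategy's combined relative risks.  Costs (prevention on the well state,
acute costs at event inflows, annual post-event costs) are discounted at
the cost rate; YLD and YLL at the effect rate.  No half-cycle correction
by default; deaths within a cycle credit half that cycle's YLD.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .domain import ModelParameters, Strategy, params_fingerprint
from .effects import combined_rr

__all__ = [
    "HealthState",
    "N_STATES",
    "MarkovTrace",
    "build_transition_matrix",
    "run_cohort",
    "compute_dalys",
    "effectiveness_vs_baseline",
    "discounted_life_years",
    "annuity_factor",
    "trace_to_frame",
]


class HealthState(enum.IntEnum):
    WELL = 0
    ACUTE_MI = 1
    POST_MI = 2
    ACUTE_STROKE_MILD = 3
    ACUTE_STROKE_MODERATE = 4
    ACUTE_STROKE_SEVERE = 5
    POST_STROKE = 6
    DEAD = 7


N_STATES = len(HealthState)

ACUTE_STROKE_STATES = (
    HealthState.ACUTE_STROKE_MILD,
    HealthState.ACUTE_STROKE_MODERATE,
    HealthState.ACUTE_STROKE_SEVERE,
)

#: Minimum live occupancy below which the cohort counts as extinct.
EXTINCTION_TOL = 1e-9


def state_weights(params: ModelParameters) -> np.ndarray:
    """Disability weight vector over states (dead excluded from YLD)."""
    w = params.weights
    vec = np.zeros(N_STATES)
    vec[HealthState.WELL] = w.well
    vec[HealthState.ACUTE_MI] = w.acute_mi
    vec[HealthState.POST_MI] = w.post_mi
    vec[HealthState.ACUTE_STROKE_MILD] = w.stroke_mild
    vec[HealthState.ACUTE_STROKE_MODERATE] = w.stroke_moderate
    vec[HealthState.ACUTE_STROKE_SEVERE] = w.stroke_severe
    vec[HealthState.POST_STROKE] = w.post_stroke
    return vec


def annuity_factor(years: float, rate: float) -> float:
    """Present value of one life-year per year over ``years`` at ``rate``:
    (1 - (1+r)^(-L)) / r, degenerating to L at r = 0."""
    if years < 0:
        raise ValueError("years must be nonnegative")
    if rate == 0.0:
        return years
    return (1.0 - (1.0 + rate) ** (-years)) / rate


def _effective_rr(rr: float, adherence: float) -> float:
    # Partial adherence shrinks the risk reduction, not the RR itself.
    return 1.0 - adherence * (1.0 - rr)


def build_transition_matrix(
    params: ModelParameters,
    strategy: Strategy,
    age: float,
    rr_mi: float | None = None,
    rr_stroke: float | None = None,
) -> np.ndarray:
    """Row-stochastic transition matrix over the 8 states at one age.

    ``rr_mi``/``rr_stroke`` may pass pre-resolved combined relative risks;
    otherwise they are resolved from the strategy and the effect table.
    Raises if any row entry would become negative (treatment effects
    inconsistent with the base risks, or probabilities summing above 1).
    """
    t = params.transitions
    sex = params.profile.sex
    if rr_mi is None:
        rr_mi = _effective_rr(combined_rr(strategy, params.effects, "mi"), params.adherence)
    if rr_stroke is None:
        rr_stroke = _effective_rr(
            combined_rr(strategy, params.effects, "stroke"), params.adherence
        )

    p_mi = rr_mi * t.annual_mi_prob
    p_stroke = rr_stroke * t.annual_stroke_prob
    d_bg = params.life_table.background_mortality(age, sex)
    split = t.first_stroke_severity_split

    M = np.zeros((N_STATES, N_STATES))
    # well
    stay_well = 1.0 - p_mi - p_stroke - d_bg
    M[HealthState.WELL, HealthState.ACUTE_MI] = p_mi
    for s, share in zip(ACUTE_STROKE_STATES, split):
        M[HealthState.WELL, s] = p_stroke * share
    M[HealthState.WELL, HealthState.DEAD] = d_bg
    M[HealthState.WELL, HealthState.WELL] = stay_well
    # acute tunnels
    cf_mi = t.case_fatality_mi.at(age, sex)
    M[HealthState.ACUTE_MI, HealthState.DEAD] = cf_mi
    M[HealthState.ACUTE_MI, HealthState.POST_MI] = 1.0 - cf_mi
    cf_stroke = t.case_fatality_stroke.at(age, sex)
    for s in ACUTE_STROKE_STATES:
        M[s, HealthState.DEAD] = cf_stroke
        M[s, HealthState.POST_STROKE] = 1.0 - cf_stroke
    # post states
    d_post = min(1.0, d_bg + t.post_event_excess_mortality)
    M[HealthState.POST_MI, HealthState.DEAD] = d_post
    M[HealthState.POST_MI, HealthState.POST_MI] = 1.0 - d_post
    p_sub = t.subsequent_stroke_prob
    for s, share in zip(ACUTE_STROKE_STATES, split):
        M[HealthState.POST_STROKE, s] = p_sub * share
    M[HealthState.POST_STROKE, HealthState.DEAD] = d_post
    M[HealthState.POST_STROKE, HealthState.POST_STROKE] = 1.0 - p_sub - d_post
    # absorbing death
    M[HealthState.DEAD, HealthState.DEAD] = 1.0

    if (M < -1e-15).any():
        bad = np.argwhere(M < -1e-15)[0]
        raise ValueError(
            f"negative transition probability at {HealthState(bad[0]).name} -> "
            f"{HealthState(bad[1]).name}; event probabilities exceed 1 after "
            "RR application"
        )
    np.clip(M, 0.0, 1.0, out=M)
    rows = M.sum(axis=1)
    if not np.allclose(rows, 1.0, atol=1e-12):
        raise ValueError(f"transition rows do not sum to 1: {rows}")
    return M


@dataclass
class MarkovTrace:
    """Per-cycle record of one cohort run.

    ``occupancy[t]`` is the start-of-cycle state distribution (t = 0 is the
    index age; the array has one extra final row).  ``death_inflow[t, s]``
    is the fraction dying during cycle t out of state s.  Cost and YLD
    accumulators are already discounted.
    """

    strategy_label: str
    start_age: int
    ages: np.ndarray  # (T,)
    occupancy: np.ndarray  # (T+1, N_STATES)
    death_inflow: np.ndarray  # (T, N_STATES)
    mi_event_inflow: np.ndarray  # (T,)
    stroke_event_inflow: np.ndarray  # (T,)
    cycle_costs_usd: np.ndarray  # (T,), discounted
    cycle_ylds: np.ndarray  # (T,), discounted
    yll_total: float
    params_fingerprint: str

    @property
    def n_cycles(self) -> int:
        return len(self.ages)

    @property
    def total_cost(self) -> float:
        return float(self.cycle_costs_usd.sum())

    @property
    def total_dalys(self) -> float:
        return float(self.cycle_ylds.sum() + self.yll_total)


def _health_accumulators(
    occupancy: np.ndarray,
    death_inflow: np.ndarray,
    ages: np.ndarray,
    params: ModelParameters,
) -> tuple[np.ndarray, float]:
    """Discounted per-cycle YLD vector and total YLL for given trajectories."""
    weights = state_weights(params)
    r_eff = params.discount.effect_rate
    sex = params.profile.sex
    cl = params.cycle_length_years
    T = len(ages)
    ylds = np.zeros(T)
    yll = 0.0
    for t in range(T):
        df = (1.0 + r_eff) ** (-t * cl)
        yld = float(occupancy[t, :N_STATES] @ weights) * cl
        deaths_t = death_inflow[t]
        if params.half_cycle_death_yld:
            yld -= 0.5 * float(deaths_t @ weights) * cl
        ylds[t] = df * yld
        total_deaths = float(deaths_t.sum())
        if total_deaths > 0:
            L = params.life_table.expectancy(ages[t], sex)
            yll += df * total_deaths * annuity_factor(L, r_eff)
    return ylds, yll


def run_cohort(params: ModelParameters, strategy: Strategy) -> MarkovTrace:
    """Simulate one cohort under one strategy from the index age to age 100
    (or extinction), returning the full trace with discounted accumulators."""
    age0 = params.profile.age_years
    horizon = max(1, params.max_age - age0)
    rr_mi = _effective_rr(combined_rr(strategy, params.effects, "mi"), params.adherence)
    rr_stroke = _effective_rr(
        combined_rr(strategy, params.effects, "stroke"), params.adherence
    )

    occ = np.zeros((horizon + 1, N_STATES))
    occ[0, HealthState.WELL] = 1.0
    death_inflow = np.zeros((horizon, N_STATES))
    mi_inflow = np.zeros(horizon)
    stroke_inflow = np.zeros(horizon)
    costs = np.zeros(horizon)

    prevention = params.costs.annual_prevention_cost(strategy)
    cost_mi = params.costs.acute_event_cost("mi")
    cost_stroke = params.costs.acute_event_cost("stroke")
    post_cost = params.costs.annual_post_event_cost()
    r_cost = params.discount.cost_rate
    cl = params.cycle_length_years

    T = horizon
    for t in range(horizon):
        age = age0 + t * cl
        M = build_transition_matrix(params, strategy, age, rr_mi=rr_mi, rr_stroke=rr_stroke)
        cur = occ[t]
        nxt = cur @ M
        death_inflow[t] = cur * M[:, HealthState.DEAD]
        death_inflow[t, HealthState.DEAD] = 0.0  # already dead: not a new death
        mi_inflow[t] = cur[HealthState.WELL] * M[HealthState.WELL, HealthState.ACUTE_MI]
        stroke_sources = (
            cur[HealthState.WELL] * M[HealthState.WELL, list(ACUTE_STROKE_STATES)].sum()
            + cur[HealthState.POST_STROKE]
            * M[HealthState.POST_STROKE, list(ACUTE_STROKE_STATES)].sum()
        )
        stroke_inflow[t] = stroke_sources

        df_cost = (1.0 + r_cost) ** (-t * cl)
        cycle_cost = (
            cur[HealthState.WELL] * prevention
            + (cur[HealthState.POST_MI] + cur[HealthState.POST_STROKE]) * post_cost
            + mi_inflow[t] * cost_mi
            + stroke_inflow[t] * cost_stroke
        )
        costs[t] = df_cost * cycle_cost

        occ[t + 1] = nxt
        if nxt[: HealthState.DEAD].sum() < EXTINCTION_TOL:
            T = t + 1
            break

    ages = np.array([age0 + t * cl for t in range(T)])
    occ = occ[: T + 1]
    death_inflow = death_inflow[:T]
    ylds, yll = _health_accumulators(occ, death_inflow, ages, params)
    return MarkovTrace(
        strategy_label=strategy.label,
        start_age=age0,
        ages=ages,
        occupancy=occ,
        death_inflow=death_inflow,
        mi_event_inflow=mi_inflow[:T],
        stroke_event_inflow=stroke_inflow[:T],
        cycle_costs_usd=costs[:T],
        cycle_ylds=ylds,
        yll_total=yll,
        params_fingerprint=params_fingerprint(params),
    )


def compute_dalys(trace: MarkovTrace, params: ModelParameters) -> float:
    """Total discounted DALYs (YLD + YLL) recomputed from the trace arrays.

    YLD sums start-of-cycle occupancy times state disability weights (with
    the half-cycle death credit if enabled); YLL credits each death the
    discounted annuity of remaining sex-specific life expectancy at the age
    of death.  Nonnegative and nondecreasing in every disability weight.
    """
    ylds, yll = _health_accumulators(
        trace.occupancy, trace.death_inflow, trace.ages, params
    )
    return float(ylds.sum() + yll)


def effectiveness_vs_baseline(
    trace_strategy: MarkovTrace, trace_no_treatment: MarkovTrace
) -> float:
    """DALYs averted by a strategy relative to the no-treatment run of the
    same parameter set: DALYs(no treatment) - DALYs(strategy)."""
    if trace_strategy.params_fingerprint != trace_no_treatment.params_fingerprint:
        raise ValueError("traces come from different parameter sets")
    return trace_no_treatment.total_dalys - trace_strategy.total_dalys


def discounted_life_years(trace: MarkovTrace, rate: float) -> float:
    """Expected discounted life-years lived (alive occupancy at cycle starts)."""
    alive = 1.0 - trace.occupancy[:-1, HealthState.DEAD]
    t = np.arange(len(alive))
    return float((alive * (1.0 + rate) ** (-t)).sum())


def trace_to_frame(trace: MarkovTrace) -> pd.DataFrame:
    """Tidy per-(cycle, state) export of a cohort trace."""
    rows = []
    for t, age in enumerate(trace.ages):
        for s in HealthState:
            rows.append(
                {
                    "cycle": t,
                    "age": float(age),
                    "state": s.name.lower(),
                    "occupancy": trace.occupancy[t, s],
                    "discounted_cost": trace.cycle_costs_usd[t] if s == HealthState.WELL else np.nan,
                    "discounted_daly": trace.cycle_ylds[t] if s == HealthState.WELL else np.nan,
                }
            )
    return pd.DataFrame(rows)
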