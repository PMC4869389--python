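"""Synthetic parameter sets, index cohorts, life tables and the published
base-case fixture.

The primary parameter tables behind the original analysis (index-cohort
risk factors, case fatalities, per-drug relative risks and costs) were not
deposited, so this module generates complete, internally consistent
stand-ins: event probabilities drawn inside non-overlapping per-risk-level
bands, case fatalities rising with age, relative risks below one, costs
ordered by regimen size, and +/-15% one-way ranges with moment-matched
sampling distributions attached.  All magnitudes are synthetic conventions
(documented in the methods note); tests built on them assert structure and
properties, never published cost or effect levels.

The published base-case table itself (strategy, cost, incremental cost,
effectiveness, incremental effectiveness, ICER per model and risk level)
is packaged verbatim as a CSV fixture and exposed by :func:`table3_fixture`.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import pandas as pd

from .domain import (
    AgeSexSchedule,
    CostSet,
    DisabilityWeights,
    DiscountSpec,
    LifeTable,
    ModelParameters,
    ParamRange,
    RiskFactorProfile,
    RiskLevel,
    TransitionParameters,
    TreatmentEffect,
)
from .uncertainty import build_distribution

__all__ = [
    "SyntheticSpec",
    "index_profile",
    "INDEX_PROFILES",
    "generate_life_table",
    "generate_parameter_set",
    "table3_fixture",
]


@dataclass
class SyntheticSpec:
    """Deterministic recipe for one synthetic parameter set."""

    seed: int
    model: str = "cvd"
    risk_level: RiskLevel = RiskLevel.high
    use_framingham: bool = False  # True: derive event risks from the profile


#: Index cohorts per risk level: a female cohort for low risk and male
#: cohorts for moderate to very-high risk, with risk factors escalating so
#: the derived event risks order strictly across levels.  Synthetic
#: stand-ins for the unpublished index-cohort table.
INDEX_PROFILES: dict[RiskLevel, RiskFactorProfile] = {
    RiskLevel.low: RiskFactorProfile(50, "female", 125.0, 4.5, 1.4, False, False),
    RiskLevel.moderate: RiskFactorProfile(50, "male", 142.0, 5.2, 1.2, False, False),
    RiskLevel.high: RiskFactorProfile(55, "male", 155.0, 6.0, 1.1, True, False),
    RiskLevel.very_high: RiskFactorProfile(60, "male", 170.0, 6.8, 0.9, True, False),
}

#: Annual first-MI probability bands per risk level (synthetic convention).
MI_BANDS: dict[RiskLevel, tuple[float, float]] = {
    RiskLevel.low: (0.002, 0.005),
    RiskLevel.moderate: (0.005, 0.015),
    RiskLevel.high: (0.015, 0.03),
    RiskLevel.very_high: (0.03, 0.06),
}
#: Stroke bands: the MI band scaled down (strokes rarer than coronary events
#: in these cohorts).
STROKE_BAND_SCALE = 0.6

#: Patient-side annual cost of receiving preventive care, and the uplift for
#: receiving CVD treatment (57.5% above the prevention figure).
PATIENT_PREVENTION_COST = 123.0
PATIENT_TREATMENT_UPLIFT = 1.575


def index_profile(level: RiskLevel, model: str = "cvd", swap_gender: bool = False) -> RiskFactorProfile:
    """The packaged index cohort for a risk level; the diabetes model flips
    the diabetic flag, ``swap_gender`` flips the sex."""
    base = INDEX_PROFILES[RiskLevel(level)]
    profile = replace(base, diabetic=(model == "cvd_with_diabetes"))
    if swap_gender:
        profile = replace(profile, sex="female" if profile.sex == "male" else "male")
    return profile


def _rng(seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(zlib.crc32(label.encode()),))
    )


def generate_life_table(
    seed: int = 0,
    max_age: int = 100,
    level_scale: float = 1.0,
) -> LifeTable:
    """Gompertz-shaped synthetic life table with internally consistent
    remaining life expectancy.

    Mortality q(a) = min(0.7, A * exp(B * a)) with a small sex gap and an
    age-rising CVD-attributable fraction; life expectancy is computed from
    the table itself by summing survival, so e(a) = max_age - a exactly when
    mortality is zero.
    """
    if max_age < 100:
        raise ValueError("max_age must be at least 100")
    rng = _rng(seed, "life_table")
    A = 4.0e-5 * level_scale * (1.0 + 0.2 * rng.uniform(-1, 1))
    B = 0.085
    ages = np.arange(max_age + 1)
    q_male = np.minimum(0.7, A * np.exp(B * ages))
    q_female = np.minimum(0.7, 0.85 * A * np.exp(B * ages))
    frac = np.clip(0.02 + 0.0015 * ages, 0.0, 0.25)

    def expectancy(q: np.ndarray) -> tuple[float, ...]:
        e = []
        for a in range(max_age + 1):
            surv = 1.0
            total = 0.0
            for k in range(a, max_age):
                surv *= 1.0 - float(q[k])
                total += surv
            e.append(total)
        return tuple(e)

    return LifeTable(
        max_age=max_age,
        all_cause_male=tuple(float(x) for x in q_male),
        all_cause_female=tuple(float(x) for x in q_female),
        cvd_attributable_fraction=tuple(float(x) for x in frac),
        life_expectancy_male=expectancy(q_male),
        life_expectancy_female=expectancy(q_female),
    )


def _default_effects(rng: np.random.Generator, model: str) -> list[TreatmentEffect]:
    """Per-drug RRs in (0.5, 1.0); aspirin affects MI only by default."""
    drugs = ["ACEI", "ARB", "BB", "CCB", "Diu", "Sta", "ASA"]
    if model == "cvd_with_diabetes":
        drugs += ["Big", "Sulf"]
    effects = []
    for drug in drugs:
        rr_mi = float(rng.uniform(0.72, 0.95))
        rr_stroke = 1.0 if drug == "ASA" else float(rng.uniform(0.65, 0.95))
        effects.append(TreatmentEffect(drug, rr_mi, rr_stroke))
    return effects


def generate_parameter_set(spec: SyntheticSpec) -> ModelParameters:
    """A complete, valid synthetic :class:`ModelParameters`.

    Deterministic in the spec (same spec -> identical set); every generated
    set passes :func:`cvdprev.domain.validate_parameters` with an empty
    report, and event probabilities order strictly across risk levels for a
    fixed seed because the bands are disjoint.
    """
    level = RiskLevel(spec.risk_level)
    key = f"{spec.model}:{level.value}"
    rng = _rng(spec.seed, key)

    profile = index_profile(level, spec.model)

    if spec.use_framingham:
        from .risk import annual_risks_for_level

        risks = annual_risks_for_level(level, profile)
        p_mi, p_stroke = risks.p_mi_annual, risks.p_stroke_annual
    else:
        lo, hi = MI_BANDS[level]
        p_mi = float(rng.uniform(lo, hi))
        p_stroke = float(rng.uniform(lo * STROKE_BAND_SCALE, hi * STROKE_BAND_SCALE))
        if profile.diabetic:  # diabetes raises both event risks within-band
            p_mi = min(hi, p_mi * 1.15)
            p_stroke = min(hi * STROKE_BAND_SCALE, p_stroke * 1.15)

    age_breaks = (0, 45, 55, 65, 75, 85)
    cf_mi_base = float(rng.uniform(0.25, 0.45))
    cf_stroke_base = float(rng.uniform(0.2, 0.4))

    def schedule(base: float) -> AgeSexSchedule:
        male = tuple(min(0.95, base * (1.0 + 0.08 * i)) for i in range(len(age_breaks)))
        female = tuple(min(0.95, v * 0.93) for v in male)
        return AgeSexSchedule(age_breaks, male, female)

    transitions = TransitionParameters(
        annual_mi_prob=p_mi,
        annual_stroke_prob=p_stroke,
        case_fatality_mi=schedule(cf_mi_base),
        case_fatality_stroke=schedule(cf_stroke_base),
        first_stroke_severity_split=(0.45, 0.35, 0.2),
        subsequent_stroke_prob=float(rng.uniform(0.04, 0.08)),
        post_event_excess_mortality=float(rng.uniform(0.01, 0.03)),
    )

    effects = _default_effects(_rng(spec.seed, f"effects:{spec.model}"), spec.model)

    # generic formulations in the public supply chain: a few tens of US$/year
    drug_costs = {
        e.drug: float(_rng(spec.seed, f"cost:{e.drug}").uniform(6.0, 40.0))
        for e in effects
    }
    costs = CostSet(
        annual_drug_cost_provider_usd=drug_costs,
        annual_monitoring_cost_provider_usd=12.0,
        annual_prevention_patient_usd=PATIENT_PREVENTION_COST,
        acute_event_cost_provider_usd={
            "mi": float(rng.uniform(250.0, 450.0)),
            "stroke": float(rng.uniform(350.0, 600.0)),
        },
        acute_event_cost_patient_usd={
            "mi": float(rng.uniform(40.0, 80.0)),
            "stroke": float(rng.uniform(50.0, 100.0)),
        },
        annual_post_event_cost_provider_usd=float(rng.uniform(150.0, 300.0)),
        annual_post_event_cost_patient_usd=PATIENT_PREVENTION_COST
        * PATIENT_TREATMENT_UPLIFT,
        perspective="societal",
    )

    life_table = generate_life_table(spec.seed)

    params = ModelParameters(
        profile=profile,
        risk_level=level,
        transitions=transitions,
        effects=effects,
        costs=costs,
        weights=DisabilityWeights(),
        life_table=life_table,
        discount=DiscountSpec(),
    )

    # +/-15% one-way ranges and moment-matched sampling distributions for
    # the scalar transition probabilities, the per-drug RRs and the cost
    # scalars (age-indexed schedules are left unranged).
    ranges: list[ParamRange] = []
    prob_paths = [
        "transitions.annual_mi_prob",
        "transitions.annual_stroke_prob",
        "transitions.subsequent_stroke_prob",
        "transitions.post_event_excess_mortality",
    ]
    for path in prob_paths:
        from .domain import get_param

        ranges.append(ParamRange.pct15(path, get_param(params, path), probability=True))
    for e in effects:
        ranges.append(ParamRange.pct15(f"effects.{e.drug}.rr_mi", e.rr_mi))
        if e.rr_stroke < 1.0:
            ranges.append(ParamRange.pct15(f"effects.{e.drug}.rr_stroke", e.rr_stroke))
    cost_paths = [
        *(f"costs.annual_drug_cost_provider_usd.{d}" for d in drug_costs),
        "costs.annual_prevention_patient_usd",
        "costs.acute_event_cost_provider_usd.mi",
        "costs.acute_event_cost_provider_usd.stroke",
        "costs.annual_post_event_cost_provider_usd",
        "costs.annual_post_event_cost_patient_usd",
    ]
    for path in cost_paths:
        from .domain import get_param

        ranges.append(ParamRange.pct15(path, get_param(params, path)))

    params.dsa_ranges = ranges
    dists = []
    for r in ranges:
        if r.parameter_id.startswith("transitions."):
            family = "beta"
        elif ".rr_" in r.parameter_id:
            family = "lognormal"
        else:
            family = "gamma"
        dists.append(build_distribution(r, family))
    params.psa_distributions = dists
    return params


def table3_fixture() -> pd.DataFrame:
    """The published base-case table, verbatim, as a tidy frame.

    Columns: model, risk_level, strategy_printed (the printed drug order),
    cost_usd, incremental_cost_usd, effect_dalys_averted,
    incremental_effect, icer_usd_per_daly (NaN on the no-treatment anchors).
    """
    ref = resources.files("cvdprev.data") / "table3_base_case.csv"
    with ref.open() as fh:
        return pd.read_csv(fh)
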