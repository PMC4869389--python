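"""Shared data types for the CVD primary-prevention decision model.

The package evaluates drug strategies for primary prevention of
cardiovascular disease (CVD) with two Markov cohort models — CVD risk
without diabetes and CVD risk with diabetes — each run for four absolute
risk levels (low, moderate, high, very high).  Everything downstream
(risk equations, cohort engine, frontier analysis, uncertainty analysis)
consumes the types defined here.

Units are encoded in field names: costs in US$, blood pressure in mmHg,
cholesterol in mmol/L (the WHO chart convention; a converter from mg/dL
is provided at the I/O boundary), probabilities per annual cycle.
"""

from __future__ import annotations

import copy
import dataclasses
import enum
import hashlib
import json
import math
from bisect import bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "RiskLevel",
    "RiskFactorProfile",
    "DrugClass",
    "DRUG_UNIVERSE",
    "ANTIHYPERTENSIVES",
    "ORAL_HYPOGLYCEMICS",
    "NO_TREATMENT_LABEL",
    "Strategy",
    "TreatmentEffect",
    "AgeSexSchedule",
    "TransitionParameters",
    "CostSet",
    "DisabilityWeights",
    "LifeTable",
    "DiscountSpec",
    "ParamRange",
    "ParamDistribution",
    "ModelParameters",
    "Violation",
    "validate_parameters",
    "cholesterol_mgdl_to_mmol_l",
    "get_param",
    "set_param",
    "params_fingerprint",
    "save_parameters",
    "load_parameters",
]

#: mg/dL per mmol/L for total and HDL cholesterol.
MG_PER_DL_PER_MMOL_L = 38.67

SEXES = ("male", "female")

PERSPECTIVES = ("societal", "provider")


def cholesterol_mgdl_to_mmol_l(value_mgdl: float) -> float:
    """Convert a cholesterol concentration from mg/dL to mmol/L."""
    return value_mgdl / MG_PER_DL_PER_MMOL_L


class RiskLevel(str, enum.Enum):
    """Absolute 10-year CVD risk band, following the WHO prediction charts."""

    low = "low"
    moderate = "moderate"
    high = "high"
    very_high = "very_high"

    @classmethod
    def ordered(cls) -> tuple["RiskLevel", ...]:
        return (cls.low, cls.moderate, cls.high, cls.very_high)


@dataclass
class RiskFactorProfile:
    """Risk-factor profile of one index cohort.

    ``lvh`` (left-ventricular hypertrophy) exists only because the stroke
    risk equation carries it as a covariate; index cohorts default it to
    False.  ``diabetic`` both enters the risk equations and selects which
    of the two cohort models (with/without diabetes) applies.
    """

    age_years: int
    sex: str
    systolic_bp_mmHg: float
    total_cholesterol_mmol_per_L: float
    hdl_cholesterol_mmol_per_L: float
    smoker: bool
    diabetic: bool
    lvh: bool = False


@dataclass(frozen=True)
class DrugClass:
    acronym: str
    drug_name: str
    daily_dosage: str


#: The nine drug classes of the intervention set (closed universe).
DRUG_UNIVERSE: dict[str, DrugClass] = {
    "ACEI": DrugClass("ACEI", "Captopril", "12.5 mg twice"),
    "ARB": DrugClass("ARB", "Losartan", "50 mg once"),
    "BB": DrugClass("BB", "Atenolol", "50 mg once"),
    "Big": DrugClass("Big", "Metformin", "500 mg thrice"),
    "CCB": DrugClass("CCB", "Nifedipine", "20 mg twice"),
    "ASA": DrugClass("ASA", "Aspirin", "75 mg once"),
    "Sta": DrugClass("Sta", "Simvastatin", "40 mg once"),
    "Sulf": DrugClass("Sulf", "Glibenclamide", "5 mg once"),
    "Diu": DrugClass("Diu", "Bendrofluazide", "2.5 mg or 5 mg once"),
}

ANTIHYPERTENSIVES = frozenset({"ACEI", "ARB", "BB", "CCB", "Diu"})
ORAL_HYPOGLYCEMICS = frozenset({"Big", "Sulf"})

NO_TREATMENT_LABEL = "No treatment"


@dataclass(frozen=True)
class Strategy:
    """An unordered, duplicate-free set of drug classes (empty = no treatment).

    The canonical label joins the sorted acronyms with "_", so label equality
    is set equality.  Published tables sometimes print the same set in a
    different order (e.g. "Big_Sulf_ACEI_CCB"); :meth:`from_label` normalises
    any order back to the canonical set.
    """

    drugs: frozenset[str]

    def __post_init__(self) -> None:
        unknown = set(self.drugs) - set(DRUG_UNIVERSE)
        if unknown:
            raise ValueError(f"unknown drug acronyms: {sorted(unknown)}")

    @property
    def label(self) -> str:
        if not self.drugs:
            return NO_TREATMENT_LABEL
        return "_".join(sorted(self.drugs))

    @property
    def is_no_treatment(self) -> bool:
        return not self.drugs

    @classmethod
    def no_treatment(cls) -> "Strategy":
        return cls(frozenset())

    @classmethod
    def from_label(cls, label: str) -> "Strategy":
        if label.strip() == NO_TREATMENT_LABEL or not label.strip():
            return cls.no_treatment()
        return cls(frozenset(label.split("_")))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


def canonical_label(printed_label: str) -> str:
    """Canonicalise a printed strategy label (any drug order) to sorted form."""
    return Strategy.from_label(printed_label).label


@dataclass
class TreatmentEffect:
    """Per-drug relative risks on the two first-event endpoints.

    RR = 1 encodes "no effect on this endpoint"; combination effects are
    resolved multiplicatively in :mod:`cvdprev.effects`.
    """

    drug: str
    rr_mi: float
    rr_stroke: float


@dataclass
class AgeSexSchedule:
    """Step function of age, by sex (used for case-fatality probabilities).

    ``age_breaks`` are the left edges of age bands; ``male``/``female`` hold
    the band values.  Lookup uses the band containing the age (ages below the
    first break take the first band).
    """

    age_breaks: tuple[int, ...]
    male: tuple[float, ...]
    female: tuple[float, ...]

    def at(self, age: float, sex: str) -> float:
        values = self.male if sex == "male" else self.female
        idx = max(0, bisect_right(self.age_breaks, age) - 1)
        return values[idx]

    def all_values(self) -> tuple[float, ...]:
        return tuple(self.male) + tuple(self.female)


@dataclass
class TransitionParameters:
    """Untreated annual event probabilities and downstream transition inputs."""

    annual_mi_prob: float
    annual_stroke_prob: float
    case_fatality_mi: AgeSexSchedule
    case_fatality_stroke: AgeSexSchedule
    #: (mild, moderate, severe) shares of a first (or subsequent) stroke.
    first_stroke_severity_split: tuple[float, float, float]
    #: Annual probability of a subsequent stroke (constant after the second event).
    subsequent_stroke_prob: float
    #: Annual excess (non-acute) mortality in post-event states, additive to
    #: background mortality.
    post_event_excess_mortality: float


@dataclass
class CostSet:
    """Annual and per-event costs in US$, split into provider and patient parts.

    The societal perspective counts provider + patient components; the
    provider perspective zeroes the patient component only.  Prevention costs
    are composed from per-drug annual provider costs plus a flat annual
    monitoring cost (provider) and a flat annual access cost borne by the
    patient; the per-strategy totals the model consumes come from
    :meth:`annual_prevention_cost`.
    """

    annual_drug_cost_provider_usd: dict[str, float]
    annual_monitoring_cost_provider_usd: float
    annual_prevention_patient_usd: float
    acute_event_cost_provider_usd: dict[str, float]  # keys: "mi", "stroke"
    acute_event_cost_patient_usd: dict[str, float]
    annual_post_event_cost_provider_usd: float
    annual_post_event_cost_patient_usd: float
    perspective: str = "societal"

    def _include_patient(self) -> bool:
        return self.perspective == "societal"

    def prevention_provider_component(self, strategy: Strategy) -> float:
        if strategy.is_no_treatment:
            return 0.0
        drugs = sum(self.annual_drug_cost_provider_usd[d] for d in strategy.drugs)
        return drugs + self.annual_monitoring_cost_provider_usd

    def prevention_patient_component(self, strategy: Strategy) -> float:
        if strategy.is_no_treatment:
            return 0.0
        return self.annual_prevention_patient_usd

    def annual_prevention_cost(self, strategy: Strategy) -> float:
        total = self.prevention_provider_component(strategy)
        if self._include_patient():
            total += self.prevention_patient_component(strategy)
        return total

    def acute_event_cost(self, event: str) -> float:
        total = self.acute_event_cost_provider_usd[event]
        if self._include_patient():
            total += self.acute_event_cost_patient_usd[event]
        return total

    def annual_post_event_cost(self) -> float:
        total = self.annual_post_event_cost_provider_usd
        if self._include_patient():
            total += self.annual_post_event_cost_patient_usd
        return total


@dataclass
class DisabilityWeights:
    """GBD-2010 style disability weights (0 = full health, 1 = dead).

    The chronic post-stroke state forgets its severity, so it carries a
    single configurable weight (default: the moderate-stroke weight).  MI
    leaves no chronic disability by default (the 0.422 weight belongs to the
    acute episode); ``post_mi`` is configurable.
    """

    acute_mi: float = 0.422
    stroke_mild: float = 0.021
    stroke_moderate: float = 0.076
    stroke_severe: float = 0.539
    post_stroke: float = 0.076
    post_mi: float = 0.0
    well: float = 0.0
    dead: float = 1.0


@dataclass
class LifeTable:
    """All-cause mortality by single year of age and sex, with the fraction
    attributable to CVD and remaining life expectancy.

    Background (non-CVD) mortality used by the cohort engine is
    all-cause × (1 − CVD-attributable fraction), which avoids double counting
    CVD deaths that the model generates explicitly.
    """

    max_age: int
    all_cause_male: tuple[float, ...]
    all_cause_female: tuple[float, ...]
    cvd_attributable_fraction: tuple[float, ...]
    life_expectancy_male: tuple[float, ...]
    life_expectancy_female: tuple[float, ...]

    def _idx(self, age: float) -> int:
        return min(int(age), self.max_age)

    def all_cause_mortality(self, age: float, sex: str) -> float:
        table = self.all_cause_male if sex == "male" else self.all_cause_female
        return table[self._idx(age)]

    def background_mortality(self, age: float, sex: str) -> float:
        frac = self.cvd_attributable_fraction[self._idx(age)]
        return self.all_cause_mortality(age, sex) * (1.0 - frac)

    def expectancy(self, age: float, sex: str) -> float:
        table = (
            self.life_expectancy_male if sex == "male" else self.life_expectancy_female
        )
        return table[self._idx(age)]


@dataclass
class DiscountSpec:
    """Annual discount rates; the base case discounts costs and health
    non-differentially at 3%."""

    cost_rate: float = 0.03
    effect_rate: float = 0.03


@dataclass
class ParamRange:
    """One-way sensitivity range for a scalar parameter.

    ``source`` records how the range was obtained: a reported 95% CI, a
    standard error, or the ±15% default band around the base value
    (probabilities truncated to [0, 1]).
    """

    parameter_id: str
    base: float
    low: float
    high: float
    source: str = "pct15"

    @classmethod
    def pct15(
        cls, parameter_id: str, base: float, probability: bool = False
    ) -> "ParamRange":
        low, high = 0.85 * base, 1.15 * base
        if probability:
            low, high = max(0.0, low), min(1.0, high)
        return cls(parameter_id, base, low, high, source="pct15")


@dataclass
class ParamDistribution:
    """Sampling distribution for one parameter in the probabilistic analysis.

    Families follow the conventional support-respecting choices: beta for
    probabilities, gamma for costs, lognormal for relative risks, uniform as
    a fallback.  ``hyperparameters`` are family-specific:
    beta (alpha, beta); gamma (shape, scale); lognormal (mu_log, sigma_log);
    uniform (low, high).
    """

    parameter_id: str
    family: str
    hyperparameters: tuple[float, ...]


@dataclass
class ModelParameters:
    """The complete numeric input set for one model run."""

    profile: RiskFactorProfile
    risk_level: RiskLevel
    transitions: TransitionParameters
    effects: list[TreatmentEffect]
    costs: CostSet
    weights: DisabilityWeights
    life_table: LifeTable
    discount: DiscountSpec
    cycle_length_years: float = 1.0
    max_age: int = 100
    #: Deaths during a cycle contribute half that cycle's YLD (togglable).
    half_cycle_death_yld: bool = True
    #: Optional half-cycle correction on state membership (off: annual-cycle
    #: convention without correction).
    half_cycle_correction: bool = False
    #: Adherence multiplier on treatment effects (1 = perfect adherence).
    adherence: float = 1.0
    dsa_ranges: list[ParamRange] = field(default_factory=list)
    psa_distributions: list[ParamDistribution] = field(default_factory=list)

    @property
    def model(self) -> str:
        return "cvd_with_diabetes" if self.profile.diabetic else "cvd"

    def effect_for(self, drug: str) -> TreatmentEffect | None:
        for eff in self.effects:
            if eff.drug == drug:
                return eff
        return None

    def copy(self) -> "ModelParameters":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# Validation


@dataclass
class Violation:
    field: str
    value: Any
    rule: str
    severity: str = "error"


def _check_prob(report: list[Violation], name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        report.append(Violation(name, value, "probability must lie in [0, 1]"))


def validate_parameters(params: ModelParameters) -> list[Violation]:
    """Check every type invariant; returns a report instead of raising.

    An empty report means the parameter set is fully valid.  Entries carry
    the offending field, its value and the violated rule; non-fatal findings
    (e.g. a non-monotone life table above age 30) are flagged with severity
    "warning" and do not appear for well-formed synthetic sets.
    """
    report: list[Violation] = []
    p = params.profile
    if not (25 <= p.age_years <= 100):
        report.append(Violation("profile.age_years", p.age_years, "age in [25, 100]"))
    if p.sex not in SEXES:
        report.append(Violation("profile.sex", p.sex, "sex in {male, female}"))
    if not (80 <= p.systolic_bp_mmHg <= 250):
        report.append(
            Violation("profile.systolic_bp_mmHg", p.systolic_bp_mmHg, "SBP in [80, 250]")
        )
    if p.total_cholesterol_mmol_per_L <= 0:
        report.append(
            Violation(
                "profile.total_cholesterol_mmol_per_L",
                p.total_cholesterol_mmol_per_L,
                "cholesterol must be positive",
            )
        )
    if p.hdl_cholesterol_mmol_per_L <= 0:
        report.append(
            Violation(
                "profile.hdl_cholesterol_mmol_per_L",
                p.hdl_cholesterol_mmol_per_L,
                "cholesterol must be positive",
            )
        )

    t = params.transitions
    _check_prob(report, "transitions.annual_mi_prob", t.annual_mi_prob)
    _check_prob(report, "transitions.annual_stroke_prob", t.annual_stroke_prob)
    _check_prob(report, "transitions.subsequent_stroke_prob", t.subsequent_stroke_prob)
    _check_prob(
        report, "transitions.post_event_excess_mortality", t.post_event_excess_mortality
    )
    if t.annual_mi_prob + t.annual_stroke_prob > 1.0:
        report.append(
            Violation(
                "transitions.annual_mi_prob",
                t.annual_mi_prob + t.annual_stroke_prob,
                "competing first-event probabilities must sum to at most 1",
            )
        )
    for name, sched in (
        ("case_fatality_mi", t.case_fatality_mi),
        ("case_fatality_stroke", t.case_fatality_stroke),
    ):
        for v in sched.all_values():
            _check_prob(report, f"transitions.{name}", v)
    split = t.first_stroke_severity_split
    if len(split) != 3:
        report.append(
            Violation(
                "transitions.first_stroke_severity_split",
                split,
                "severity split has exactly three components",
            )
        )
    else:
        for v in split:
            _check_prob(report, "transitions.first_stroke_severity_split", v)
        if abs(sum(split) - 1.0) > 1e-12:
            report.append(
                Violation(
                    "transitions.first_stroke_severity_split",
                    sum(split),
                    "severity split must sum to 1 (tolerance 1e-12)",
                )
            )

    for eff in params.effects:
        if eff.rr_mi <= 0 or eff.rr_stroke <= 0:
            report.append(
                Violation(
                    f"effects.{eff.drug}",
                    (eff.rr_mi, eff.rr_stroke),
                    "relative risks must be positive",
                )
            )

    c = params.costs
    cost_fields = [
        ("costs.annual_monitoring_cost_provider_usd", c.annual_monitoring_cost_provider_usd),
        ("costs.annual_prevention_patient_usd", c.annual_prevention_patient_usd),
        ("costs.annual_post_event_cost_provider_usd", c.annual_post_event_cost_provider_usd),
        ("costs.annual_post_event_cost_patient_usd", c.annual_post_event_cost_patient_usd),
    ]
    cost_fields += [
        (f"costs.annual_drug_cost_provider_usd.{k}", v)
        for k, v in c.annual_drug_cost_provider_usd.items()
    ]
    cost_fields += [
        (f"costs.acute_event_cost_provider_usd.{k}", v)
        for k, v in c.acute_event_cost_provider_usd.items()
    ]
    cost_fields += [
        (f"costs.acute_event_cost_patient_usd.{k}", v)
        for k, v in c.acute_event_cost_patient_usd.items()
    ]
    for name, v in cost_fields:
        if v < 0:
            report.append(Violation(name, v, "costs must be nonnegative"))
    if c.perspective not in PERSPECTIVES:
        report.append(
            Violation("costs.perspective", c.perspective, "perspective in {societal, provider}")
        )

    w = params.weights
    for name in ("acute_mi", "stroke_mild", "stroke_moderate", "stroke_severe",
                 "post_stroke", "post_mi", "well", "dead"):
        v = getattr(w, name)
        if not (0.0 <= v <= 1.0):
            report.append(Violation(f"weights.{name}", v, "disability weight in [0, 1]"))
    if w.dead != 1.0:
        report.append(Violation("weights.dead", w.dead, "dead weight must equal 1 exactly"))

    d = params.discount
    for name, v in (("cost_rate", d.cost_rate), ("effect_rate", d.effect_rate)):
        if not (0.0 <= v <= 0.2):
            report.append(Violation(f"discount.{name}", v, "discount rate in [0, 0.2]"))

    lt = params.life_table
    for sex in SEXES:
        table = lt.all_cause_male if sex == "male" else lt.all_cause_female
        for v in table:
            _check_prob(report, f"life_table.all_cause_{sex}", v)
        prev = None
        for age in range(31, lt.max_age + 1):
            q = table[age]
            if prev is not None and q < prev:
                report.append(
                    Violation(
                        f"life_table.all_cause_{sex}",
                        (age, q),
                        "all-cause mortality should be nondecreasing above age 30",
                        severity="warning",
                    )
                )
                break
            prev = q
    for v in lt.cvd_attributable_fraction:
        if not (0.0 <= v < 1.0):
            report.append(
                Violation(
                    "life_table.cvd_attributable_fraction",
                    v,
                    "CVD-attributable fraction in [0, 1)",
                )
            )

    if params.cycle_length_years <= 0:
        report.append(
            Violation("cycle_length_years", params.cycle_length_years, "cycle length positive")
        )
    if not (0.0 <= params.adherence <= 1.0):
        report.append(Violation("adherence", params.adherence, "adherence in [0, 1]"))
    return report


# ---------------------------------------------------------------------------
# Parameter-path access (used by sensitivity analyses)


def _resolve(obj: Any, key: str) -> Any:
    if isinstance(obj, dict):
        return obj[key]
    if isinstance(obj, (list, tuple)):
        if key.isdigit():
            return obj[int(key)]
        # address a list of per-drug entries by acronym
        return next(e for e in obj if getattr(e, "drug", None) == key)
    return getattr(obj, key)


def get_param(params: ModelParameters, path: str) -> float:
    """Fetch a scalar by dotted path, e.g. ``"transitions.annual_mi_prob"``,
    ``"costs.annual_drug_cost_provider_usd.ACEI"`` or
    ``"transitions.first_stroke_severity_split.1"``."""
    obj: Any = params
    for key in path.split("."):
        obj = _resolve(obj, key)
    return obj


def set_param(params: ModelParameters, path: str, value: float) -> None:
    """Set a scalar by dotted path in place (tuples are rebuilt).

    ``effects.<DRUG>.rr_mi``-style paths address the per-drug effect list.
    """
    parts = path.split(".")
    obj: Any = params
    for i, key in enumerate(parts[:-1]):
        if isinstance(obj, list) and not key.isdigit():
            # address list of TreatmentEffect by drug acronym
            obj = next(e for e in obj if getattr(e, "drug", None) == key)
            continue
        nxt = _resolve(obj, key)
        if isinstance(nxt, tuple):
            nxt = list(nxt)
            if isinstance(obj, dict):
                obj[key] = nxt
            else:
                setattr(obj, key, nxt)
        obj = nxt
    last = parts[-1]
    if isinstance(obj, dict):
        obj[last] = value
    elif isinstance(obj, list):
        if last.isdigit():
            obj[int(last)] = value
        else:
            raise KeyError(path)
    else:
        setattr(obj, last, value)
    # restore tuple-ness where dataclass fields expect tuples
    t = params.transitions
    if isinstance(t.first_stroke_severity_split, list):
        t.first_stroke_severity_split = tuple(t.first_stroke_severity_split)


# ---------------------------------------------------------------------------
# Serialization (JSON canonical, YAML accepted)


def _to_jsonable(obj: Any) -> Any:
    if isinstance(obj, enum.Enum):
        return obj.value
    if isinstance(obj, frozenset):
        return sorted(obj)
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def params_to_dict(params: ModelParameters) -> dict:
    return _to_jsonable(params)


def params_from_dict(data: dict) -> ModelParameters:
    def tup(x):
        return tuple(x)

    profile = RiskFactorProfile(**data["profile"])
    transitions = TransitionParameters(
        annual_mi_prob=data["transitions"]["annual_mi_prob"],
        annual_stroke_prob=data["transitions"]["annual_stroke_prob"],
        case_fatality_mi=AgeSexSchedule(
            tup(data["transitions"]["case_fatality_mi"]["age_breaks"]),
            tup(data["transitions"]["case_fatality_mi"]["male"]),
            tup(data["transitions"]["case_fatality_mi"]["female"]),
        ),
        case_fatality_stroke=AgeSexSchedule(
            tup(data["transitions"]["case_fatality_stroke"]["age_breaks"]),
            tup(data["transitions"]["case_fatality_stroke"]["male"]),
            tup(data["transitions"]["case_fatality_stroke"]["female"]),
        ),
        first_stroke_severity_split=tup(data["transitions"]["first_stroke_severity_split"]),
        subsequent_stroke_prob=data["transitions"]["subsequent_stroke_prob"],
        post_event_excess_mortality=data["transitions"]["post_event_excess_mortality"],
    )
    effects = [TreatmentEffect(**e) for e in data["effects"]]
    costs = CostSet(**data["costs"])
    weights = DisabilityWeights(**data["weights"])
    lt = data["life_table"]
    life_table = LifeTable(
        max_age=lt["max_age"],
        all_cause_male=tup(lt["all_cause_male"]),
        all_cause_female=tup(lt["all_cause_female"]),
        cvd_attributable_fraction=tup(lt["cvd_attributable_fraction"]),
        life_expectancy_male=tup(lt["life_expectancy_male"]),
        life_expectancy_female=tup(lt["life_expectancy_female"]),
    )
    discount = DiscountSpec(**data["discount"])
    dsa_ranges = [ParamRange(**r) for r in data.get("dsa_ranges", [])]
    psa_distributions = [
        ParamDistribution(
            parameter_id=d["parameter_id"],
            family=d["family"],
            hyperparameters=tup(d["hyperparameters"]),
        )
        for d in data.get("psa_distributions", [])
    ]
    return ModelParameters(
        profile=profile,
        risk_level=RiskLevel(data["risk_level"]),
        transitions=transitions,
        effects=effects,
        costs=costs,
        weights=weights,
        life_table=life_table,
        discount=discount,
        cycle_length_years=data.get("cycle_length_years", 1.0),
        max_age=data.get("max_age", 100),
        half_cycle_death_yld=data.get("half_cycle_death_yld", True),
        half_cycle_correction=data.get("half_cycle_correction", False),
        adherence=data.get("adherence", 1.0),
        dsa_ranges=dsa_ranges,
        psa_distributions=psa_distributions,
    )


def save_parameters(params: ModelParameters, path: str | Path) -> None:
    path = Path(path)
    path.write_text(json.dumps(params_to_dict(params), indent=1, sort_keys=True))


def load_parameters(path: str | Path) -> ModelParameters:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return params_from_dict(data)


def params_fingerprint(params: ModelParameters) -> str:
    """Stable hash of the full parameter set (used to detect trace mismatches)."""
    blob = json.dumps(params_to_dict(params), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
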