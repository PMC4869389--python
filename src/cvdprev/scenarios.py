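"""Scenario analyses as pure parameter transformations.

Scenarios never introduce model-specific code paths: each one is a
transformation of a :class:`ModelParameters` instance (perspective switch,
differential discounting of health outcomes, index-cohort gender swap), so
scenarios compose safely and the base-case specification is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .cea import CEResult
from .domain import DiscountSpec, ModelParameters

__all__ = ["ScenarioSpec", "apply_scenario", "ScenarioDelta", "compare_scenarios"]

_SCENARIO_FIELDS = {"perspective", "discount", "cohort_gender_swap"}


@dataclass
class ScenarioSpec:
    """Base case: societal perspective, 3%/3% discounting, no gender swap."""

    perspective: str = "societal"
    discount: DiscountSpec = field(default_factory=DiscountSpec)
    cohort_gender_swap: bool = False

    @classmethod
    def from_dict(cls, data: dict) -> "ScenarioSpec":
        unknown = set(data) - _SCENARIO_FIELDS
        if unknown:
            raise ValueError(f"unknown scenario fields: {sorted(unknown)}")
        disc = data.get("discount", {})
        if isinstance(disc, dict):
            disc = DiscountSpec(**disc)
        return cls(
            perspective=data.get("perspective", "societal"),
            discount=disc,
            cohort_gender_swap=data.get("cohort_gender_swap", False),
        )


def apply_scenario(params: ModelParameters, spec: ScenarioSpec) -> ModelParameters:
    """Return a new parameter set with the scenario applied.

    Provider perspective excludes the patient-borne cost components only
    (prevention access costs and patient shares of event/post-event care);
    differential discounting replaces the effect rate; the gender swap
    substitutes the opposite-sex index cohort.  Everything else is
    untouched, and the base-case spec is the identity.
    """
    if spec.perspective not in ("societal", "provider"):
        raise ValueError(f"unknown perspective: {spec.perspective!r}")
    out = params.copy()
    out.costs.perspective = spec.perspective
    out.discount = DiscountSpec(spec.discount.cost_rate, spec.discount.effect_rate)
    if spec.cohort_gender_swap:
        other = "female" if params.profile.sex == "male" else "male"
        out.profile = replace(out.profile, sex=other)
    return out


@dataclass
class ScenarioDelta:
    """Per-strategy ICER differences and frontier-ordering changes."""

    icer_delta_usd_per_daly: dict[str, float]
    base_nondominated: list[str]
    scenario_nondominated: list[str]
    rank_changed: bool


def compare_scenarios(
    base_results: list[CEResult], scenario_results: list[CEResult]
) -> ScenarioDelta:
    """Compare two frontier runs over the same strategy universe."""
    base_by_label = {r.strategy_label: r for r in base_results}
    scen_by_label = {r.strategy_label: r for r in scenario_results}
    if set(base_by_label) != set(scen_by_label):
        raise ValueError("strategy universes differ between runs")
    deltas: dict[str, float] = {}
    for label, b in base_by_label.items():
        s = scen_by_label[label]
        if b.icer_usd_per_daly is not None and s.icer_usd_per_daly is not None:
            deltas[label] = s.icer_usd_per_daly - b.icer_usd_per_daly
    base_nd = [r.strategy_label for r in base_results if r.status == "nondominated"]
    scen_nd = [r.strategy_label for r in scenario_results if r.status == "nondominated"]
    return ScenarioDelta(
        icer_delta_usd_per_daly=deltas,
        base_nondominated=base_nd,
        scenario_nondominated=scen_nd,
        rank_changed=base_nd != scen_nd,
    )
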