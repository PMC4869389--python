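"""Treatment-effect resolution and per-cell strategy universes.

A strategy's effect on an endpoint is the product of its drugs' relative
risks (RR_1 x RR_2 x ... x RR_n); an empty strategy has RR 1.  The default
endpoint mapping follows the evidence classes: anti-hypertensives and the
statin affect both MI and stroke, aspirin affects MI only, and the oral
hypoglycemics affect both endpoints via glycaemic control.  All of it is
overridable through the per-drug effect table.

The admissible strategy universe for a (model, risk level) cell encodes the
clinical constraints of the analysis: aspirin is restricted to very-high
risk, oral hypoglycemics appear only in the diabetes model, and triple
anti-hypertensive therapy is excluded at moderate risk.  No-treatment is
always admissible.
"""

from __future__ import annotations

import math
from itertools import combinations

from .domain import (
    ANTIHYPERTENSIVES,
    ORAL_HYPOGLYCEMICS,
    RiskLevel,
    Strategy,
    TreatmentEffect,
)

__all__ = ["combined_rr", "admissible_strategies", "MAX_ANTIHYPERTENSIVES"]

#: At most a triple anti-hypertensive combination is ever considered.
MAX_ANTIHYPERTENSIVES = 3


def combined_rr(
    strategy: Strategy, effects: list[TreatmentEffect], endpoint: str
) -> float:
    """Multiplicative combined relative risk of a strategy on one endpoint.

    Order-independent; the empty strategy returns exactly 1.0.  Raises if a
    drug lacks an effect entry or carries a nonpositive RR.
    """
    if endpoint not in ("mi", "stroke"):
        raise ValueError(f"unsupported endpoint: {endpoint!r}")
    table = {e.drug: e for e in effects}
    rr = 1.0
    for drug in sorted(strategy.drugs):
        if drug not in table:
            raise KeyError(f"no treatment-effect entry for drug {drug!r}")
        value = table[drug].rr_mi if endpoint == "mi" else table[drug].rr_stroke
        if value <= 0:
            raise ValueError(f"nonpositive RR {value} for drug {drug!r}")
        rr *= value
    return rr


def _antihypertensive_subsets(max_size: int) -> list[frozenset[str]]:
    out: list[frozenset[str]] = []
    for size in range(0, max_size + 1):
        for combo in combinations(sorted(ANTIHYPERTENSIVES), size):
            out.append(frozenset(combo))
    return out


def admissible_strategies(model: str, risk_level: RiskLevel) -> list[Strategy]:
    """The strategy universe evaluated for one (model, risk level) cell.

    Packaged defaults (the full published combination list was not
    available, so the universe is generated from the constraint rules):

    * 0-3 anti-hypertensive classes, but no triple at moderate risk;
    * the statin optional everywhere;
    * aspirin only at very-high risk;
    * 0-2 oral hypoglycemics, diabetes model only;
    * no-treatment always included.
    """
    if model not in ("cvd", "cvd_with_diabetes"):
        raise ValueError(f"unknown model: {model!r}")
    risk_level = RiskLevel(risk_level)
    max_aht = MAX_ANTIHYPERTENSIVES
    if risk_level is RiskLevel.moderate:
        max_aht = 2
    asa_options = [frozenset(), frozenset({"ASA"})] if risk_level is RiskLevel.very_high else [frozenset()]
    sta_options = [frozenset(), frozenset({"Sta"})]
    if model == "cvd_with_diabetes":
        hypo_options = [
            frozenset(c)
            for size in range(0, 3)
            for c in combinations(sorted(ORAL_HYPOGLYCEMICS), size)
        ]
    else:
        hypo_options = [frozenset()]

    universe: set[frozenset[str]] = set()
    for aht in _antihypertensive_subsets(max_aht):
        for sta in sta_options:
            for asa in asa_options:
                for hypo in hypo_options:
                    universe.add(aht | sta | asa | hypo)
    strategies = sorted((Strategy(drugs) for drugs in universe), key=lambda s: (len(s.drugs), s.label))
    return strategies


def log_combined_rr(strategy: Strategy, effects: list[TreatmentEffect], endpoint: str) -> float:
    """exp(sum of log RRs); numerically identical route used for cross-checks."""
    table = {e.drug: e for e in effects}
    total = 0.0
    for drug in strategy.drugs:
        value = table[drug].rr_mi if endpoint == "mi" else table[drug].rr_stroke
        total += math.log(value)
    return math.exp(total)
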