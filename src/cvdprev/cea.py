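"""Incremental cost-effectiveness analysis: dominance, frontiers, ICERs.

Given per-strategy expected lifetime costs and DALYs averted (vs the
no-treatment anchor), the frontier routine removes strictly dominated
strategies (weakly more costly and no more effective than another, with at
least one strict inequality), then iteratively removes extendedly dominated
ones until ICERs are strictly increasing along the cost-sorted survivors.
ICERs are computed against the preceding surviving strategy.  A strategy
is adopted at willingness-to-pay lambda if its ICER is at most lambda
(inclusive at equality), which coincides with maximizing net monetary
benefit lambda*effect - cost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "CEResult",
    "icer",
    "round_usd",
    "frontier",
    "optimal_at_wtp",
    "nmb",
    "results_to_frame",
]


@dataclass
class CEResult:
    strategy_label: str
    cost_usd: float
    effect_dalys_averted: float
    status: str  # "nondominated" | "dominated" | "extendedly_dominated"
    incremental_cost_usd: float | None = None
    incremental_effect: float | None = None
    icer_usd_per_daly: float | None = None


def icer(incremental_cost_usd: float, incremental_effect: float) -> float:
    """Incremental cost-effectiveness ratio, cost per DALY averted."""
    if incremental_effect == 0:
        raise ZeroDivisionError(
            "ICER undefined for zero incremental effect (dominance tie)"
        )
    return incremental_cost_usd / incremental_effect


def round_usd(value: float) -> int:
    """Half-up rounding to whole US$ for display (internal math unrounded)."""
    return int(math.floor(value + 0.5)) if value >= 0 else -int(math.floor(-value + 0.5))


def nmb(cost_usd: float, effect_dalys_averted: float, wtp_usd_per_daly: float) -> float:
    """Net monetary benefit at willingness-to-pay lambda."""
    return wtp_usd_per_daly * effect_dalys_averted - cost_usd


def frontier(results: list[tuple[str, float, float]]) -> list[CEResult]:
    """Compute the efficient frontier from (label, cost, effect) triples.

    Returns one :class:`CEResult` per input strategy, sorted by cost, with
    dominance status and, for surviving strategies, incremental cost/effect
    and the ICER against the preceding survivor (absent for the cheapest).
    Exact ties in both cost and effect keep the lexicographically smaller
    label and mark the other dominated.
    """
    if not results:
        raise ValueError("at least one strategy is required")
    labels = [r[0] for r in results]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate strategy labels")

    entries = sorted(results, key=lambda r: (r[1], -r[2], r[0]))
    status = {label: "nondominated" for label in labels}

    # exact cost/effect ties: keep the lexicographically smaller label
    for i, (label, cost, effect) in enumerate(entries):
        for other, ocost, oeffect in entries[:i]:
            if status[other] != "nondominated":
                continue
            if ocost == cost and oeffect == effect:
                status[max(label, other)] = "dominated"

    # strict dominance
    for label, cost, effect in entries:
        for other, ocost, oeffect in entries:
            if other == label or status[other] != "nondominated":
                continue
            if ocost <= cost and oeffect >= effect and (ocost < cost or oeffect > effect):
                status[label] = "dominated"
                break

    # extended dominance: restore strictly increasing ICERs
    changed = True
    while changed:
        changed = False
        surv = [e for e in entries if status[e[0]] == "nondominated"]
        for i in range(1, len(surv) - 1):
            prev_, cur, nxt = surv[i - 1], surv[i], surv[i + 1]
            icer_cur = icer(cur[1] - prev_[1], cur[2] - prev_[2])
            icer_nxt = icer(nxt[1] - cur[1], nxt[2] - cur[2])
            if icer_cur >= icer_nxt:
                status[cur[0]] = "extendedly_dominated"
                changed = True
                break

    out: list[CEResult] = []
    prev: tuple[str, float, float] | None = None
    for label, cost, effect in entries:
        res = CEResult(label, cost, effect, status[label])
        if status[label] == "nondominated":
            if prev is not None:
                res.incremental_cost_usd = cost - prev[1]
                res.incremental_effect = effect - prev[2]
                res.icer_usd_per_daly = icer(res.incremental_cost_usd, res.incremental_effect)
            prev = (label, cost, effect)
        out.append(res)
    return out


def optimal_at_wtp(frontier_results: list[CEResult], wtp_usd_per_daly: float) -> str:
    """Label of the optimal strategy at a willingness-to-pay threshold.

    The most effective frontier strategy whose ICER is at most the
    threshold; the cheapest frontier strategy (typically no-treatment) if
    none qualifies.  Equivalent to maximizing expected net monetary benefit,
    with ties resolved toward the more effective strategy.
    """
    if wtp_usd_per_daly < 0:
        raise ValueError("willingness to pay must be nonnegative")
    surviving = [r for r in frontier_results if r.status == "nondominated"]
    if not surviving:
        raise ValueError("no surviving strategies on the frontier")
    surviving.sort(key=lambda r: r.cost_usd)
    best = surviving[0]
    for res in surviving[1:]:
        assert res.icer_usd_per_daly is not None
        if res.icer_usd_per_daly <= wtp_usd_per_daly:
            best = res
    return best.strategy_label


def results_to_frame(results: list[CEResult]) -> pd.DataFrame:
    """Base-case table mirroring the published layout (display-rounded ICER)."""
    rows = []
    for r in results:
        rows.append(
            {
                "strategy": r.strategy_label,
                "cost_usd": r.cost_usd,
                "incremental_cost_usd": r.incremental_cost_usd,
                "effect_dalys_averted": r.effect_dalys_averted,
                "incremental_effect": r.incremental_effect,
                "icer_usd_per_daly": (
                    round_usd(r.icer_usd_per_daly) if r.icer_usd_per_daly is not None else None
                ),
                "status": r.status,
            }
        )
    return pd.DataFrame(rows)
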