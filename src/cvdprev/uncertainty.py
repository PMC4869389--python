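"""Sensitivity and value-of-information analyses.

* One-way deterministic sensitivity analysis (tornado): re-evaluate a named
  ICER comparison at each parameter's low/high bound with everything else at
  base; parameters whose swing contributes less than 1% of the summed
  absolute swings are omitted from the default report.
* Probabilistic sensitivity analysis: joint independent Monte-Carlo draws of
  all distributed parameters; every admissible strategy is run on the same
  draw.  Per-parameter random streams are derived deterministically from the
  shared seed, so adding a parameter does not perturb the others' draws.
* Cost-effectiveness acceptability frontier (CEAF): at each willingness to
  pay, the strategy maximizing expected net monetary benefit and the
  fraction of samples in which it attains the per-sample maximum.
* EVPI: mean over samples of the per-sample best net benefit minus the best
  expected net benefit; population EVPI scales by a discounted cohort of
  beneficiaries (first year undiscounted).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from . import cea
from .domain import (
    ModelParameters,
    ParamDistribution,
    ParamRange,
    Strategy,
    get_param,
    set_param,
    validate_parameters,
)
from .markov import effectiveness_vs_baseline, run_cohort

__all__ = [
    "ParamRange",
    "ParamDistribution",
    "TornadoEntry",
    "IcerComparison",
    "one_way_dsa",
    "build_distribution",
    "sample_distribution",
    "PsaOutput",
    "run_psa",
    "ceaf",
    "evpi_per_person",
    "population_evpi",
    "population_evpi_multiplier",
    "EvpiCurve",
    "evpi_curve",
    "default_wtp_grid",
]


def default_wtp_grid() -> np.ndarray:
    """Willingness-to-pay grid, 0-3000 US$/DALY in steps of 10 (covers every
    decision threshold of interest, 115-1327)."""
    return np.arange(0.0, 3001.0, 10.0)


# ---------------------------------------------------------------------------
# One-way DSA


@dataclass
class IcerComparison:
    """The ICER outcome of interest: strategy vs comparator (label strings)."""

    strategy: str
    comparator: str


@dataclass
class TornadoEntry:
    parameter_id: str
    low: float
    high: float
    outcome_low: float
    outcome_high: float

    @property
    def swing(self) -> float:
        return abs(self.outcome_high - self.outcome_low)


def _icer_outcome(params: ModelParameters, comparison: IcerComparison) -> float:
    s = Strategy.from_label(comparison.strategy)
    c = Strategy.from_label(comparison.comparator)
    trace_s = run_cohort(params, s)
    trace_c = run_cohort(params, c)
    d_cost = trace_s.total_cost - trace_c.total_cost
    d_eff = trace_c.total_dalys - trace_s.total_dalys
    return cea.icer(d_cost, d_eff)


def one_way_dsa(
    params: ModelParameters,
    comparison: IcerComparison,
    ranges: list[ParamRange] | None = None,
    *,
    min_share: float = 0.01,
    include_all: bool = False,
) -> list[TornadoEntry]:
    """Tornado entries for the ICER of ``comparison``, sorted by swing
    (largest first).

    Each parameter is set to its low and high bound in turn with all others
    at base.  Entries contributing less than ``min_share`` of the summed
    absolute swings are omitted unless ``include_all`` is set.
    """
    if ranges is None:
        ranges = params.dsa_ranges
    entries: list[TornadoEntry] = []
    for rng in ranges:
        if not (rng.low <= rng.base <= rng.high):
            raise ValueError(
                f"invalid range for {rng.parameter_id}: low <= base <= high required"
            )
        outcomes = []
        for bound in (rng.low, rng.high):
            trial = params.copy()
            set_param(trial, rng.parameter_id, bound)
            bad = [v for v in validate_parameters(trial) if v.severity == "error"]
            if bad:
                raise ValueError(
                    f"range bound {bound} for {rng.parameter_id} violates "
                    f"invariants: {bad[0].rule}"
                )
            outcomes.append(_icer_outcome(trial, comparison))
        entries.append(
            TornadoEntry(rng.parameter_id, rng.low, rng.high, outcomes[0], outcomes[1])
        )
    entries.sort(key=lambda e: e.swing, reverse=True)
    total = sum(e.swing for e in entries)
    if include_all or total == 0:
        return entries
    return [e for e in entries if e.swing / total >= min_share]


# ---------------------------------------------------------------------------
# Distributions


def build_distribution(
    rng: ParamRange, family: str | None = None
) -> ParamDistribution:
    """Moment-match a sampling distribution to a base value and range.

    The range is read as an approximate 95% interval, so sd =
    (high - low) / (2 * 1.96).  Families: beta (probabilities), gamma
    (costs), lognormal (relative risks, base as median), uniform.  A
    zero-width range yields a degenerate uniform.
    """
    base, low, high = rng.base, rng.low, rng.high
    sd = (high - low) / (2.0 * 1.959963984540054)
    if family is None:
        family = "uniform"
    if sd == 0.0 or family == "uniform":
        if sd == 0.0:
            return ParamDistribution(rng.parameter_id, "uniform", (base, base))
        return ParamDistribution(rng.parameter_id, "uniform", (low, high))
    if family == "beta":
        m = min(max(base, 1e-9), 1 - 1e-9)
        var = sd * sd
        common = m * (1 - m) / var - 1.0
        if common <= 0:  # variance too large for the support; fall back
            return ParamDistribution(rng.parameter_id, "uniform", (low, high))
        return ParamDistribution(rng.parameter_id, "beta", (m * common, (1 - m) * common))
    if family == "gamma":
        if base <= 0:
            return ParamDistribution(rng.parameter_id, "uniform", (low, high))
        shape = (base / sd) ** 2
        scale = sd * sd / base
        return ParamDistribution(rng.parameter_id, "gamma", (shape, scale))
    if family == "lognormal":
        if low <= 0 or high <= 0 or base <= 0:
            return ParamDistribution(rng.parameter_id, "uniform", (max(low, 0.0), high))
        sigma_log = (np.log(high) - np.log(low)) / (2.0 * 1.959963984540054)
        return ParamDistribution(
            rng.parameter_id, "lognormal", (float(np.log(base)), float(sigma_log))
        )
    raise ValueError(f"unknown distribution family: {family!r}")


def sample_distribution(
    dist: ParamDistribution, rng: np.random.Generator, size: int
) -> np.ndarray:
    a = dist.hyperparameters
    if dist.family == "uniform":
        if a[0] == a[1]:
            return np.full(size, a[0])
        return rng.uniform(a[0], a[1], size)
    if dist.family == "beta":
        return rng.beta(a[0], a[1], size)
    if dist.family == "gamma":
        return rng.gamma(a[0], a[1], size)
    if dist.family == "lognormal":
        return rng.lognormal(a[0], a[1], size)
    raise ValueError(f"invalid hyperparameters or family: {dist}")


def _param_rng(seed: int, parameter_id: str) -> np.random.Generator:
    key = zlib.crc32(parameter_id.encode())
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


# ---------------------------------------------------------------------------
# PSA


@dataclass
class PsaOutput:
    """Monte-Carlo samples of (cost, DALYs averted) per strategy."""

    n_samples: int
    seed: int
    strategies: list[str]
    costs: dict[str, np.ndarray] = field(default_factory=dict)
    effects: dict[str, np.ndarray] = field(default_factory=dict)

    def nmb_matrix(self, wtp: float) -> np.ndarray:
        """(n_samples, n_strategies) net-monetary-benefit matrix."""
        cols = [
            wtp * self.effects[s] - self.costs[s] for s in self.strategies
        ]
        return np.column_stack(cols)


_MAX_RESAMPLE = 100


def run_psa(
    params: ModelParameters,
    strategies: list[Strategy],
    distributions: list[ParamDistribution] | None = None,
    n_samples: int = 1000,
    seed: int = 0,
) -> PsaOutput:
    """Joint Monte-Carlo over all distributed parameters.

    For every sample all strategies (the no-treatment anchor is added if
    missing) are run on the same draw; effects are DALYs averted vs the
    same-draw no-treatment run.  Identical seeds yield identical output.
    Draws violating hard invariants are resampled (capped, then an error).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be at least 1")
    if distributions is None:
        distributions = params.psa_distributions
    if not any(s.is_no_treatment for s in strategies):
        strategies = [Strategy.no_treatment()] + list(strategies)

    rngs = {d.parameter_id: _param_rng(seed, d.parameter_id) for d in distributions}
    draws = {
        d.parameter_id: sample_distribution(d, rngs[d.parameter_id], n_samples)
        for d in distributions
    }

    labels = [s.label for s in strategies]
    costs = {lab: np.zeros(n_samples) for lab in labels}
    effects = {lab: np.zeros(n_samples) for lab in labels}

    for i in range(n_samples):
        trial = None
        for attempt in range(_MAX_RESAMPLE):
            trial = params.copy()
            for d in distributions:
                set_param(trial, d.parameter_id, float(draws[d.parameter_id][i]))
            bad = [v for v in validate_parameters(trial) if v.severity == "error"]
            if not bad:
                break
            for d in distributions:  # redraw this sample from each stream
                draws[d.parameter_id][i] = sample_distribution(
                    d, rngs[d.parameter_id], 1
                )[0]
        else:
            raise RuntimeError(
                f"sample {i}: could not draw a valid parameter set in "
                f"{_MAX_RESAMPLE} attempts"
            )
        baseline = run_cohort(trial, Strategy.no_treatment())
        for s, lab in zip(strategies, labels):
            trace = baseline if s.is_no_treatment else run_cohort(trial, s)
            costs[lab][i] = trace.total_cost
            effects[lab][i] = effectiveness_vs_baseline(trace, baseline)
    return PsaOutput(n_samples, seed, labels, costs, effects)


# ---------------------------------------------------------------------------
# CEAF and EVPI


def ceaf(psa: PsaOutput, wtp_grid: np.ndarray) -> list[tuple[float, str, float]]:
    """Per willingness-to-pay: the expected-NMB-optimal strategy and the
    probability (sample fraction) that it attains the per-sample maximum.

    Probabilities over all strategies at one threshold sum to 1 (each sample
    has exactly one winner).
    """
    if psa.n_samples == 0 or not psa.strategies:
        raise ValueError("empty PSA output")
    out = []
    for wtp in np.asarray(wtp_grid, dtype=float):
        M = psa.nmb_matrix(wtp)
        frontier_idx = int(np.argmax(M.mean(axis=0)))
        winners = np.argmax(M, axis=1)
        prob = float(np.mean(winners == frontier_idx))
        out.append((float(wtp), psa.strategies[frontier_idx], prob))
    return out


def evpi_per_person(psa: PsaOutput, wtp: float) -> float:
    """Expected value of perfect information per beneficiary:
    E[max_s NMB] - max_s E[NMB]; nonnegative by Jensen's inequality."""
    M = psa.nmb_matrix(float(wtp))
    value = float(M.max(axis=1).mean() - M.mean(axis=0).max())
    return max(0.0, value)  # clip only guards the sign against roundoff


def population_evpi_multiplier(
    annual_population: int = 1000, rate: float = 0.03, years: int = 10
) -> float:
    """Discounted beneficiary-years: sum over t = 1..years of
    population / (1 + rate)^(t-1); the first year is undiscounted."""
    return float(
        sum(annual_population / (1.0 + rate) ** (t - 1) for t in range(1, years + 1))
    )


def population_evpi(
    evpi_pp: float,
    annual_population: int = 1000,
    rate: float = 0.03,
    years: int = 10,
) -> float:
    """Per-person EVPI scaled to the discounted beneficiary population."""
    if evpi_pp < 0 or annual_population < 0 or rate < 0 or years < 0:
        raise ValueError("population EVPI inputs must be nonnegative")
    return evpi_pp * population_evpi_multiplier(annual_population, rate, years)


@dataclass
class EvpiCurve:
    wtp_grid: np.ndarray
    evpi_per_person: np.ndarray
    population_evpi: np.ndarray


def evpi_curve(
    psa: PsaOutput,
    wtp_grid: np.ndarray | None = None,
    annual_population: int = 1000,
    rate: float = 0.03,
    years: int = 10,
) -> EvpiCurve:
    if wtp_grid is None:
        wtp_grid = default_wtp_grid()
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    pp = np.array([evpi_per_person(psa, w) for w in wtp_grid])
    mult = population_evpi_multiplier(annual_population, rate, years)
    return EvpiCurve(wtp_grid, pp, pp * mult)
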