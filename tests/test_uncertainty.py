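"""One-way DSA, PSA, acceptability frontiers and value of information."""

import math

import numpy as np
import pytest

from cvdprev.domain import ParamDistribution, ParamRange, Strategy
from cvdprev.markov import effectiveness_vs_baseline, run_cohort
from cvdprev.uncertainty import (
    IcerComparison,
    PsaOutput,
    build_distribution,
    ceaf,
    evpi_curve,
    evpi_per_person,
    one_way_dsa,
    population_evpi,
    population_evpi_multiplier,
    run_psa,
    sample_distribution,
)

COMPARISON = IcerComparison("ACEI_Diu", "No treatment")


def make_psa(costs: dict, effects: dict, seed=0) -> PsaOutput:
    labels = list(costs)
    n = len(next(iter(costs.values())))
    return PsaOutput(
        n_samples=n,
        seed=seed,
        strategies=labels,
        costs={k: np.asarray(v, dtype=float) for k, v in costs.items()},
        effects={k: np.asarray(v, dtype=float) for k, v in effects.items()},
    )


class TestOneWayDsa:
    def test_zero_width_range_is_omitted(self, params_high):
        base = params_high.transitions.annual_mi_prob
        ranges = [
            ParamRange("transitions.annual_mi_prob", base, base, base),
            ParamRange.pct15("effects.ACEI.rr_mi", 0.9),
        ]
        entries = one_way_dsa(params_high, COMPARISON, ranges)
        ids = [e.parameter_id for e in entries]
        assert "transitions.annual_mi_prob" not in ids
        assert "effects.ACEI.rr_mi" in ids

    def test_matches_direct_recomputation(self, params_high):
        """Tornado outcomes must equal brute-force re-evaluation of the
        ICER at each bound (independent loop over set-and-run)."""
        from cvdprev.cea import icer as icer_op
        from cvdprev.domain import set_param

        ranges = params_high.dsa_ranges[:5]
        entries = one_way_dsa(params_high, COMPARISON, ranges, include_all=True)
        by_id = {e.parameter_id: e for e in entries}
        for rng in ranges:
            for bound, attr in ((rng.low, "outcome_low"), (rng.high, "outcome_high")):
                trial = params_high.copy()
                set_param(trial, rng.parameter_id, bound)
                nt = run_cohort(trial, Strategy.no_treatment())
                s = run_cohort(trial, Strategy.from_label("ACEI_Diu"))
                expected = icer_op(
                    s.total_cost - nt.total_cost, effectiveness_vs_baseline(s, nt)
                )
                assert getattr(by_id[rng.parameter_id], attr) == pytest.approx(expected)

    def test_small_contributors_dropped_from_default_report(self, params_high):
        entries_all = one_way_dsa(
            params_high, COMPARISON, params_high.dsa_ranges, include_all=True
        )
        total = sum(e.swing for e in entries_all)
        entries = one_way_dsa(params_high, COMPARISON, params_high.dsa_ranges)
        assert all(e.swing / total >= 0.01 for e in entries)
        swings = [e.swing for e in entries]
        assert swings == sorted(swings, reverse=True)

    def test_invalid_range_signalled(self, params_high):
        bad = [ParamRange("transitions.annual_mi_prob", 0.02, 0.01, 1.5)]
        with pytest.raises(ValueError):
            one_way_dsa(params_high, COMPARISON, bad)


class TestDistributions:
    def test_beta_moment_matching(self):
        rng = ParamRange.pct15("p", 0.3, probability=True)
        dist = build_distribution(rng, "beta")
        a, b = dist.hyperparameters
        assert a / (a + b) == pytest.approx(0.3, rel=1e-9)
        sd = (rng.high - rng.low) / (2 * 1.959963984540054)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        assert math.sqrt(var) == pytest.approx(sd, rel=1e-9)

    def test_gamma_moment_matching(self):
        rng = ParamRange.pct15("c", 200.0)
        dist = build_distribution(rng, "gamma")
        shape, scale = dist.hyperparameters
        assert shape * scale == pytest.approx(200.0, rel=1e-9)

    def test_lognormal_median_is_base(self):
        rng = ParamRange("rr", 0.8, 0.7, 0.92, source="ci95")
        dist = build_distribution(rng, "lognormal")
        assert math.exp(dist.hyperparameters[0]) == pytest.approx(0.8)

    def test_beta_draws_respect_support(self):
        dist = build_distribution(ParamRange.pct15("p", 0.5, probability=True), "beta")
        draws = sample_distribution(dist, np.random.default_rng(0), 5000)
        assert ((draws >= 0) & (draws <= 1)).all()

    def test_degenerate_range_gives_constant(self):
        dist = build_distribution(ParamRange("x", 3.0, 3.0, 3.0))
        draws = sample_distribution(dist, np.random.default_rng(0), 10)
        assert (draws == 3.0).all()


class TestRunPsa:
    STRATS = [Strategy.no_treatment(), Strategy.from_label("ACEI_Diu")]

    def test_same_seed_is_bitwise_identical(self, params_high):
        a = run_psa(params_high, self.STRATS, n_samples=5, seed=3)
        b = run_psa(params_high, self.STRATS, n_samples=5, seed=3)
        for lab in a.strategies:
            assert (a.costs[lab] == b.costs[lab]).all()
            assert (a.effects[lab] == b.effects[lab]).all()

    def test_different_seed_differs(self, params_high):
        a = run_psa(params_high, self.STRATS, n_samples=5, seed=3)
        b = run_psa(params_high, self.STRATS, n_samples=5, seed=4)
        assert any((a.costs[lab] != b.costs[lab]).any() for lab in a.strategies)

    def test_degenerate_distributions_recover_base_case(self, params_high):
        from cvdprev.domain import get_param

        degenerate = []
        for d in params_high.psa_distributions[:3]:
            base = get_param(params_high, d.parameter_id)
            degenerate.append(ParamDistribution(d.parameter_id, "uniform", (base, base)))
        out = run_psa(params_high, self.STRATS, degenerate, n_samples=1, seed=0)
        nt = run_cohort(params_high, Strategy.no_treatment())
        s = run_cohort(params_high, Strategy.from_label("ACEI_Diu"))
        assert out.costs["No treatment"][0] == nt.total_cost
        assert out.costs["ACEI_Diu"][0] == s.total_cost
        assert out.effects["ACEI_Diu"][0] == effectiveness_vs_baseline(s, nt)

    def test_adding_a_parameter_preserves_other_streams(self, params_high):
        dists = params_high.psa_distributions
        a = run_psa(params_high, self.STRATS, dists[:3], n_samples=4, seed=9)
        b = run_psa(params_high, self.STRATS, dists[:4], n_samples=4, seed=9)
        # same seed: the first three parameters' draws are unchanged, so the
        # two runs differ only through the fourth parameter's influence
        from cvdprev.uncertainty import _param_rng, sample_distribution as sd

        for d in dists[:3]:
            x = sd(d, _param_rng(9, d.parameter_id), 4)
            y = sd(d, _param_rng(9, d.parameter_id), 4)
            assert (x == y).all()
        assert a.n_samples == b.n_samples

    def test_requires_at_least_one_sample(self, params_high):
        with pytest.raises(ValueError):
            run_psa(params_high, self.STRATS, n_samples=0)


class TestCeaf:
    def test_single_strategy_probability_one(self):
        psa = make_psa({"Only": [10, 12, 11]}, {"Only": [0.1, 0.2, 0.15]})
        for _, label, prob in ceaf(psa, [0, 500, 1000]):
            assert label == "Only"
            assert prob == 1.0

    def test_zero_wtp_prefers_cheapest(self):
        psa = make_psa(
            {"No treatment": [0.0] * 4, "A": [100.0] * 4},
            {"No treatment": [0.0] * 4, "A": [1.0] * 4},
        )
        wtp, label, prob = ceaf(psa, [0.0])[0]
        assert label == "No treatment"
        assert prob == 1.0

    def test_probabilities_sum_to_one_across_strategies(self):
        rng = np.random.default_rng(5)
        n = 2000
        psa = make_psa(
            {"No treatment": np.zeros(n), "A": rng.normal(500, 80, n), "B": rng.normal(900, 80, n)},
            {"No treatment": np.zeros(n), "A": rng.normal(1.0, 0.3, n), "B": rng.normal(1.6, 0.3, n)},
        )
        for wtp in (0.0, 400.0, 800.0):
            M = psa.nmb_matrix(wtp)
            winners = np.argmax(M, axis=1)
            total = sum(np.mean(winners == j) for j in range(3))
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_gaussian_crossing_matches_analytic_tie_point(self):
        """Two strategies with Gaussian (cost, effect): the CEAF switch must
        sit at the analytic expected-NMB tie lambda = dC/dE."""
        rng = np.random.default_rng(12)
        n = 40000
        dc, de = 300.0, 0.5  # tie at lambda = 600
        psa = make_psa(
            {"No treatment": np.zeros(n), "A": rng.normal(dc, 30, n)},
            {"No treatment": np.zeros(n), "A": rng.normal(de, 0.05, n)},
        )
        grid = np.arange(0, 1201, 1.0)
        rows = ceaf(psa, grid)
        switch = next(w for w, label, _ in rows if label == "A")
        assert switch == pytest.approx(600.0, abs=10.0)


class TestEvpi:
    def test_dominant_strategy_has_zero_evpi(self):
        psa = make_psa(
            {"No treatment": [0, 0, 0], "A": [10, 12, 11]},
            {"No treatment": [0, 0, 0], "A": [1.0, 1.1, 0.9]},
        )
        assert evpi_per_person(psa, 1000.0) == 0.0

    def test_zero_wtp_with_nonnegative_costs_is_zero(self):
        rng = np.random.default_rng(1)
        psa = make_psa(
            {"No treatment": np.zeros(100), "A": rng.uniform(10, 30, 100)},
            {"No treatment": np.zeros(100), "A": rng.uniform(0, 1, 100)},
        )
        assert evpi_per_person(psa, 0.0) == 0.0

    def test_matches_direct_enumeration(self):
        costs = {"No treatment": [0.0, 0.0], "A": [100.0, 100.0]}
        effects = {"No treatment": [0.0, 0.0], "A": [1.0, -0.5]}
        psa = make_psa(costs, effects)
        lam = 200.0
        nmbs = np.array(
            [[lam * effects[s][i] - costs[s][i] for s in psa.strategies] for i in range(2)]
        )
        expected = nmbs.max(axis=1).mean() - nmbs.mean(axis=0).max()
        assert evpi_per_person(psa, lam) == pytest.approx(expected, abs=1e-12)

    def test_nonnegative_on_random_psas(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = 200
            labels = [f"S{i}" for i in range(int(rng.integers(2, 5)))]
            psa = make_psa(
                {lab: rng.normal(500, 200, n) for lab in labels},
                {lab: rng.normal(1, 0.5, n) for lab in labels},
            )
            for lam in (0.0, 300.0, 1500.0):
                assert evpi_per_person(psa, lam) >= 0.0


class TestPopulationEvpi:
    def test_zero_in_zero_out(self):
        assert population_evpi(0.0) == 0.0

    def test_undiscounted_multiplier(self):
        assert population_evpi_multiplier(1000, 0.0, 10) == 10000.0

    def test_default_multiplier_matches_geometric_series(self):
        v = 1.0 / 1.03
        closed_form = 1000.0 * (1.0 - v**10) / (1.0 - v)
        assert population_evpi_multiplier() == pytest.approx(closed_form, abs=1e-9)
        assert population_evpi_multiplier() == pytest.approx(8786.11, abs=0.01)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            population_evpi(-1.0)

    def test_curve_scales_per_person_values(self):
        psa = make_psa(
            {"No treatment": [0.0, 0.0], "A": [100.0, 100.0]},
            {"No treatment": [0.0, 0.0], "A": [1.0, -0.5]},
        )
        curve = evpi_curve(psa, np.array([0.0, 200.0, 400.0]))
        mult = population_evpi_multiplier()
        assert np.allclose(curve.population_evpi, curve.evpi_per_person * mult)
        assert (curve.evpi_per_person >= 0).all()
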