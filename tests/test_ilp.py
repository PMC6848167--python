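"""ILP engine: toy oracles, constraint semantics, pool behavior."""

import numpy as np
import pytest

from causalnet import (
    MeasurementSet,
    NodePenaltyWeights,
    PerturbationSet,
    SignedNetwork,
    aggregate_pool,
    audit_solution,
    build_ilp,
    build_inverse,
    solve_pool,
)
from causalnet.core import InputError, UNKNOWN
from causalnet.exhaustive import (
    exhaustive_inverse_optimum,
    exhaustive_optimum,
)
from oracles import random_ilp_instance as _random_instance


def _measured(ms):
    return {v: (m.alpha, m.m) for v, m in ms.entries.items()}


class TestStandardMode:
    def test_activating_chain_fully_recovered(self, chain_pkn, no_gamma, cfg_factory):
        ms = MeasurementSet.from_scores({"T": 2.0})
        perturb = PerturbationSet.build({"P": 1}, chain_pkn)
        cfg = cfg_factory(beta=0.1)
        pool = solve_pool(build_ilp(chain_pkn, ms, no_gamma, perturb, cfg), cfg)
        sol = pool.solutions[0]
        assert sol.states == {"P": 1, "A": 1, "T": 1}
        assert sol.objective_value == pytest.approx(0.3)
        best, optima = exhaustive_optimum(chain_pkn, ms, no_gamma, perturb, 0.1)
        assert pool.best_objective == pytest.approx(best)
        assert sol.states in optima

    def test_inhibitory_middle_edge_forces_mismatch(self, no_gamma, cfg_factory):
        pkn = SignedNetwork.from_edges([("P", "A", 1), ("A", "T", -1)])
        ms = MeasurementSet.from_scores({"T": 2.0})
        perturb = PerturbationSet.build({"P": 1}, pkn)
        cfg = cfg_factory(beta=0.1)
        pool = solve_pool(build_ilp(pkn, ms, no_gamma, perturb, cfg), cfg)
        best, _ = exhaustive_optimum(pkn, ms, no_gamma, perturb, 0.1)
        # explaining T=+1 is impossible through a sign-consistent path; the
        # cheapest move is to leave T unexplained (mismatch 1*alpha) rather
        # than set T=-1 (mismatch 2*alpha)
        assert pool.best_objective == pytest.approx(best)
        assert pool.solutions[0].states["T"] == 0

    def test_gamma_adjusts_activation_cost(self, cfg_factory):
        # with gamma_A = +1 and beta = 0.5, activating A is free while
        # inhibiting it costs 2*beta = 1
        pkn = SignedNetwork.from_edges([("P", "A", 1)])
        gamma = NodePenaltyWeights(gamma={"A": 1.0})
        perturb = PerturbationSet.build({"P": 1}, pkn)
        ms = MeasurementSet.from_scores({"A": 0.01})
        cfg = cfg_factory(beta=0.5)
        prob = build_ilp(pkn, ms, gamma, perturb, cfg)
        j = prob.nodes.index("A")
        # node-penalty part of the coefficients (A also carries the mismatch
        # term -alpha*m = -0.01 on up and +0.01 on down)
        assert prob.c[prob.up(j)] == pytest.approx(0.5 * (1 - 1.0) - 0.01)
        assert prob.c[prob.down(j)] == pytest.approx(0.5 * (1 + 1.0) + 0.01)

    def test_standard_mode_requires_targets(self, chain_pkn, no_gamma, cfg_factory):
        ms = MeasurementSet.from_scores({"T": 1.0})
        with pytest.raises(InputError, match="inverse"):
            build_ilp(chain_pkn, ms, no_gamma, PerturbationSet(), cfg_factory())

    def test_unknown_effect_root_free_but_exempt(self, no_gamma, cfg_factory):
        # an unknown-effect target may take either sign to explain downstream
        pkn = SignedNetwork.from_edges([("P", "T", -1)])
        ms = MeasurementSet.from_scores({"T": 3.0})
        perturb = PerturbationSet.build({"P": UNKNOWN}, pkn)
        cfg = cfg_factory(beta=0.1)
        pool = solve_pool(build_ilp(pkn, ms, no_gamma, perturb, cfg), cfg)
        assert pool.solutions[0].states == {"P": -1, "T": 1}

    def test_measured_node_must_be_causally_reachable(self, no_gamma, cfg_factory):
        # T measured but disconnected from the root: its state stays 0
        pkn = SignedNetwork.from_edges([("P", "A", 1), ("B", "T", 1)])
        ms = MeasurementSet.from_scores({"T": 5.0})
        perturb = PerturbationSet.build({"P": 1}, pkn)
        cfg = cfg_factory(beta=0.1)
        pool = solve_pool(build_ilp(pkn, ms, no_gamma, perturb, cfg), cfg)
        assert pool.solutions[0].states["T"] == 0


class TestInverseMode:
    def test_diamond_root_inferred(self, diamond_pkn, no_gamma, cfg_factory):
        ms = MeasurementSet.from_scores({"T1": 1.5, "T2": 1.5})
        cfg = cfg_factory(mode="inverse")
        pool = solve_pool(build_inverse(diamond_pkn, ms, no_gamma, cfg), cfg)
        sol = pool.solutions[0]
        assert sol.inferred_perturbations == {"U": 1}
        assert sol.states["U"] == 1
        best, optima = exhaustive_inverse_optimum(diamond_pkn, ms, no_gamma, 0.1)
        assert pool.best_objective == pytest.approx(best)
        assert sol.states in optima

    def test_inferred_sign_minimizes_mismatch(self, no_gamma, cfg_factory):
        pkn = SignedNetwork.from_edges([("U", "T", -1)])
        ms = MeasurementSet.from_scores({"T": 2.0})
        cfg = cfg_factory(mode="inverse")
        pool = solve_pool(build_inverse(pkn, ms, no_gamma, cfg), cfg)
        sol = pool.solutions[0]
        # activating T through the inhibitory edge requires U = -1
        assert sol.states == {"U": -1, "T": 1}
        assert sol.inferred_perturbations == {"U": -1}

    def test_empty_measurements_give_empty_network(self, diamond_pkn, no_gamma, cfg_factory):
        cfg = cfg_factory(mode="inverse")
        pool = solve_pool(build_inverse(diamond_pkn, MeasurementSet(), no_gamma, cfg), cfg)
        assert pool.best_objective == pytest.approx(0.0)
        assert all(s == 0 for s in pool.solutions[0].states.values())

    def test_artificial_root_never_reported(self, diamond_pkn, no_gamma, cfg_factory):
        ms = MeasurementSet.from_scores({"T1": 1.0})
        cfg = cfg_factory(mode="inverse")
        pool = solve_pool(build_inverse(diamond_pkn, ms, no_gamma, cfg), cfg)
        for sol in pool.solutions:
            assert set(sol.states) == set(diamond_pkn.nodes)
            for e in sol.used_edges:
                assert e in set(diamond_pkn.edges)

    def test_cyclic_network_falls_back_to_all_nodes(self, no_gamma, cfg_factory):
        pkn = SignedNetwork.from_edges([("A", "B", 1), ("B", "A", 1)])
        ms = MeasurementSet.from_scores({"B": 1.0})
        cfg = cfg_factory(mode="inverse")
        pool = solve_pool(build_inverse(pkn, ms, no_gamma, cfg), cfg)
        assert pool.solutions[0].states["B"] == 1


class TestPoolSemantics:
    def test_unique_optimum_single_solution(self, chain_pkn, no_gamma, cfg_factory):
        ms = MeasurementSet.from_scores({"T": 2.0})
        perturb = PerturbationSet.build({"P": 1}, chain_pkn)
        cfg = cfg_factory()
        pool = solve_pool(build_ilp(chain_pkn, ms, no_gamma, perturb, cfg), cfg)
        assert len(pool) == 1

    def test_symmetric_co_optimal_paths_both_found(self, no_gamma, cfg_factory):
        # two disjoint equal-length activating paths P -> X|Y -> T
        pkn = SignedNetwork.from_edges(
            [("P", "X", 1), ("P", "Y", 1), ("X", "T", 1), ("Y", "T", 1)]
        )
        ms = MeasurementSet.from_scores({"T": 2.0})
        perturb = PerturbationSet.build({"P": 1}, pkn)
        cfg = cfg_factory()
        pool = solve_pool(build_ilp(pkn, ms, no_gamma, perturb, cfg), cfg)
        assert len(pool) >= 2
        objs = [s.objective_value for s in pool.solutions]
        assert max(objs) - min(objs) <= 1e-9
        best, optima = exhaustive_optimum(pkn, ms, no_gamma, perturb, 0.1)
        assert pool.best_objective == pytest.approx(best)
        # co-optimal state assignments confirmed by the enumeration oracle
        assert len(optima) >= 2

    def test_relgap_zero_pool_shares_optimum(self, diamond_pkn, no_gamma, cfg_factory):
        ms = MeasurementSet.from_scores({"T1": 1.0, "T2": 1.0})
        perturb = PerturbationSet.build({"U": 1}, diamond_pkn)
        cfg = cfg_factory(relgap=0.0)
        pool = solve_pool(build_ilp(diamond_pkn, ms, no_gamma, perturb, cfg), cfg)
        for sol in pool.solutions:
            assert sol.objective_value == pytest.approx(pool.best_objective)

    def test_solutions_distinct(self, no_gamma, cfg_factory):
        pkn = SignedNetwork.from_edges(
            [("P", "X", 1), ("P", "Y", 1), ("X", "T", 1), ("Y", "T", 1)]
        )
        ms = MeasurementSet.from_scores({"T": 2.0})
        perturb = PerturbationSet.build({"P": 1}, pkn)
        cfg = cfg_factory()
        pool = solve_pool(build_ilp(pkn, ms, no_gamma, perturb, cfg), cfg)
        seen = {(tuple(sorted(s.states.items())), tuple(sorted(s.used_edges)))
                for s in pool.solutions}
        assert len(seen) == len(pool.solutions)

    def test_capacity_thins_by_diversity_keeping_optimum(self, no_gamma):
        from causalnet.core import SolverConfig

        pkn = SignedNetwork.from_edges(
            [("P", "X", 1), ("P", "Y", 1), ("X", "T", 1), ("Y", "T", 1)]
        )
        ms = MeasurementSet.from_scores({"T": 2.0})
        perturb = PerturbationSet.build({"P": 1}, pkn)
        cfg = SolverConfig(beta=0.1, relgap=0.0, pool_populate=10, pool_capacity=2,
                           time_limit_s=60)
        pool = solve_pool(build_ilp(pkn, ms, no_gamma, perturb, cfg), cfg)
        assert len(pool) == 2
        assert pool.solutions[0].objective_value == pytest.approx(pool.best_objective)


class TestAggregation:
    def test_node_activity_mean_over_solutions(self, no_gamma, cfg_factory):
        pkn = SignedNetwork.from_edges(
            [("P", "X", 1), ("P", "Y", 1), ("X", "T", 1), ("Y", "T", 1)]
        )
        ms = MeasurementSet.from_scores({"T": 2.0})
        perturb = PerturbationSet.build({"P": 1}, pkn)
        cfg = cfg_factory()
        pool = solve_pool(build_ilp(pkn, ms, no_gamma, perturb, cfg), cfg)
        summary = aggregate_pool(pool)
        assert summary.node_activity["P"] == pytest.approx(1.0)
        assert summary.node_activity["T"] == pytest.approx(1.0)
        # X and Y split across the co-optimal paths
        assert 0.0 < summary.node_activity["X"] < 1.0
        for e, f in summary.edge_frequency.items():
            assert 0.0 < f <= 1.0

    def test_multi_beta_flat_average(self, chain_pkn, no_gamma, cfg_factory):
        ms = MeasurementSet.from_scores({"T": 2.0})
        perturb = PerturbationSet.build({"P": 1}, chain_pkn)
        pools = []
        for beta in (0.03, 0.1, 0.3, 0.5, 0.8):
            cfg = cfg_factory(beta=beta)
            pools.append(solve_pool(build_ilp(chain_pkn, ms, no_gamma, perturb, cfg), cfg))
        summary = aggregate_pool(pools)
        assert summary.n_solutions == sum(len(p) for p in pools)
        assert summary.node_activity["T"] == pytest.approx(1.0)


class TestInvariants:
    @pytest.mark.parametrize("beta", [0.0, 0.1, 1.0])
    def test_random_instances_match_exhaustive_oracle(self, beta, no_gamma, cfg_factory):
        rng = np.random.default_rng(20240 + int(beta * 10))
        for _ in range(25):
            pkn, ms, perturb, gamma = _random_instance(rng)
            cfg = cfg_factory(beta=beta, pool_populate=1, pool_capacity=1)
            pool = solve_pool(build_ilp(pkn, ms, gamma, perturb, cfg), cfg)
            best, _ = exhaustive_optimum(pkn, ms, gamma, perturb, beta)
            assert pool.best_objective == pytest.approx(best, abs=1e-9)
            for sol in pool.solutions:
                audit_solution(pkn, sol, measured=_measured(ms),
                               gamma=gamma, beta=beta)

    def test_beta_monotone_shrinks_network(self, no_gamma, cfg_factory):
        rng = np.random.default_rng(99)
        pkn, ms, perturb, _ = _random_instance(rng, n=9, ne=13)
        sizes = []
        for beta in (0.0, 0.05, 0.2, 0.5, 1.0, 2.0):
            cfg = cfg_factory(beta=beta, pool_populate=1, pool_capacity=1)
            pool = solve_pool(build_ilp(pkn, ms, no_gamma, perturb, cfg), cfg)
            sizes.append(sum(1 for s in pool.solutions[0].states.values() if s != 0))
        assert sizes == sorted(sizes, reverse=True)

    def test_beta_zero_matches_all_reachable_measurements(self, no_gamma, cfg_factory):
        # P -(+) A -(+) T1 and P -(-) B -(+) T2: both targets explainable
        pkn = SignedNetwork.from_edges(
            [("P", "A", 1), ("A", "T1", 1), ("P", "B", -1), ("B", "T2", 1)]
        )
        ms = MeasurementSet.from_scores({"T1": 1.0, "T2": -1.0})
        perturb = PerturbationSet.build({"P": 1}, pkn)
        cfg = cfg_factory(beta=0.0, pool_populate=1, pool_capacity=1)
        pool = solve_pool(build_ilp(pkn, ms, no_gamma, perturb, cfg), cfg)
        sol = pool.solutions[0]
        assert sol.objective_value == pytest.approx(0.0)
        assert sol.states["T1"] == 1 and sol.states["T2"] == -1
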