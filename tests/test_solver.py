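"""Branch-and-bound solver: selection/aggregation rules and exactness."""

import itertools

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from ehgm.core import (
    Assignment,
    DissimilarityTensor,
    MatchingProblem,
    brute_force_solve,
    enumerate_assignments,
    evaluate_objective,
)
from ehgm.solver import (
    aggregation_cost,
    build_queue,
    decompose_objective,
    ehgm_solve,
    general_branch_cost,
    initial_branch_cost,
)

from helpers import random_problem


def as_branches(points, k):
    return [tuple(points[b * k : (b + 1) * k]) for b in range(len(points) // k)]


class TestSelectionRules:
    def test_initial_cost_restricted_subproblem(self):
        """H of the first branch equals the objective of the instance
        restricted to the first-branch vertices."""
        rng = np.random.default_rng(2)
        p = random_problem(6, 7, 2, (1, 2), rng)
        sub_tensors = []
        for d, ts in p.tensors.items():
            for t in ts:
                scope = [vt for vt in t.scope if vt[-1] < 2]
                if not scope:
                    continue
                costs = {
                    (vt, pt): t.cost_of(vt, pt)
                    for vt in scope
                    for pt in itertools.permutations(range(p.n2), d)
                }
                sub_tensors.append(DissimilarityTensor(d, scope, costs))
        sub = MatchingProblem(2, p.n2, 2, sub_tensors)
        for K1 in itertools.permutations(range(p.n2), 2):
            assert initial_branch_cost(p, K1) == pytest.approx(
                evaluate_objective(sub, Assignment(K1)), rel=1e-12
            )

    def test_branch_costs_sum_to_objective_low_degree(self):
        """With no tensor above degree 2k, the per-branch selection
        costs alone account for the full objective."""
        rng = np.random.default_rng(3)
        p = random_problem(6, 8, 2, (1, 2, 4), rng)
        for a in itertools.islice(enumerate_assignments(p), 0, 2000, 131):
            branches = as_branches(a.points, 2)
            total = initial_branch_cost(p, branches[0])
            for b in range(1, 3):
                total += general_branch_cost(p, branches[:b], branches[b])
            assert total == pytest.approx(evaluate_objective(p, a), rel=1e-9)

    def test_aggregation_zero_without_high_degree_tensors(self):
        p = random_problem(6, 6, 2, (1, 2), np.random.default_rng(4))
        a = next(enumerate_assignments(p))
        branches = as_branches(a.points, 2)
        for b in range(1, 3):
            assert aggregation_cost(p, branches[:b], branches[b]) == 0.0

    def test_full_degree_tensor_aggregates_only_at_final_branch(self):
        n1 = 6
        full_vt = tuple(range(n1))
        lazy = DissimilarityTensor(n1, [full_vt], lambda vt, pt: 1.25, mode="lazy")
        unary = DissimilarityTensor(
            1, [(v,) for v in range(n1)],
            {((v,), (q,)): 0.0 for v in range(n1) for q in range(n1)},
        )
        p = MatchingProblem(n1, n1, 2, [unary, lazy])
        a = next(enumerate_assignments(p))
        branches = as_branches(a.points, 2)
        assert aggregation_cost(p, branches[:1], branches[1]) == 0.0
        assert aggregation_cost(p, branches[:2], branches[2]) == pytest.approx(1.25)

    def test_committed_point_reuse_rejected(self):
        p = random_problem(4, 5, 2, (1, 2), np.random.default_rng(5))
        with pytest.raises(ValueError, match="reuses a committed point"):
            general_branch_cost(p, [(0, 1)], (1, 2))


class TestDecomposition:
    def test_identity_across_degrees(self):
        """Sum of per-branch H + I equals the full objective for random
        problems spanning low and high hyperedge degrees."""
        rng = np.random.default_rng(6)
        for trial in range(10):
            p = random_problem(6, 6 + trial % 3, 2, (1, 2, 4, 6), rng)
            for a in itertools.islice(enumerate_assignments(p), 0, 500, 61):
                total = sum(h + i for h, i in decompose_objective(p, a))
                ref = evaluate_objective(p, a)
                assert total == pytest.approx(ref, rel=1e-9)

    def test_low_degree_models_have_zero_aggregation_terms(self):
        p = random_problem(6, 7, 2, (1, 2, 4), np.random.default_rng(7))
        a = next(enumerate_assignments(p))
        assert all(i == 0.0 for _, i in decompose_objective(p, a))

    def test_incomplete_assignment_errors(self):
        p = random_problem(4, 4, 2, (1,), np.random.default_rng(8))
        with pytest.raises(ValueError, match="complete"):
            decompose_objective(p, Assignment((0, 1)))


class TestBuildQueue:
    def test_order_matches_resorted_costs(self):
        rng = np.random.default_rng(9)
        p = random_problem(6, 7, 2, (1, 2), rng)
        committed = [(3, 5)]
        queue = build_queue(p, committed, b=1)
        recomputed = sorted(
            (general_branch_cost(p, committed, Km), Km)
            for _, Km in queue
        )
        assert [(pytest.approx(c), Km) for c, Km in recomputed] == [
            (pytest.approx(c), Km) for c, Km in queue
        ]
        costs = [c for c, _ in queue]
        assert costs == sorted(costs)

    def test_unseeded_queue_size(self):
        p = random_problem(4, 6, 2, (1, 2), np.random.default_rng(10))
        queue = build_queue(p, [(0, 1)], b=1)
        assert len(queue) == 4 * 3  # permutations of the 4 unused points

    def test_fully_seeded_branch_single_entry(self):
        p = random_problem(4, 6, 2, (1, 2), np.random.default_rng(11))
        queue = build_queue(p, [(0, 1)], b=1, seeds={2: 4, 3: 2})
        assert queue == [(queue[0][0], (4, 2))]

    def test_overconstrained_seeds_empty_queue(self):
        p = random_problem(4, 4, 2, (1, 2), np.random.default_rng(12))
        queue = build_queue(p, [(0, 1)], b=1, seeds={2: 0})
        assert queue == []


class TestExactness:
    @pytest.mark.parametrize("n2", [6, 7, 8])
    def test_pool_matches_brute_force(self, n2):
        rng = np.random.default_rng(100 + n2)
        for _ in range(3):
            p = random_problem(6, n2, 2, (1, 2, 4, 6), rng)
            oracle = brute_force_solve(p, x=3)
            pool, stats = ehgm_solve(p, x=3)
            assert stats.proved_optimal
            assert [a.points for a, _ in pool.entries] == [
                a.points for a, _ in oracle.entries
            ]
            for (_, c1), (_, c2) in zip(pool.entries, oracle.entries):
                assert c1 == pytest.approx(c2, rel=1e-9)

    def test_linear_assignment_reduction(self):
        """Degree-1-only instances reduce to the linear assignment
        problem; the solver must match an independent LAP routine."""
        rng = np.random.default_rng(200)
        n = 8
        cost = rng.uniform(0.0, 1.0, size=(n, n))
        scope = [(v,) for v in range(n)]
        table = {((v,), (q,)): float(cost[v, q]) for v in range(n) for q in range(n)}
        p = MatchingProblem(n, n, 2, [DissimilarityTensor(1, scope, table)])
        pool, _ = ehgm_solve(p, x=1)
        rows, cols = linear_sum_assignment(cost)
        assert pool.best()[1] == pytest.approx(float(cost[rows, cols].sum()), rel=1e-9)

    def test_fully_seeded_no_branching(self):
        rng = np.random.default_rng(13)
        p = random_problem(6, 7, 2, (1, 2, 4), rng)
        truth = next(enumerate_assignments(p))
        seeds = dict(enumerate(truth.points))
        pool, stats = ehgm_solve(p, seeds=seeds, x=3)
        assert len(pool) == 1
        a, c = pool.best()
        assert a.points == truth.points
        assert c == pytest.approx(evaluate_objective(p, truth), rel=1e-9)
        assert stats.nodes_expanded == p.n_branches  # one forced entry per branch

    def test_infeasible_seeds_error(self):
        p = random_problem(4, 4, 2, (1,), np.random.default_rng(14))
        with pytest.raises(ValueError, match="conflicting seeds"):
            ehgm_solve(p, seeds={0: 1, 1: 1})


class TestSearchBehaviour:
    def test_seeding_shrinks_search_and_preserves_exactness(self):
        rng = np.random.default_rng(15)
        for _ in range(5):
            p = random_problem(6, 8, 2, (1, 2, 4, 6), rng)
            pool, stats = ehgm_solve(p, x=3)
            best = pool.best()[0]
            seeds = {0: best.points[0], 1: best.points[1]}
            spool, sstats = ehgm_solve(p, seeds=seeds, x=3)
            oracle = brute_force_solve(p, seeds=seeds, x=3)
            assert [a.points for a, _ in spool.entries] == [
                a.points for a, _ in oracle.entries
            ]
            assert sstats.nodes_expanded < stats.nodes_expanded
            assert all(
                a.points[0] == seeds[0] and a.points[1] == seeds[1]
                for a, _ in spool.entries
            )

    def test_incumbent_bound_nonincreasing(self):
        rng = np.random.default_rng(16)
        p = random_problem(6, 8, 2, (1, 2, 4), rng)
        _, stats = ehgm_solve(p, x=3)
        trace = [b for b in stats.bound_trace if b != float("inf")]
        assert all(a >= b for a, b in zip(trace, trace[1:]))

    def test_time_limit_yields_unproven_pool(self):
        rng = np.random.default_rng(17)
        p = random_problem(8, 10, 2, (1, 2), rng)
        pool, stats = ehgm_solve(p, x=1, time_limit=0.0)
        assert not stats.proved_optimal

    def test_warm_start_assignment_enters_pool(self):
        rng = np.random.default_rng(18)
        p = random_problem(4, 4, 2, (1, 2), rng)
        warm = next(enumerate_assignments(p))
        pool, stats = ehgm_solve(p, x=1, warm_start=warm)
        oracle = brute_force_solve(p, x=1)
        assert pool.best()[1] == pytest.approx(oracle.best()[1], rel=1e-9)
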