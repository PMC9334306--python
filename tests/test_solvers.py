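"""Exact solvers: worked examples, brute-force oracle agreement, effort."""

import itertools
import math

import numpy as np
import pytest

from hardcog import _tsp
from hardcog.exceptions import UnsupportedSizeError
from hardcog.generators import GeneratorConfig, sample_kp, sample_sat3, sample_tsp
from hardcog.instances import KpInstance, Sat3Instance, TspInstance
from hardcog.solvers import solve, solve_kp, solve_sat3, solve_tsp, solver_effort


# ---------------------------------------------------------------------------
# independent brute-force oracles
# ---------------------------------------------------------------------------

def maxsat_oracle(inst: Sat3Instance) -> int:
    best = 0
    for bits in itertools.product((False, True), repeat=inst.num_vars):
        sat = 0
        for cl in inst.clauses:
            if any(bits[abs(l) - 1] == (l > 0) for l in cl):
                sat += 1
        best = max(best, sat)
    return best


def tsp_oracle(inst: TspInstance) -> float:
    d = inst.distance_matrix()
    n = inst.num_cities
    best = math.inf
    for perm in itertools.permutations(range(1, n)):
        tour = (0, *perm)
        length = sum(d[tour[i], tour[(i + 1) % n]] for i in range(n))
        best = min(best, length)
    return best


def kp_oracle(inst: KpInstance) -> int:
    best = 0
    n = inst.num_items
    for mask in range(1 << n):
        w = sum(inst.weights[i] for i in range(n) if mask >> i & 1)
        v = sum(inst.values[i] for i in range(n) if mask >> i & 1)
        if w <= inst.capacity:
            best = max(best, v)
    return best


# ---------------------------------------------------------------------------
# 3SAT
# ---------------------------------------------------------------------------

class TestSat3Solver:
    def test_empty_formula_vacuously_satisfiable(self):
        res = solve_sat3(Sat3Instance(5, ()))
        assert res.satisfiable
        assert res.optimum == 0
        assert res.effort == 1  # single root node

    def test_all_sign_patterns_over_three_variables(self):
        """The 8 clauses covering every sign pattern on {1,2,3} are jointly
        unsatisfiable; every assignment falsifies exactly one clause."""
        clauses = tuple(
            (s1 * 1, s2 * 2, s3 * 3)
            for s1 in (1, -1) for s2 in (1, -1) for s3 in (1, -1)
        )
        res = solve_sat3(Sat3Instance(3, clauses))
        assert not res.satisfiable
        assert res.optimum == 7
        assert res.witness is None

    def test_worked_three_clause_formula(self):
        # (!x3 | !x4 | x5) & (x2 | x3 | !x4) & (!x1 | x2 | !x3)
        inst = Sat3Instance(5, ((-3, -4, 5), (2, 3, -4), (-1, 2, -3)))
        res = solve_sat3(inst)
        assert res.optimum == maxsat_oracle(inst) == 3
        assert res.satisfiable

    def test_witness_satisfies_every_clause(self):
        rng = np.random.default_rng(0)
        cfg = GeneratorConfig(problem="sat3", size=5, alpha=4.8)
        found = 0
        while found < 30:
            inst = sample_sat3(cfg, rng)
            res = solve_sat3(inst)
            if not res.satisfiable:
                continue
            found += 1
            for cl in inst.clauses:
                assert any(bool(res.witness[abs(l) - 1]) == (l > 0) for l in cl)

    def test_optimum_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(1)
        for alpha in (2.0, 4.8, 7.0):
            cfg = GeneratorConfig(problem="sat3", size=5, alpha=alpha)
            for _ in range(70):
                inst = sample_sat3(cfg, rng)
                res = solve_sat3(inst)
                oracle = maxsat_oracle(inst)
                assert res.optimum == oracle
                assert res.satisfiable == (oracle == inst.num_clauses)


# ---------------------------------------------------------------------------
# TSP
# ---------------------------------------------------------------------------

class TestTspSolver:
    def test_three_cities_gives_triangle_perimeter(self):
        inst = TspInstance(((0.0, 0.0), (3.0, 0.0), (0.0, 4.0)), map_side=10.0, path_limit=12.0)
        res = solve_tsp(inst)
        assert res.optimum == pytest.approx(3 + 4 + 5)
        assert res.satisfiable
        assert sorted(res.witness) == [0, 1, 2]

    def test_unit_square_perimeter(self):
        inst = TspInstance(
            ((0.0, 0.0), (1.0, 0.0), (1.0, 1.0), (0.0, 1.0)), map_side=1.0, path_limit=3.9
        )
        res = solve_tsp(inst)
        assert res.optimum == pytest.approx(4.0)
        assert not res.satisfiable  # 4 > 3.9
        assert res.witness is None

    def test_optimum_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(2)
        cfg = GeneratorConfig(problem="tsp", size=8, alpha=-0.85)
        for _ in range(40):
            inst = sample_tsp(cfg, rng)
            res = solve_tsp(inst)
            assert res.optimum == pytest.approx(tsp_oracle(inst), rel=1e-9)

    def test_dp_and_branch_and_bound_agree(self):
        rng = np.random.default_rng(3)
        cfg = GeneratorConfig(problem="tsp", size=12, alpha=-0.85)
        for _ in range(20):
            d = sample_tsp(cfg, rng).distance_matrix()
            hk, _ = _tsp.held_karp(d)
            bb, _ = _tsp.bnb_tsp(d)
            assert hk == pytest.approx(bb, rel=1e-12)

    def test_witness_tour_length_within_limit(self):
        rng = np.random.default_rng(4)
        cfg = GeneratorConfig(problem="tsp", size=10, alpha=-0.99)
        inst = sample_tsp(cfg, rng)
        res = solve_tsp(inst)
        assert res.satisfiable
        d = inst.distance_matrix()
        tour = res.witness
        length = sum(d[tour[i], tour[(i + 1) % len(tour)]] for i in range(len(tour)))
        assert length <= inst.path_limit
        assert sorted(tour) == list(range(10))

    def test_optimum_invariant_under_relabeling_and_rigid_motion(self):
        rng = np.random.default_rng(5)
        cfg = GeneratorConfig(problem="tsp", size=9, alpha=-0.85)
        inst = sample_tsp(cfg, rng)
        base = solve_tsp(inst, compute_effort=False).optimum
        # relabel cities
        perm = rng.permutation(9)
        relabeled = TspInstance(
            tuple(inst.coords[i] for i in perm), inst.map_side, inst.path_limit
        )
        assert solve_tsp(relabeled, compute_effort=False).optimum == pytest.approx(base)
        # rotate 90 degrees about the map centre and translate within bounds
        c = 500.0
        rotated = TspInstance(
            tuple((c - (y - c), x) for x, y in inst.coords), inst.map_side, inst.path_limit
        )
        assert solve_tsp(rotated, compute_effort=False).optimum == pytest.approx(base)

    def test_oversize_instance_raises_instead_of_heuristic(self):
        coords = tuple((float(i), float(2 * i % 29)) for i in range(30))
        inst = TspInstance(coords, map_side=100.0, path_limit=500.0)
        with pytest.raises(UnsupportedSizeError):
            solve_tsp(inst)


# ---------------------------------------------------------------------------
# KP
# ---------------------------------------------------------------------------

class TestKpSolver:
    def test_every_item_too_heavy_is_unsatisfiable(self):
        inst = KpInstance((10, 12, 11), (5, 5, 5), capacity=9, target_profit=5)
        res = solve_kp(inst)
        assert res.optimum == 0
        assert not res.satisfiable

    def test_everything_fits_takes_everything(self):
        with pytest.warns(UserWarning):  # vacuous capacity
            inst = KpInstance((2, 3, 4), (7, 1, 9), capacity=100, target_profit=17)
        res = solve_kp(inst)
        assert res.optimum == 17
        assert res.satisfiable
        assert res.witness == (0, 1, 2)

    def test_optimum_matches_subset_enumeration(self):
        rng = np.random.default_rng(6)
        cfg = GeneratorConfig(problem="kp", size=6)
        for _ in range(200):
            inst = sample_kp(cfg, rng)
            res = solve_kp(inst)
            assert res.optimum == kp_oracle(inst)
            assert res.satisfiable == (res.optimum >= inst.target_profit)

    def test_witness_respects_both_constraints(self):
        rng = np.random.default_rng(7)
        cfg = GeneratorConfig(problem="kp", size=6, alpha_p_band=(0.35, 0.40))
        found = 0
        while found < 30:
            inst = sample_kp(cfg, rng)
            res = solve_kp(inst)
            if not res.satisfiable:
                continue
            found += 1
            w = sum(inst.weights[i] for i in res.witness)
            v = sum(inst.values[i] for i in res.witness)
            assert w <= inst.capacity and v >= inst.target_profit


# ---------------------------------------------------------------------------
# solver effort
# ---------------------------------------------------------------------------

class TestSolverEffort:
    def test_effort_deterministic_across_repeated_calls(self):
        rng = np.random.default_rng(8)
        insts = [
            sample_sat3(GeneratorConfig(problem="sat3", size=5, alpha=4.8), rng),
            sample_tsp(GeneratorConfig(problem="tsp", size=10, alpha=-0.85), rng),
            sample_kp(GeneratorConfig(problem="kp", size=6), rng),
        ]
        for inst in insts:
            efforts = {solver_effort(inst) for _ in range(5)}
            assert len(efforts) == 1

    def test_mean_effort_peaks_near_threshold_for_sat3(self):
        """Search effort at the satisfiability threshold exceeds the
        underconstrained region on average (the easy-hard pattern)."""
        rng = np.random.default_rng(9)
        means = {}
        for alpha in (2.0, 4.8):
            cfg = GeneratorConfig(problem="sat3", size=5, alpha=alpha)
            efforts = [solver_effort(sample_sat3(cfg, rng)) for _ in range(200)]
            means[alpha] = np.mean(efforts)
        assert means[4.8] > means[2.0]
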