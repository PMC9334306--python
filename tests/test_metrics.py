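"""Hardness metrics: witness counts, IC identities, TCC labels, curves."""

import itertools
import math

import numpy as np
import pytest

from hardcog.exceptions import ConsistencyError, RangeError, UnclassifiedAlphaError
from hardcog.generators import GeneratorConfig, sample_kp, sample_sat3, sample_tsp
from hardcog.instances import KpInstance, Sat3Instance, TspInstance
from hardcog.metrics import (
    RegionBand,
    RegionSpec,
    SatCurve,
    count_witnesses,
    estimate_threshold,
    instance_complexity,
    max_isotonic_residual,
    satisfiability_curve,
    tcc_label,
)
from hardcog.solvers import solve, solve_kp, solve_sat3


SAT3_REGIONS = RegionSpec(
    "sat3",
    {
        "underconstrained": RegionBand(2.0, 2.0),
        "threshold": RegionBand(4.8, 4.8),
        "overconstrained": RegionBand(7.0, 7.0),
    },
)


class TestCountWitnesses:
    def test_empty_formula_has_all_assignments(self):
        assert count_witnesses(Sat3Instance(5, ())) == (32, False)

    def test_unsatisfiable_instances_have_zero_witnesses(self):
        rng = np.random.default_rng(0)
        cfg = GeneratorConfig(problem="sat3", size=5, alpha=7.0)
        seen = 0
        while seen < 25:
            inst = sample_sat3(cfg, rng)
            res = solve_sat3(inst)
            if res.satisfiable:
                continue
            seen += 1
            assert count_witnesses(inst) == (0, False)

    def test_kp_two_unit_items(self):
        # weights (1,1), values (1,1), c=2, p=1: {1}, {2}, {1,2} qualify
        with pytest.warns(UserWarning):  # capacity is vacuous by design here
            inst = KpInstance((1, 1), (1, 1), capacity=2, target_profit=1)
        assert count_witnesses(inst) == (3, False)

    def test_sat3_count_matches_enumeration(self):
        rng = np.random.default_rng(1)
        cfg = GeneratorConfig(problem="sat3", size=5, alpha=4.8)
        for _ in range(100):
            inst = sample_sat3(cfg, rng)
            count, capped = count_witnesses(inst)
            brute = sum(
                all(any(bits[abs(l) - 1] == (l > 0) for l in cl) for cl in inst.clauses)
                for bits in itertools.product((False, True), repeat=5)
            )
            assert (count, capped) == (brute, False)

    def test_tsp_count_matches_directed_enumeration(self):
        """Directed tours from city 0, reversals distinct — counted against
        explicit permutation enumeration."""
        rng = np.random.default_rng(2)
        cfg = GeneratorConfig(problem="tsp", size=7, alpha=-0.9)
        for _ in range(40):
            inst = sample_tsp(cfg, rng)
            d = inst.distance_matrix()
            brute = 0
            for perm in itertools.permutations(range(1, 7)):
                tour = (0, *perm)
                length = sum(d[tour[i], tour[(i + 1) % 7]] for i in range(7))
                brute += length <= inst.path_limit
            assert count_witnesses(inst) == (brute, False)

    def test_tsp_cap_truncates(self):
        rng = np.random.default_rng(3)
        inst = sample_tsp(GeneratorConfig(problem="tsp", size=8, alpha=-1.4), rng)
        count, capped = count_witnesses(inst, cap=10)
        assert capped and count == 10


class TestInstanceComplexity:
    def test_satisfiable_sat3_has_zero_ic(self):
        rng = np.random.default_rng(4)
        cfg = GeneratorConfig(problem="sat3", size=5, alpha=4.8)
        seen = 0
        while seen < 25:
            inst = sample_sat3(cfg, rng)
            res = solve_sat3(inst)
            if res.satisfiable:
                seen += 1
                assert instance_complexity(inst, res) == 0.0

    def test_unsat_sat3_ic_is_falsified_fraction(self):
        clauses = tuple(
            (s1 * 1, s2 * 2, s3 * 3)
            for s1 in (1, -1) for s2 in (1, -1) for s3 in (1, -1)
        )
        inst = Sat3Instance(3, clauses)
        res = solve_sat3(inst)
        assert instance_complexity(inst, res) == pytest.approx((8 - 7) / 3)

    def test_tsp_ic_zero_when_limit_equals_optimum(self):
        coords = ((0.0, 0.0), (3.0, 0.0), (0.0, 4.0))
        inst = TspInstance(coords, map_side=10.0, path_limit=12.0)
        res = solve(inst)
        assert res.optimum == pytest.approx(12.0)
        assert instance_complexity(inst, res) == pytest.approx(0.0)

    def test_tsp_ic_normalisation(self):
        coords = ((0.0, 0.0), (3.0, 0.0), (0.0, 4.0))
        inst = TspInstance(coords, map_side=10.0, path_limit=18.0)
        res = solve(inst)
        assert instance_complexity(inst, res) == pytest.approx(6.0 / (10.0 * math.sqrt(3)))

    def test_kp_hand_computed_value(self):
        inst = KpInstance((5, 5), (10, 10), capacity=5, target_profit=15)
        res = solve_kp(inst)
        assert res.optimum == 10
        assert instance_complexity(inst, res) == pytest.approx(0.25)

    def test_mismatched_result_rejected(self):
        rng = np.random.default_rng(5)
        cfg = GeneratorConfig(problem="sat3", size=5, alpha=2.0)
        a, b = sample_sat3(cfg, rng), sample_sat3(cfg, rng)
        with pytest.raises(ConsistencyError):
            instance_complexity(a, solve_sat3(b))

    def test_ic_invariant_under_item_relabeling(self):
        rng = np.random.default_rng(6)
        inst = sample_kp(GeneratorConfig(problem="kp", size=6), rng)
        perm = rng.permutation(6)
        relabeled = KpInstance(
            tuple(inst.weights[i] for i in perm),
            tuple(inst.values[i] for i in perm),
            inst.capacity,
            inst.target_profit,
        )
        assert instance_complexity(inst, solve_kp(inst)) == pytest.approx(
            instance_complexity(relabeled, solve_kp(relabeled))
        )

    def test_witness_count_tracks_ic_among_satisfiable(self):
        """Among satisfiable instances at a fixed alpha band, both
        solution-space metrics measure slack from the decision boundary:
        a higher witness count goes with an optimum further past the
        target, i.e. a larger IC (hardness decreases in both), so their
        rank correlation is positive."""
        from scipy.stats import spearmanr

        rng = np.random.default_rng(7)
        cfg = GeneratorConfig(problem="kp", size=6)
        ics, wits = [], []
        while len(ics) < 200:
            inst = sample_kp(cfg, rng)
            res = solve_kp(inst)
            if not res.satisfiable:
                continue
            ics.append(instance_complexity(inst, res))
            wits.append(count_witnesses(inst)[0])
        rho = spearmanr(wits, ics).statistic
        assert rho > 0


class TestTccLabel:
    @pytest.mark.parametrize(
        "alpha, region, tcc",
        [
            (2.0, "underconstrained", "low"),
            (4.8, "threshold", "high"),
            (7.0, "overconstrained", "low"),
        ],
    )
    def test_study_alpha_mapping(self, alpha, region, tcc):
        assert tcc_label(alpha, SAT3_REGIONS) == (region, tcc)

    def test_unclassified_alpha_raises(self):
        with pytest.raises(UnclassifiedAlphaError):
            tcc_label(3.7, SAT3_REGIONS)


class TestSatisfiabilityCurve:
    def test_extreme_regions_saturate(self):
        rng = np.random.default_rng(8)
        curve = satisfiability_curve("sat3", 5, [2.0, 7.0], 500, rng)
        assert curve.fractions[0] > 0.9
        assert curve.fractions[1] < 0.1

    def test_exact_half_point_is_selected(self):
        curve = SatCurve("sat3", 5, [4.7, 4.8, 4.9], [0.60, 0.50, 0.41], 1000)
        assert estimate_threshold(curve).alpha_s == 4.8

    def test_tie_breaks_toward_less_constrained(self):
        curve = SatCurve("sat3", 5, [4.7, 4.8], [0.55, 0.45], 1000)
        assert estimate_threshold(curve).alpha_s == 4.7

    def test_curve_not_bracketing_half_raises(self):
        curve = SatCurve("sat3", 5, [1.0, 2.0], [0.99, 0.93], 100)
        with pytest.raises(RangeError):
            estimate_threshold(curve)

    def test_grid_must_be_increasing(self):
        with pytest.raises(ValueError):
            SatCurve("sat3", 5, [2.0, 1.0], [0.5, 0.6], 10)

    def test_isotonic_residual_flags_gross_nonmonotonicity(self):
        good = SatCurve("sat3", 5, [1.0, 2.0, 3.0], [0.9, 0.5, 0.1], 1000)
        bad = SatCurve("sat3", 5, [1.0, 2.0, 3.0], [0.2, 0.9, 0.1], 1000)
        assert max_isotonic_residual(good) == 0.0
        assert max_isotonic_residual(bad) > 3.0
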