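import numpy as np
import pytest

from snpeval import (
    StandardsConfig,
    ValidationError,
    build_problem,
    brute_force_oracle,
    cost_gap,
    solve,
    solve_budget_capped,
)
from snpeval.lp import LPProblem, LPResult
from conftest import random_floor_problem


def _toy_2x2(prices=(0.01, 0.02)):
    """Two foods, two floor constraints crossing at a hand-solved vertex.

    1.0*a + 0.2*b >= 100 and 0.2*a + 1.0*b >= 100 meet at a = b = 250/3;
    the price vector lies in the cone of the constraint normals, so that
    vertex is optimal: cost = 250/3 * (p1 + p2).
    """
    return LPProblem(
        food_ids=["A", "B"],
        densities=np.zeros((2, 10)),
        prices_per_g=np.array(prices),
        constraint_names=["n1", "n2"],
        A=np.array([[1.0, 0.2], [0.2, 1.0]]),
        lb=np.array([100.0, 100.0]),
        ub=np.array([np.inf, np.inf]),
        portion_caps=np.array([1000.0, 1000.0]),
        total_grams_cap=None,
    )


class TestSolve:
    def test_hand_solved_vertex(self):
        res = solve(_toy_2x2())
        assert res.status == "optimal"
        assert res.grams["A"] == pytest.approx(250 / 3, abs=1e-6)
        assert res.grams["B"] == pytest.approx(250 / 3, abs=1e-6)
        assert res.total_cost == pytest.approx(250 / 3 * 0.03, abs=1e-6)
        assert set(res.binding) >= {"n1", "n2"}

    def test_price_scaling_homogeneity(self):
        base = solve(_toy_2x2())
        scaled = solve(_toy_2x2(prices=(0.03, 0.06)))
        assert scaled.total_cost == pytest.approx(3 * base.total_cost, rel=1e-6)
        for f in ("A", "B"):
            assert scaled.grams[f] == pytest.approx(base.grams[f], abs=1e-5)

    def test_zero_caps_infeasible(self):
        p = _toy_2x2()
        p.portion_caps = np.zeros(2)
        assert solve(p).status == "infeasible"

    def test_constraints_satisfied_on_random_problems(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            p = random_floor_problem(rng, int(rng.integers(2, 6)))
            res = solve(p)
            assert res.status == "optimal"
            x = np.array([res.grams[f] for f in p.food_ids])
            vals = p.A @ x
            assert np.all(vals >= p.lb - 1e-6 * np.maximum(1.0, np.abs(p.lb)))

    def test_relaxing_lower_bound_never_raises_cost(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = random_floor_problem(rng, 3)
            c0 = solve(p).total_cost
            k = int(rng.integers(0, len(p.lb)))
            p.lb = p.lb.copy()
            p.lb[k] *= 0.5
            assert solve(p).total_cost <= c0 + 1e-8

    def test_duplicated_food_same_cost(self, small_table, snp2012):
        prices = {"rice": 35.0, "lentil": 110.0, "oil": 130.0}
        p1 = build_problem(small_table, prices, snp2012, total_grams_cap=None)
        p2 = build_problem(small_table + [small_table[0]], prices, snp2012, total_grams_cap=None)
        r1, r2 = solve(p1), solve(p2)
        assert r1.status == r2.status
        if r1.status == "optimal":
            assert r2.total_cost == pytest.approx(r1.total_cost, rel=1e-6)


class TestOracle:
    def test_matches_lp_within_grid_bound(self):
        rng = np.random.default_rng(7)
        step = 10.0
        n_feasible = 0
        for _ in range(50):
            p = random_floor_problem(rng, int(rng.integers(2, 4)))
            lp_res = solve(p)
            oracle = brute_force_oracle(p, grid_step_g=step)
            assert lp_res.status == oracle.status == "optimal"
            n_feasible += 1
            bound = float(np.sum(p.prices_per_g) * step)
            assert oracle.total_cost >= lp_res.total_cost - 1e-9
            assert oracle.total_cost - lp_res.total_cost <= bound + 1e-9
        assert n_feasible == 50

    def test_refinement_converges(self):
        rng = np.random.default_rng(11)
        p = random_floor_problem(rng, 2)
        lp_cost = solve(p).total_cost
        gaps = [
            brute_force_oracle(p, grid_step_g=s).total_cost - lp_cost
            for s in (40.0, 20.0, 10.0, 5.0)
        ]
        assert all(g >= -1e-9 for g in gaps)
        assert gaps[-1] <= gaps[0] + 1e-9
        assert gaps[-1] <= float(np.sum(p.prices_per_g)) * 5.0 + 1e-9

    def test_vertex_on_grid_exact_agreement(self):
        p = _toy_2x2()
        p.A = np.array([[1.0, 0.0], [0.0, 1.0]])  # vertex at (100, 100)
        oracle = brute_force_oracle(p, grid_step_g=50.0)
        lp_res = solve(p)
        assert oracle.total_cost == pytest.approx(lp_res.total_cost, abs=1e-9)

    def test_infeasible_agreement(self):
        p = _toy_2x2()
        p.portion_caps = np.zeros(2)
        assert brute_force_oracle(p, grid_step_g=10.0).status == "infeasible"

    def test_too_many_foods_refused(self):
        rng = np.random.default_rng(0)
        p = random_floor_problem(rng, 5)
        with pytest.raises(ValidationError, match="4 foods"):
            brute_force_oracle(p, grid_step_g=50.0)


class TestBuildProblem:
    def test_fixture_state_dimensions(self, dataset, snp2023):
        foods = [f for f in dataset.foods if f.food_id in
                 ("rice", "lentil", "sunflower_oil", "egg", "milk", "spinach")]
        p = build_problem(foods, dataset.prices, snp2023, forts=dataset.forts)
        assert p.n_foods == 6
        # energy band + protein floor + fat band + 7 micronutrient floors
        assert len(p.constraint_names) == 10

    def test_additions_mode_zero_feasible_when_base_adequate(self, dataset, snp2012):
        basket = [f for f in dataset.foods if f.food_id in
                  ("rice", "lentil", "sunflower_oil", "milk", "milk_powder", "egg",
                   "spinach", "amaranth_leaves", "carrot", "banana", "sesame", "chickpea")]
        full = solve(build_problem(basket, dataset.prices, snp2012,
                                   total_grams_cap=600.0, portion_caps=200.0))
        assert full.status == "optimal"
        add = build_problem(
            basket, dataset.prices, snp2012, mode="additions",
            base_menu={f: g for f, g in full.grams.items()},
            total_grams_cap=600.0, portion_caps=200.0,
        )
        res = solve(add)
        assert res.status == "optimal"
        assert res.total_cost == pytest.approx(0.0, abs=1e-7)

    def test_unpriced_food_rejected(self, small_table, snp2012):
        with pytest.raises(ValidationError, match="price"):
            build_problem(small_table, {"rice": 35.0}, snp2012)

    def test_empty_food_list_rejected(self, snp2012):
        with pytest.raises(ValidationError, match="empty"):
            build_problem([], {}, snp2012)

    def test_single_food_degenerate(self, snp2012):
        from snpeval import FoodRecord

        superfood = FoodRecord(
            food_id="sf", name="Complete food", group="condiments_other",
            moisture_pct=5.0,
            nutrients={
                "energy_kcal": 400.0, "protein_g": 15.0, "fat_g": 13.5,
                "calcium_mg": 400.0, "iron_mg": 8.0, "zinc_mg": 4.0,
                "folate_ug": 100.0, "vitamin_a_ug": 280.0, "vitamin_b6_mg": 0.8,
                "vitamin_b12_ug": 1.0,
            },
        )
        p = build_problem([superfood], {"sf": 100.0}, snp2012, portion_caps=200.0)
        assert p.n_foods == 1
        assert solve(p).status == "optimal"


class TestCostGap:
    def test_clamp_arithmetic(self):
        res = LPResult(status="optimal", total_cost=16.0)
        assert cost_gap(res, 8.0) == pytest.approx(8.0)
        res.total_cost = 20.0
        assert cost_gap(res, 8.0) == pytest.approx(12.0)

    def test_within_allocation_clamps_to_zero(self):
        assert cost_gap(LPResult(status="optimal", total_cost=6.5), 8.0) == 0.0

    def test_non_optimal_rejected(self):
        with pytest.raises(ValidationError):
            cost_gap(LPResult(status="infeasible"), 8.0)


class TestBudgetCapped:
    def test_shortfall_zero_when_budget_sufficient(self):
        p = _toy_2x2()
        p.allocation = 100.0
        res = solve_budget_capped(p)
        assert res.status == "optimal"
        assert res.total_cost <= 100.0 + 1e-9
        # budget is ample, so the full-cost optimum is affordable
        assert res.total_cost == pytest.approx(solve(p).total_cost, abs=1e-5)

    def test_respects_tight_budget(self):
        p = _toy_2x2()
        res = solve_budget_capped(p, budget=1.0)
        assert res.status == "optimal"
        assert res.total_cost <= 1.0 + 1e-9
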