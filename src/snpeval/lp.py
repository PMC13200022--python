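"""Linear-programming menu optimisation (the diet problem for SNP menus).

Finds the minimum-cost combination of state-listed foods meeting the
nutrient standards,

    min  sum_f p_f x_f
    s.t. L_k <= sum_f n_{f,k} (x_f + b_f) <= U_k     for each nutrient k
         0 <= x_f <= cap_f,   sum_f (x_f + b_f) <= V

with x_f raw grams of food f per child per day, p_f the mean vendor price
per gram, n_{f,k} the (fortification-applied) nutrient density per gram,
b_f an optional fixed base menu (additions mode), cap_f per-food portion
caps and V a total meal-volume cap reflecting young children's limited
gastric capacity. Energy is constrained as a band around the target to
avoid excess energy; micronutrients are floor-only. The per-child daily
allocation (₹8 by default) is not a hard constraint: the optimal cost is
compared with it afterwards and reported as a budget gap, and a
goal-programming mode (minimise weighted shortfall subject to cost <= B)
is available for budget-capped planning.

The solver is HiGHS via scipy.optimize.linprog; every reported optimum is
re-checked against the constraints independently of the solver's own
status. A brute-force grid-search oracle over small problems validates the
LP path in tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linprog

from .io import (
    KCAL_PER_G_FAT,
    NUTRIENT_KEYS,
    FoodRecord,
    FortificationSpec,
    PriceQuote,
    StandardsConfig,
    ValidationError,
)
from .engine import fortified_table

#: Default cap on total raw grams per child per day (meal-volume proxy).
DEFAULT_TOTAL_GRAMS_CAP = 350.0
#: Default per-food portion cap, grams per child per day.
DEFAULT_PORTION_CAP = 150.0
#: Default per-child daily allocation, rupees.
DEFAULT_ALLOCATION = 8.0

_FEAS_TOL = 1e-6


@dataclass
class LPProblem:
    """A fully numeric diet LP: densities, prices, bounds, caps, base menu."""

    food_ids: list[str]
    densities: np.ndarray  # (F, K) nutrient per gram
    prices_per_g: np.ndarray  # (F,)
    constraint_names: list[str]
    A: np.ndarray  # (R, F) constraint rows acting on grams
    lb: np.ndarray  # (R,) -inf where absent
    ub: np.ndarray  # (R,) +inf where absent
    portion_caps: np.ndarray  # (F,)
    total_grams_cap: float | None = DEFAULT_TOTAL_GRAMS_CAP
    base_grams: np.ndarray | None = None
    allocation: float = DEFAULT_ALLOCATION
    nutrient_keys: tuple[str, ...] = NUTRIENT_KEYS

    @property
    def n_foods(self) -> int:
        return len(self.food_ids)

    def base(self) -> np.ndarray:
        return self.base_grams if self.base_grams is not None else np.zeros(self.n_foods)


@dataclass
class LPResult:
    """Solved menu: status, grams per food, cost, budget gap, diagnostics."""

    status: str  # optimal | infeasible | unbounded | failed
    grams: dict[str, float] = field(default_factory=dict)
    total_cost: float = float("nan")
    cost_gap: float = float("nan")
    achieved: dict[str, float] = field(default_factory=dict)
    binding: list[str] = field(default_factory=list)


def _prices_per_g(prices, food_ids: Sequence[str]) -> np.ndarray:
    """Resolve prices (₹/kg quotes or mapping) to a ₹-per-gram vector."""
    if isinstance(prices, Mapping):
        per_kg = dict(prices)
    else:
        per_kg = {q.food_id: q.mean_price for q in prices}
    missing = [f for f in food_ids if f not in per_kg]
    if missing:
        raise ValidationError("/prices", f"foods without a price: {missing}")
    return np.array([per_kg[f] / 1000.0 for f in food_ids], dtype=float)


def build_problem(
    foods: Sequence[FoodRecord],
    prices: Sequence[PriceQuote] | Mapping[str, float],
    standards_cfg: StandardsConfig,
    portion_caps: Mapping[str, float] | float | None = None,
    base_menu: Mapping[str, float] | None = None,
    mode: str = "full",
    forts: Sequence[FortificationSpec] = (),
    use_digestible_protein: bool = True,
    total_grams_cap: float | None = DEFAULT_TOTAL_GRAMS_CAP,
    allocation: float = DEFAULT_ALLOCATION,
    use_tolerance: bool = True,
) -> LPProblem:
    """Assemble the diet LP from foods, prices and a standards config.

    ``mode='additions'`` treats ``base_menu`` (food_id -> grams/day) as a
    fixed contribution and optimises increments on top of it; ``'full'``
    designs the menu from scratch. Nutrient bounds come from the standards
    via the adequacy rules: energy gets a (1±tolerance) band around the
    target, protein a floor (digestibility-weighted when selected), fat
    its band widened by the tolerance, micronutrients a floor at
    meal_fraction × EAR × (1−tolerance). ``use_tolerance=False`` uses the
    unrelaxed requirements (energy band [1, 1+tol]×target).
    """
    if mode not in ("full", "additions"):
        raise ValidationError("/lp/mode", f"unknown mode {mode!r}")
    if len(foods) == 0:
        raise ValidationError("/lp/foods", "empty food list")
    by_id = fortified_table(foods, forts, mode=standards_cfg.fortification_mode)
    food_ids = list(by_id)
    dens = np.array(
        [[by_id[f].nutrients[k] / 100.0 for k in NUTRIENT_KEYS] for f in food_ids]
    )
    prices_g = _prices_per_g(prices, food_ids)

    cfg = standards_cfg
    tol = cfg.tolerance if use_tolerance else 0.0
    ki = {k: j for j, k in enumerate(NUTRIENT_KEYS)}
    names: list[str] = []
    rows: list[np.ndarray] = []
    lbs: list[float] = []
    ubs: list[float] = []

    def add(name: str, coeffs: np.ndarray, lo: float, hi: float) -> None:
        names.append(name)
        rows.append(coeffs)
        lbs.append(lo)
        ubs.append(hi)

    e_row = dens[:, ki["energy_kcal"]]
    add(
        "energy_band",
        e_row,
        (1.0 - tol) * cfg.energy_target_kcal,
        (1.0 + cfg.tolerance) * cfg.energy_target_kcal,
    )
    p_row = dens[:, ki["protein_g"]]
    if use_digestible_protein:
        add("protein_floor_digestible", p_row * cfg.digestibility_factor,
            (1.0 - tol) * cfg.protein_min_g, np.inf)
    else:
        add("protein_floor", p_row, (1.0 - tol) * cfg.protein_min_g, np.inf)
    f_row = dens[:, ki["fat_g"]]
    hi_factor = (1.0 + cfg.tolerance) if cfg.fat_allowance_two_sided else 1.0
    if cfg.fat_rule.kind == "ratio_band":
        # r_lo <= 100*9*fat/energy <= r_hi, linearised as 9*fat - (r/100)*energy rows
        add("fat_ratio_lower", KCAL_PER_G_FAT * f_row - (cfg.fat_rule.lower * (1.0 - tol) / 100.0) * e_row,
            0.0, np.inf)
        add("fat_ratio_upper", KCAL_PER_G_FAT * f_row - (cfg.fat_rule.upper * hi_factor / 100.0) * e_row,
            -np.inf, 0.0)
    else:
        add("fat_band", f_row, (1.0 - tol) * cfg.fat_rule.lower, hi_factor * cfg.fat_rule.upper)
    for k in NUTRIENT_KEYS:
        if k in cfg.ear_per_day:
            add(f"{k}_floor", dens[:, ki[k]],
                (1.0 - tol) * cfg.meal_fraction * cfg.ear_per_day[k], np.inf)

    if portion_caps is None:
        caps = np.full(len(food_ids), DEFAULT_PORTION_CAP)
    elif isinstance(portion_caps, Mapping):
        caps = np.array([float(portion_caps.get(f, DEFAULT_PORTION_CAP)) for f in food_ids])
    else:
        caps = np.full(len(food_ids), float(portion_caps))
    if np.any(caps < 0):
        raise ValidationError("/lp/portion_caps", "caps must be >= 0")

    base = None
    if mode == "additions":
        base_menu = base_menu or {}
        unknown = sorted(set(base_menu) - set(food_ids))
        if unknown:
            raise ValidationError("/lp/base_menu", f"base foods not in the food list: {unknown}")
        base = np.array([float(base_menu.get(f, 0.0)) for f in food_ids])
    elif base_menu:
        raise ValidationError("/lp/base_menu", "base_menu only allowed in additions mode")

    return LPProblem(
        food_ids=food_ids,
        densities=dens,
        prices_per_g=prices_g,
        constraint_names=names,
        A=np.vstack(rows),
        lb=np.array(lbs),
        ub=np.array(ubs),
        portion_caps=caps,
        total_grams_cap=total_grams_cap,
        base_grams=base,
        allocation=allocation,
    )


def _violations(problem: LPProblem, x: np.ndarray, tol: float = _FEAS_TOL) -> list[str]:
    """Constraint violations of a candidate grams vector, solver-independent."""
    out = []
    g = x + problem.base()
    vals = problem.A @ g
    for name, v, lo, hi in zip(problem.constraint_names, vals, problem.lb, problem.ub):
        scale = max(1.0, abs(lo) if np.isfinite(lo) else 0.0, abs(hi) if np.isfinite(hi) else 0.0)
        if v < lo - tol * scale:
            out.append(f"{name}: {v:.6g} < lower {lo:.6g}")
        if v > hi + tol * scale:
            out.append(f"{name}: {v:.6g} > upper {hi:.6g}")
    if np.any(x < -tol) or np.any(x > problem.portion_caps + tol):
        out.append("portion caps violated")
    if problem.total_grams_cap is not None and g.sum() > problem.total_grams_cap + tol * max(
        1.0, problem.total_grams_cap
    ):
        out.append(f"total grams {g.sum():.6g} > cap {problem.total_grams_cap:.6g}")
    return out


def _result_from_x(problem: LPProblem, x: np.ndarray) -> LPResult:
    g = x + problem.base()
    vals = problem.A @ g
    achieved = {
        k: float(v)
        for k, v in zip(problem.nutrient_keys, problem.densities.T @ g)
    }
    binding = []
    for name, v, lo, hi in zip(problem.constraint_names, vals, problem.lb, problem.ub):
        scale = max(1.0, abs(v))
        if (np.isfinite(lo) and abs(v - lo) <= 1e-6 * scale) or (
            np.isfinite(hi) and abs(v - hi) <= 1e-6 * scale
        ):
            binding.append(name)
    for f, xi, cap in zip(problem.food_ids, x, problem.portion_caps):
        if cap > 0 and abs(xi - cap) <= 1e-6 * max(1.0, cap):
            binding.append(f"portion_cap:{f}")
    if problem.total_grams_cap is not None and abs(g.sum() - problem.total_grams_cap) <= 1e-6 * max(
        1.0, problem.total_grams_cap
    ):
        binding.append("total_grams_cap")
    cost = float(problem.prices_per_g @ x)
    return LPResult(
        status="optimal",
        grams={f: float(xi) for f, xi in zip(problem.food_ids, x)},
        total_cost=cost,
        cost_gap=max(0.0, cost - problem.allocation),
        achieved=achieved,
        binding=binding,
    )


def solve(problem: LPProblem) -> LPResult:
    """Minimise menu cost subject to the problem's nutrient and volume bounds.

    Deterministic given the problem. A reported optimum is re-checked
    against all constraints within 1e-6 before being returned; solver
    failure yields an explicit non-optimal status, never a partial answer.
    """
    base = problem.base()
    A_ub_rows, b_ub = [], []
    for row, lo, hi in zip(problem.A, problem.lb, problem.ub):
        shift = float(row @ base)
        if np.isfinite(lo):
            A_ub_rows.append(-row)
            b_ub.append(-(lo - shift))
        if np.isfinite(hi):
            A_ub_rows.append(row)
            b_ub.append(hi - shift)
    if problem.total_grams_cap is not None:
        A_ub_rows.append(np.ones(problem.n_foods))
        b_ub.append(problem.total_grams_cap - float(base.sum()))
    res = linprog(
        c=problem.prices_per_g,
        A_ub=np.vstack(A_ub_rows) if A_ub_rows else None,
        b_ub=np.array(b_ub) if b_ub else None,
        bounds=list(zip(np.zeros(problem.n_foods), problem.portion_caps)),
        method="highs",
    )
    if res.status == 2:
        return LPResult(status="infeasible")
    if res.status == 3:
        return LPResult(status="unbounded")
    if res.status != 0:
        return LPResult(status="failed")
    x = np.asarray(res.x, dtype=float)
    bad = _violations(problem, x)
    if bad:
        raise RuntimeError(f"solver returned an infeasible optimum: {bad}")
    return _result_from_x(problem, np.clip(x, 0.0, problem.portion_caps))


def brute_force_oracle(problem: LPProblem, grid_step_g: float) -> LPResult:
    """Exhaustive grid search over gram multiples of ``grid_step_g``.

    Validation oracle for small problems: at most 4 foods with finite
    caps. Returns the cheapest feasible grid point (its cost is an upper
    bound on the LP optimum, converging as the grid refines).
    """
    if problem.n_foods > 4:
        raise ValidationError("/lp/oracle", "oracle limited to <= 4 foods")
    if grid_step_g <= 0:
        raise ValidationError("/lp/oracle", "grid_step_g must be positive")
    if not np.all(np.isfinite(problem.portion_caps)):
        raise ValidationError("/lp/oracle", "oracle requires finite portion caps")
    axes = [
        np.arange(0.0, cap + grid_step_g / 2.0, grid_step_g) for cap in problem.portion_caps
    ]
    n_points = int(np.prod([len(a) for a in axes]))
    if n_points > 5_000_000:
        raise ValidationError("/lp/oracle", f"grid too large ({n_points} points)")
    best_cost, best_x = np.inf, None
    for combo in itertools.product(*axes):
        x = np.array(combo)
        if not _violations(problem, x):
            cost = float(problem.prices_per_g @ x)
            if cost < best_cost - 1e-12:
                best_cost, best_x = cost, x
    if best_x is None:
        return LPResult(status="infeasible")
    return _result_from_x(problem, best_x)


def cost_gap(result: LPResult, allocation_B: float = DEFAULT_ALLOCATION) -> float:
    """Extra rupees per child per day beyond the allocation: max(0, cost − B)."""
    if result.status != "optimal":
        raise ValidationError("/lp/result", f"cost gap undefined for status {result.status!r}")
    return max(0.0, result.total_cost - allocation_B)


def solve_budget_capped(problem: LPProblem, budget: float | None = None) -> LPResult:
    """Goal-programming mode: minimise total relative nutrient shortfall
    subject to cost <= budget.

    For each floor/band lower bound L_r a slack s_r >= 0 absorbs the
    shortfall ((A x)_r >= L_r − s_r·L_r-scale) and the objective is the sum
    of relative slacks; upper bounds stay hard. Identifies the 'best
    feasible' menu when fully meeting the standards is unaffordable.
    """
    B = problem.allocation if budget is None else budget
    base = problem.base()
    F = problem.n_foods
    lo_rows = [
        (i, row, lo)
        for i, (row, lo) in enumerate(zip(problem.A, problem.lb))
        if np.isfinite(lo)
    ]
    S = len(lo_rows)
    # tiny cost weight: among equally adequate menus, return the cheapest
    c = np.concatenate([1e-6 * problem.prices_per_g, np.ones(S)])
    A_ub_rows, b_ub = [], []
    for j, (_, row, lo) in enumerate(lo_rows):
        slack_scale = abs(lo) if lo != 0 else 1.0
        r = np.zeros(F + S)
        r[:F] = -row
        r[F + j] = -slack_scale
        A_ub_rows.append(r)
        b_ub.append(-(lo - float(row @ base)))
    for row, hi in zip(problem.A, problem.ub):
        if np.isfinite(hi):
            r = np.zeros(F + S)
            r[:F] = row
            A_ub_rows.append(r)
            b_ub.append(hi - float(row @ base))
    if problem.total_grams_cap is not None:
        r = np.zeros(F + S)
        r[:F] = 1.0
        A_ub_rows.append(r)
        b_ub.append(problem.total_grams_cap - float(base.sum()))
    r = np.zeros(F + S)
    r[:F] = problem.prices_per_g
    A_ub_rows.append(r)
    b_ub.append(B)
    bounds = [(0.0, cap) for cap in problem.portion_caps] + [(0.0, 1.0)] * S
    res = linprog(c=c, A_ub=np.vstack(A_ub_rows), b_ub=np.array(b_ub), bounds=bounds, method="highs")
    if res.status != 0:
        return LPResult(status={2: "infeasible", 3: "unbounded"}.get(res.status, "failed"))
    x = np.clip(np.asarray(res.x[:F]), 0.0, problem.portion_caps)
    out = _result_from_x(problem, x)
    out.cost_gap = max(0.0, out.total_cost - B)
    return out
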