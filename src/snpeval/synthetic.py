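"""Synthetic food tables, menu cycles, prices and test states.

Everything here is generated, labelled synthetic data of realistic
magnitude — plausibility ranges per food group stand in for copyrighted
food-composition tables. The generator emulates the structure of Indian
anganwadi meal programmes: cereal-dominant multi-day menu cycles (6-15
days), a morning snack plus hot cooked meal, pulses and oil daily, milk /
egg / vegetables intermittently, vendor price quotes per food, and
fortified staples (iron/folic-acid/B12 rice, vitamin-A oil) in a
configurable fraction of states.

Profiles:

* ``cereal_heavy`` — the observed pattern: cereals contribute a target
  share (drawn within 38-77%) of total energy;
* ``adequate`` — a state whose daily menu is an internally LP-solved
  minimum-cost diet meeting every 2012 target, for guaranteed-green
  adequacy fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io import (
    FoodRecord,
    FortificationSpec,
    MenuCycle,
    MenuDay,
    MenuIngredient,
    PriceQuote,
    StandardsConfig,
    ValidationError,
    write_food_table,
    write_fortifications,
    write_menus,
    write_prices,
)
from . import lp as lpmod

#: (food_id, name, group, moisture% range, nutrient ranges per 100 g raw).
#: Synthetic plausibility ranges, not values from any published table.
_CATALOG: list[tuple[str, str, str, tuple[float, float], dict[str, tuple[float, float]]]] = [
    ("rice", "Raw rice", "cereals_millets", (9, 13),
     {"energy_kcal": (340, 360), "protein_g": (6.5, 8.5), "fat_g": (0.4, 1.5),
      "calcium_mg": (7, 20), "iron_mg": (0.5, 1.2), "zinc_mg": (1.0, 1.5),
      "folate_ug": (8, 15), "vitamin_b6_mg": (0.10, 0.20)}),
    ("fortified_rice", "Fortified rice kernels blend", "cereals_millets", (9, 13),
     {"energy_kcal": (340, 360), "protein_g": (6.5, 8.5), "fat_g": (0.4, 1.5),
      "calcium_mg": (7, 20), "iron_mg": (0.5, 1.2), "zinc_mg": (1.0, 1.5),
      "folate_ug": (8, 15), "vitamin_b6_mg": (0.10, 0.20)}),
    ("wheat_flour", "Whole wheat flour", "cereals_millets", (9, 13),
     {"energy_kcal": (330, 350), "protein_g": (9, 12), "fat_g": (1.2, 2.0),
      "calcium_mg": (25, 45), "iron_mg": (3.5, 5.0), "zinc_mg": (2.0, 3.0),
      "folate_ug": (25, 40), "vitamin_b6_mg": (0.20, 0.40)}),
    ("ragi", "Finger millet", "cereals_millets", (9, 13),
     {"energy_kcal": (310, 330), "protein_g": (6, 8), "fat_g": (1.3, 2.0),
      "calcium_mg": (320, 370), "iron_mg": (3.5, 5.0), "zinc_mg": (2.0, 2.6),
      "folate_ug": (30, 40), "vitamin_b6_mg": (0.05, 0.15)}),
    ("semolina", "Semolina (suji)", "cereals_millets", (8, 12),
     {"energy_kcal": (330, 350), "protein_g": (9, 11), "fat_g": (0.7, 1.2),
      "calcium_mg": (15, 30), "iron_mg": (1.0, 2.0), "zinc_mg": (1.0, 2.0),
      "folate_ug": (20, 40), "vitamin_b6_mg": (0.10, 0.30)}),
    ("lentil", "Red lentil (masoor dal)", "pulses_legumes", (9, 12),
     {"energy_kcal": (320, 345), "protein_g": (22, 26), "fat_g": (0.7, 1.5),
      "calcium_mg": (40, 90), "iron_mg": (6.0, 8.0), "zinc_mg": (3.0, 4.0),
      "folate_ug": (150, 200), "vitamin_b6_mg": (0.40, 0.60)}),
    ("chickpea", "Bengal gram", "pulses_legumes", (8, 11),
     {"energy_kcal": (340, 370), "protein_g": (17, 21), "fat_g": (4.0, 6.0),
      "calcium_mg": (100, 180), "iron_mg": (4.5, 6.5), "zinc_mg": (3.0, 4.0),
      "folate_ug": (300, 500), "vitamin_b6_mg": (0.40, 0.60)}),
    ("green_gram", "Green gram (moong)", "pulses_legumes", (9, 12),
     {"energy_kcal": (320, 350), "protein_g": (22, 25), "fat_g": (1.0, 1.5),
      "calcium_mg": (80, 130), "iron_mg": (4.0, 6.0), "zinc_mg": (2.5, 3.5),
      "folate_ug": (400, 500), "vitamin_b6_mg": (0.30, 0.50)}),
    ("milk", "Cow milk", "milk_products", (87, 89),
     {"energy_kcal": (60, 80), "protein_g": (3.0, 3.5), "fat_g": (3.5, 4.5),
      "calcium_mg": (110, 130), "iron_mg": (0.02, 0.10), "zinc_mg": (0.30, 0.50),
      "folate_ug": (5, 10), "vitamin_a_ug": (30, 60), "vitamin_b6_mg": (0.03, 0.06),
      "vitamin_b12_ug": (0.30, 0.50)}),
    ("milk_powder", "Whole milk powder", "milk_products", (2, 4),
     {"energy_kcal": (480, 500), "protein_g": (25, 27), "fat_g": (26, 28),
      "calcium_mg": (900, 950), "iron_mg": (0.2, 0.6), "zinc_mg": (3.0, 3.6),
      "folate_ug": (35, 50), "vitamin_a_ug": (250, 350), "vitamin_b6_mg": (0.25, 0.40),
      "vitamin_b12_ug": (2.5, 3.5)}),
    ("egg", "Hen egg, whole", "eggs", (74, 77),
     {"energy_kcal": (140, 160), "protein_g": (12, 14), "fat_g": (9, 11),
      "calcium_mg": (50, 60), "iron_mg": (1.7, 2.2), "zinc_mg": (1.2, 1.5),
      "folate_ug": (45, 55), "vitamin_a_ug": (140, 190), "vitamin_b6_mg": (0.10, 0.20),
      "vitamin_b12_ug": (0.9, 1.3)}),
    ("chicken", "Chicken, lean", "flesh_foods", (73, 76),
     {"energy_kcal": (110, 130), "protein_g": (20, 23), "fat_g": (2, 5),
      "calcium_mg": (8, 15), "iron_mg": (0.7, 1.2), "zinc_mg": (1.0, 2.0),
      "folate_ug": (5, 10), "vitamin_b6_mg": (0.40, 0.60), "vitamin_b12_ug": (0.30, 0.50)}),
    ("spinach", "Spinach", "green_leafy_veg", (90, 92),
     {"energy_kcal": (23, 30), "protein_g": (2, 3), "fat_g": (0.3, 0.7),
      "calcium_mg": (90, 120), "iron_mg": (2.5, 3.5), "zinc_mg": (0.4, 0.7),
      "folate_ug": (140, 200), "vitamin_a_ug": (350, 560), "vitamin_b6_mg": (0.15, 0.25)}),
    ("amaranth_leaves", "Amaranth leaves", "green_leafy_veg", (85, 90),
     {"energy_kcal": (30, 45), "protein_g": (3, 4), "fat_g": (0.3, 0.8),
      "calcium_mg": (300, 400), "iron_mg": (3.0, 8.0), "zinc_mg": (0.8, 1.2),
      "folate_ug": (120, 180), "vitamin_a_ug": (400, 700), "vitamin_b6_mg": (0.15, 0.30)}),
    ("tomato", "Tomato", "other_veg", (93, 95),
     {"energy_kcal": (15, 25), "protein_g": (0.8, 1.2), "fat_g": (0.1, 0.4),
      "calcium_mg": (8, 15), "iron_mg": (0.3, 0.6), "zinc_mg": (0.1, 0.3),
      "folate_ug": (10, 30), "vitamin_a_ug": (30, 80), "vitamin_b6_mg": (0.05, 0.10)}),
    ("pumpkin", "Pumpkin", "other_veg", (91, 94),
     {"energy_kcal": (20, 30), "protein_g": (0.8, 1.4), "fat_g": (0.1, 0.3),
      "calcium_mg": (15, 30), "iron_mg": (0.4, 0.8), "zinc_mg": (0.2, 0.4),
      "folate_ug": (10, 25), "vitamin_a_ug": (100, 250), "vitamin_b6_mg": (0.05, 0.10)}),
    ("french_beans", "French beans", "other_veg", (89, 92),
     {"energy_kcal": (25, 35), "protein_g": (1.5, 2.5), "fat_g": (0.1, 0.4),
      "calcium_mg": (40, 60), "iron_mg": (0.8, 1.5), "zinc_mg": (0.2, 0.5),
      "folate_ug": (30, 60), "vitamin_a_ug": (30, 80), "vitamin_b6_mg": (0.05, 0.15)}),
    ("potato", "Potato", "roots_tubers", (78, 82),
     {"energy_kcal": (70, 90), "protein_g": (1.5, 2.5), "fat_g": (0.05, 0.2),
      "calcium_mg": (8, 15), "iron_mg": (0.4, 0.8), "zinc_mg": (0.2, 0.4),
      "folate_ug": (10, 25), "vitamin_b6_mg": (0.20, 0.30)}),
    ("carrot", "Carrot", "roots_tubers", (86, 90),
     {"energy_kcal": (30, 45), "protein_g": (0.8, 1.2), "fat_g": (0.1, 0.3),
      "calcium_mg": (25, 40), "iron_mg": (0.5, 1.0), "zinc_mg": (0.2, 0.4),
      "folate_ug": (10, 25), "vitamin_a_ug": (300, 700), "vitamin_b6_mg": (0.08, 0.15)}),
    ("onion", "Onion", "roots_tubers", (86, 90),
     {"energy_kcal": (35, 50), "protein_g": (1.0, 1.5), "fat_g": (0.05, 0.2),
      "calcium_mg": (20, 40), "iron_mg": (0.3, 0.7), "zinc_mg": (0.1, 0.3),
      "folate_ug": (10, 25), "vitamin_b6_mg": (0.08, 0.15)}),
    ("banana", "Banana", "fruits", (70, 76),
     {"energy_kcal": (85, 110), "protein_g": (1.0, 1.4), "fat_g": (0.2, 0.4),
      "calcium_mg": (5, 15), "iron_mg": (0.2, 0.5), "zinc_mg": (0.1, 0.3),
      "folate_ug": (15, 25), "vitamin_a_ug": (2, 10), "vitamin_b6_mg": (0.30, 0.40)}),
    ("guava", "Guava", "fruits", (80, 85),
     {"energy_kcal": (50, 70), "protein_g": (1.5, 2.6), "fat_g": (0.3, 1.0),
      "calcium_mg": (15, 30), "iron_mg": (0.2, 0.5), "zinc_mg": (0.2, 0.4),
      "folate_ug": (30, 50), "vitamin_a_ug": (10, 40), "vitamin_b6_mg": (0.08, 0.15)}),
    ("sunflower_oil", "Sunflower oil", "oils_fats", (0, 0.2),
     {"energy_kcal": (880, 900), "fat_g": (99.5, 100)}),
    ("fortified_oil", "Edible oil (fortification vehicle)", "oils_fats", (0, 0.2),
     {"energy_kcal": (880, 900), "fat_g": (99.5, 100)}),
    ("ghee", "Ghee", "oils_fats", (0, 0.5),
     {"energy_kcal": (890, 900), "fat_g": (99, 100), "vitamin_a_ug": (500, 700)}),
    ("sugar", "Sugar", "sugars", (0, 1),
     {"energy_kcal": (395, 400)}),
    ("jaggery", "Jaggery", "sugars", (3, 8),
     {"energy_kcal": (370, 390), "protein_g": (0.3, 1.0), "fat_g": (0.05, 0.2),
      "calcium_mg": (60, 100), "iron_mg": (2.5, 5.0), "zinc_mg": (0.2, 0.5),
      "folate_ug": (1, 5)}),
    ("groundnut", "Groundnut", "nuts_seeds", (4, 7),
     {"energy_kcal": (550, 580), "protein_g": (23, 26), "fat_g": (45, 50),
      "calcium_mg": (50, 90), "iron_mg": (2.0, 3.0), "zinc_mg": (3.0, 4.0),
      "folate_ug": (80, 120), "vitamin_b6_mg": (0.30, 0.50)}),
    ("sesame", "Sesame seed", "nuts_seeds", (3, 6),
     {"energy_kcal": (550, 600), "protein_g": (18, 20), "fat_g": (43, 50),
      "calcium_mg": (800, 1200), "iron_mg": (9, 15), "zinc_mg": (7, 12),
      "folate_ug": (90, 130), "vitamin_b6_mg": (0.5, 0.8)}),
    ("spice_mix", "Mixed spices and condiments", "condiments_other", (5, 10),
     {"energy_kcal": (250, 350), "protein_g": (8, 12), "fat_g": (5, 15),
      "calcium_mg": (200, 500), "iron_mg": (5, 20), "zinc_mg": (2, 5),
      "folate_ug": (20, 60), "vitamin_b6_mg": (0.2, 0.6)}),
]

#: Vendor-quote ranges per food group, rupees per kg (synthetic retail scale).
PRICE_RANGES: dict[str, tuple[float, float]] = {
    "cereals_millets": (25, 45),
    "pulses_legumes": (80, 140),
    "milk_products": (50, 75),
    "eggs": (150, 220),
    "flesh_foods": (180, 300),
    "green_leafy_veg": (30, 80),
    "other_veg": (30, 60),
    "roots_tubers": (20, 45),
    "fruits": (40, 100),
    "oils_fats": (100, 160),
    "sugars": (40, 60),
    "nuts_seeds": (120, 250),
    "condiments_other": (80, 200),
}

#: Fortification levels for staples: iron/folic-acid/B12 rice per 100 g and
#: vitamin-A oil per litre (converted at 0.92 g/ml).
RICE_FORTIFICATION = FortificationSpec(
    vehicle_food_id="fortified_rice",
    additions={"iron_mg": 4.25, "folate_ug": 12.5, "vitamin_b12_ug": 0.125},
    basis="per_100g",
)
OIL_FORTIFICATION = FortificationSpec(
    vehicle_food_id="fortified_oil",
    additions={"vitamin_a_ug": 750.0},
    basis="per_litre",
    density_g_per_ml=0.92,
)


@dataclass
class SyntheticConfig:
    """Knobs of the generator; the defaults are the study-like conditions."""

    seed: int
    n_states: int = 3
    anganwadis_per_state: int = 4
    cycle_length_range: tuple[int, int] = (6, 15)
    cereal_energy_share_range: tuple[float, float] = (38.0, 77.0)
    price_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(PRICE_RANGES)
    )
    fortified_states_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValidationError("/synthetic/seed", "seed is mandatory")
        for name, (lo, hi) in (
            ("cycle_length_range", self.cycle_length_range),
            ("cereal_energy_share_range", self.cereal_energy_share_range),
        ):
            if lo > hi:
                raise ValidationError(f"/synthetic/{name}", f"range not well-ordered: {lo} > {hi}")


@dataclass
class SyntheticDataset:
    """One generated multi-state dataset plus its file writers."""

    foods: list[FoodRecord]
    cycles: list[MenuCycle]
    prices: list[PriceQuote]
    forts: list[FortificationSpec]
    config: SyntheticConfig
    profiles: dict[str, str]

    def write(self, out_dir) -> dict[str, str]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_food_table(self.foods, out / "foods.csv")
        write_menus(self.cycles, out / "menu.json")
        write_prices(self.prices, out / "prices.csv")
        write_fortifications(self.forts, out / "fortification.json")
        return {
            "foods": str(out / "foods.csv"),
            "menu": str(out / "menu.json"),
            "prices": str(out / "prices.csv"),
            "fortification": str(out / "fortification.json"),
        }


def gen_food_table(cfg: SyntheticConfig) -> list[FoodRecord]:
    """Draw a food table from the per-group plausibility ranges (seeded)."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    records = []
    for food_id, name, group, (mlo, mhi), ranges in _CATALOG:
        nutrients = {
            k: float(rng.uniform(lo, hi)) for k, (lo, hi) in ranges.items()
        }
        records.append(
            FoodRecord(
                food_id=food_id,
                name=name,
                group=group,
                moisture_pct=float(rng.uniform(mlo, mhi)),
                nutrients=nutrients,
                source="synthetic",
            )
        )
    return records


def gen_prices(cfg: SyntheticConfig, foods: list[FoodRecord], state_index: int = 0) -> list[PriceQuote]:
    """Three vendor quotes per food from the group's retail range (seeded)."""
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 303, state_index]))
    quotes = []
    for rec in foods:
        lo, hi = cfg.price_ranges[rec.group]
        base = rng.uniform(lo, hi)
        quotes.append(
            PriceQuote(
                food_id=rec.food_id,
                vendor_quotes=[round(float(base * rng.uniform(0.92, 1.08)), 2) for _ in range(3)],
            )
        )
    return quotes


def _cereal_heavy_cycles(
    cfg: SyntheticConfig, foods: list[FoodRecord], rng: np.random.Generator, state_id: str
) -> list[MenuCycle]:
    by_id = {r.food_id: r for r in foods}
    fortified = rng.random() < cfg.fortified_states_fraction
    rice_id = "fortified_rice" if fortified else "rice"
    oil_id = "fortified_oil" if fortified else "sunflower_oil"
    # between-state variability in portion size (meals range from well below
    # to well above the energy standard across states)
    state_scale = float(rng.uniform(0.7, 1.3))
    cycles = []
    for a in range(cfg.anganwadis_per_state):
        n_days = int(rng.integers(cfg.cycle_length_range[0], cfg.cycle_length_range[1] + 1))
        days = []
        for d in range(n_days):
            hcm = [
                MenuIngredient(rice_id, state_scale * float(rng.uniform(55, 85))),
                MenuIngredient("lentil", state_scale * float(rng.uniform(12, 25))),
                MenuIngredient(oil_id, state_scale * float(rng.uniform(4, 8))),
            ]
            if rng.random() < 0.5:
                veg = str(rng.choice(["spinach", "potato", "tomato", "pumpkin", "carrot"]))
                hcm.append(MenuIngredient(veg, state_scale * float(rng.uniform(15, 40))))
            if rng.random() < 0.15:
                hcm.append(MenuIngredient("egg", state_scale * float(rng.uniform(30, 50))))
            ms = [
                MenuIngredient(str(rng.choice(["semolina", "wheat_flour", "ragi"])),
                               state_scale * float(rng.uniform(15, 35))),
                MenuIngredient(str(rng.choice(["sugar", "jaggery"])),
                               state_scale * float(rng.uniform(5, 10))),
            ]
            if rng.random() < 0.4:
                ms.append(MenuIngredient("milk", state_scale * float(rng.uniform(40, 60))))
            if rng.random() < 0.1:
                # supplied through another scheme; excluded from SNP totals
                ms.append(MenuIngredient("banana", float(rng.uniform(40, 80)), snp_funded=False))
            days.append(
                MenuDay(
                    day_label=f"day{d + 1}",
                    meal_components=[
                        ("morning_snack", "snack", ms),
                        ("hot_cooked_meal", "khichdi", hcm),
                    ],
                )
            )
        cycles.append(MenuCycle(state_id=state_id, anganwadi_id=f"{state_id}_awc{a + 1}", days=days))

    # rescale grams so the pooled cereal energy share hits a target drawn
    # inside the configured band, while preserving total energy: cereal
    # grams scale to t*E, non-cereal to (1-t)*E
    lo, hi = cfg.cereal_energy_share_range
    target = rng.uniform(max(lo, 45.0), min(hi, 72.0)) / 100.0
    e_cereal = e_other = 0.0
    for c in cycles:
        for day in c.days:
            for ing in day.iter_ingredients():
                if not ing.snp_funded:
                    continue
                e = ing.raw_grams_per_child * by_id[ing.food_id].nutrients["energy_kcal"] / 100.0
                if by_id[ing.food_id].group == "cereals_millets":
                    e_cereal += e
                else:
                    e_other += e
    total = e_cereal + e_other
    f_cereal = target * total / e_cereal
    f_other = (1.0 - target) * total / e_other
    for c in cycles:
        for day in c.days:
            for _, _, ingredients in day.meal_components:
                for ing in ingredients:
                    if by_id[ing.food_id].group == "cereals_millets":
                        ing.raw_grams_per_child *= f_cereal
                    else:
                        ing.raw_grams_per_child *= f_other
    return cycles


#: Food list offered to the internal LP when building an "adequate" state.
_ADEQUATE_BASKET = [
    "rice", "lentil", "sunflower_oil", "milk", "milk_powder", "egg",
    "spinach", "amaranth_leaves", "carrot", "banana", "sesame", "chickpea",
]


def _adequate_cycles(
    cfg: SyntheticConfig,
    foods: list[FoodRecord],
    prices: list[PriceQuote],
    rng: np.random.Generator,
    state_id: str,
) -> list[MenuCycle]:
    by_id = {r.food_id: r for r in foods}
    basket = [by_id[f] for f in _ADEQUATE_BASKET]
    problem = lpmod.build_problem(
        basket,
        prices,
        StandardsConfig.snp2012(),
        mode="full",
        use_tolerance=False,  # meet full targets, not the relaxed floors
        total_grams_cap=600.0,
        portion_caps=200.0,
    )
    sol = lpmod.solve(problem)
    if sol.status != "optimal":
        raise ValidationError(
            f"/synthetic/{state_id}", f"adequate profile infeasible ({sol.status})"
        )
    ingredients = [
        MenuIngredient(f, g) for f, g in sol.grams.items() if g > 1e-6
    ]
    cycles = []
    for a in range(cfg.anganwadis_per_state):
        n_days = int(rng.integers(cfg.cycle_length_range[0], cfg.cycle_length_range[1] + 1))
        days = [
            MenuDay(
                day_label=f"day{d + 1}",
                meal_components=[
                    (
                        "hot_cooked_meal",
                        "optimised meal",
                        [MenuIngredient(i.food_id, i.raw_grams_per_child) for i in ingredients],
                    )
                ],
            )
            for d in range(n_days)
        ]
        cycles.append(MenuCycle(state_id=state_id, anganwadi_id=f"{state_id}_awc{a + 1}", days=days))
    return cycles


def gen_state(
    cfg: SyntheticConfig,
    foods: list[FoodRecord],
    state_index: int = 0,
    profile: str = "cereal_heavy",
) -> tuple[list[MenuCycle], list[PriceQuote], list[FortificationSpec]]:
    """Generate one state's menu cycles, vendor prices and fortifications."""
    if profile not in ("cereal_heavy", "adequate"):
        raise ValidationError("/synthetic/profile", f"unknown profile {profile!r}")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 202, state_index]))
    state_id = f"state{state_index + 1:02d}"
    prices = gen_prices(cfg, foods, state_index=state_index)
    if profile == "cereal_heavy":
        cycles = _cereal_heavy_cycles(cfg, foods, rng, state_id)
    else:
        cycles = _adequate_cycles(cfg, foods, prices, rng, state_id)
    used = {ing.food_id for c in cycles for d in c.days for ing in d.iter_ingredients()}
    forts = [
        spec
        for spec in (RICE_FORTIFICATION, OIL_FORTIFICATION)
        if spec.vehicle_food_id in used
    ]
    return cycles, prices, forts


def gen_dataset(
    cfg: SyntheticConfig, profiles: list[str] | None = None
) -> SyntheticDataset:
    """Generate a complete multi-state dataset sharing one food table.

    Prices are taken from the first state's quotes (one prices file per
    dataset); fortification specs target dedicated vehicle foods, so a
    single fortification file applies cleanly across states.
    """
    foods = gen_food_table(cfg)
    if profiles is None:
        profiles = ["cereal_heavy"] * cfg.n_states
    if len(profiles) != cfg.n_states:
        raise ValidationError("/synthetic/profiles", "one profile per state required")
    all_cycles: list[MenuCycle] = []
    prices: list[PriceQuote] = []
    profile_map: dict[str, str] = {}
    for s, profile in enumerate(profiles):
        cycles, state_prices, _ = gen_state(cfg, foods, state_index=s, profile=profile)
        if s == 0:
            prices = state_prices
        all_cycles.extend(cycles)
        profile_map[cycles[0].state_id] = profile
    return SyntheticDataset(
        foods=foods,
        cycles=all_cycles,
        prices=prices,
        forts=[RICE_FORTIFICATION, OIL_FORTIFICATION],
        config=cfg,
        profiles=profile_map,
    )


def gen_lognormal_case(
    mu_true: float, sigma_true: float, n_days: int, seed: int
) -> np.ndarray:
    """Lognormal daily provision series for parameter-recovery testing."""
    if sigma_true < 0:
        raise ValidationError("/synthetic/sigma_true", "sigma must be >= 0")
    rng = np.random.default_rng(seed)
    if sigma_true == 0:
        return np.full(n_days, np.exp(mu_true))
    return rng.lognormal(mean=mu_true, sigma=sigma_true, size=n_days)
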