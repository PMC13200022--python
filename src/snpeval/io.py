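"""Data model and readers/writers for the SNP meal-evaluation pipeline.

Domain objects: food composition records (nutrient densities per 100 g raw
food), fortification specifications, menu cycles (per-state repeating day
plans of raw ingredient grams per child), vendor price quotes, and the
nutrient-standards configuration (2012 and 2023 programme standards plus
the ICMR-style EAR table for 3-6 year olds).

File dialects are deliberately plain: UTF-8 comma-separated CSV with a
mandatory header for tabular data, JSON for nested structures. Schema
violations raise :class:`ValidationError` carrying a JSON-pointer-style
path to the offending element.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: The fixed 10-nutrient panel evaluated throughout the package. Keys carry
#: their unit suffix; densities are per 100 g raw food.
NUTRIENT_KEYS: tuple[str, ...] = (
    "energy_kcal",
    "protein_g",
    "fat_g",
    "calcium_mg",
    "iron_mg",
    "zinc_mg",
    "folate_ug",
    "vitamin_a_ug",
    "vitamin_b6_mg",
    "vitamin_b12_ug",
)

FOOD_GROUPS: tuple[str, ...] = (
    "cereals_millets",
    "pulses_legumes",
    "milk_products",
    "eggs",
    "flesh_foods",
    "green_leafy_veg",
    "other_veg",
    "roots_tubers",
    "fruits",
    "oils_fats",
    "sugars",
    "nuts_seeds",
    "condiments_other",
)

FOOD_SOURCES = ("ifct", "usda_moisture_adjusted", "synthetic")
MEAL_LABELS = ("morning_snack", "hot_cooked_meal", "other")

#: kcal released per gram of fat (Atwater factor).
KCAL_PER_G_FAT = 9.0


class ValidationError(ValueError):
    """Schema or invariant violation, with a JSON-pointer-style path."""

    def __init__(self, path: str, message: str):
        self.path = path
        super().__init__(f"{path}: {message}")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class FoodRecord:
    """Nutrient densities of one raw food, per 100 g as purchased.

    ``nutrients`` always holds the complete 10-key panel; a nutrient absent
    from the source table is stored as an explicit zero and its key listed
    in ``imputed_zero`` rather than silently dropped.
    """

    food_id: str
    name: str
    group: str
    moisture_pct: float
    nutrients: dict[str, float]
    source: str = "synthetic"
    imputed_zero: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.group not in FOOD_GROUPS:
            raise ValidationError(
                f"/foods/{self.food_id}/group",
                f"unknown group {self.group!r}; accepted: {', '.join(FOOD_GROUPS)}",
            )
        if self.source not in FOOD_SOURCES:
            raise ValidationError(
                f"/foods/{self.food_id}/source", f"unknown source {self.source!r}"
            )
        if not 0 <= self.moisture_pct < 100:
            raise ValidationError(
                f"/foods/{self.food_id}/moisture_pct",
                f"must be in [0, 100), got {self.moisture_pct}",
            )
        missing = [k for k in NUTRIENT_KEYS if k not in self.nutrients]
        if missing:
            self.nutrients = dict(self.nutrients)
            for k in missing:
                self.nutrients[k] = 0.0
            self.imputed_zero = tuple(sorted(set(self.imputed_zero) | set(missing)))
        unknown = set(self.nutrients) - set(NUTRIENT_KEYS)
        if unknown:
            raise ValidationError(
                f"/foods/{self.food_id}/nutrients",
                f"unknown nutrient keys {sorted(unknown)}; accepted: {list(NUTRIENT_KEYS)}",
            )
        for k, v in self.nutrients.items():
            if not math.isfinite(v) or v < 0:
                raise ValidationError(
                    f"/foods/{self.food_id}/nutrients/{k}",
                    f"density must be finite and >= 0, got {v}",
                )


@dataclass
class FortificationSpec:
    """Nutrients added to a vehicle food (fortified rice, oil, ...).

    ``additions`` are amounts added per 100 g of vehicle when
    ``basis='per_100g'``, or per litre when ``basis='per_litre'`` (the
    mass density converts litres to grams).
    """

    vehicle_food_id: str
    additions: dict[str, float]
    basis: str = "per_100g"
    density_g_per_ml: float | None = None

    def __post_init__(self) -> None:
        root = f"/fortifications/{self.vehicle_food_id}"
        if self.basis not in ("per_100g", "per_litre"):
            raise ValidationError(f"{root}/basis", f"unknown basis {self.basis!r}")
        if self.basis == "per_litre":
            if self.density_g_per_ml is None or self.density_g_per_ml <= 0:
                raise ValidationError(
                    f"{root}/density_g_per_ml",
                    "positive density required when basis='per_litre'",
                )
        unknown = set(self.additions) - set(NUTRIENT_KEYS)
        if unknown:
            raise ValidationError(
                f"{root}/additions", f"unknown nutrient keys {sorted(unknown)}"
            )
        for k, v in self.additions.items():
            if not math.isfinite(v) or v < 0:
                raise ValidationError(
                    f"{root}/additions/{k}", f"addition must be >= 0, got {v}"
                )


@dataclass
class MenuIngredient:
    """One raw ingredient in a dish: grams per child per day.

    Ingredients funded outside the SNP (other safety-net schemes) carry
    ``snp_funded=False`` and are excluded from SNP provision totals.
    """

    food_id: str
    raw_grams_per_child: float
    snp_funded: bool = True

    def __post_init__(self) -> None:
        g = self.raw_grams_per_child
        if not math.isfinite(g) or g < 0:
            raise ValidationError(
                f"/ingredients/{self.food_id}/raw_grams_per_child",
                f"must be finite and >= 0, got {g}",
            )


@dataclass
class MenuDay:
    """One operational day: meal components (morning snack, hot cooked meal)."""

    day_label: str
    meal_components: list[tuple[str, str, list[MenuIngredient]]]

    def __post_init__(self) -> None:
        for meal, dish, ingredients in self.meal_components:
            if meal not in MEAL_LABELS:
                raise ValidationError(
                    f"/days/{self.day_label}/meal", f"unknown meal label {meal!r}"
                )
            if not ingredients:
                raise ValidationError(
                    f"/days/{self.day_label}/{dish}",
                    "each listed dish needs at least one ingredient",
                )

    def iter_ingredients(self) -> Iterable[MenuIngredient]:
        for _, _, ingredients in self.meal_components:
            yield from ingredients


@dataclass
class MenuCycle:
    """Repeating meal plan of one anganwadi (typically 6-15 day cycles)."""

    state_id: str
    anganwadi_id: str
    days: list[MenuDay]
    cycle_length_days: int = 0

    def __post_init__(self) -> None:
        if self.cycle_length_days == 0:
            self.cycle_length_days = len(self.days)
        if self.cycle_length_days != len(self.days) or self.cycle_length_days < 1:
            raise ValidationError(
                f"/menus/{self.state_id}/{self.anganwadi_id}/cycle_length_days",
                f"cycle_length_days ({self.cycle_length_days}) must equal "
                f"number of days ({len(self.days)}) and be >= 1",
            )


@dataclass
class PriceQuote:
    """Vendor retail quotes for one food; the arithmetic mean feeds the LP."""

    food_id: str
    vendor_quotes: list[float]
    mean_price: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        self.mean_price = mean_price(self.vendor_quotes, food_id=self.food_id)


def mean_price(quotes: Sequence[float], food_id: str = "?") -> float:
    """Arithmetic mean of vendor quotes in rupees per kg (>= 1 quote, all > 0)."""
    if len(quotes) == 0:
        raise ValidationError(f"/prices/{food_id}", "at least one vendor quote required")
    for i, q in enumerate(quotes):
        if not math.isfinite(q) or q <= 0:
            raise ValidationError(
                f"/prices/{food_id}/{i}", f"quotes must be positive, got {q}"
            )
    return float(sum(quotes)) / len(quotes)


@dataclass
class FatRule:
    """Fat adequacy rule: share-of-energy band (%) or absolute band (g/day)."""

    kind: str  # "ratio_band" | "absolute_band"
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.kind not in ("ratio_band", "absolute_band"):
            raise ValidationError("/standards/fat_rule/kind", f"unknown kind {self.kind!r}")
        if not 0 < self.lower <= self.upper:
            raise ValidationError(
                "/standards/fat_rule", f"need 0 < lower <= upper, got {self.lower}, {self.upper}"
            )


#: Default EAR table for 3-6 y used by the shipped example configurations.
#: These are synthetic illustrative values of realistic magnitude, NOT an
#: authoritative ICMR table; supply your own `ear_per_day` for real use.
DEFAULT_EAR_3_6Y: dict[str, float] = {
    "calcium_mg": 450.0,
    "iron_mg": 8.0,
    "zinc_mg": 4.0,
    "folate_ug": 100.0,
    "vitamin_a_ug": 280.0,
    "vitamin_b6_mg": 0.8,
    "vitamin_b12_ug": 1.0,
}


@dataclass
class StandardsConfig:
    """Programme nutrient standards and evaluation constants.

    The 2012 standard targets 500 kcal and a 12 g/day protein floor, with
    fat judged on the ICMR 25-35% fat-to-energy band. The 2023 revision
    lowers energy to 400 kcal, raises protein to a 15-20 g band and sets an
    absolute 15-20 g/day fat band. Micronutrients are judged against
    ``meal_fraction`` (default one-third) of the age-specific EAR, with a
    relative ``tolerance`` (default 10%) on met/not-met decisions and a
    protein ``digestibility_factor`` (default 0.8) for cereal-based diets.
    """

    standard_version: str
    energy_target_kcal: float
    protein_min_g: float
    protein_max_g: float | None
    fat_rule: FatRule
    ear_per_day: dict[str, float]
    meal_fraction: float = 1.0 / 3.0
    tolerance: float = 0.10
    digestibility_factor: float = 0.8
    fortification_mode: str = "increment"  # or "total"
    fat_allowance_two_sided: bool = True

    def __post_init__(self) -> None:
        if self.standard_version not in ("snp2012", "snp2023"):
            raise ValidationError(
                "/standards/standard_version",
                f"unknown version {self.standard_version!r}",
            )
        if not 0 < self.meal_fraction <= 1:
            raise ValidationError(
                "/standards/meal_fraction",
                f"must be in (0, 1], got {self.meal_fraction}",
            )
        if not 0 <= self.tolerance < 1:
            raise ValidationError(
                "/standards/tolerance", f"must be in [0, 1), got {self.tolerance}"
            )
        if not 0 < self.digestibility_factor <= 1:
            raise ValidationError(
                "/standards/digestibility_factor",
                f"must be in (0, 1], got {self.digestibility_factor}",
            )
        if self.energy_target_kcal <= 0 or self.protein_min_g <= 0:
            raise ValidationError(
                "/standards", "energy and protein targets must be positive"
            )
        if self.fortification_mode not in ("increment", "total"):
            raise ValidationError(
                "/standards/fortification_mode",
                f"unknown mode {self.fortification_mode!r}",
            )
        unknown = set(self.ear_per_day) - set(NUTRIENT_KEYS)
        if unknown:
            raise ValidationError(
                "/standards/ear_per_day",
                f"unknown nutrient keys {sorted(unknown)}; accepted: {list(NUTRIENT_KEYS)}",
            )
        for k, v in self.ear_per_day.items():
            if not math.isfinite(v) or v <= 0:
                raise ValidationError(
                    f"/standards/ear_per_day/{k}", f"EAR must be positive, got {v}"
                )

    @classmethod
    def snp2012(cls, ear_per_day: Mapping[str, float] | None = None, **kw) -> "StandardsConfig":
        """The 2012 programme standard: 500 kcal, protein floor 12 g, fat 25-35% of energy."""
        return cls(
            standard_version="snp2012",
            energy_target_kcal=500.0,
            protein_min_g=12.0,
            protein_max_g=None,
            fat_rule=FatRule("ratio_band", 25.0, 35.0),
            ear_per_day=dict(ear_per_day if ear_per_day is not None else DEFAULT_EAR_3_6Y),
            **kw,
        )

    @classmethod
    def snp2023(cls, ear_per_day: Mapping[str, float] | None = None, **kw) -> "StandardsConfig":
        """The 2023 revision: 400 kcal, protein 15-20 g, fat 15-20 g/day absolute band."""
        return cls(
            standard_version="snp2023",
            energy_target_kcal=400.0,
            protein_min_g=15.0,
            protein_max_g=20.0,
            fat_rule=FatRule("absolute_band", 15.0, 20.0),
            ear_per_day=dict(ear_per_day if ear_per_day is not None else DEFAULT_EAR_3_6Y),
            **kw,
        )


# ---------------------------------------------------------------------------
# operations on records
# ---------------------------------------------------------------------------


def moisture_adjust(source: FoodRecord, target_moisture_pct: float) -> FoodRecord:
    """Re-express nutrient densities at a different moisture content.

    Each density is scaled by ``(100 - target) / (100 - source_moisture)``,
    which keeps nutrient-per-dry-matter invariant; used to make USDA entries
    comparable with IFCT-style moisture conventions.
    """
    if not 0 <= target_moisture_pct < 100:
        raise ValidationError(
            f"/foods/{source.food_id}/moisture_pct",
            f"target moisture must be in [0, 100), got {target_moisture_pct}",
        )
    factor = (100.0 - target_moisture_pct) / (100.0 - source.moisture_pct)
    return replace(
        source,
        moisture_pct=target_moisture_pct,
        nutrients={k: v * factor for k, v in source.nutrients.items()},
        source="usda_moisture_adjusted",
    )


# ---------------------------------------------------------------------------
# CSV / JSON loaders and writers
# ---------------------------------------------------------------------------

_FOOD_COLUMNS = ("food_id", "name", "group", "moisture_pct", *NUTRIENT_KEYS, "source")


def load_food_table(path) -> list[FoodRecord]:
    """Read a food-composition CSV (one row per food, densities per 100 g raw)."""
    df = pd.read_csv(path, comment="#", dtype={"food_id": str, "name": str})
    unknown = [c for c in df.columns if c not in _FOOD_COLUMNS]
    if unknown:
        raise ValidationError(
            "/foods/columns",
            f"unknown columns {unknown}; accepted: {list(_FOOD_COLUMNS)}",
        )
    missing = [c for c in _FOOD_COLUMNS if c not in df.columns and c != "source"]
    if missing:
        raise ValidationError("/foods/columns", f"missing required columns {missing}")
    records: list[FoodRecord] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        fid = str(row["food_id"])
        if fid in seen:
            raise ValidationError(f"/foods/{i}/food_id", f"duplicate food_id {fid!r}")
        seen.add(fid)
        nutrients = {}
        for k in NUTRIENT_KEYS:
            v = row[k]
            try:
                nutrients[k] = float(v)
            except (TypeError, ValueError):
                raise ValidationError(f"/foods/{i}/{k}", f"not a number: {v!r}") from None
            if math.isnan(nutrients[k]):
                raise ValidationError(f"/foods/{i}/{k}", "missing value")
        try:
            m = float(row["moisture_pct"])
        except (TypeError, ValueError):
            raise ValidationError(
                f"/foods/{i}/moisture_pct", f"not a number: {row['moisture_pct']!r}"
            ) from None
        records.append(
            FoodRecord(
                food_id=fid,
                name=str(row["name"]),
                group=str(row["group"]),
                moisture_pct=m,
                nutrients=nutrients,
                source=str(row["source"]) if "source" in df.columns else "synthetic",
            )
        )
    return records


def write_food_table(records: Sequence[FoodRecord], path) -> None:
    rows = [
        {
            "food_id": r.food_id,
            "name": r.name,
            "group": r.group,
            "moisture_pct": r.moisture_pct,
            **{k: r.nutrients[k] for k in NUTRIENT_KEYS},
            "source": r.source,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(_FOOD_COLUMNS)).to_csv(path, index=False)


def _menu_cycle_from_dict(state_id: str, node: dict, path: str) -> MenuCycle:
    days = []
    for j, day in enumerate(node.get("days", [])):
        comps = []
        for meal in day.get("meals", []):
            ingredients = [
                MenuIngredient(
                    food_id=str(ing["food_id"]),
                    raw_grams_per_child=float(ing["raw_grams_per_child"]),
                    snp_funded=bool(ing.get("snp_funded", True)),
                )
                for ing in meal.get("ingredients", [])
            ]
            comps.append((meal.get("meal", "other"), meal.get("dish", ""), ingredients))
        days.append(MenuDay(day_label=str(day.get("day_label", f"day{j + 1}")), meal_components=comps))
    if not days:
        raise ValidationError(f"{path}/days", "menu cycle has no days")
    return MenuCycle(
        state_id=state_id,
        anganwadi_id=str(node.get("anganwadi_id", "awc1")),
        days=days,
        cycle_length_days=int(node.get("cycle_length_days", len(days))),
    )


def load_menus(path) -> list[MenuCycle]:
    """Read a menu JSON file: states -> anganwadis -> day plans -> dishes."""
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    cycles: list[MenuCycle] = []
    try:
        for s, state in enumerate(doc["states"]):
            sid = str(state["state_id"])
            for a, awc in enumerate(state["anganwadis"]):
                cycles.append(
                    _menu_cycle_from_dict(sid, awc, f"/states/{s}/anganwadis/{a}")
                )
    except KeyError as e:
        raise ValidationError("/states", f"missing key {e}") from None
    return cycles


def load_menu_cycle(path) -> MenuCycle:
    """Read a menu file expected to contain exactly one anganwadi cycle."""
    cycles = load_menus(path)
    if len(cycles) != 1:
        raise ValidationError("/states", f"expected exactly one menu cycle, found {len(cycles)}")
    return cycles[0]


def write_menus(cycles: Sequence[MenuCycle], path) -> None:
    states: dict[str, list[MenuCycle]] = {}
    for c in cycles:
        states.setdefault(c.state_id, []).append(c)
    doc = {
        "states": [
            {
                "state_id": sid,
                "anganwadis": [
                    {
                        "anganwadi_id": c.anganwadi_id,
                        "cycle_length_days": c.cycle_length_days,
                        "days": [
                            {
                                "day_label": d.day_label,
                                "meals": [
                                    {
                                        "meal": meal,
                                        "dish": dish,
                                        "ingredients": [
                                            {
                                                "food_id": ing.food_id,
                                                "raw_grams_per_child": ing.raw_grams_per_child,
                                                "snp_funded": ing.snp_funded,
                                            }
                                            for ing in ingredients
                                        ],
                                    }
                                    for meal, dish, ingredients in d.meal_components
                                ],
                            }
                            for d in c.days
                        ],
                    }
                    for c in group
                ],
            }
            for sid, group in states.items()
        ]
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


def load_prices(path) -> list[PriceQuote]:
    """Read a vendor-price CSV: food_id, then one column per vendor (rupees/kg)."""
    df = pd.read_csv(path, comment="#", dtype={"food_id": str})
    if "food_id" not in df.columns or df.shape[1] < 2:
        raise ValidationError("/prices/columns", "need food_id plus >=1 vendor column")
    quotes = []
    for i, row in df.iterrows():
        vals = [float(v) for v in row.iloc[1:] if not (isinstance(v, float) and math.isnan(v))]
        quotes.append(PriceQuote(food_id=str(row["food_id"]), vendor_quotes=vals))
    return quotes


def write_prices(quotes: Sequence[PriceQuote], path) -> None:
    n = max(len(q.vendor_quotes) for q in quotes)
    cols = ["food_id"] + [f"vendor{i + 1}" for i in range(n)]
    rows = [
        {"food_id": q.food_id, **{f"vendor{i + 1}": v for i, v in enumerate(q.vendor_quotes)}}
        for q in quotes
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def load_fortifications(path) -> list[FortificationSpec]:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    specs = []
    for i, node in enumerate(doc.get("fortifications", doc if isinstance(doc, list) else [])):
        try:
            specs.append(
                FortificationSpec(
                    vehicle_food_id=str(node["vehicle_food_id"]),
                    additions={k: float(v) for k, v in node["additions"].items()},
                    basis=node.get("basis", "per_100g"),
                    density_g_per_ml=node.get("density_g_per_ml"),
                )
            )
        except KeyError as e:
            raise ValidationError(f"/fortifications/{i}", f"missing key {e}") from None
    return specs


def write_fortifications(specs: Sequence[FortificationSpec], path) -> None:
    doc = {
        "fortifications": [
            {
                "vehicle_food_id": s.vehicle_food_id,
                "additions": s.additions,
                "basis": s.basis,
                **({"density_g_per_ml": s.density_g_per_ml} if s.density_g_per_ml else {}),
            }
            for s in specs
        ]
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


def load_standards(path) -> StandardsConfig:
    """Read a standards JSON config; unknown nutrient keys are refused."""
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    try:
        fat = doc["fat_rule"]
        return StandardsConfig(
            standard_version=doc["standard_version"],
            energy_target_kcal=float(doc["energy_target_kcal"]),
            protein_min_g=float(doc["protein_min_g"]),
            protein_max_g=(None if doc.get("protein_max_g") is None else float(doc["protein_max_g"])),
            fat_rule=FatRule(kind=fat["kind"], lower=float(fat["lower"]), upper=float(fat["upper"])),
            ear_per_day={k: float(v) for k, v in doc["ear_per_day"].items()},
            meal_fraction=float(doc.get("meal_fraction", 1.0 / 3.0)),
            tolerance=float(doc.get("tolerance", 0.10)),
            digestibility_factor=float(doc.get("digestibility_factor", 0.8)),
            fortification_mode=doc.get("fortification_mode", "increment"),
            fat_allowance_two_sided=bool(doc.get("fat_allowance_two_sided", True)),
        )
    except KeyError as e:
        raise ValidationError("/standards", f"missing key {e}") from None


def write_standards(cfg: StandardsConfig, path) -> None:
    doc = {
        "standard_version": cfg.standard_version,
        "energy_target_kcal": cfg.energy_target_kcal,
        "protein_min_g": cfg.protein_min_g,
        "protein_max_g": cfg.protein_max_g,
        "fat_rule": {"kind": cfg.fat_rule.kind, "lower": cfg.fat_rule.lower, "upper": cfg.fat_rule.upper},
        "ear_per_day": cfg.ear_per_day,
        "meal_fraction": cfg.meal_fraction,
        "tolerance": cfg.tolerance,
        "digestibility_factor": cfg.digestibility_factor,
        "fortification_mode": cfg.fortification_mode,
        "fat_allowance_two_sided": cfg.fat_allowance_two_sided,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
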