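"""Per-child daily nutrient provision from menus.

Provision is linear in raw ingredient grams: for nutrient *k* and day *d*,

    totals_k = sum_f grams_f * density_{f,k} / 100

over SNP-funded ingredients, with fortification overlays applied to vehicle
foods first. Food-group decomposition reports the percentage contribution
of each major food group to total energy and protein over a menu cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import (
    FOOD_GROUPS,
    KCAL_PER_G_FAT,
    NUTRIENT_KEYS,
    FoodRecord,
    FortificationSpec,
    MenuCycle,
    MenuDay,
    ValidationError,
)


@dataclass
class DailyProvision:
    """Nutrients provided to one child on one operational day of one anganwadi."""

    state_id: str
    anganwadi_id: str
    day_label: str
    totals: dict[str, float]


@dataclass
class FoodGroupShares:
    """Percent contribution of each food group to cycle energy and protein."""

    energy_share_pct: dict[str, float]
    protein_share_pct: dict[str, float]


def apply_fortification(
    record: FoodRecord, spec: FortificationSpec, mode: str = "increment"
) -> FoodRecord:
    """Overlay a fortification spec on its vehicle food.

    In ``increment`` mode (the Indian fortification-standards "added"
    convention) each addition is added on top of the base density; in
    ``total`` mode the addition is read as the fortified food's total
    content, so the resulting density is max(base, addition). Per-litre
    specs (fortified oil) are converted to per-100 g with the configured
    mass density: ``per_100g = per_litre / 1000 * 100 / density_g_per_ml``.
    """
    if spec.vehicle_food_id != record.food_id:
        raise ValidationError(
            f"/fortifications/{spec.vehicle_food_id}",
            f"spec vehicle does not match food {record.food_id!r}",
        )
    if mode not in ("increment", "total"):
        raise ValidationError("/fortification_mode", f"unknown mode {mode!r}")
    nutrients = dict(record.nutrients)
    for k, amount in spec.additions.items():
        if spec.basis == "per_litre":
            add_per_100g = amount / 1000.0 * 100.0 / spec.density_g_per_ml
        else:
            add_per_100g = amount
        if mode == "increment":
            nutrients[k] = nutrients[k] + add_per_100g
        else:
            nutrients[k] = max(nutrients[k], add_per_100g)
    return replace(record, nutrients=nutrients)


def fortified_table(
    table: Sequence[FoodRecord],
    forts: Sequence[FortificationSpec],
    mode: str = "increment",
) -> dict[str, FoodRecord]:
    """Index the table by food_id with any matching fortification applied."""
    by_id: dict[str, FoodRecord] = {}
    for rec in table:
        by_id[rec.food_id] = rec
    for spec in forts:
        if spec.vehicle_food_id in by_id:
            by_id[spec.vehicle_food_id] = apply_fortification(
                by_id[spec.vehicle_food_id], spec, mode=mode
            )
    return by_id


def day_provision(
    day: MenuDay,
    table: Sequence[FoodRecord] | Mapping[str, FoodRecord],
    forts: Sequence[FortificationSpec] = (),
    include_non_snp: bool = False,
    state_id: str = "",
    anganwadi_id: str = "",
    fortification_mode: str = "increment",
) -> DailyProvision:
    """Sum nutrient totals for one day's SNP-funded ingredients.

    Items flagged as funded by other government initiatives are excluded
    unless ``include_non_snp`` is set. Unresolvable food ids raise an error
    naming every missing id.
    """
    if isinstance(table, Mapping):
        by_id = dict(table)
        for spec in forts:
            if spec.vehicle_food_id in by_id:
                by_id[spec.vehicle_food_id] = apply_fortification(
                    by_id[spec.vehicle_food_id], spec, mode=fortification_mode
                )
    else:
        by_id = fortified_table(table, forts, mode=fortification_mode)
    missing = sorted(
        {ing.food_id for ing in day.iter_ingredients() if ing.food_id not in by_id}
    )
    if missing:
        raise ValidationError(
            f"/days/{day.day_label}", f"unresolvable food ids: {missing}"
        )
    totals = {k: 0.0 for k in NUTRIENT_KEYS}
    for ing in day.iter_ingredients():
        if not ing.snp_funded and not include_non_snp:
            continue
        rec = by_id[ing.food_id]
        for k in NUTRIENT_KEYS:
            totals[k] += ing.raw_grams_per_child * rec.nutrients[k] / 100.0
    return DailyProvision(
        state_id=state_id, anganwadi_id=anganwadi_id, day_label=day.day_label, totals=totals
    )


def cycle_provisions(
    cycle: MenuCycle,
    table: Sequence[FoodRecord],
    forts: Sequence[FortificationSpec] = (),
    include_non_snp: bool = False,
    fortification_mode: str = "increment",
) -> list[DailyProvision]:
    """Per-day provisions for every day of one anganwadi's menu cycle."""
    by_id = fortified_table(table, forts, mode=fortification_mode)
    return [
        day_provision(
            day,
            by_id,
            include_non_snp=include_non_snp,
            state_id=cycle.state_id,
            anganwadi_id=cycle.anganwadi_id,
        )
        for day in cycle.days
    ]


def fat_energy_ratio(p: DailyProvision | Mapping[str, float]) -> float:
    """Percent of energy from fat: 100 * fat_g * 9 kcal/g / energy_kcal."""
    totals = p.totals if isinstance(p, DailyProvision) else p
    energy = totals["energy_kcal"]
    if energy <= 0:
        raise ValidationError("/provision/energy_kcal", "fat-to-energy ratio undefined at zero energy")
    return 100.0 * totals["fat_g"] * KCAL_PER_G_FAT / energy


def food_group_shares(
    days: Iterable[MenuDay],
    table: Sequence[FoodRecord],
    forts: Sequence[FortificationSpec] = (),
    include_non_snp: bool = False,
    fortification_mode: str = "increment",
) -> FoodGroupShares:
    """Percent contribution of each food group to pooled energy and protein.

    Energy and protein are accumulated per group over all days of the cycle
    (cycle-pooled convention) and normalised by the cycle totals.
    """
    by_id = fortified_table(table, forts, mode=fortification_mode)
    energy = {g: 0.0 for g in FOOD_GROUPS}
    protein = {g: 0.0 for g in FOOD_GROUPS}
    for day in days:
        for ing in day.iter_ingredients():
            if not ing.snp_funded and not include_non_snp:
                continue
            if ing.food_id not in by_id:
                raise ValidationError(
                    f"/days/{day.day_label}", f"unresolvable food id {ing.food_id!r}"
                )
            rec = by_id[ing.food_id]
            energy[rec.group] += ing.raw_grams_per_child * rec.nutrients["energy_kcal"] / 100.0
            protein[rec.group] += ing.raw_grams_per_child * rec.nutrients["protein_g"] / 100.0
    total_e = sum(energy.values())
    total_p = sum(protein.values())
    if total_e <= 0:
        raise ValidationError("/days", "total energy is zero; group shares undefined")
    return FoodGroupShares(
        energy_share_pct={g: 100.0 * e / total_e for g, e in energy.items()},
        protein_share_pct={
            g: (100.0 * p / total_p if total_p > 0 else 0.0) for g, p in protein.items()
        },
    )


def provisions_frame(provisions: Sequence[DailyProvision]) -> pd.DataFrame:
    """Tabulate provisions: one row per anganwadi-day, one column per nutrient."""
    rows = [
        {
            "state_id": p.state_id,
            "anganwadi_id": p.anganwadi_id,
            "day_label": p.day_label,
            **p.totals,
        }
        for p in provisions
    ]
    return pd.DataFrame(rows, columns=["state_id", "anganwadi_id", "day_label", *NUTRIENT_KEYS])
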