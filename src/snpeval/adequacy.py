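"""Adequacy scoring of simulated provision against programme standards.

Two layers are kept distinct:

* met / not-met — the programme decision, applying the 10% flexibility
  margin to both macro- and micronutrient floors (energy adequate at
  >= 90% of target, protein at >= 90% of the floor, micronutrients at
  >= 90% of one-third EAR; fat adequate within its band widened by 10%);
* traffic-light status — green >= 90% of requirement, yellow [80, 90)%,
  red < 80%, with an excess rule for energy and fat marking provision
  more than 10% above the recommendation red.

Protein is evaluated twice: on crude grams against the programme floor,
and after multiplying by the digestibility factor (0.8 for predominantly
cereal-based diets) against the same floor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .io import NUTRIENT_KEYS, StandardsConfig, ValidationError
from .simulate import StateNutrientSummary

GREEN, YELLOW, RED = "green", "yellow", "red"


@dataclass
class AdequacyResult:
    """Outcome of one nutrient's evaluation under one standard."""

    nutrient: str
    provision: float
    requirement: float
    pct_of_requirement: float
    status: str
    met: bool
    rule_applied: str


def classify(pct: float, has_upper_rule: bool = False) -> str:
    """Traffic-light banding of percent-of-requirement.

    Green at >= 90% (and <= 110% when the excess rule applies, as for
    energy and fat), yellow on [80, 90), red below 80% or in excess.
    Band edges are half-open: exactly 90 is green, exactly 80 is yellow.
    """
    if pct < 0:
        raise ValidationError("/pct", f"percent must be >= 0, got {pct}")
    if has_upper_rule and pct > 110.0:
        return RED
    if pct >= 90.0:
        return GREEN
    if pct >= 80.0:
        return YELLOW
    return RED


def digestible_protein(crude_g: float, d: float) -> float:
    """Utilisable protein: crude grams times the digestibility factor."""
    if not 0 < d <= 1:
        raise ValidationError("/digestibility_factor", f"must be in (0, 1], got {d}")
    if crude_g < 0:
        raise ValidationError("/protein", f"crude protein must be >= 0, got {crude_g}")
    return crude_g * d


def evaluate_energy(provision_kcal: float, cfg: StandardsConfig) -> AdequacyResult:
    """Energy against the programme target (500 kcal 2012; 400 kcal 2023).

    Adequate at >= 90% of target; status red when more than 10% above it.
    """
    if provision_kcal < 0:
        raise ValidationError("/provision/energy_kcal", "must be >= 0")
    target = cfg.energy_target_kcal
    pct = 100.0 * provision_kcal / target
    return AdequacyResult(
        nutrient="energy_kcal",
        provision=provision_kcal,
        requirement=target,
        pct_of_requirement=pct,
        status=classify(pct, has_upper_rule=True),
        met=provision_kcal >= (1.0 - cfg.tolerance) * target,
        rule_applied="energy_90pct",
    )


def evaluate_protein(
    crude_g: float, cfg: StandardsConfig, apply_digestibility: bool = False
) -> AdequacyResult:
    """Protein against the programme floor (12 g 2012; 15 g 2023).

    With ``apply_digestibility`` the operative value is crude grams times
    the digestibility factor. The floor gets the 10% flexibility margin for
    the met decision; the 2023 upper bound is reported but not a failure.
    """
    value = digestible_protein(crude_g, cfg.digestibility_factor) if apply_digestibility else crude_g
    floor = cfg.protein_min_g
    pct = 100.0 * value / floor
    return AdequacyResult(
        nutrient="protein_g",
        provision=value,
        requirement=floor,
        pct_of_requirement=pct,
        status=classify(pct),
        met=value >= (1.0 - cfg.tolerance) * floor,
        rule_applied="protein_digestible" if apply_digestibility else "protein_floor",
    )


def evaluate_fat(
    fat_g: float, energy_kcal: float, cfg: StandardsConfig
) -> AdequacyResult:
    """Fat against the operative band with the 10% allowance.

    Under the 2012 evaluation the band is the ICMR 25-35% fat-to-energy
    ratio; under 2023 it is an absolute 15-20 g/day band. Percent of
    requirement is taken against the band's lower edge; status is red
    above the allowance-widened upper edge (excess rule).
    """
    rule = cfg.fat_rule
    if rule.kind == "ratio_band":
        if energy_kcal <= 0:
            raise ValidationError(
                "/provision/energy_kcal", "fat-to-energy ratio undefined at zero energy"
            )
        from .engine import fat_energy_ratio

        value = fat_energy_ratio({"fat_g": fat_g, "energy_kcal": energy_kcal})
        tag = "fat_ratio_band"
    else:
        value = fat_g
        tag = "fat_absolute_band"
    lo = rule.lower * (1.0 - cfg.tolerance)
    hi = rule.upper * (1.0 + cfg.tolerance) if cfg.fat_allowance_two_sided else rule.upper
    met = lo <= value <= hi
    pct = 100.0 * value / rule.lower
    if value > hi:
        status = RED
    else:
        status = classify(pct)
    return AdequacyResult(
        nutrient="fat_g",
        provision=value,
        requirement=rule.lower,
        pct_of_requirement=pct,
        status=status,
        met=met,
        rule_applied=tag,
    )


def evaluate_micronutrient(
    provision: float, nutrient: str, cfg: StandardsConfig
) -> AdequacyResult:
    """A micronutrient against meal_fraction (default one-third) of its EAR."""
    if nutrient not in cfg.ear_per_day:
        raise ValidationError(
            f"/standards/ear_per_day/{nutrient}", f"no EAR configured for {nutrient!r}"
        )
    if provision < 0:
        raise ValidationError(f"/provision/{nutrient}", "must be >= 0")
    requirement = cfg.ear_per_day[nutrient] * cfg.meal_fraction
    pct = 100.0 * provision / requirement
    return AdequacyResult(
        nutrient=nutrient,
        provision=provision,
        requirement=requirement,
        pct_of_requirement=pct,
        status=classify(pct),
        met=provision >= (1.0 - cfg.tolerance) * requirement,
        rule_applied="micronutrient_third_ear",
    )


def evaluate_provision(
    totals: dict[str, float], cfg: StandardsConfig
) -> list[AdequacyResult]:
    """Score a raw provision vector (any totals dict) under one standard."""
    results = [
        evaluate_energy(totals["energy_kcal"], cfg),
        evaluate_protein(totals["protein_g"], cfg, apply_digestibility=False),
        evaluate_protein(totals["protein_g"], cfg, apply_digestibility=True),
    ]
    if cfg.fat_rule.kind == "ratio_band" and totals["energy_kcal"] <= 0:
        results.append(
            AdequacyResult(
                nutrient="fat_g", provision=totals["fat_g"], requirement=cfg.fat_rule.lower,
                pct_of_requirement=0.0, status=RED, met=False, rule_applied="fat_ratio_band",
            )
        )
    else:
        results.append(evaluate_fat(totals["fat_g"], totals["energy_kcal"], cfg))
    for k in NUTRIENT_KEYS:
        if k in cfg.ear_per_day:
            results.append(evaluate_micronutrient(totals[k], k, cfg))
    return results


def evaluate_state(summary: StateNutrientSummary, cfg: StandardsConfig) -> list[AdequacyResult]:
    """Score one state's simulated medians under one standard version.

    Adequacy is computed on the simulated median of each nutrient (the
    reported central value); protein appears twice, crude and
    digestibility-adjusted. Running the same summary under the 2012 and
    2023 configs yields two parallel tables.
    """
    totals = {k: summary.nutrients[k].sim_median for k in NUTRIENT_KEYS}
    return evaluate_provision(totals, cfg)


def adequacy_frame(
    summaries: Sequence[StateNutrientSummary], cfg: StandardsConfig
) -> pd.DataFrame:
    """State-by-nutrient adequacy table (median, IQR, percent, status)."""
    rows = []
    for s in summaries:
        for r in evaluate_state(s, cfg):
            nm = s.nutrients[r.nutrient]
            rows.append(
                {
                    "state_id": s.state_id,
                    "standard_version": cfg.standard_version,
                    "nutrient": r.nutrient,
                    "rule_applied": r.rule_applied,
                    "sim_median": nm.sim_median,
                    "sim_q1": nm.sim_q1,
                    "sim_q3": nm.sim_q3,
                    "provision": r.provision,
                    "requirement": r.requirement,
                    "pct_of_requirement": r.pct_of_requirement,
                    "met": r.met,
                    "status": r.status,
                }
            )
    return pd.DataFrame(rows)
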