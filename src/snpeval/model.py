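"""Model/Results interface over the evaluation pipeline.

`SNPMealModel` is constructed from menu cycles, a food-composition table,
fortification specs and a standards configuration; `fit()` computes
per-anganwadi-day provisions, state-wise lognormal moment fits and the
Monte-Carlo provision summaries, returning an `SNPMealResults` that
carries the estimates, the adequacy classification and a text summary
table, with menu optimisation hanging off the results.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from .io import (
    NUTRIENT_KEYS,
    FoodRecord,
    FortificationSpec,
    MenuCycle,
    PriceQuote,
    StandardsConfig,
    ValidationError,
    load_fortifications,
    load_food_table,
    load_menus,
    load_standards,
)
from . import adequacy as adq
from . import engine, lp, simulate


class SNPMealModel:
    """State-wise nutrient-provision model for a supplementary meal programme.

    Parameters
    ----------
    menus
        Menu cycles (one per anganwadi), raw ingredient grams per child.
    food_table
        Food-composition records, densities per 100 g raw food.
    fortifications
        Fortification overlays applied to vehicle foods before provisioning.
    standards
        Evaluation standard; defaults to the 2012 programme standard.
    """

    def __init__(
        self,
        menus: Sequence[MenuCycle],
        food_table: Sequence[FoodRecord],
        fortifications: Sequence[FortificationSpec] = (),
        standards: StandardsConfig | None = None,
    ):
        if not menus:
            raise ValidationError("/model/menus", "at least one menu cycle required")
        self.menus = list(menus)
        self.food_table = list(food_table)
        self.fortifications = list(fortifications)
        self.standards = standards if standards is not None else StandardsConfig.snp2012()

    @classmethod
    def from_files(
        cls,
        menu_path,
        foods_path,
        fortification_path=None,
        standards_path=None,
    ) -> "SNPMealModel":
        return cls(
            menus=load_menus(menu_path),
            food_table=load_food_table(foods_path),
            fortifications=(
                load_fortifications(fortification_path) if fortification_path else ()
            ),
            standards=load_standards(standards_path) if standards_path else None,
        )

    @property
    def state_ids(self) -> list[str]:
        return sorted({c.state_id for c in self.menus})

    def provisions(self, include_non_snp: bool = False) -> list[engine.DailyProvision]:
        out = []
        for cycle in self.menus:
            out.extend(
                engine.cycle_provisions(
                    cycle,
                    self.food_table,
                    self.fortifications,
                    include_non_snp=include_non_snp,
                    fortification_mode=self.standards.fortification_mode,
                )
            )
        return out

    def fit(self, n_draws: int = 1000, seed: int = 0) -> "SNPMealResults":
        """Compute provisions, fit state lognormals, run the simulation."""
        provisions = self.provisions()
        by_state: dict[str, list[engine.DailyProvision]] = {}
        for p in provisions:
            by_state.setdefault(p.state_id, []).append(p)
        summaries = {
            sid: simulate.state_summary(
                by_state[sid], n_draws=n_draws, seed=seed, state_index=i
            )
            for i, sid in enumerate(sorted(by_state))
        }
        return SNPMealResults(self, provisions, summaries, n_draws=n_draws, seed=seed)


class SNPMealResults:
    """Fitted provision distributions, adequacy tables and diagnostics."""

    def __init__(
        self,
        model: SNPMealModel,
        provisions: list[engine.DailyProvision],
        summaries: dict[str, simulate.StateNutrientSummary],
        n_draws: int,
        seed: int,
    ):
        self.model = model
        self.provisions = provisions
        self.summaries = summaries
        self.n_draws = n_draws
        self.seed = seed

    @property
    def provisions_frame(self) -> pd.DataFrame:
        return engine.provisions_frame(self.provisions)

    @property
    def summaries_frame(self) -> pd.DataFrame:
        return simulate.summaries_frame(list(self.summaries.values()))

    def adequacy(self, standards: StandardsConfig | None = None) -> pd.DataFrame:
        """State-by-nutrient adequacy under the given (or model) standard."""
        cfg = standards if standards is not None else self.model.standards
        return adq.adequacy_frame(list(self.summaries.values()), cfg)

    def food_group_shares(self) -> pd.DataFrame:
        """Percent of cycle energy and protein by food group, per state."""
        rows = []
        for sid in sorted({c.state_id for c in self.model.menus}):
            days = [d for c in self.model.menus if c.state_id == sid for d in c.days]
            shares = engine.food_group_shares(
                days, self.model.food_table, self.model.fortifications,
                fortification_mode=self.model.standards.fortification_mode,
            )
            for group in shares.energy_share_pct:
                rows.append(
                    {
                        "state_id": sid,
                        "food_group": group,
                        "energy_share_pct": shares.energy_share_pct[group],
                        "protein_share_pct": shares.protein_share_pct[group],
                    }
                )
        return pd.DataFrame(rows)

    def optimize(
        self,
        prices: Sequence[PriceQuote] | Mapping[str, float],
        state_id: str | None = None,
        mode: str = "additions",
        foods: Sequence[str] | None = None,
        allocation: float = lp.DEFAULT_ALLOCATION,
        standards: StandardsConfig | None = None,
        **kw,
    ) -> lp.LPResult:
        """Minimum-cost menu (or additions to a state's mean daily menu)."""
        cfg = standards if standards is not None else self.model.standards
        table = {r.food_id: r for r in self.model.food_table}
        food_ids = list(foods) if foods is not None else list(table)
        base = None
        if mode == "additions":
            sid = state_id if state_id is not None else self.model.state_ids[0]
            base = mean_daily_grams(self.model.menus, sid)
            food_ids = sorted(set(food_ids) | set(base))
        problem = lp.build_problem(
            [table[f] for f in food_ids],
            prices,
            cfg,
            base_menu=base,
            mode=mode,
            forts=self.model.fortifications,
            allocation=allocation,
            **kw,
        )
        return lp.solve(problem)

    def summary(self, standards: StandardsConfig | None = None) -> str:
        """Human-readable per-state adequacy report (median, IQR, % target)."""
        cfg = standards if standards is not None else self.model.standards
        df = self.adequacy(cfg)
        lines = [
            "SNP meal provision evaluation",
            "=" * 74,
            f"standard: {cfg.standard_version}   states: {len(self.summaries)}   "
            f"anganwadi-days: {len(self.provisions)}",
            f"draws per nutrient: {self.n_draws}   seed: {self.seed}",
            "=" * 74,
        ]
        for sid, sdf in df.groupby("state_id"):
            lines.append(f"\n{sid}")
            lines.append(
                f"  {'nutrient':<22}{'rule':<26}{'median':>9}{'% req':>8}  status"
            )
            for _, r in sdf.iterrows():
                lines.append(
                    f"  {r['nutrient']:<22}{r['rule_applied']:<26}"
                    f"{r['provision']:>9.1f}{r['pct_of_requirement']:>8.1f}  {r['status']}"
                )
        return "\n".join(lines)

    def plot_adequacy(self, standards: StandardsConfig | None = None, ax=None):
        """Bar chart of percent-of-requirement by nutrient and state."""
        import matplotlib.pyplot as plt

        df = self.adequacy(standards)
        df = df[df["rule_applied"] != "protein_floor"]  # keep the digestible arm
        if ax is None:
            _, ax = plt.subplots(figsize=(9, 4))
        colors = {"green": "#2ca02c", "yellow": "#ffbf00", "red": "#d62728"}
        pivot = df.pivot(index="nutrient", columns="state_id", values="pct_of_requirement")
        pivot.plot.bar(ax=ax, legend=True)
        ax.axhline(90, ls="--", lw=1, color=colors["yellow"])
        ax.axhline(110, ls=":", lw=1, color=colors["red"])
        ax.set_ylabel("% of requirement")
        return ax


def mean_daily_grams(menus: Sequence[MenuCycle], state_id: str) -> dict[str, float]:
    """Mean SNP-funded grams per food per day across a state's cycles."""
    cycles = [c for c in menus if c.state_id == state_id]
    if not cycles:
        raise ValidationError("/model/state_id", f"no menus for state {state_id!r}")
    totals: dict[str, float] = {}
    n_days = 0
    for c in cycles:
        n_days += len(c.days)
        for d in c.days:
            for ing in d.iter_ingredients():
                if ing.snp_funded:
                    totals[ing.food_id] = totals.get(ing.food_id, 0.0) + ing.raw_grams_per_child
    return {f: g / n_days for f, g in totals.items()}
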