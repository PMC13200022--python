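# snpeval

Evaluation and linear-programming optimisation of supplementary-nutrition
menus, modelled on India's Integrated Child Development Services (ICDS)
Supplementary Nutrition Programme (SNP): a morning snack and hot cooked
meal served to 3–6 year olds at anganwadi centres, with state-specific
menus, a ₹8 per-child daily allocation, and nutrient standards revised in
2023 (energy 500 → 400 kcal, protein 12 → 15–20 g, a new 15–20 g fat band
and micronutrient benchmarks at one-third of the age-specific Estimated
Average Requirement, EAR).

It is written for nutrition epidemiologists and programme analysts who
need to go from *written menus* (raw ingredient grams per child per day,
over 6–15 day cycles) to *adequacy statements per state* and *cost-optimal
menu improvements*.

## What it computes

1. **Provision.** Per-child daily nutrient totals from menu cycles and a
   food-composition table (10-nutrient panel: energy, protein, fat,
   calcium, iron, zinc, folate, vitamins A, B6, B12; densities per 100 g
   raw food), with fortification overlays (e.g. rice fortified with
   4.25 mg iron, 12.5 µg folic acid and 0.125 µg B12 per 100 g; oil with
   750 µg vitamin A per litre) and exclusion of items funded outside the
   programme.
2. **State distributions.** For each state, the anganwadi-day provisions
   are summarised by mean *m* and variance *v*, matched to a lognormal
   (σ² = ln(1 + v/m²), µ = ln m − σ²/2), and 1000 Monte-Carlo draws give
   the median and inter-quartile range of daily provision.
3. **Adequacy.** The simulated median is scored against the 2012 or 2023
   standards: energy adequate at ≥ 90% of target, protein against the
   programme floor both crude and after a 0.8 digestibility correction,
   fat against the 25–35% fat-to-energy band (2012) or 15–20 g band
   (2023), micronutrients against EAR/3 — all with a 10% flexibility
   margin — plus a green / yellow / red traffic-light classification
   (≥ 90 / 80–90 / < 80% of requirement, red also above 110% for energy
   and fat).
4. **Optimisation.** A diet LP (min Σ p_f x_f s.t. L ≤ N(x + base) ≤ U,
   0 ≤ x ≤ caps, total grams ≤ volume cap) finds minimum-cost menus or
   minimum-cost *additions* to an existing menu, and reports the gap
   versus the ₹8 allocation. A budget-capped goal-programming mode
   minimises nutrient shortfall when the standards are unaffordable.

A seeded synthetic-data module generates food tables, cereal-dominant
menu cycles, vendor prices and fortification specs, so the full pipeline
runs and is tested without any external data.

## Worked example

```python
import snpeval as s

ds = s.gen_dataset(s.SyntheticConfig(seed=42, n_states=2))
model = s.SNPMealModel(ds.cycles, ds.foods, ds.forts)   # defaults to the 2012 standard
results = model.fit(n_draws=1000, seed=42)
print(results.summary())
```

```
SNP meal provision evaluation
==========================================================================
standard: snp2012   states: 2   anganwadi-days: 83
draws per nutrient: 1000   seed: 42
==========================================================================

state01
  nutrient              rule                         median   % req  status
  energy_kcal           energy_90pct                  446.3    89.3  yellow
  protein_g             protein_floor                  11.5    95.7  green
  protein_g             protein_digestible              9.2    76.6  red
  fat_g                 fat_ratio_band                 13.8    55.0  red
  calcium_mg            micronutrient_third_ear        72.8    48.5  red
  iron_mg               micronutrient_third_ear         2.6    99.3  green
  ...
```

state01's meals provide a median 446 kcal — 89.3% of the 500 kcal target,
just under the 90% adequacy line — and protein meets the 12 g floor in
crude terms (95.7%) but not after the 0.8 digestibility correction
(76.6%, red). Fat supplies only 13.8% of energy against the 25–35% band,
and calcium, vitamin A and B12 fall far below one-third of the EAR: the
familiar picture of a cereal-dominated meal. Asking the LP for the
cheapest additions that would fix it:

```python
res = results.optimize(ds.prices, state_id="state01", mode="additions",
                       total_grams_cap=700.0)
print(res.grams, res.total_cost, res.cost_gap)
```

```
additions (g/day): {'amaranth_leaves': 1.1, 'ghee': 4.1, 'milk_powder': 7.5}
cost of additions: Rs 1.09   budget gap vs Rs 8 allocation: 0.00
binding: ['protein_floor_digestible', 'fat_ratio_lower', 'vitamin_a_ug_floor']
```

— a few grams of milk powder, ghee and green leafy vegetables close the
digestible-protein, fat and vitamin-A gaps, with the binding constraints
telling you which targets drove the solution.

The same workflow is available from the shell:

```sh
snp-eval synth --seed 7 --n-states 3 --out-dir fixtures/
snp-eval run --config run.json        # provision -> simulate -> adequacy -> LP
```

## Layout

- `snpeval.io` — domain types, validation, CSV/JSON readers and writers
- `snpeval.engine` — provision arithmetic, fortification, food-group shares
- `snpeval.simulate` — moments, lognormal fits, Monte-Carlo summaries
- `snpeval.adequacy` — standards rules and traffic-light classification
- `snpeval.lp` — diet LP, budget-capped mode, brute-force validation oracle
- `snpeval.synthetic` — seeded generators for every input
- `snpeval.model` — `SNPMealModel` / `SNPMealResults`
- `snpeval.cli` — `snp-eval` subcommands and the end-to-end pipeline

See `docs/methods.md` for the statistical model, parameter choices and
limitations.
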