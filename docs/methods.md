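# Methods

## Scope and model

The package treats a public feeding programme's menus as a deterministic
linear map from raw ingredient grams to nutrients, a stochastic model of
between-day/centre variability, a rule-based adequacy layer, and a diet
linear program. Each layer is described below with its assumptions and
the choices that were genuinely open.

### Provision

For food *f* with nutrient density n_{f,k} per 100 g raw food and a day's
ingredient grams g_f per child, provision is

    T_k = Σ_f g_f · n_{f,k} / 100.

Quantities are raw (as-purchased) grams; cooking yields and retention
factors are out of scope, as is any bioavailability modelling beyond the
protein digestibility scalar. Ingredients funded by other schemes are
excluded from programme totals (they carry an `snp_funded=false` flag and
every exclusion is counted in the pipeline log). Days on which no
programme food is served yield an all-zero provision and are kept: they
are real operational days and contribute to state variance.

Fortification is an overlay on the vehicle food's densities. Additions
are interpreted as **increments** over the unfortified base, matching the
"added amount" convention of fortification standards; a
`fortification_mode="total"` switch reads them as total fortified content
(density becomes max(base, addition)) for tables quoted that way.
Per-litre specifications (fortified oil) convert to per-100 g through a
configurable mass density, default 0.92 g/ml for edible oil:
per_100g = per_litre / 1000 × 100 / density.

Food-group shares (percent of energy and of protein by group) are
**cycle-pooled**: group totals are accumulated over all days of a cycle
(or state) and normalised once, rather than computed per day and
averaged. With near-constant day totals the two conventions agree; the
pooled form is well-defined even when single days are degenerate.

### State provision distributions

The observation unit is one anganwadi-day provision, pooled across a
state's surveyed centres. Per state and nutrient the sample mean m and
unbiased variance v (n−1 denominator; v = 0 when n = 1) are matched to a
lognormal by method of moments:

    σ² = ln(1 + v/m²),   µ = ln m − σ²/2,

so the fitted distribution reproduces (m, v) exactly (the fit is tested
to round-trip to 1e-9). The lognormal is the conventional choice for
intake-like quantities: positive support and right skew. Moment matching
(not maximum likelihood) is used because the distribution is defined
from summary moments, not from a likelihood over raw days.

1000 Monte-Carlo draws per nutrient and state (the reporting convention
this pipeline follows) give the median and inter-quartile range used in
all downstream reporting. Numerical conventions, fixed because software
defaults differ:

- quartiles use linear interpolation between order statistics
  (`numpy.percentile(..., method="linear")`);
- each (state, nutrient) pair draws from an independent substream spawned
  from `(seed, state_index, nutrient_index)` with states in sorted order,
  so results are order-independent and fully reproducible from one seed;
- v = 0 gives a point mass at m (σ = 0), not an error;
- a nutrient never provided (m = 0) is reported as zero provision and not
  simulated.

No within-person/between-person variance decomposition ("usual intake"
deattenuation) is attempted; the simulation describes provision
variability, not individual intake.

### Adequacy

Two distinct layers:

**Met / not-met** applies a 10% flexibility margin (the `tolerance`
parameter) to the floors: energy adequate at ≥ 90% of the target
(500 kcal under the 2012 standard, 400 kcal under 2023), protein at
≥ 90% of the floor (12 g; 15 g under 2023 — the 20 g upper bound is
reported, not failed), micronutrients at ≥ 90% of `meal_fraction` × EAR
(meal_fraction defaults to 1/3: the programme meals are expected to cover
a third of daily needs). Fat is a band — 25–35% of energy (2012, using
the 9 kcal/g Atwater factor) or 15–20 g/day (2023) — widened by the
margin on **both** edges by default (22.5–38.5% of energy); a
`fat_allowance_two_sided=False` switch applies it to the lower edge only,
since which reading is intended is ambiguous.

**Traffic light** uses percent-of-requirement bands: green ≥ 90%, yellow
[80, 90), red < 80, with band edges half-open (exactly 90 is green). For
energy and fat an excess rule marks provision more than 10% above the
recommendation red. For fat the percent is taken against the band's lower
edge, so the colour grades shortfall; excess is caught by the band's own
upper rule.

Protein is evaluated twice: crude, and multiplied by the digestibility
factor d = 0.8 recommended for predominantly cereal-based diets
(`digestibility_factor`, configurable in (0, 1]).

Adequacy is computed on the **simulated median** (the reported central
value); `evaluate_provision` scores any raw provision vector directly
when that is wanted.

The shipped default EAR table for 3–6 y (calcium 450 mg, iron 8 mg, zinc
4 mg, folate 100 µg, vitamin A 280 µg, B6 0.8 mg, B12 1 µg per day) is a
synthetic illustration of realistic magnitude. Real analyses should
supply the authoritative age-specific EARs in the standards config; the
loader refuses unknown nutrient keys.

### Linear programming

The diet problem: minimise Σ p_f x_f over gram vectors x subject to
nutrient bounds, per-food portion caps, and a total-grams cap (default
350 g/day) standing in for young children's limited gastric capacity.
Bounds derive from the standards via the adequacy rules: energy is a
**band** (0.9–1.1 × target by default — excess energy is a concern, not
just shortfall), protein a floor on digestibility-weighted protein
(selectable), fat its band (the 2012 ratio band is linearised as
9·fat − (r/100)·energy ≷ 0 rows), micronutrients floors only. Prices are
the arithmetic mean of vendor quotes, ₹/kg converted to ₹/g internally.

The budget (₹8/child/day allocation) is **not** a hard constraint in the
primary mode: the optimal cost is compared with it post hoc
(`cost_gap = max(0, cost − B)`), reflecting that adequate menus can and
do exceed the allocation. A budget-capped goal-programming mode
(`solve_budget_capped`) minimises the sum of relative shortfalls subject
to cost ≤ B (with a 1e-6-weighted cost term so ties resolve to the
cheapest adequate menu) for "best feasible" planning.

In **additions mode** the existing menu enters as a fixed contribution
and the variables are increments; a base menu already meeting all targets
admits the zero addition at cost 0. Note that additions cannot *remove*
food: a state already above the energy ceiling is correctly reported
infeasible in this mode.

Solved with HiGHS (`scipy.optimize.linprog`); variables are continuous
grams (no integer portions). Every reported optimum is re-verified
against the constraints to 1e-6 independently of the solver's status; a
solver failure returns an explicit non-optimal status. A brute-force grid
oracle (≤ 4 foods, finite caps) validates the LP in tests: for floor-only
problems with grid-aligned caps, rounding the LP optimum up to the grid
stays feasible, so oracle cost − LP cost ∈ [0, Σ_f p_f · step].

## Synthetic data

The generator emulates the structural features of anganwadi meal data:
20–40 foods across all 13 food groups with densities drawn from
documented per-group plausibility ranges (synthetic stand-ins, not values
from any published composition table); 6–15-day cycles with 4 anganwadis
per state; a rice/lentil/oil hot cooked meal and a cereal morning snack
with intermittent milk, egg and vegetables; three vendor quotes per food
from per-group retail ranges; fortified rice and oil (as dedicated
vehicle foods) in a configurable fraction of states; occasional
non-programme items to exercise the exclusion path.

The `cereal_heavy` profile draws a per-state target cereal energy share
inside the 38–77% band and rescales cereal and non-cereal grams to hit it
exactly while preserving total energy; a per-state portion scale
(0.7–1.3) spreads state means from well below to well above the energy
standard. The `adequate` profile solves the internal LP at **full**
targets (tolerance 0, energy band [1.0, 1.1] × target) and serves the
optimal menu every day, guaranteeing an all-green state at/above 100% of
every requirement. All generation is deterministic from the single seed
via spawned substreams.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: correlated day-to-day menus (festival or
seasonal patterns), measurement error in portion estimation, within-state
price heterogeneity, recipe-level cooking transformations, and any
resemblance to a specific state's actual menus. Tests demonstrate the
pipeline's arithmetic, statistical conventions and optimisation are
correct, not that any real state has any particular adequacy profile.

## Problem sizes

Default test and pipeline sizes are deliberately desk-scale: 3–6 states ×
4 anganwadis × 6–15 days (≈ 100–300 anganwadi-day observations), 1000
draws per nutrient, LP problems of ≤ 30 foods × ~10 constraint rows, and
oracle grids of ≤ 21³ points. Parameter-recovery checks use 10⁴-day
series; Monte-Carlo consistency checks 10⁵ draws.

## Known limitations

- Adequacy on the median ignores the spread the simulation produces; a
  full probability-of-adequacy (EAR cut-point prevalence over draws) is
  not implemented.
- The lognormal is fitted per nutrient independently; cross-nutrient
  correlation (meals high in energy are high in everything) is not
  simulated, so joint statements across nutrients are not supported.
- The digestibility scalar applies to total protein, not per-food protein
  quality (no amino-acid scoring).
- Additions-mode LP cannot reduce any nutrient, so over-provided states
  are infeasible rather than "re-balanced"; full-mode redesign is the
  tool for those.
- Prices are static means; procurement variability and seasonality are
  out of scope.
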