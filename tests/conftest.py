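import numpy as np
import pytest

from snpeval import (
    FoodRecord,
    FortificationSpec,
    MenuDay,
    MenuIngredient,
    MenuCycle,
    StandardsConfig,
    SyntheticConfig,
    gen_dataset,
)


@pytest.fixture
def rice():
    return FoodRecord(
        food_id="rice",
        name="Raw rice",
        group="cereals_millets",
        moisture_pct=11.0,
        nutrients={
            "energy_kcal": 345.0, "protein_g": 7.0, "fat_g": 0.5,
            "calcium_mg": 10.0, "iron_mg": 0.65, "zinc_mg": 1.2,
            "folate_ug": 9.0, "vitamin_a_ug": 0.0, "vitamin_b6_mg": 0.12,
            "vitamin_b12_ug": 0.0,
        },
        source="ifct",
    )


@pytest.fixture
def lentil():
    return FoodRecord(
        food_id="lentil",
        name="Red lentil",
        group="pulses_legumes",
        moisture_pct=10.0,
        nutrients={
            "energy_kcal": 330.0, "protein_g": 24.0, "fat_g": 1.0,
            "calcium_mg": 60.0, "iron_mg": 7.0, "zinc_mg": 3.3,
            "folate_ug": 180.0, "vitamin_a_ug": 2.0, "vitamin_b6_mg": 0.5,
            "vitamin_b12_ug": 0.0,
        },
        source="ifct",
    )


@pytest.fixture
def oil():
    return FoodRecord(
        food_id="oil",
        name="Edible oil",
        group="oils_fats",
        moisture_pct=0.1,
        nutrients={"energy_kcal": 890.0, "fat_g": 100.0},
        source="ifct",
    )


@pytest.fixture
def small_table(rice, lentil, oil):
    return [rice, lentil, oil]


@pytest.fixture
def simple_day():
    """80 g rice + 20 g lentil + 5 g oil, all SNP-funded."""
    return MenuDay(
        day_label="day1",
        meal_components=[
            (
                "hot_cooked_meal",
                "khichdi",
                [
                    MenuIngredient("rice", 80.0),
                    MenuIngredient("lentil", 20.0),
                    MenuIngredient("oil", 5.0),
                ],
            )
        ],
    )


@pytest.fixture
def simple_cycle(simple_day):
    return MenuCycle(state_id="st1", anganwadi_id="awc1", days=[simple_day])


@pytest.fixture
def rice_fortification():
    return FortificationSpec(
        vehicle_food_id="rice",
        additions={"iron_mg": 4.25, "folate_ug": 12.5, "vitamin_b12_ug": 0.125},
    )


@pytest.fixture
def oil_fortification():
    return FortificationSpec(
        vehicle_food_id="oil",
        additions={"vitamin_a_ug": 750.0},
        basis="per_litre",
        density_g_per_ml=0.92,
    )


@pytest.fixture
def snp2012():
    return StandardsConfig.snp2012()


@pytest.fixture
def snp2023():
    return StandardsConfig.snp2023()


@pytest.fixture(scope="session")
def dataset():
    """A 3-state cereal-heavy synthetic dataset shared across tests."""
    return gen_dataset(SyntheticConfig(seed=20220801, n_states=3))


def random_floor_problem(rng: np.random.Generator, n_foods: int):
    """A random feasible floor-only diet LP for oracle/monotonicity checks.

    Lower bounds are set at what a random interior point achieves, so the
    problem is feasible by construction; caps are grid-aligned.
    """
    from snpeval.lp import LPProblem

    n_rows = int(rng.integers(2, 5))
    A = rng.uniform(0.1, 2.0, size=(n_rows, n_foods))
    caps = np.full(n_foods, 200.0)
    x0 = rng.uniform(20.0, 120.0, size=n_foods)
    lb = A @ x0
    return LPProblem(
        food_ids=[f"f{i}" for i in range(n_foods)],
        densities=np.zeros((n_foods, 10)),
        prices_per_g=rng.uniform(0.005, 0.05, size=n_foods),
        constraint_names=[f"row{r}" for r in range(n_rows)],
        A=A,
        lb=lb,
        ub=np.full(n_rows, np.inf),
        portion_caps=caps,
        total_grams_cap=None,
    )
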