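import pytest

from dietopt.foods import BaselineDiet, FoodDatabase, FoodItem, NutrientDef
from dietopt.requirements import NutrientBounds, RequirementSet
from dietopt.synthetic import SynthSpec, generate


def make_food(food_id, group="grain_foods", serving=100.0, composition=None,
              price=1.0, ghge=1.0, bioavailability=None, subgroup="sub0"):
    return FoodItem(
        food_id=food_id,
        name=food_id,
        group=group,
        subgroup=subgroup,
        serving_size_g=serving,
        composition=composition or {},
        bioavailability=bioavailability or {},
        ghge_per_kg=ghge,
        price_per_kg=price,
    )


def make_db(foods, nutrient_ids=None):
    if nutrient_ids is None:
        nutrient_ids = sorted({n for f in foods for n in f.composition})
    nutrients = {
        nid: NutrientDef(nutrient_id=nid, display_name=nid, unit="g")
        for nid in nutrient_ids
    }
    return FoodDatabase(nutrients=nutrients, foods={f.food_id: f for f in foods})


@pytest.fixture
def simple_db():
    """Four foods, three nutrients, integer-friendly coefficients."""
    return make_db([
        make_food("bread", "grain_foods", serving=100.0,
                  composition={"n1": 10.0, "n2": 2.0, "n3": 0.0},
                  price=2.0, ghge=1.0),
        make_food("milk", "dairy", serving=250.0,
                  composition={"n1": 4.0, "n2": 12.0, "n3": 1.0},
                  price=3.0, ghge=2.0),
        make_food("beef", "mspe", serving=200.0,
                  composition={"n1": 20.0, "n2": 1.0, "n3": 2.0},
                  price=15.0, ghge=25.0),
        make_food("beer", "alcoholic_beverages", serving=330.0,
                  composition={"n1": 0.5, "n2": 0.1, "n3": 0.0},
                  price=6.0, ghge=1.5),
    ])


@pytest.fixture
def simple_baseline():
    return BaselineDiet(
        demographic_label="female",
        servings={"bread": 7.0, "milk": 7.0, "beef": 4.0, "beer": 3.0},
    )


@pytest.fixture
def simple_requirements():
    return RequirementSet(
        sex="female",
        age_group="19-30",
        bounds={
            "n1": NutrientBounds(lower=10.0, upper=None),
            "n2": NutrientBounds(lower=5.0, upper=60.0),
            "n3": NutrientBounds(lower=None, upper=10.0),
        },
    )


SMALL_SPEC = dict(
    n_foods_per_group={"grain_foods": 2, "dairy": 1, "mspe": 1,
                       "alcoholic_beverages": 1},
    n_nutrients=4,
    planted_max_servings=2,
)


@pytest.fixture(scope="session")
def default_bundle():
    return generate(SynthSpec(seed=42))


@pytest.fixture(scope="session")
def small_bundle():
    return generate(SynthSpec(seed=7, **SMALL_SPEC))
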