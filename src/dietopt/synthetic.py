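"""Seeded synthetic food databases, baselines, and requirement sets.

Feasibility is controlled by construction: a known integer diet is planted
first and nutrient bounds are derived from its supply, so
``feasibility="guaranteed"`` specs carry a feasibility certificate at any
size.  Outputs serialise through the :mod:`dietopt.foods` readers
(round-trip guaranteed), which makes every other module testable offline.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .foods import (
    FOOD_GROUPS,
    BaselineDiet,
    FoodDatabase,
    FoodItem,
    NutrientDef,
    load_baseline,
    load_food_database,
)
from .optimise import evaluate_diet
from .requirements import (
    AGE_GROUPS,
    SEXES,
    NutrientBounds,
    RequirementSet,
    dump_requirement_sets,
)


def _default_group_counts() -> dict[str, int]:
    return {
        "fruits_vegetables": 4,
        "grain_foods": 4,
        "legumes_nuts_seeds": 3,
        "mspe": 4,
        "dairy": 3,
        "dairy_alternatives": 2,
        "discretionary": 2,
        "fats_oils": 2,
        "miscellaneous": 1,
        "non_alcoholic_beverages": 2,
        "alcoholic_beverages": 2,
    }


def _default_price_mult() -> dict[str, float]:
    # grains cheap, animal-sourced foods and dairy alternatives dear
    return {
        "grain_foods": 0.5,
        "legumes_nuts_seeds": 0.8,
        "mspe": 2.5,
        "dairy": 1.2,
        "dairy_alternatives": 1.8,
        "alcoholic_beverages": 2.0,
    }


def _default_ghge_mult() -> dict[str, float]:
    # animal-sourced foods emission-heavy, plants light
    return {
        "mspe": 4.0,
        "dairy": 2.0,
        "grain_foods": 0.5,
        "legumes_nuts_seeds": 0.4,
        "fruits_vegetables": 0.7,
    }


FEASIBILITY_MODES = ("guaranteed", "infeasible", "random")


@dataclass
class SynthSpec:
    """Parameters of one synthetic fixture.  Same spec + seed = same output."""

    n_foods_per_group: dict[str, int] = field(default_factory=_default_group_counts)
    n_nutrients: int = 8
    seed: int = 0
    feasibility: str = "guaranteed"
    infeasible_on: str | None = None
    price_ghge_correlation: float = 0.5
    fortified_fraction: float = 0.0
    fortified_multiplier: float = 10.0
    planted_max_servings: int = 5
    baseline_scale: int = 2
    serving_ceiling: int = 200
    #: derive bounds from the baseline itself so the baseline diet audits
    #: adequate (used for zero-deviation fixtures); incompatible with the
    #: battery's alcohol exclusion, see module docs.
    adequate_baseline: bool = False
    lower_fraction_range: tuple[float, float] = (0.55, 0.85)
    # uppers sit between 1x and 2x the planted supply, so the planted diet
    # stays feasible while the scaled baseline typically violates some of
    # them and minimum-deviation solutions are genuinely constrained
    upper_fraction_range: tuple[float, float] = (1.3, 2.0)
    random_lower_range: tuple[float, float] = (0.5, 1.6)
    random_upper_range: tuple[float, float] = (1.2, 3.0)
    group_price_mult: dict[str, float] = field(default_factory=_default_price_mult)
    group_ghge_mult: dict[str, float] = field(default_factory=_default_ghge_mult)
    protein_bioavailability_range: tuple[float, float] = (0.6, 0.95)

    def __post_init__(self):
        if self.feasibility not in FEASIBILITY_MODES:
            raise ConfigError(f"feasibility {self.feasibility!r} not in {FEASIBILITY_MODES}")
        if self.feasibility == "guaranteed" and self.infeasible_on is not None:
            raise ConfigError("contradictory spec: guaranteed feasibility with infeasible_on")
        if self.feasibility == "infeasible" and self.infeasible_on is None:
            raise ConfigError("feasibility='infeasible' requires infeasible_on")
        for g, n in self.n_foods_per_group.items():
            if g not in FOOD_GROUPS:
                raise ConfigError(f"unknown food group {g!r}")
            if n < 1:
                raise ConfigError(f"group {g!r}: count must be >= 1, got {n}")
        if not -1.0 <= self.price_ghge_correlation <= 1.0:
            raise ConfigError("price_ghge_correlation must be in [-1, 1]")
        if not 0.0 <= self.fortified_fraction <= 1.0:
            raise ConfigError("fortified_fraction must be in [0, 1]")
        if self.planted_max_servings < 1 or self.baseline_scale < 1:
            raise ConfigError("planted_max_servings and baseline_scale must be >= 1")

    def nutrient_ids(self) -> list[str]:
        if self.n_nutrients < 1:
            raise ConfigError("n_nutrients must be >= 1")
        ids = ["protein"]
        ids += [f"nutr{k:02d}" for k in range(1, self.n_nutrients)]
        return ids


@dataclass
class SynthBundle:
    """A generated fixture: database, baselines, requirement sets, and the
    planted feasibility certificates (integer diets per sex)."""

    spec: SynthSpec
    db: FoodDatabase
    baselines: dict[str, BaselineDiet]
    requirement_sets: dict[tuple[str, str], RequirementSet]
    planted: dict[str, dict[str, int]]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        return write_fixture(self, out_dir)


def generate(spec: SynthSpec) -> SynthBundle:
    """Generate a seeded synthetic fixture with controlled feasibility.

    ``guaranteed``: an integer diet is planted per sex and every (sex, age
    group) bound set is derived from its absorbable weekly supply (lower
    strictly below, upper strictly above), so a feasible serving vector
    exists within the ceilings for every scenario.  ``infeasible``: the
    lower bound for ``infeasible_on`` is set above the maximum attainable
    supply under the serving ceiling.  ``random``: bound fractions straddle
    1, so feasibility is genuinely uncertain.
    """
    rng = np.random.default_rng(spec.seed)
    nutrient_ids = spec.nutrient_ids()

    nutrients = {}
    for k, nid in enumerate(nutrient_ids):
        bound_kind = "lower" if nid == "protein" or k % 2 == 1 else "both"
        nutrients[nid] = NutrientDef(
            nutrient_id=nid, display_name=nid, unit="g", bound_kind=bound_kind
        )

    # per-nutrient base density scale, then group-level means, then per-food noise
    base_scale = {
        nid: (8.0 if nid == "protein" else float(np.exp(rng.normal(math.log(4.0), 0.8))))
        for nid in nutrient_ids
    }

    foods: dict[str, FoodItem] = {}
    rho = spec.price_ghge_correlation
    for group in FOOD_GROUPS:
        count = spec.n_foods_per_group.get(group, 0)
        if count == 0:
            continue
        group_mean = {
            nid: base_scale[nid] * float(np.exp(rng.normal(0.0, 0.5)))
            for nid in nutrient_ids
        }
        p_mult = spec.group_price_mult.get(group, 1.0)
        g_mult = spec.group_ghge_mult.get(group, 1.0)
        for i in range(count):
            fid = f"{group}_{i:02d}"
            serving = float(rng.integers(30, 301))
            composition = {
                nid: group_mean[nid] * float(np.exp(rng.normal(0.0, 0.3)))
                for nid in nutrient_ids
            }
            z1 = rng.standard_normal()
            z2 = rho * z1 + math.sqrt(max(0.0, 1.0 - rho * rho)) * rng.standard_normal()
            price = p_mult * float(np.exp(math.log(6.0) + 0.4 * z1))
            ghge = g_mult * float(np.exp(math.log(2.0) + 0.5 * z2))
            lo, hi = spec.protein_bioavailability_range
            bio = {"protein": float(rng.uniform(lo, hi))}
            foods[fid] = FoodItem(
                food_id=fid,
                name=fid.replace("_", " "),
                group=group,
                subgroup=f"{group}_sub{i % 2}",
                serving_size_g=serving,
                composition=composition,
                bioavailability=bio,
                ghge_per_kg=ghge,
                price_per_kg=price,
            )

    db = FoodDatabase(nutrients=nutrients, foods=foods)

    if spec.fortified_fraction > 0:
        n_fortify = max(1, round(spec.fortified_fraction * len(foods)))
        candidates = sorted(fid for fid in foods if foods[fid].group != "alcoholic_beverages")
        chosen = rng.choice(candidates, size=min(n_fortify, len(candidates)), replace=False)
        for fid in chosen:
            nid = str(rng.choice(nutrient_ids))
            db = plant_fortified_food(db, nid, spec.fortified_multiplier, food_id=str(fid))

    non_alcohol = [fid for fid in db.food_ids()
                   if db.foods[fid].group != "alcoholic_beverages"]
    alcohol = [fid for fid in db.food_ids()
               if db.foods[fid].group == "alcoholic_beverages"]

    baselines: dict[str, BaselineDiet] = {}
    planted: dict[str, dict[str, int]] = {}
    requirement_sets: dict[tuple[str, str], RequirementSet] = {}

    for sex in SEXES:
        by_group: dict[str, list[str]] = {}
        for fid in non_alcohol:
            by_group.setdefault(db.foods[fid].group, []).append(fid)
        plant: dict[str, int] = {}
        for group, fids in sorted(by_group.items()):
            n_pick = max(1, (len(fids) + 1) // 2)
            picked = rng.choice(sorted(fids), size=n_pick, replace=False)
            for fid in picked:
                plant[str(fid)] = int(rng.integers(1, spec.planted_max_servings + 1))
        planted[sex] = plant

        base: dict[str, float] = {
            fid: float(spec.baseline_scale * s) for fid, s in plant.items()
        }
        leftovers = sorted(set(non_alcohol) - set(plant))
        if leftovers:
            n_extra = max(1, len(leftovers) // 4)
            for fid in rng.choice(leftovers, size=min(n_extra, len(leftovers)), replace=False):
                base[str(fid)] = 1.0
        for fid in alcohol:
            base[fid] = float(rng.integers(1, 4))
        baselines[sex] = BaselineDiet(demographic_label=sex, servings=base)

        ref_supply = evaluate_diet(db, plant).supply
        if spec.adequate_baseline:
            ref_supply = evaluate_diet(db, base).supply

        for age in AGE_GROUPS:
            bounds: dict[str, NutrientBounds] = {}
            for nid in nutrient_ids:
                s = ref_supply.get(nid, 0.0)
                if s <= 0:
                    continue
                if spec.feasibility == "random":
                    f_lo = rng.uniform(*spec.random_lower_range)
                    f_up = rng.uniform(*spec.random_upper_range)
                elif spec.adequate_baseline:
                    f_lo = rng.uniform(*spec.lower_fraction_range)
                    f_up = rng.uniform(1.5, 3.0)
                else:
                    f_lo = rng.uniform(*spec.lower_fraction_range)
                    f_up = rng.uniform(*spec.upper_fraction_range)
                kind = nutrients[nid].bound_kind
                lower = s * f_lo / 7.0 if kind in ("lower", "both") else None
                upper = s * f_up / 7.0 if kind in ("upper", "both") else None
                if lower is not None and upper is not None and lower > upper:
                    lower, upper = upper, lower
                bounds[nid] = NutrientBounds(lower=lower, upper=upper)
            if spec.feasibility == "infeasible":
                nid = spec.infeasible_on
                if nid not in nutrient_ids:
                    raise ConfigError(f"infeasible_on nutrient {nid!r} not generated")
                ceiling_diet = {fid: float(spec.serving_ceiling) for fid in db.food_ids()}
                max_supply = evaluate_diet(db, ceiling_diet).supply[nid]
                bounds[nid] = NutrientBounds(lower=2.0 * max_supply / 7.0, upper=None)
            requirement_sets[(sex, age)] = RequirementSet(
                sex=sex, age_group=age, bounds=bounds
            )

    return SynthBundle(
        spec=spec,
        db=db,
        baselines=baselines,
        requirement_sets=requirement_sets,
        planted=planted,
    )


def plant_fortified_food(
    db: FoodDatabase,
    nutrient_id: str,
    density_multiplier: float,
    food_id: str | None = None,
) -> FoodDatabase:
    """Return a copy of the database with one food's nutrient density scaled.

    With no ``food_id`` given, the food with the highest existing density of
    the nutrient is chosen (deterministic).  A multiplier of 1 is the
    identity; 0 zeroes the density.
    """
    known = set(db.nutrients)
    for food in db.foods.values():
        known.update(food.composition)
    if nutrient_id not in known:
        raise ConfigError(f"unknown nutrient {nutrient_id!r}")
    if density_multiplier < 0:
        raise ValidationError(f"negative density multiplier {density_multiplier}")
    if food_id is None:
        food_id = max(
            db.food_ids(), key=lambda f: db.foods[f].composition.get(nutrient_id, 0.0)
        )
    elif food_id not in db.foods:
        raise ConfigError(f"unknown food {food_id!r}")
    new_db = copy.deepcopy(db)
    food = new_db.foods[food_id]
    food.composition[nutrient_id] = (
        food.composition.get(nutrient_id, 0.0) * density_multiplier
    )
    return new_db


# ---------------------------------------------------------------------------
# Fixture serialisation (delimited text, round-trips through foods readers)
# ---------------------------------------------------------------------------

def write_fixture(bundle: SynthBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write the fixture as the delimited-text schemas of :mod:`dietopt.foods`.

    Returns a name → path map.  Output is deterministic for a fixed spec.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    db = bundle.db
    food_ids = db.food_ids()
    nutrient_ids = db.nutrient_ids()

    comp = pd.DataFrame(
        [
            {"food_id": fid, **{nid: db.foods[fid].composition.get(nid, 0.0)
                                for nid in nutrient_ids}}
            for fid in food_ids
        ]
    )
    # two store observations per food, both at the same per-kg price so the
    # averaged price reproduces the generated value exactly
    price_rows = []
    for fid in food_ids:
        p = db.foods[fid].price_per_kg
        price_rows.append({"food_id": fid, "store_label": "store_a",
                           "price": p, "package_mass_g": 1000.0})
        price_rows.append({"food_id": fid, "store_label": "store_b",
                           "price": p / 2.0, "package_mass_g": 500.0})
    prices = pd.DataFrame(price_rows)
    ghge = pd.DataFrame(
        [{"food_id": fid, "kg_co2e_per_kg": db.foods[fid].ghge_per_kg} for fid in food_ids]
    )
    servings = pd.DataFrame(
        [
            {
                "food_id": fid,
                "serving_size_g": db.foods[fid].serving_size_g,
                "group": db.foods[fid].group,
                "subgroup": db.foods[fid].subgroup,
            }
            for fid in food_ids
        ]
    )
    nutrients = pd.DataFrame(
        [
            {
                "nutrient_id": nid,
                "display_name": db.nutrients[nid].display_name,
                "unit": db.nutrients[nid].unit,
                "bound_kind": db.nutrients[nid].bound_kind,
            }
            for nid in nutrient_ids
        ]
    )
    bio_rows = []
    for fid in food_ids:
        for nid in sorted(db.foods[fid].bioavailability):
            bio_rows.append({
                "food_id": fid,
                "nutrient_id": nid,
                "coefficient": db.foods[fid].bioavailability[nid],
            })
    bio = pd.DataFrame(bio_rows)

    paths = {}
    for name, frame in [
        ("compositions", comp),
        ("prices", prices),
        ("ghge", ghge),
        ("servings", servings),
        ("nutrients", nutrients),
        ("bioavailability", bio),
    ]:
        path = out / f"{name}.csv"
        frame.to_csv(path, index=False, float_format="%.17g")
        paths[name] = path

    for sex, baseline in sorted(bundle.baselines.items()):
        frame = pd.DataFrame(
            [
                {"food_id": fid, "weekly_servings": baseline.servings[fid]}
                for fid in sorted(baseline.servings)
            ]
        )
        path = out / f"baseline_{sex}.csv"
        frame.to_csv(path, index=False, float_format="%.17g")
        paths[f"baseline_{sex}"] = path

    req_path = out / "requirements.yaml"
    req_path.write_text(dump_requirement_sets(bundle.requirement_sets), encoding="utf-8")
    paths["requirements"] = req_path
    return paths


def load_fixture(fixture_dir: str | Path):
    """Load a written fixture back through the standard readers."""
    from .requirements import load_requirement_sets

    d = Path(fixture_dir)
    db, report = load_food_database(
        d / "compositions.csv",
        d / "prices.csv",
        d / "ghge.csv",
        d / "servings.csv",
        nutrients_path=d / "nutrients.csv",
        bioavailability_path=d / "bioavailability.csv",
    )
    baselines = {}
    for sex in SEXES:
        path = d / f"baseline_{sex}.csv"
        if path.exists():
            baselines[sex] = load_baseline(path, sex, db)
    sets = load_requirement_sets(d / "requirements.yaml")
    return db, report, baselines, sets
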