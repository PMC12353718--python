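import math

import numpy as np
import pytest

from dietopt.errors import (
    ConfigError,
    EnumerationBudgetError,
    SolverError,
    ValidationError,
)
from dietopt.foods import BaselineDiet
from dietopt.optimise import (
    CapSpec,
    DecisionSpec,
    ObjectiveSpec,
    brute_force_optimum,
    build_model,
    deviation_l1,
    evaluate_diet,
    food_weekly_amount,
    solve_model,
)
from dietopt.requirements import NutrientBounds, WeeklyBounds
from dietopt.synthetic import SynthSpec, generate

from conftest import make_db, make_food


def wb(**bounds):
    return WeeklyBounds(bounds={
        nid: NutrientBounds(lower=b[0], upper=b[1]) for nid, b in bounds.items()
    })


class TestFoodWeeklyAmount:
    def test_calcium_example(self):
        food = make_food("milk", "dairy", serving=250.0, composition={"ca": 120.0})
        assert food_weekly_amount(food, 7, "ca") == pytest.approx(2100.0)

    def test_zero_servings(self):
        food = make_food("milk", "dairy", serving=250.0, composition={"ca": 120.0})
        assert food_weekly_amount(food, 0, "ca") == 0.0

    def test_bioavailability_applied(self):
        food = make_food("tofu", "legumes_nuts_seeds", serving=100.0,
                         composition={"protein": 10.0},
                         bioavailability={"protein": 0.9})
        assert food_weekly_amount(food, 1, "protein") == pytest.approx(9.0)
        assert food_weekly_amount(food, 1, "protein", absorbable=False) == pytest.approx(10.0)

    def test_amino_acid_via_protein_profile(self):
        food = make_food("tofu", "legumes_nuts_seeds", serving=100.0,
                         composition={"protein": 10.0})
        food.aa_per_g_protein = {"lys": 0.08}
        assert food_weekly_amount(food, 2, "lys") == pytest.approx(1.6)

    def test_unknown_nutrient_is_error(self):
        food = make_food("milk", "dairy", composition={"ca": 1.0})
        with pytest.raises(ConfigError):
            food_weekly_amount(food, 1, "unobtainium")


class TestEvaluateDiet:
    def test_ghge_example(self):
        db = make_db([make_food("x", serving=100.0, composition={"n1": 1.0}, ghge=5.0)])
        assert evaluate_diet(db, {"x": 2}).ghge == pytest.approx(1.0)

    def test_empty_diet_all_zero(self, simple_db):
        totals = evaluate_diet(simple_db, {})
        assert totals.price == 0.0 and totals.ghge == 0.0
        assert all(v == 0.0 for v in totals.supply.values())

    def test_group_decomposition_partitions_totals(self, simple_db, simple_baseline):
        totals = evaluate_diet(simple_db, simple_baseline.servings)
        assert sum(totals.ghge_by_group.values()) == pytest.approx(totals.ghge, abs=1e-9)
        assert sum(totals.price_by_group.values()) == pytest.approx(totals.price, abs=1e-9)

    def test_unknown_food_is_error(self, simple_db):
        with pytest.raises(ConfigError, match="ghost"):
            evaluate_diet(simple_db, {"ghost": 1})


class TestBuildModel:
    def test_structure_counts(self):
        foods = [make_food(f"f{i}", composition={"n1": 1.0, "n2": 1.0, "n3": 1.0})
                 for i in range(5)]
        db = make_db(foods)
        baseline = BaselineDiet("f", {"f0": 1.0})
        model = build_model(
            db, wb(n1=(1, None), n2=(1, None), n3=(1, None)),
            ObjectiveSpec("MIN_DEVIATION", baseline),
        )
        assert model.n_vars == 10
        assert int(model.integrality.sum()) == 5
        dev_rows = [r for r in model.rows if r[0].startswith("dev_")]
        nut_rows = [r for r in model.rows if r[0].startswith("nutrient_")]
        assert len(dev_rows) == 10
        assert len(nut_rows) == 3

    def test_price_cap_rhs(self, simple_db, simple_baseline):
        base_price = evaluate_diet(simple_db, simple_baseline.servings).price
        model = build_model(
            simple_db, wb(n1=(10, None)),
            ObjectiveSpec("MIN_DEVIATION", simple_baseline),
            caps=CapSpec(price_cap_fraction=0.7),
        )
        cap_rows = [r for r in model.rows if r[0] == "cap_price"]
        assert len(cap_rows) == 1
        assert cap_rows[0][3] == pytest.approx(0.7 * base_price)

    def test_exclusions_fix_variables_at_zero(self, simple_db, simple_baseline):
        model = build_model(
            simple_db, wb(n1=(10, None)),
            ObjectiveSpec("MIN_DEVIATION", simple_baseline),
            exclusions=["beer"],
        )
        j = model.food_ids.index("beer")
        assert model.var_lb[j] == 0.0 and model.var_ub[j] == 0.0

    def test_cap_without_baseline_is_config_error(self, simple_db):
        with pytest.raises(ConfigError):
            build_model(simple_db, wb(n1=(10, None)),
                        ObjectiveSpec("MIN_PRICE"),
                        caps=CapSpec(price_cap_fraction=0.7))

    def test_lp_export_mentions_integers_and_rows(self, simple_db, simple_baseline):
        model = build_model(simple_db, wb(n1=(10, None), n3=(None, 50)),
                            ObjectiveSpec("MIN_DEVIATION", simple_baseline))
        lp = model.to_lp()
        assert "Minimize" in lp and "Generals" in lp and "End" in lp
        assert "x_bread" in lp and "d_bread" in lp
        assert "nutrient_n1" in lp


class TestSolveModel:
    def test_one_variable_instance(self):
        # lower bound 25 at 10 per serving -> 3 servings is minimal
        db = make_db([make_food("only", composition={"n1": 10.0}, price=2.0)])
        model = build_model(db, wb(n1=(25, None)), ObjectiveSpec("MIN_PRICE"))
        sol = solve_model(model)
        assert sol.status == "optimal"
        assert sol.servings["only"] == 3
        assert sol.objective_value == pytest.approx(3 * 2.0 * 100.0 / 1000.0)

    def test_constructed_infeasibility(self):
        # lower bound on n1 needs >= 3 servings but UL on n2 allows at most 1
        db = make_db([make_food("only", composition={"n1": 10.0, "n2": 10.0})])
        model = build_model(db, wb(n1=(25, None), n2=(None, 15)),
                            ObjectiveSpec("MIN_PRICE"))
        sol = solve_model(model)
        assert sol.status == "infeasible"
        assert any(nid == "n1" for nid, _ in sol.infeasible_nutrients)

    def test_zero_deviation_identity(self, simple_db, simple_baseline):
        totals = evaluate_diet(simple_db, simple_baseline.servings)
        bounds = WeeklyBounds(bounds={
            nid: NutrientBounds(lower=0.5 * v, upper=2.0 * v)
            for nid, v in totals.supply.items() if v > 0
        })
        model = build_model(simple_db, bounds,
                            ObjectiveSpec("MIN_DEVIATION", simple_baseline))
        sol = solve_model(model)
        assert sol.status == "optimal"
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)
        assert sol.servings == {fid: pytest.approx(simple_baseline.servings.get(fid, 0.0))
                                for fid in sol.servings}

    def test_totals_match_independent_reevaluation(self, simple_db, simple_baseline):
        totals = evaluate_diet(simple_db, simple_baseline.servings)
        bounds = WeeklyBounds(bounds={
            "n1": NutrientBounds(lower=0.5 * totals.supply["n1"]),
            "n2": NutrientBounds(lower=0.5 * totals.supply["n2"]),
        })
        sol = solve_model(build_model(simple_db, bounds, ObjectiveSpec("MIN_GHGE")))
        again = evaluate_diet(simple_db, sol.servings)
        assert again.price == pytest.approx(sol.totals.price, abs=1e-6)
        assert again.ghge == pytest.approx(sol.totals.ghge, abs=1e-6)
        for nid, v in again.supply.items():
            assert sol.totals.supply[nid] == pytest.approx(v, abs=1e-6)

    def test_excluded_foods_zero_in_solution(self, simple_db, simple_baseline):
        bounds = wb(n1=(50, None))
        sol = solve_model(build_model(
            simple_db, bounds, ObjectiveSpec("MIN_DEVIATION", simple_baseline),
            exclusions=["beer"],
        ))
        assert sol.status == "optimal"
        assert sol.servings["beer"] == 0

    def test_scale_invariance_of_min_price(self, simple_db):
        bounds = wb(n1=(100, None), n2=(50, None))
        sol1 = solve_model(build_model(simple_db, bounds, ObjectiveSpec("MIN_PRICE")))
        import copy
        db2 = copy.deepcopy(simple_db)
        for f in db2.foods.values():
            f.price_per_kg *= 3.0
        sol2 = solve_model(build_model(db2, bounds, ObjectiveSpec("MIN_PRICE")))
        assert sol2.objective_value == pytest.approx(3.0 * sol1.objective_value, rel=1e-9)

    def test_relaxed_integrality_is_continuous(self, simple_db):
        db = make_db([make_food("only", composition={"n1": 10.0}, price=2.0)])
        model = build_model(db, wb(n1=(25, None)), ObjectiveSpec("MIN_PRICE"),
                            decisions=DecisionSpec(integral=False))
        sol = solve_model(model)
        assert sol.servings["only"] == pytest.approx(2.5)


class TestBruteForce:
    def test_candidate_count(self, simple_db):
        db = make_db([make_food(f"f{i}", composition={"n1": 1.0}) for i in range(3)])
        res = brute_force_optimum(db, wb(n1=(0, None)), ObjectiveSpec("MIN_PRICE"),
                                  max_servings=4)
        assert res.n_candidates == 125

    def test_budget_refused(self):
        db = make_db([make_food(f"f{i}", composition={"n1": 1.0}) for i in range(10)])
        with pytest.raises(EnumerationBudgetError):
            brute_force_optimum(db, wb(n1=(0, None)), ObjectiveSpec("MIN_PRICE"),
                                max_servings=9, budget=1e6)

    def test_infeasible_verdict_matches_solver(self):
        db = make_db([make_food("only", composition={"n1": 10.0, "n2": 10.0})])
        bounds = wb(n1=(25, None), n2=(None, 15))
        res = brute_force_optimum(db, bounds, ObjectiveSpec("MIN_PRICE"),
                                  max_servings=4)
        sol = solve_model(build_model(db, bounds, ObjectiveSpec("MIN_PRICE"),
                                      decisions=DecisionSpec(default_upper=4)))
        assert res.status == sol.status == "infeasible"

    def test_ties_are_exposed(self):
        db = make_db([
            make_food("a", composition={"n1": 10.0}, price=2.0),
            make_food("b", composition={"n1": 10.0}, price=2.0),
        ])
        res = brute_force_optimum(db, wb(n1=(10, None)), ObjectiveSpec("MIN_PRICE"),
                                  max_servings=2)
        assert res.status == "optimal"
        assert len(res.argmins) == 2  # (1,0) and (0,1)


def _random_instance(seed):
    spec = SynthSpec(
        n_foods_per_group={"grain_foods": 2, "dairy": 2, "mspe": 1},
        n_nutrients=4,
        seed=seed,
        feasibility="random",
        planted_max_servings=2,
    )
    return generate(spec)


@pytest.mark.parametrize("seed", range(12))
@pytest.mark.parametrize("kind", ["MIN_DEVIATION", "MIN_PRICE", "MIN_GHGE"])
def test_oracle_equivalence_random_instances(seed, kind):
    bundle = _random_instance(seed)
    from dietopt.requirements import to_weekly

    bounds = to_weekly(bundle.requirement_sets[("female", "19-30")])
    baseline = bundle.baselines["female"]
    caps = CapSpec(price_cap_fraction=0.9) if seed % 3 == 0 else CapSpec()
    objective = ObjectiveSpec(kind, baseline)
    oracle = brute_force_optimum(bundle.db, bounds, objective, caps=caps,
                                 max_servings=4)
    sol = solve_model(build_model(bundle.db, bounds, objective, caps=caps,
                                  decisions=DecisionSpec(default_upper=4)))
    assert sol.status == oracle.status
    if sol.status == "optimal":
        assert sol.objective_value == pytest.approx(oracle.objective_value, abs=1e-9)


def test_cap_monotonicity(default_bundle):
    from dietopt.requirements import to_weekly

    bounds = to_weekly(default_bundle.requirement_sets[("female", "19-30")])
    baseline = default_bundle.baselines["female"]
    objective = ObjectiveSpec("MIN_DEVIATION", baseline)
    prev = math.inf
    for frac in [0.6, 0.7, 0.8, 0.9, 1.0]:
        sol = solve_model(build_model(
            default_bundle.db, bounds, objective,
            caps=CapSpec(price_cap_fraction=frac),
        ))
        if sol.status != "optimal":
            continue
        assert sol.objective_value <= prev + 1e-9
        prev = sol.objective_value


def test_min_price_dominates_every_feasible_diet(default_bundle):
    from dietopt.requirements import to_weekly

    bounds = to_weekly(default_bundle.requirement_sets[("male", "19-30")])
    baseline = default_bundle.baselines["male"]
    dev = solve_model(build_model(default_bundle.db, bounds,
                                  ObjectiveSpec("MIN_DEVIATION", baseline)))
    cheapest = solve_model(build_model(default_bundle.db, bounds,
                                       ObjectiveSpec("MIN_PRICE")))
    assert dev.status == cheapest.status == "optimal"
    assert cheapest.totals.price <= dev.totals.price + 1e-9
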