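"""Mixed-integer weekly diet optimisation.

One integer variable per food counts weekly servings.  Three objective
kinds are supported: minimise L1 deviation from a baseline diet (in
servings, linearised with one continuous auxiliary per food), minimise
total weekly price, or minimise total weekly greenhouse-gas emissions.
Nutrient supply rows enforce weekly lower/upper bounds; optional cap rows
bound total price/GHGE at a fraction of the baseline's.

Solved with HiGHS via :func:`scipy.optimize.milp` at zero MIP gap; every
optimal solution is audited by independent re-evaluation before return.
A brute-force enumeration oracle is provided for small instances.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp

from .errors import ConfigError, EnumerationBudgetError, SolverError, ValidationError
from .foods import BaselineDiet, FoodDatabase, FoodItem

#: Absolute feasibility tolerance used for both the solution audit and the
#: brute-force oracle, so the two routes agree on feasibility verdicts.
FEAS_TOL = 1e-6

OBJECTIVE_KINDS = ("MIN_DEVIATION", "MIN_PRICE", "MIN_GHGE")

#: Default per-food weekly serving ceiling.  A modelling parameter (not a
#: literature value): it bounds the feasible region for objectives without
#: a deviation term and keeps the enumeration oracle finite.
DEFAULT_MAX_SERVINGS = 200


@dataclass
class DecisionSpec:
    """Per-food serving-count bounds and integrality.

    ``per_food`` overrides the default (lower, upper) range for named foods.
    """

    default_lower: int = 0
    default_upper: int = DEFAULT_MAX_SERVINGS
    integral: bool = True
    per_food: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        if not 0 <= self.default_lower <= self.default_upper:
            raise ValidationError(
                f"need 0 <= lower <= upper, got ({self.default_lower}, {self.default_upper})"
            )
        for fid, (lo, hi) in self.per_food.items():
            if not 0 <= lo <= hi:
                raise ValidationError(f"food {fid!r}: need 0 <= lower <= upper, got ({lo}, {hi})")

    def range_for(self, food_id: str) -> tuple[float, float]:
        return self.per_food.get(food_id, (self.default_lower, self.default_upper))


@dataclass
class ObjectiveSpec:
    kind: str
    baseline: BaselineDiet | None = None

    def __post_init__(self):
        if self.kind not in OBJECTIVE_KINDS:
            raise ValidationError(f"objective kind {self.kind!r} not in {OBJECTIVE_KINDS}")
        if self.kind == "MIN_DEVIATION" and self.baseline is None:
            raise ConfigError("MIN_DEVIATION objective requires a baseline diet")


@dataclass
class CapSpec:
    """Optional price/GHGE caps as fractions of the baseline totals."""

    price_cap_fraction: float | None = None
    ghge_cap_fraction: float | None = None

    def __post_init__(self):
        for name, frac in (
            ("price_cap_fraction", self.price_cap_fraction),
            ("ghge_cap_fraction", self.ghge_cap_fraction),
        ):
            if frac is not None and not 0.0 < frac <= 1.0:
                raise ValidationError(f"{name}={frac} outside (0, 1]")

    @property
    def any(self) -> bool:
        return self.price_cap_fraction is not None or self.ghge_cap_fraction is not None


@dataclass
class DietTotals:
    """Audited weekly totals for a serving vector."""

    price: float
    ghge: float
    supply: dict[str, float]  # absorbable where a bioavailability coefficient exists
    grams_by_group: dict[str, float]
    price_by_group: dict[str, float]
    ghge_by_group: dict[str, float]


@dataclass
class DietSolution:
    status: str  # optimal | infeasible | unbounded_guard | error
    servings: dict[str, float]
    objective_value: float | None
    totals: DietTotals | None
    deviation_l1: float | None = None
    gap: float | None = None
    infeasible_nutrients: list[tuple[str, float]] = field(default_factory=list)

    @property
    def n_distinct_foods(self) -> int:
        return sum(1 for v in self.servings.values() if v > 0.5)


# ---------------------------------------------------------------------------
# Supply arithmetic
# ---------------------------------------------------------------------------

def _per_serving_amount(food: FoodItem, nutrient_id: str, absorbable: bool = True) -> float:
    """Nutrient amount contributed by one serving of ``food``.

    Amino acids absent from the composition map are derived from the
    normalised profile times protein content.  When ``absorbable`` is set,
    the food's bioavailability coefficient (default 1) is applied.
    """
    if nutrient_id in food.composition:
        gross = food.composition[nutrient_id] * food.serving_size_g / 100.0
    elif nutrient_id in food.aa_per_g_protein:
        gross = (
            food.aa_per_g_protein[nutrient_id]
            * food.composition.get("protein", 0.0)
            * food.serving_size_g
            / 100.0
        )
    else:
        return 0.0
    if absorbable:
        return gross * food.bioavailability.get(nutrient_id, 1.0)
    return gross


def food_weekly_amount(
    food: FoodItem, servings: float, nutrient_id: str, absorbable: bool = True
) -> float:
    """Weekly amount of a nutrient supplied by ``servings`` of one food."""
    if servings < 0:
        raise ValidationError(f"negative servings {servings}")
    if nutrient_id not in food.composition and nutrient_id not in food.aa_per_g_protein:
        raise ConfigError(f"food {food.food_id!r} has no data for nutrient {nutrient_id!r}")
    return _per_serving_amount(food, nutrient_id, absorbable=absorbable) * servings


def evaluate_diet(db: FoodDatabase, servings: Mapping[str, float]) -> DietTotals:
    """Exact weekly totals for a serving vector.

    Per-group aggregations partition the totals (sums over groups equal the
    overall total).  Supply covers every database nutrient plus any amino
    acid carried by the foods, absorbable where coefficients exist.
    """
    unknown = sorted(set(servings) - set(db.foods))
    if unknown:
        raise ConfigError(f"unknown food id(s) in diet: {', '.join(unknown)}")

    nutrient_ids = set(db.nutrients)
    for food in db.foods.values():
        nutrient_ids.update(food.aa_per_g_protein)

    price = 0.0
    ghge = 0.0
    supply = {nid: 0.0 for nid in nutrient_ids}
    grams_by_group: dict[str, float] = {}
    price_by_group: dict[str, float] = {}
    ghge_by_group: dict[str, float] = {}
    for fid in sorted(servings):
        count = servings[fid]
        if count == 0:
            continue
        food = db.foods[fid]
        f_price = food.price_per_serving * count
        f_ghge = food.ghge_per_serving * count
        price += f_price
        ghge += f_ghge
        grams_by_group[food.group] = (
            grams_by_group.get(food.group, 0.0) + food.serving_size_g * count
        )
        price_by_group[food.group] = price_by_group.get(food.group, 0.0) + f_price
        ghge_by_group[food.group] = ghge_by_group.get(food.group, 0.0) + f_ghge
        for nid in nutrient_ids:
            supply[nid] += _per_serving_amount(food, nid) * count
    return DietTotals(
        price=price,
        ghge=ghge,
        supply=supply,
        grams_by_group=grams_by_group,
        price_by_group=price_by_group,
        ghge_by_group=ghge_by_group,
    )


def deviation_l1(
    servings: Mapping[str, float],
    baseline: BaselineDiet,
    ignore: Iterable[str] = (),
) -> float:
    """Total absolute serving-count deviation from baseline, skipping ``ignore``."""
    ignore = set(ignore)
    total = 0.0
    for fid in set(servings) | set(baseline.servings):
        if fid in ignore:
            continue
        total += abs(servings.get(fid, 0.0) - baseline.servings.get(fid, 0.0))
    return total


# ---------------------------------------------------------------------------
# Model construction
# ---------------------------------------------------------------------------

@dataclass
class MilpModel:
    """Assembled MILP: variables, objective vector, and constraint rows.

    Variables 0..n_foods-1 are serving counts (ordered by ``food_ids``);
    for MIN_DEVIATION, variables n_foods..2*n_foods-1 are the continuous
    deviation auxiliaries of the corresponding foods.
    """

    db: FoodDatabase
    food_ids: list[str]
    weekly_bounds: "WeeklyBoundsLike"
    objective: ObjectiveSpec
    caps: CapSpec
    exclusions: list[str]
    decisions: DecisionSpec
    c: np.ndarray
    var_lb: np.ndarray
    var_ub: np.ndarray
    integrality: np.ndarray
    rows: list[tuple[str, np.ndarray, float, float]]  # (name, coeffs, lb, ub)
    baseline_price: float | None = None
    baseline_ghge: float | None = None

    @property
    def n_foods(self) -> int:
        return len(self.food_ids)

    @property
    def n_vars(self) -> int:
        return len(self.c)

    def to_lp(self) -> str:
        """Render the model in LP file format for cross-solver inspection."""
        names = [f"x_{fid}" for fid in self.food_ids]
        if self.n_vars > self.n_foods:
            names += [f"d_{fid}" for fid in self.food_ids]

        def expr(coeffs: np.ndarray) -> str:
            terms = []
            for j, a in enumerate(coeffs):
                if a == 0:
                    continue
                sign = "+" if a >= 0 else "-"
                terms.append(f"{sign} {abs(a):.12g} {names[j]}")
            return " ".join(terms) if terms else "0 " + names[0]

        lines = ["Minimize", f" obj: {expr(self.c)}", "Subject To"]
        for i, (name, coeffs, lb, ub) in enumerate(self.rows):
            if lb == ub:
                lines.append(f" {name}_{i}: {expr(coeffs)} = {lb:.12g}")
                continue
            if lb > -math.inf:
                lines.append(f" {name}_{i}_lo: {expr(coeffs)} >= {lb:.12g}")
            if ub < math.inf:
                lines.append(f" {name}_{i}_up: {expr(coeffs)} <= {ub:.12g}")
        lines.append("Bounds")
        for j, nm in enumerate(names):
            lines.append(f" {self.var_lb[j]:.12g} <= {nm} <= {self.var_ub[j]:.12g}")
        ints = [names[j] for j in range(self.n_vars) if self.integrality[j]]
        if ints:
            lines.append("Generals")
            lines.append(" " + " ".join(ints))
        lines.append("End")
        return "\n".join(lines) + "\n"


def build_model(
    db: FoodDatabase,
    weekly_bounds,
    objective: ObjectiveSpec,
    caps: CapSpec | None = None,
    exclusions: Sequence[str] = (),
    decisions: DecisionSpec | None = None,
) -> MilpModel:
    """Assemble the MILP for one scenario.

    Excluded foods have their variables fixed at zero and, for
    MIN_DEVIATION, are dropped from the deviation objective (their
    deviation is forced by the exclusion, not chosen).  Cap rows reference
    the baseline diet's audited weekly price/GHGE; requesting a cap without
    a baseline is a configuration error.
    """
    if not db.foods:
        raise ConfigError("empty food database")
    if not weekly_bounds.bounds:
        raise ConfigError("no weekly nutrient bounds")
    caps = caps or CapSpec()
    decisions = decisions or DecisionSpec()
    exclusions = sorted(set(exclusions))
    unknown = [fid for fid in exclusions if fid not in db.foods]
    if unknown:
        raise ConfigError(f"exclusion(s) not in database: {', '.join(unknown)}")

    baseline = objective.baseline
    if caps.any and baseline is None:
        raise ConfigError("price/GHGE cap requested without a baseline diet")

    food_ids = db.food_ids()
    n = len(food_ids)
    with_dev = objective.kind == "MIN_DEVIATION"
    n_vars = 2 * n if with_dev else n

    var_lb = np.zeros(n_vars)
    var_ub = np.full(n_vars, np.inf)
    integrality = np.zeros(n_vars, dtype=int)
    for j, fid in enumerate(food_ids):
        lo, hi = decisions.range_for(fid)
        if fid in exclusions:
            lo, hi = 0.0, 0.0
        var_lb[j], var_ub[j] = lo, hi
        integrality[j] = 1 if decisions.integral else 0

    c = np.zeros(n_vars)
    rows: list[tuple[str, np.ndarray, float, float]] = []

    baseline_price = baseline_ghge = None
    if baseline is not None:
        base_totals = evaluate_diet(db, baseline.servings)
        baseline_price = base_totals.price
        baseline_ghge = base_totals.ghge

    if with_dev:
        assert baseline is not None
        for j, fid in enumerate(food_ids):
            if fid in exclusions:
                continue  # forced deviation, not penalised
            b = baseline.servings.get(fid, 0.0)
            c[n + j] = 1.0
            # d_j >= x_j - b  and  d_j >= b - x_j
            row = np.zeros(n_vars)
            row[n + j] = 1.0
            row[j] = -1.0
            rows.append((f"dev_pos_{fid}", row, -b, np.inf))
            row = np.zeros(n_vars)
            row[n + j] = 1.0
            row[j] = 1.0
            rows.append((f"dev_neg_{fid}", row, b, np.inf))
    elif objective.kind == "MIN_PRICE":
        for j, fid in enumerate(food_ids):
            c[j] = db.foods[fid].price_per_serving
    else:  # MIN_GHGE
        for j, fid in enumerate(food_ids):
            c[j] = db.foods[fid].ghge_per_serving

    for nid in weekly_bounds.nutrient_ids():
        b = weekly_bounds.bounds[nid]
        if b.lower is None and b.upper is None:
            continue
        coeffs = np.zeros(n_vars)
        for j, fid in enumerate(food_ids):
            coeffs[j] = _per_serving_amount(db.foods[fid], nid)
        rows.append((
            f"nutrient_{nid}",
            coeffs,
            -np.inf if b.lower is None else b.lower,
            np.inf if b.upper is None else b.upper,
        ))

    if caps.price_cap_fraction is not None:
        coeffs = np.zeros(n_vars)
        for j, fid in enumerate(food_ids):
            coeffs[j] = db.foods[fid].price_per_serving
        rows.append(("cap_price", coeffs, -np.inf, caps.price_cap_fraction * baseline_price))
    if caps.ghge_cap_fraction is not None:
        coeffs = np.zeros(n_vars)
        for j, fid in enumerate(food_ids):
            coeffs[j] = db.foods[fid].ghge_per_serving
        rows.append(("cap_ghge", coeffs, -np.inf, caps.ghge_cap_fraction * baseline_ghge))

    return MilpModel(
        db=db,
        food_ids=food_ids,
        weekly_bounds=weekly_bounds,
        objective=objective,
        caps=caps,
        exclusions=list(exclusions),
        decisions=decisions,
        c=c,
        var_lb=var_lb,
        var_ub=var_ub,
        integrality=integrality,
        rows=rows,
        baseline_price=baseline_price,
        baseline_ghge=baseline_ghge,
    )


# ---------------------------------------------------------------------------
# Solving and auditing
# ---------------------------------------------------------------------------

def _audit(model: MilpModel, servings: dict[str, float]) -> DietTotals:
    """Re-evaluate totals independently and check all bounds and caps."""
    totals = evaluate_diet(model.db, servings)
    for nid in model.weekly_bounds.nutrient_ids():
        b = model.weekly_bounds.bounds[nid]
        s = totals.supply.get(nid, 0.0)
        if b.lower is not None and s < b.lower - FEAS_TOL:
            raise SolverError(f"audit failure: {nid} supply {s} below lower {b.lower}")
        if b.upper is not None and s > b.upper + FEAS_TOL:
            raise SolverError(f"audit failure: {nid} supply {s} above upper {b.upper}")
    if model.caps.price_cap_fraction is not None:
        cap = model.caps.price_cap_fraction * model.baseline_price
        if totals.price > cap + FEAS_TOL:
            raise SolverError(f"audit failure: price {totals.price} exceeds cap {cap}")
    if model.caps.ghge_cap_fraction is not None:
        cap = model.caps.ghge_cap_fraction * model.baseline_ghge
        if totals.ghge > cap + FEAS_TOL:
            raise SolverError(f"audit failure: ghge {totals.ghge} exceeds cap {cap}")
    for fid in model.exclusions:
        if servings.get(fid, 0.0) != 0:
            raise SolverError(f"audit failure: excluded food {fid!r} has servings")
    return totals


def _recompute_objective(model: MilpModel, servings: dict[str, float], totals: DietTotals) -> float:
    if model.objective.kind == "MIN_DEVIATION":
        return deviation_l1(servings, model.objective.baseline, ignore=model.exclusions)
    if model.objective.kind == "MIN_PRICE":
        return totals.price
    return totals.ghge


def solve_model(
    model: MilpModel, seed: int = 0, time_limit: float | None = None
) -> DietSolution:
    """Solve the MILP to proven optimality and return an audited solution.

    The seed only permutes variable ordering (solver tie-breaking); totals
    and the objective are recomputed independently from the integer serving
    vector, so solver nondeterminism cannot change reported values
    undetected.  A time-limit hit raises :class:`SolverError` carrying the
    incumbent gap.
    """
    n_vars = model.n_vars
    perm = np.arange(n_vars)
    if seed:
        rng = np.random.default_rng(seed)
        food_perm = rng.permutation(model.n_foods)
        if n_vars > model.n_foods:
            perm = np.concatenate([food_perm, model.n_foods + food_perm])
        else:
            perm = food_perm
    inv = np.argsort(perm)

    A = np.array([row for _, row, _, _ in model.rows])
    row_lb = np.array([lb for _, _, lb, _ in model.rows])
    row_ub = np.array([ub for _, _, _, ub in model.rows])

    options: dict = {"mip_rel_gap": 0.0, "presolve": True}
    if time_limit is not None:
        options["time_limit"] = float(time_limit)

    res = milp(
        c=model.c[perm],
        constraints=LinearConstraint(A[:, perm], row_lb, row_ub) if len(model.rows) else (),
        integrality=model.integrality[perm],
        bounds=Bounds(model.var_lb[perm], model.var_ub[perm]),
        options=options,
    )

    if res.status == 2:  # infeasible
        diag = diagnose_infeasibility(model)
        return DietSolution(
            status="infeasible",
            servings={},
            objective_value=None,
            totals=None,
            infeasible_nutrients=diag,
        )
    if res.status == 3:
        return DietSolution(
            status="unbounded_guard", servings={}, objective_value=None, totals=None
        )
    if res.status == 1:
        gap = getattr(res, "mip_gap", None)
        raise SolverError(f"solver hit iteration/time limit (gap={gap})")
    if res.status != 0 or res.x is None:
        raise SolverError(f"solver failure: status={res.status} message={res.message!r}")

    x = np.asarray(res.x)[inv]
    servings: dict[str, float] = {}
    for j, fid in enumerate(model.food_ids):
        val = x[j]
        if model.integrality[j]:
            rounded = round(val)
            if abs(val - rounded) > 1e-4:
                raise SolverError(
                    f"integer variable for {fid!r} is fractional: {val}"
                )
            val = float(rounded)
        servings[fid] = max(val, 0.0)

    totals = _audit(model, servings)
    objective_value = _recompute_objective(model, servings, totals)
    if abs(objective_value - res.fun) > 1e-5 * max(1.0, abs(res.fun)):
        raise SolverError(
            f"objective mismatch: recomputed {objective_value} vs solver {res.fun}"
        )
    dev = None
    if model.objective.baseline is not None:
        dev = deviation_l1(servings, model.objective.baseline, ignore=model.exclusions)
    return DietSolution(
        status="optimal",
        servings=servings,
        objective_value=objective_value,
        totals=totals,
        deviation_l1=dev,
        gap=getattr(res, "mip_gap", None),
    )


def diagnose_infeasibility(model: MilpModel, tol: float = 1e-9) -> list[tuple[str, float]]:
    """Elastic re-solve: minimal slack on nutrient rows, reported per nutrient.

    Returns (nutrient_id, violation) pairs with positive minimal slack.
    Diagnostic plumbing only — never affects the primal solve.
    """
    nutrient_rows = [
        (name, coeffs, lb, ub)
        for name, coeffs, lb, ub in model.rows
        if name.startswith("nutrient_")
    ]
    n_slack = len(nutrient_rows)
    if n_slack == 0:
        return []
    n_vars = model.n_vars

    c = np.concatenate([np.zeros(n_vars), np.ones(2 * n_slack)])
    var_lb = np.concatenate([model.var_lb, np.zeros(2 * n_slack)])
    var_ub = np.concatenate([model.var_ub, np.full(2 * n_slack, np.inf)])
    integrality = np.concatenate([model.integrality, np.zeros(2 * n_slack, dtype=int)])

    rows_A, rows_lb, rows_ub = [], [], []
    k = 0
    for name, coeffs, lb, ub in model.rows:
        row = np.concatenate([coeffs, np.zeros(2 * n_slack)])
        if name.startswith("nutrient_"):
            row[n_vars + 2 * k] = 1.0  # relaxes the lower bound
            row[n_vars + 2 * k + 1] = -1.0  # relaxes the upper bound
            k += 1
        rows_A.append(row)
        rows_lb.append(lb)
        rows_ub.append(ub)

    res = milp(
        c=c,
        constraints=LinearConstraint(np.array(rows_A), np.array(rows_lb), np.array(rows_ub)),
        integrality=integrality,
        bounds=Bounds(var_lb, var_ub),
        options={"mip_rel_gap": 0.0},
    )
    if res.status != 0 or res.x is None:
        return []
    out = []
    for k, (name, _, _, _) in enumerate(nutrient_rows):
        slack = res.x[n_vars + 2 * k] + res.x[n_vars + 2 * k + 1]
        if slack > tol:
            out.append((name[len("nutrient_"):], float(slack)))
    return out


# ---------------------------------------------------------------------------
# Enumeration oracle
# ---------------------------------------------------------------------------

@dataclass
class BruteForceResult:
    status: str  # optimal | infeasible
    objective_value: float | None
    argmins: list[dict[str, int]]
    n_candidates: int


def brute_force_optimum(
    db: FoodDatabase,
    weekly_bounds,
    objective: ObjectiveSpec,
    caps: CapSpec | None = None,
    exclusions: Sequence[str] = (),
    max_servings: int = 4,
    budget: float = 1e7,
) -> BruteForceResult:
    """Exact optimum by exhaustive enumeration of integer serving vectors.

    Intended as a testing oracle for small instances; shares
    :data:`FEAS_TOL` with the solver audit so feasibility verdicts agree.
    Returns every optimum to expose ties.  Instances whose candidate count
    ``(max_servings+1)**n_foods`` exceeds ``budget`` are refused.
    """
    caps = caps or CapSpec()
    exclusions = set(exclusions)
    food_ids = db.food_ids()
    n = len(food_ids)
    n_candidates = (max_servings + 1) ** sum(1 for f in food_ids if f not in exclusions)
    if n * n_candidates > budget:
        raise EnumerationBudgetError(
            f"{n} foods x {n_candidates} candidates exceeds budget {budget:g}"
        )

    baseline = objective.baseline
    if caps.any and baseline is None:
        raise ConfigError("price/GHGE cap requested without a baseline diet")
    price_cap = ghge_cap = None
    if baseline is not None:
        base_totals = evaluate_diet(db, baseline.servings)
        if caps.price_cap_fraction is not None:
            price_cap = caps.price_cap_fraction * base_totals.price
        if caps.ghge_cap_fraction is not None:
            ghge_cap = caps.ghge_cap_fraction * base_totals.ghge

    bound_items = [
        (nid, weekly_bounds.bounds[nid]) for nid in weekly_bounds.nutrient_ids()
    ]
    # precompute per-serving coefficient vectors
    nutrient_coeffs = {
        nid: np.array([_per_serving_amount(db.foods[f], nid) for f in food_ids])
        for nid, _ in bound_items
    }
    price_coeffs = np.array([db.foods[f].price_per_serving for f in food_ids])
    ghge_coeffs = np.array([db.foods[f].ghge_per_serving for f in food_ids])
    base_vec = np.array(
        [baseline.servings.get(f, 0.0) if baseline else 0.0 for f in food_ids]
    )
    dev_mask = np.array([f not in exclusions for f in food_ids])

    ranges = [
        [0] if f in exclusions else range(max_servings + 1) for f in food_ids
    ]
    best: float | None = None
    argmins: list[dict[str, int]] = []
    count = 0
    for combo in itertools.product(*ranges):
        count += 1
        x = np.array(combo, dtype=float)
        feasible = True
        for nid, b in bound_items:
            s = float(nutrient_coeffs[nid] @ x)
            if b.lower is not None and s < b.lower - FEAS_TOL:
                feasible = False
                break
            if b.upper is not None and s > b.upper + FEAS_TOL:
                feasible = False
                break
        if not feasible:
            continue
        if price_cap is not None and float(price_coeffs @ x) > price_cap + FEAS_TOL:
            continue
        if ghge_cap is not None and float(ghge_coeffs @ x) > ghge_cap + FEAS_TOL:
            continue

        if objective.kind == "MIN_DEVIATION":
            val = float(np.abs((x - base_vec))[dev_mask].sum())
        elif objective.kind == "MIN_PRICE":
            val = float(price_coeffs @ x)
        else:
            val = float(ghge_coeffs @ x)

        if best is None or val < best - 1e-12:
            best = val
            argmins = [dict(zip(food_ids, combo))]
        elif abs(val - best) <= 1e-12:
            argmins.append(dict(zip(food_ids, combo)))

    if best is None:
        return BruteForceResult(
            status="infeasible", objective_value=None, argmins=[], n_candidates=count
        )
    return BruteForceResult(
        status="optimal", objective_value=best, argmins=argmins, n_candidates=count
    )
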