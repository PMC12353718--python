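"""Scenario battery definition, execution, and report tables.

The default battery holds nine scenarios per sex: a baseline evaluation,
minimum-deviation nutrient-adequate diets for four age groups, capped
variants (70% price cap, 70% GHGE cap), and unconstrained minimum-GHGE /
minimum-price diets.  Alcoholic beverages are excluded from every
optimised scenario by default.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .errors import ConfigError, DietOptError, SolverError, ValidationError
from .foods import FOOD_GROUPS, BaselineDiet, FoodDatabase
from .optimise import (
    CapSpec,
    DecisionSpec,
    DietSolution,
    DietTotals,
    ObjectiveSpec,
    build_model,
    evaluate_diet,
    solve_model,
)
from .requirements import RequirementSet, audit_diet, to_weekly

logger = logging.getLogger(__name__)

DEFAULT_EXCLUDED_GROUPS = ("alcoholic_beverages",)

_SEX_PREFIX = {"female": "F", "male": "M"}


@dataclass(frozen=True)
class Scenario:
    """One row of the scenario battery."""

    label: str
    sex: str
    age_group: str
    objective_kind: str | None  # None for the baseline evaluation
    price_cap_fraction: float | None = None
    ghge_cap_fraction: float | None = None
    excluded_groups: tuple[str, ...] = DEFAULT_EXCLUDED_GROUPS
    deviation_constrained: bool = True

    def __post_init__(self):
        for frac in (self.price_cap_fraction, self.ghge_cap_fraction):
            if frac is not None and not 0.0 < frac <= 1.0:
                raise ValidationError(f"{self.label}: cap fraction {frac} outside (0, 1]")

    @property
    def is_baseline(self) -> bool:
        return self.objective_kind is None


@dataclass
class PercentChange:
    """Signed percent change vs baseline, or the 'new item' status."""

    status: str  # change | new
    value: float | None


@dataclass
class ScenarioReport:
    """Solved (or evaluated) scenario with derived report tables."""

    scenario: Scenario
    solution: DietSolution
    adequacy: object | None  # requirements.AdequacyReport (None on non-optimal)
    group_grams: dict[str, float] = field(default_factory=dict)
    group_price: dict[str, float] = field(default_factory=dict)
    group_ghge: dict[str, float] = field(default_factory=dict)
    pct_change_grams: dict[str, PercentChange] = field(default_factory=dict)
    pct_change_supply: dict[str, PercentChange] = field(default_factory=dict)
    wall_seconds: float = 0.0
    error: str | None = None


def default_battery(sexes: Sequence[str] = ("female", "male")) -> list[Scenario]:
    """The standard nine-scenario battery per sex.

    Per sex: ``Base`` (evaluation only), ``NAD``/``NAD_35``/``NAD_55``/
    ``NAD_75`` (minimum deviation, one per age group), ``NAD_P`` (70%
    price cap), ``NAD_E`` (70% GHGE cap), ``Min_E`` and ``Min_P``
    (no deviation constraint).
    """
    battery = []
    for sex in sexes:
        p = _SEX_PREFIX[sex]
        battery.append(Scenario(f"{p}.Base", sex, "19-30", None))
        for suffix, age in (
            ("NAD", "19-30"), ("NAD_35", "31-50"), ("NAD_55", "51-69"), ("NAD_75", "70+"),
        ):
            battery.append(Scenario(f"{p}.{suffix}", sex, age, "MIN_DEVIATION"))
        battery.append(
            Scenario(f"{p}.NAD_P", sex, "19-30", "MIN_DEVIATION", price_cap_fraction=0.7)
        )
        battery.append(
            Scenario(f"{p}.NAD_E", sex, "19-30", "MIN_DEVIATION", ghge_cap_fraction=0.7)
        )
        battery.append(
            Scenario(f"{p}.Min_E", sex, "19-30", "MIN_GHGE", deviation_constrained=False)
        )
        battery.append(
            Scenario(f"{p}.Min_P", sex, "19-30", "MIN_PRICE", deviation_constrained=False)
        )
    return battery


def battery_labels(battery: Sequence[Scenario] | None = None) -> list[str]:
    return [s.label for s in (battery if battery is not None else default_battery())]


def percent_change(baseline_value: float, scenario_value: float) -> PercentChange:
    """Signed percent change; a zero baseline with nonzero scenario is 'new'."""
    if baseline_value < 0 or scenario_value < 0:
        raise ValidationError(
            f"percent_change requires non-negative inputs, got "
            f"({baseline_value}, {scenario_value})"
        )
    if baseline_value == 0:
        if scenario_value == 0:
            return PercentChange(status="change", value=0.0)
        return PercentChange(status="new", value=None)
    return PercentChange(
        status="change", value=100.0 * (scenario_value - baseline_value) / baseline_value
    )


def group_intake_table(report: ScenarioReport) -> dict[str, float]:
    """Weekly grams per food group; groups without foods report 0."""
    return {g: report.group_grams.get(g, 0.0) for g in FOOD_GROUPS}


def nutrient_contribution_table(
    report: ScenarioReport, nutrient_id: str, db: FoodDatabase
) -> dict[str, float]:
    """Per-group weekly contribution to one nutrient's total supply.

    Contributions partition the total: their sum equals the diet's supply.
    """
    totals = report.solution.totals
    if totals is None:
        raise ConfigError(f"scenario {report.scenario.label} has no solution totals")
    if nutrient_id not in totals.supply:
        raise ConfigError(f"unknown nutrient {nutrient_id!r}")
    from .optimise import _per_serving_amount

    out = {g: 0.0 for g in FOOD_GROUPS}
    for fid, count in report.solution.servings.items():
        if count == 0:
            continue
        food = db.foods[fid]
        out[food.group] += _per_serving_amount(food, nutrient_id) * count
    return out


def _exclusion_ids(db: FoodDatabase, groups: Sequence[str]) -> list[str]:
    ids = []
    for g in groups:
        ids.extend(db.foods_in_group(g))
    return ids


def _make_report(
    scenario: Scenario,
    solution: DietSolution,
    db: FoodDatabase,
    baseline_totals: DietTotals,
    weekly_bounds,
    wall: float,
    error: str | None = None,
) -> ScenarioReport:
    adequacy = None
    group_grams: dict[str, float] = {}
    group_price: dict[str, float] = {}
    group_ghge: dict[str, float] = {}
    pct_grams: dict[str, PercentChange] = {}
    pct_supply: dict[str, PercentChange] = {}
    totals = solution.totals
    if totals is not None:
        from .optimise import FEAS_TOL

        if weekly_bounds is not None:
            adequacy = audit_diet(totals.supply, weekly_bounds, tol=FEAS_TOL)
        group_grams = {g: totals.grams_by_group.get(g, 0.0) for g in FOOD_GROUPS}
        group_price = {g: totals.price_by_group.get(g, 0.0) for g in FOOD_GROUPS}
        group_ghge = {g: totals.ghge_by_group.get(g, 0.0) for g in FOOD_GROUPS}
        for g in FOOD_GROUPS:
            pct_grams[g] = percent_change(
                baseline_totals.grams_by_group.get(g, 0.0), group_grams[g]
            )
        for nid in sorted(totals.supply):
            pct_supply[nid] = percent_change(
                baseline_totals.supply.get(nid, 0.0), totals.supply[nid]
            )
    return ScenarioReport(
        scenario=scenario,
        solution=solution,
        adequacy=adequacy,
        group_grams=group_grams,
        group_price=group_price,
        group_ghge=group_ghge,
        pct_change_grams=pct_grams,
        pct_change_supply=pct_supply,
        wall_seconds=wall,
        error=error,
    )


def run_scenario(
    scenario: Scenario,
    db: FoodDatabase,
    baseline: BaselineDiet,
    requirement_set: RequirementSet | None,
    baseline_totals: DietTotals | None = None,
    decisions: DecisionSpec | None = None,
    seed: int = 0,
    time_limit: float | None = None,
) -> ScenarioReport:
    """Run one scenario: evaluate the baseline, or build + solve + audit."""
    t0 = time.perf_counter()
    if baseline_totals is None:
        baseline_totals = evaluate_diet(db, baseline.servings)

    if scenario.is_baseline:
        solution = DietSolution(
            status="evaluated",
            servings=dict(baseline.servings),
            objective_value=None,
            totals=baseline_totals,
            deviation_l1=0.0,
        )
        weekly = to_weekly(requirement_set) if requirement_set is not None else None
        return _make_report(
            scenario, solution, db, baseline_totals, weekly, time.perf_counter() - t0
        )

    if requirement_set is None:
        raise ConfigError(f"scenario {scenario.label}: missing requirement set")
    weekly = to_weekly(requirement_set)
    exclusions = _exclusion_ids(db, scenario.excluded_groups)
    objective = ObjectiveSpec(kind=scenario.objective_kind, baseline=baseline)
    caps = CapSpec(
        price_cap_fraction=scenario.price_cap_fraction,
        ghge_cap_fraction=scenario.ghge_cap_fraction,
    )
    model = build_model(
        db, weekly, objective, caps=caps, exclusions=exclusions, decisions=decisions
    )
    solution = solve_model(model, seed=seed, time_limit=time_limit)
    report = _make_report(
        scenario, solution, db, baseline_totals, weekly, time.perf_counter() - t0
    )
    if solution.status == "optimal" and report.adequacy is not None:
        if not report.adequacy.adequate:
            bad = [s.nutrient_id for s in report.adequacy.violations]
            raise SolverError(
                f"scenario {scenario.label}: optimal solution fails adequacy audit: {bad}"
            )
    return report


def run_battery(
    db: FoodDatabase,
    baselines: Mapping[str, BaselineDiet],
    requirement_sets: Mapping[tuple[str, str], RequirementSet],
    battery: Sequence[Scenario] | None = None,
    seed: int = 0,
    decisions: DecisionSpec | None = None,
    time_limit: float | None = None,
) -> list[ScenarioReport]:
    """Run a scenario battery; per-scenario failures are isolated.

    A missing baseline or requirement set for any scenario's demographic is
    a configuration error naming the scenario (raised before any solve).
    Solver failures inside a scenario are captured in that scenario's
    report with status ``error`` and do not abort the battery.
    """
    battery = list(battery) if battery is not None else default_battery()
    for sc in battery:
        if sc.sex not in baselines:
            raise ConfigError(f"scenario {sc.label}: no baseline diet for sex {sc.sex!r}")
        if not sc.is_baseline and (sc.sex, sc.age_group) not in requirement_sets:
            raise ConfigError(
                f"scenario {sc.label}: no requirement set for ({sc.sex}, {sc.age_group})"
            )

    base_totals = {sex: evaluate_diet(db, b.servings) for sex, b in baselines.items()}
    reports = []
    for sc in battery:
        req = requirement_sets.get((sc.sex, sc.age_group))
        try:
            report = run_scenario(
                sc,
                db,
                baselines[sc.sex],
                req,
                baseline_totals=base_totals[sc.sex],
                decisions=decisions,
                seed=seed,
                time_limit=time_limit,
            )
        except DietOptError as exc:
            logger.warning("scenario %s failed: %s", sc.label, exc)
            report = ScenarioReport(
                scenario=sc,
                solution=DietSolution(
                    status="error", servings={}, objective_value=None, totals=None
                ),
                adequacy=None,
                error=str(exc),
            )
        logger.info(
            "scenario %s: status=%s objective=%s wall=%.3fs",
            sc.label,
            report.solution.status,
            report.solution.objective_value,
            report.wall_seconds,
        )
        reports.append(report)
    return reports


# ---------------------------------------------------------------------------
# Tidy exports
# ---------------------------------------------------------------------------

def battery_summary(reports: Sequence[ScenarioReport]) -> pd.DataFrame:
    """One row per scenario: status, objective, price, GHGE, adequacy flag."""
    rows = []
    for r in reports:
        t = r.solution.totals
        rows.append({
            "scenario": r.scenario.label,
            "status": r.solution.status,
            "objective_kind": r.scenario.objective_kind or "baseline",
            "objective_value": r.solution.objective_value,
            "weekly_price": t.price if t else None,
            "weekly_ghge": t.ghge if t else None,
            "deviation_l1": r.solution.deviation_l1,
            "n_distinct_foods": r.solution.n_distinct_foods if t else None,
            "adequate": r.adequacy.adequate if r.adequacy is not None else None,
            "error": r.error,
        })
    return pd.DataFrame(rows)


def tidy_group_table(reports: Sequence[ScenarioReport]) -> pd.DataFrame:
    """Long table (scenario, group, grams, price, ghge, pct_change_grams)."""
    rows = []
    for r in reports:
        if r.solution.totals is None:
            continue
        for g in FOOD_GROUPS:
            pc = r.pct_change_grams.get(g)
            rows.append({
                "scenario": r.scenario.label,
                "group": g,
                "grams": r.group_grams.get(g, 0.0),
                "price": r.group_price.get(g, 0.0),
                "ghge": r.group_ghge.get(g, 0.0),
                "pct_change_grams": pc.value if pc and pc.status == "change" else None,
                "new_item": bool(pc and pc.status == "new"),
            })
    return pd.DataFrame(rows)


def tidy_nutrient_table(reports: Sequence[ScenarioReport]) -> pd.DataFrame:
    """Long table (scenario, nutrient, supply, lower, upper, status)."""
    rows = []
    for r in reports:
        t = r.solution.totals
        if t is None:
            continue
        statuses = r.adequacy.statuses if r.adequacy is not None else {}
        for nid in sorted(t.supply):
            st = statuses.get(nid)
            rows.append({
                "scenario": r.scenario.label,
                "nutrient": nid,
                "weekly_supply": t.supply[nid],
                "weekly_lower": st.lower if st else None,
                "weekly_upper": st.upper if st else None,
                "status": st.status if st else None,
            })
    return pd.DataFrame(rows)
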