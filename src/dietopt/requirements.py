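"""Demographic nutrient requirement sets and weekly bound conversion.

Requirement sets carry daily reference intakes (lower bounds) and upper
limits where defined, per (sex, age group).  The optimiser works on a
weekly basis, so daily bounds are scaled by 7.  Bounds are closed: a supply
exactly at a bound is adequate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .errors import ConfigError, ValidationError

SEXES = ("male", "female")
AGE_GROUPS = ("19-30", "31-50", "51-69", "70+")

DAYS_PER_WEEK = 7


@dataclass(frozen=True)
class NutrientBounds:
    """Daily (or weekly) lower/upper bounds for one nutrient; None = absent."""

    lower: float | None = None
    upper: float | None = None

    def __post_init__(self):
        if self.lower is not None and self.lower < 0:
            raise ValidationError(f"negative lower bound {self.lower}")
        if self.upper is not None and self.upper < 0:
            raise ValidationError(f"negative upper bound {self.upper}")
        if self.lower is not None and self.upper is not None and self.lower > self.upper:
            raise ValidationError(
                f"lower bound {self.lower} exceeds upper bound {self.upper}"
            )


@dataclass
class RequirementSet:
    """Daily nutrient bounds for one demographic stratum."""

    sex: str
    age_group: str
    bounds: dict[str, NutrientBounds]

    def __post_init__(self):
        if self.sex not in SEXES:
            raise ValidationError(f"sex {self.sex!r} not in {SEXES}")
        if self.age_group not in AGE_GROUPS:
            raise ValidationError(f"age_group {self.age_group!r} not in {AGE_GROUPS}")
        if not any(b.lower is not None for b in self.bounds.values()):
            raise ValidationError(
                f"requirement set {self.sex}/{self.age_group}: "
                "at least one nutrient must have a lower bound"
            )

    @property
    def label(self) -> str:
        return f"{self.sex}/{self.age_group}"


@dataclass
class WeeklyBounds:
    """Weekly optimisation bounds per nutrient (daily × 7)."""

    bounds: dict[str, NutrientBounds] = field(default_factory=dict)

    def nutrient_ids(self) -> list[str]:
        return sorted(self.bounds)


def to_weekly(req: RequirementSet) -> WeeklyBounds:
    """Scale every present daily bound by 7; absent bounds stay absent."""
    weekly = {}
    for nid, b in req.bounds.items():
        weekly[nid] = NutrientBounds(
            lower=None if b.lower is None else b.lower * DAYS_PER_WEEK,
            upper=None if b.upper is None else b.upper * DAYS_PER_WEEK,
        )
    return WeeklyBounds(bounds=weekly)


@dataclass(frozen=True)
class NutrientStatus:
    nutrient_id: str
    supply: float
    lower: float | None
    upper: float | None
    status: str  # below_lower | within | above_upper


@dataclass
class AdequacyReport:
    """Per-nutrient adequacy of a weekly supply against weekly bounds."""

    statuses: dict[str, NutrientStatus]

    @property
    def violations(self) -> list[NutrientStatus]:
        return [s for s in self.statuses.values() if s.status != "within"]

    @property
    def adequate(self) -> bool:
        return not self.violations


def audit_diet(
    supply: Mapping[str, float], bounds: WeeklyBounds, tol: float = 0.0
) -> AdequacyReport:
    """Classify a weekly nutrient supply against weekly bounds.

    Bounds are closed; ``tol`` widens them by an absolute slack (used when
    auditing solver output at its numeric tolerance).  Every bound nutrient
    must be present in ``supply``.
    """
    statuses = {}
    for nid, b in bounds.bounds.items():
        if nid not in supply:
            raise ConfigError(f"supply missing bound nutrient {nid!r}")
        s = supply[nid]
        if b.lower is not None and s < b.lower - tol:
            status = "below_lower"
        elif b.upper is not None and s > b.upper + tol:
            status = "above_upper"
        else:
            status = "within"
        statuses[nid] = NutrientStatus(
            nutrient_id=nid, supply=s, lower=b.lower, upper=b.upper, status=status
        )
    return AdequacyReport(statuses=statuses)


# ---------------------------------------------------------------------------
# Config IO
# ---------------------------------------------------------------------------

def _parse_requirement_block(block: dict) -> RequirementSet:
    try:
        sex = block["sex"]
        age_group = block["age_group"]
        raw = block["bounds"]
    except KeyError as exc:
        raise ConfigError(f"requirement block missing key {exc}") from exc
    bounds = {}
    for nid, bb in raw.items():
        if not isinstance(bb, dict):
            raise ConfigError(f"bounds for {nid!r} must be a mapping with lower/upper")
        bounds[nid] = NutrientBounds(lower=bb.get("lower"), upper=bb.get("upper"))
    try:
        return RequirementSet(sex=sex, age_group=age_group, bounds=bounds)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc


def load_requirement_sets(path: str | Path) -> dict[tuple[str, str], RequirementSet]:
    """Load requirement sets from a YAML/JSON config document.

    The document holds a ``requirement_sets`` list; each entry has ``sex``,
    ``age_group``, and a ``bounds`` map of nutrient id to
    ``{lower: x, upper: y}`` (either bound may be omitted).  Amounts are
    daily, in the database units of each nutrient.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"requirement config not found: {path}")
    text = path.read_text(encoding="utf-8")
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(doc, dict) or "requirement_sets" not in doc:
        raise ConfigError(f"{path}: expected a mapping with key 'requirement_sets'")
    sets: dict[tuple[str, str], RequirementSet] = {}
    for block in doc["requirement_sets"]:
        req = _parse_requirement_block(block)
        key = (req.sex, req.age_group)
        if key in sets:
            raise ConfigError(f"{path}: duplicate requirement set for {key}")
        sets[key] = req
    return sets


def dump_requirement_sets(
    sets: Mapping[tuple[str, str], RequirementSet]
) -> str:
    """Serialise requirement sets to a YAML document (deterministic order)."""
    blocks = []
    for key in sorted(sets):
        req = sets[key]
        bounds = {}
        for nid in sorted(req.bounds):
            b = req.bounds[nid]
            entry = {}
            if b.lower is not None:
                entry["lower"] = float(b.lower)
            if b.upper is not None:
                entry["upper"] = float(b.upper)
            bounds[nid] = entry
        blocks.append({"sex": req.sex, "age_group": req.age_group, "bounds": bounds})
    return yaml.safe_dump({"requirement_sets": blocks}, sort_keys=False)
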