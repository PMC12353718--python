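"""Food database: domain types, compilation transforms, and delimited-text IO.

The database is compiled from four comma-separated files (UTF-8, header row):

``compositions.csv``
    ``food_id`` plus one column per nutrient id (amount per 100 g edible
    portion).  Optional ``aa_<id>`` columns carry amino-acid amounts per
    100 g; they are normalised to total protein content at load time and
    require a ``protein`` column.
``prices.csv``
    ``food_id, store_label, price, package_mass_g`` — one row per store
    observation; observations are averaged to a per-kg price.
``ghge.csv``
    ``food_id, kg_co2e_per_kg`` — cradle-to-point-of-sale emission factor.
``servings.csv``
    ``food_id, serving_size_g, group, subgroup``.

Foods present in the composition file but missing serving, price, or GHGE
data are dropped and recorded in the :class:`ValidationReport`; rows in the
satellite files that reference unknown food ids are a hard join error.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import LoadError, UnmatchedFoodError, UnpricedFoodError, ValidationError

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

#: Closed set of food groups.
FOOD_GROUPS = (
    "fruits_vegetables",
    "grain_foods",
    "legumes_nuts_seeds",
    "mspe",
    "dairy",
    "dairy_alternatives",
    "discretionary",
    "fats_oils",
    "miscellaneous",
    "non_alcoholic_beverages",
    "alcoholic_beverages",
)

#: Closed set of nutrient units (amount per 100 g food).
NUTRIENT_UNITS = ("g", "mg", "µg", "kJ")

#: Which requirement bounds a nutrient may carry.
BOUND_KINDS = ("lower", "upper", "both")


@dataclass(frozen=True)
class NutrientDef:
    """Definition of one nutrient dimension of the database."""

    nutrient_id: str
    display_name: str
    unit: str
    bound_kind: str = "both"

    def __post_init__(self):
        if self.unit not in NUTRIENT_UNITS:
            raise ValidationError(
                f"nutrient {self.nutrient_id!r}: unit {self.unit!r} not in {NUTRIENT_UNITS}"
            )
        if self.bound_kind not in BOUND_KINDS:
            raise ValidationError(
                f"nutrient {self.nutrient_id!r}: bound_kind {self.bound_kind!r} not in {BOUND_KINDS}"
            )


@dataclass
class CompositionRecord:
    """One matched composition entry (per 100 g edible portion).

    ``nutrient_amounts`` values may be ``None`` for missing data; missing
    values are excluded from averages rather than treated as zero.
    ``must_retain`` marks records that take part in a grouped item and must
    be kept in the average even beyond the matching cap.
    """

    source_id: str
    source_db: str
    nutrient_amounts: dict[str, float | None]
    protein_per_100g: float = 0.0
    aa_amounts: dict[str, float] | None = None
    must_retain: bool = False

    def __post_init__(self):
        if self.protein_per_100g < 0:
            raise ValidationError(
                f"record {self.source_id!r}: negative protein {self.protein_per_100g}"
            )
        for nid, amt in self.nutrient_amounts.items():
            if amt is not None and amt < 0:
                raise ValidationError(
                    f"record {self.source_id!r}: negative amount {amt} for {nid!r}"
                )
        if self.aa_amounts:
            for aid, amt in self.aa_amounts.items():
                if amt < 0:
                    raise ValidationError(
                        f"record {self.source_id!r}: negative amino acid {amt} for {aid!r}"
                    )


@dataclass
class FoodItem:
    """One food with composition, serving size, price, and emission factor.

    Composition amounts are per 100 g edible portion.  ``bioavailability``
    maps protein and essential-amino-acid ids to absorption coefficients in
    [0, 1]; nutrients absent from the map are used gross.
    """

    food_id: str
    name: str
    group: str
    subgroup: str
    serving_size_g: float
    composition: dict[str, float]
    aa_per_g_protein: dict[str, float] = field(default_factory=dict)
    bioavailability: dict[str, float] = field(default_factory=dict)
    ghge_per_kg: float = 0.0
    price_per_kg: float = 0.0

    def __post_init__(self):
        if self.group not in FOOD_GROUPS:
            raise ValidationError(
                f"food {self.food_id!r}: group {self.group!r} not in closed group set"
            )
        if not self.serving_size_g > 0:
            raise ValidationError(
                f"food {self.food_id!r}: serving_size_g must be > 0, got {self.serving_size_g}"
            )
        if self.ghge_per_kg < 0:
            raise ValidationError(f"food {self.food_id!r}: negative ghge_per_kg")
        if self.price_per_kg < 0:
            raise ValidationError(f"food {self.food_id!r}: negative price_per_kg")
        for key, coeff in self.bioavailability.items():
            if not 0.0 <= coeff <= 1.0:
                raise ValidationError(
                    f"food {self.food_id!r}: bioavailability[{key!r}]={coeff} outside [0, 1]"
                )
        for nid, amt in self.composition.items():
            if amt < 0:
                raise ValidationError(
                    f"food {self.food_id!r}: negative composition amount for {nid!r}"
                )

    @property
    def price_per_serving(self) -> float:
        return self.price_per_kg * self.serving_size_g / 1000.0

    @property
    def ghge_per_serving(self) -> float:
        return self.ghge_per_kg * self.serving_size_g / 1000.0


@dataclass(frozen=True)
class PriceObservation:
    """A retail price observation: package price at one store."""

    food_id: str
    store_label: str
    price: float
    package_mass_g: float

    def __post_init__(self):
        if self.price < 0:
            raise ValidationError(f"{self.food_id!r}@{self.store_label!r}: negative price")
        if not self.package_mass_g > 0:
            raise ValidationError(
                f"{self.food_id!r}@{self.store_label!r}: package_mass_g must be > 0"
            )

    @property
    def price_per_kg(self) -> float:
        return self.price / self.package_mass_g * 1000.0


@dataclass
class BaselineDiet:
    """Weekly serving counts per food for one demographic (may be fractional)."""

    demographic_label: str
    servings: dict[str, float]

    def __post_init__(self):
        for fid, count in self.servings.items():
            if count < 0:
                raise ValidationError(
                    f"baseline {self.demographic_label!r}: negative servings for {fid!r}"
                )


@dataclass
class ValidationReport:
    """Outcome of a database load: dropped foods and informational messages."""

    dropped: list[tuple[str, str]] = field(default_factory=list)
    messages: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.dropped

    def to_text(self) -> str:
        lines = [f"validation report: {len(self.dropped)} food(s) dropped"]
        for fid, reason in self.dropped:
            lines.append(f"  DROP {fid}: {reason}")
        lines.extend(f"  INFO {m}" for m in self.messages)
        return "\n".join(lines) + "\n"


@dataclass
class FoodDatabase:
    """Validated food database: nutrient definitions plus one FoodItem per id."""

    nutrients: dict[str, NutrientDef]
    foods: dict[str, FoodItem]
    currency: str = "NZD"

    def __post_init__(self):
        for fid, food in self.foods.items():
            if food.food_id != fid:
                raise ValidationError(f"food key {fid!r} != food_id {food.food_id!r}")

    def __len__(self) -> int:
        return len(self.foods)

    def food_ids(self) -> list[str]:
        return sorted(self.foods)

    def nutrient_ids(self) -> list[str]:
        return sorted(self.nutrients)

    def foods_in_group(self, group: str) -> list[str]:
        return sorted(f.food_id for f in self.foods.values() if f.group == group)

    def to_json(self) -> str:
        """Serialise deterministically (sorted keys) with a schema version."""
        doc = {
            "schema_version": SCHEMA_VERSION,
            "currency": self.currency,
            "nutrients": {
                nid: dataclasses.asdict(nd) for nid, nd in sorted(self.nutrients.items())
            },
            "foods": {
                fid: dataclasses.asdict(f) for fid, f in sorted(self.foods.items())
            },
        }
        return json.dumps(doc, indent=2, sort_keys=True, ensure_ascii=False)

    @classmethod
    def from_json(cls, text: str) -> "FoodDatabase":
        doc = json.loads(text)
        if doc.get("schema_version") != SCHEMA_VERSION:
            raise LoadError(
                f"unsupported database schema version {doc.get('schema_version')!r}"
            )
        nutrients = {nid: NutrientDef(**nd) for nid, nd in doc["nutrients"].items()}
        foods = {fid: FoodItem(**f) for fid, f in doc["foods"].items()}
        return cls(nutrients=nutrients, foods=foods, currency=doc.get("currency", "NZD"))


# ---------------------------------------------------------------------------
# Compilation transforms
# ---------------------------------------------------------------------------

def average_compositions(
    matches: list[CompositionRecord], cap: int = 3
) -> CompositionRecord:
    """Average the best-matching composition records for one food.

    ``matches`` must be pre-ranked best-first.  The first ``min(cap, len)``
    records are retained, plus every record flagged ``must_retain``
    (grouped items keep at least one composition per constituent food, even
    beyond the cap).  The nutrient-wise arithmetic mean ignores missing
    (``None``) values; a nutrient missing from every retained record is
    missing from the result.
    """
    if not matches:
        raise UnmatchedFoodError("no composition matches for food")
    if cap < 1:
        raise ValidationError(f"cap must be >= 1, got {cap}")

    retained = list(matches[:cap])
    retained_ids = {id(r) for r in retained}
    for rec in matches[cap:]:
        if rec.must_retain and id(rec) not in retained_ids:
            retained.append(rec)

    nutrient_ids: set[str] = set()
    for rec in retained:
        nutrient_ids.update(rec.nutrient_amounts)

    amounts: dict[str, float | None] = {}
    for nid in nutrient_ids:
        vals = [
            rec.nutrient_amounts[nid]
            for rec in retained
            if rec.nutrient_amounts.get(nid) is not None
        ]
        amounts[nid] = sum(vals) / len(vals) if vals else None

    protein = sum(r.protein_per_100g for r in retained) / len(retained)

    aa_ids: set[str] = set()
    for rec in retained:
        if rec.aa_amounts:
            aa_ids.update(rec.aa_amounts)
    aa: dict[str, float] | None = None
    if aa_ids:
        aa = {}
        for aid in aa_ids:
            vals = [rec.aa_amounts[aid] for rec in retained
                    if rec.aa_amounts and aid in rec.aa_amounts]
            aa[aid] = sum(vals) / len(vals)

    return CompositionRecord(
        source_id="+".join(r.source_id for r in retained),
        source_db="averaged",
        nutrient_amounts=amounts,
        protein_per_100g=protein,
        aa_amounts=aa,
    )


def normalise_amino_acids(
    aa_per_100g: Mapping[str, float], protein_per_100g: float
) -> dict[str, float]:
    """Normalise amino-acid amounts per 100 g to grams per gram of protein.

    Re-scaling the result by any protein content reconstructs per-100 g
    amounts exactly.  A zero protein content is only consistent with
    all-zero amino acids (empty map returned); otherwise it is an error.
    """
    for aid, amt in aa_per_100g.items():
        if amt < 0:
            raise ValidationError(f"negative amino-acid amount {amt} for {aid!r}")
    if protein_per_100g == 0:
        if any(v > 0 for v in aa_per_100g.values()):
            raise ValidationError(
                "zero protein content with nonzero amino acids: inconsistent record"
            )
        return {}
    if protein_per_100g < 0:
        raise ValidationError(f"negative protein content {protein_per_100g}")
    return {aid: amt / protein_per_100g for aid, amt in aa_per_100g.items()}


def apply_bioavailability(gross_amount: float, coefficient: float) -> float:
    """Convert a gross nutrient amount to its absorbable fraction."""
    if not 0.0 <= coefficient <= 1.0:
        raise ValidationError(f"bioavailability coefficient {coefficient} outside [0, 1]")
    if gross_amount < 0:
        raise ValidationError(f"negative gross amount {gross_amount}")
    return gross_amount * coefficient


def average_price(observations: Iterable[PriceObservation]) -> float:
    """Arithmetic mean of per-kg prices across store observations."""
    obs = list(observations)
    if not obs:
        raise UnpricedFoodError("no price observations for food")
    return sum(o.price_per_kg for o in obs) / len(obs)


def remove_items(diet: BaselineDiet, names: Iterable[str]) -> BaselineDiet:
    """Return a baseline diet with the named foods removed.

    Names that are absent are ignored (logged at debug level).
    """
    names = set(names)
    present = names & set(diet.servings)
    for missing in sorted(names - present):
        logger.debug("remove_items: %r not present in baseline, ignored", missing)
    return BaselineDiet(
        demographic_label=diet.demographic_label,
        servings={f: s for f, s in diet.servings.items() if f not in present},
    )


# ---------------------------------------------------------------------------
# Delimited-text readers
# ---------------------------------------------------------------------------

def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise LoadError(f"input file not found: {path}")
    try:
        df = pd.read_csv(path, dtype={"food_id": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise LoadError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise LoadError(f"{path}: missing required column(s) {missing}")
    return df


def _check_join(df: pd.DataFrame, known: set[str], path: str | Path, label: str):
    unknown = sorted(set(df["food_id"]) - known)
    if unknown:
        raise LoadError(
            f"{path}: {label} rows reference unknown food id(s): {', '.join(unknown)}",
            context={"food_ids": unknown},
        )


def load_food_database(
    composition_path: str | Path,
    prices_path: str | Path,
    ghge_path: str | Path,
    servings_path: str | Path,
    nutrients_path: str | Path | None = None,
    bioavailability_path: str | Path | None = None,
    currency: str = "NZD",
) -> tuple[FoodDatabase, ValidationReport]:
    """Load and cross-join the four database files into a validated database.

    Returns the database together with a :class:`ValidationReport` listing
    foods dropped for missing serving, price, or GHGE data.  Satellite rows
    referencing food ids absent from the composition file raise
    :class:`LoadError` naming the offending ids.

    ``nutrients_path`` optionally supplies nutrient definitions
    (``nutrient_id, display_name, unit, bound_kind``); nutrients without a
    definition default to unit ``g`` with both bounds allowed.
    ``bioavailability_path`` optionally supplies absorption coefficients
    (``food_id, nutrient_id, coefficient``) for protein and essential amino
    acids; the default coefficient is 1.
    """
    comp = _read_csv(composition_path, ["food_id"])
    prices = _read_csv(prices_path, ["food_id", "store_label", "price", "package_mass_g"])
    ghge = _read_csv(ghge_path, ["food_id", "kg_co2e_per_kg"])
    servings = _read_csv(servings_path, ["food_id", "serving_size_g", "group", "subgroup"])

    if comp["food_id"].duplicated().any():
        dups = sorted(comp.loc[comp["food_id"].duplicated(), "food_id"])
        raise LoadError(f"{composition_path}: duplicate food id(s): {', '.join(dups)}")
    if ghge["food_id"].duplicated().any():
        dups = sorted(ghge.loc[ghge["food_id"].duplicated(), "food_id"])
        raise LoadError(f"{ghge_path}: duplicate food id(s): {', '.join(dups)}")
    if servings["food_id"].duplicated().any():
        dups = sorted(servings.loc[servings["food_id"].duplicated(), "food_id"])
        raise LoadError(f"{servings_path}: duplicate food id(s): {', '.join(dups)}")

    known = set(comp["food_id"])
    _check_join(prices, known, prices_path, "price")
    _check_join(ghge, known, ghge_path, "ghge")
    _check_join(servings, known, servings_path, "serving")

    aa_cols = [c for c in comp.columns if c.startswith("aa_")]
    nutrient_cols = [c for c in comp.columns if c != "food_id" and not c.startswith("aa_")]
    if aa_cols and "protein" not in nutrient_cols:
        raise LoadError(
            f"{composition_path}: amino-acid columns present but no 'protein' column"
        )

    neg = comp[nutrient_cols + aa_cols].lt(0).any(axis=None) if nutrient_cols else False
    if neg:
        bad = comp.loc[(comp[nutrient_cols + aa_cols] < 0).any(axis=1), "food_id"]
        raise LoadError(
            f"{composition_path}: negative composition amount(s) for food(s): "
            f"{', '.join(sorted(bad))}"
        )

    nutrient_defs: dict[str, NutrientDef] = {}
    if nutrients_path is not None:
        nd = _read_csv(nutrients_path, ["nutrient_id", "display_name", "unit", "bound_kind"])
        for row in nd.itertuples(index=False):
            if row.nutrient_id in nutrient_defs:
                raise LoadError(f"{nutrients_path}: duplicate nutrient id {row.nutrient_id!r}")
            nutrient_defs[row.nutrient_id] = NutrientDef(
                nutrient_id=row.nutrient_id,
                display_name=row.display_name,
                unit=row.unit,
                bound_kind=row.bound_kind,
            )
    for nid in nutrient_cols:
        nutrient_defs.setdefault(
            nid, NutrientDef(nutrient_id=nid, display_name=nid, unit="g")
        )

    bioavail: dict[str, dict[str, float]] = {}
    if bioavailability_path is not None:
        bio = _read_csv(bioavailability_path, ["food_id", "nutrient_id", "coefficient"])
        _check_join(bio, known, bioavailability_path, "bioavailability")
        for row in bio.itertuples(index=False):
            bioavail.setdefault(row.food_id, {})[row.nutrient_id] = float(row.coefficient)

    price_by_food: dict[str, list[PriceObservation]] = {}
    for row in prices.itertuples(index=False):
        try:
            obs = PriceObservation(
                food_id=row.food_id,
                store_label=str(row.store_label),
                price=float(row.price),
                package_mass_g=float(row.package_mass_g),
            )
        except ValidationError as exc:
            raise LoadError(f"{prices_path}: {exc}") from exc
        price_by_food.setdefault(row.food_id, []).append(obs)

    ghge_by_food = {r.food_id: float(r.kg_co2e_per_kg) for r in ghge.itertuples(index=False)}
    serving_by_food = {
        r.food_id: (float(r.serving_size_g), str(r.group), str(r.subgroup))
        for r in servings.itertuples(index=False)
    }

    report = ValidationReport()
    foods: dict[str, FoodItem] = {}
    for row in comp.itertuples(index=False):
        fid = row.food_id
        record = row._asdict()
        reasons = []
        if fid not in serving_by_food:
            reasons.append("missing serving data")
        if fid not in price_by_food:
            reasons.append("missing price data")
        if fid not in ghge_by_food:
            reasons.append("missing ghge data")
        if reasons:
            report.dropped.append((fid, "; ".join(reasons)))
            continue

        composition = {
            nid: float(record[nid]) for nid in nutrient_cols if pd.notna(record[nid])
        }
        aa_per_g_protein: dict[str, float] = {}
        if aa_cols:
            aa_raw = {
                c[len("aa_"):]: float(record[c]) for c in aa_cols if pd.notna(record[c])
            }
            if aa_raw:
                aa_per_g_protein = normalise_amino_acids(
                    aa_raw, composition.get("protein", 0.0)
                )

        serving_size_g, group, subgroup = serving_by_food[fid]
        try:
            foods[fid] = FoodItem(
                food_id=fid,
                name=fid,
                group=group,
                subgroup=subgroup,
                serving_size_g=serving_size_g,
                composition=composition,
                aa_per_g_protein=aa_per_g_protein,
                bioavailability=bioavail.get(fid, {}),
                ghge_per_kg=ghge_by_food[fid],
                price_per_kg=average_price(price_by_food[fid]),
            )
        except ValidationError as exc:
            raise LoadError(f"food {fid!r}: {exc}") from exc

    if ghge["kg_co2e_per_kg"].lt(0).any():
        bad = sorted(ghge.loc[ghge["kg_co2e_per_kg"] < 0, "food_id"])
        raise LoadError(f"{ghge_path}: negative ghge for food(s): {', '.join(bad)}")

    report.messages.append(
        f"loaded {len(foods)} foods, {len(nutrient_defs)} nutrients, "
        f"{len(report.dropped)} dropped"
    )
    return FoodDatabase(nutrients=nutrient_defs, foods=foods, currency=currency), report


def load_baseline(path: str | Path, demographic_label: str, db: FoodDatabase) -> BaselineDiet:
    """Load a baseline diet (``food_id, weekly_servings``) against a database."""
    df = _read_csv(path, ["food_id", "weekly_servings"])
    _check_join(df, set(db.foods), path, "baseline")
    if df["food_id"].duplicated().any():
        dups = sorted(df.loc[df["food_id"].duplicated(), "food_id"])
        raise LoadError(f"{path}: duplicate food id(s): {', '.join(dups)}")
    servings = {r.food_id: float(r.weekly_servings) for r in df.itertuples(index=False)}
    try:
        return BaselineDiet(demographic_label=demographic_label, servings=servings)
    except ValidationError as exc:
        raise LoadError(f"{path}: {exc}") from exc
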