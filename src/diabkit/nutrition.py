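"""Food--nutrition database: loading, fuzzy lookup, and intake accounting.

The store mirrors the three record shapes of a food-composition database:

* **ingredients** — per-100 g vectors over the full nutrient panel
  (energy in kcal, masses in g or mg as the units manifest declares);
* **packaged foods** — per-100 g values for the five core label nutrients
  (energy, fat, carbohydrate, protein, Na);
* **dishes** — recipes as (ingredient, amount-in-grams) lists whose
  nutrition is aggregated linearly from the ingredient table.

A ``-`` cell means the nutrient is *absent from the record* — unknown, not
zero — and that distinction is preserved through every aggregation: a dish
nutrient computed while skipping an absent ingredient value is flagged
``partially_known`` rather than silently treated as complete.

All names are matched after normalisation (case-fold, trim, collapse
internal whitespace); fuzzy lookup scores candidates by normalised edit
distance (via edlib) in [0, 1], with 1.0 reserved for exact normalised
equality.
"""

from __future__ import annotations

import datetime as _dt
import io
import math
import unicodedata
from dataclasses import dataclass, field

import edlib
import pandas as pd
import yaml

__all__ = [
    "CORE_NUTRIENTS",
    "ABSENT",
    "NutrientVector",
    "IngredientRecord",
    "PackagedFoodRecord",
    "DishRecord",
    "DietRecord",
    "NutritionDB",
    "ParseError",
    "ConflictError",
    "FoodLookupError",
    "load_database",
    "match_food",
    "dish_nutrients",
    "intake_series",
    "mean_intake",
    "normalize_name",
]

CORE_NUTRIENTS = ("energy", "fat", "carbohydrate", "protein", "Na")


class ParseError(ValueError):
    """Malformed database row; message names file and line."""


class ConflictError(ValueError):
    """Duplicate normalised name within one table."""


class FoodLookupError(KeyError):
    """A food or ingredient name that does not resolve."""


class _Absent:
    __slots__ = ()

    def __repr__(self) -> str:  # pragma: no cover
        return "ABSENT"


#: sentinel for a nutrient marked "-" (absent from the record, not zero)
ABSENT = _Absent()


def normalize_name(name: str) -> str:
    """Case-fold, trim, and collapse internal whitespace."""
    return " ".join(unicodedata.normalize("NFKC", name).casefold().split())


@dataclass
class NutrientVector:
    """Per-100 g nutrient amounts with explicit absence and partial flags."""

    amounts: dict[str, float] = field(default_factory=dict)
    absent: set[str] = field(default_factory=set)
    partially_known: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for name, v in self.amounts.items():
            if v < 0:
                raise ValueError(f"negative amount for nutrient {name!r}: {v}")
        overlap = set(self.amounts) & self.absent
        if overlap:
            raise ValueError(f"nutrients both present and absent: {sorted(overlap)}")

    def get(self, name: str):
        if name in self.absent:
            return ABSENT
        return self.amounts.get(name)

    def __contains__(self, name: str) -> bool:
        return name in self.amounts or name in self.absent

    def names(self) -> list[str]:
        return sorted(set(self.amounts) | self.absent)

    def scaled(self, factor: float) -> "NutrientVector":
        return NutrientVector(
            amounts={k: v * factor for k, v in self.amounts.items()},
            absent=set(self.absent),
            partially_known=set(self.partially_known),
        )


@dataclass(frozen=True)
class IngredientRecord:
    name: str
    nutrients: NutrientVector
    kind: str = "ingredient"


@dataclass(frozen=True)
class PackagedFoodRecord:
    name: str
    nutrients: NutrientVector
    kind: str = "packaged"

    def __post_init__(self) -> None:
        keys = set(self.nutrients.amounts) | self.nutrients.absent
        if keys != set(CORE_NUTRIENTS):
            raise ValueError(
                f"packaged food {self.name!r} must carry exactly the five core "
                f"nutrients {CORE_NUTRIENTS}, got {sorted(keys)}"
            )


@dataclass(frozen=True)
class DishRecord:
    name: str
    composition: tuple[tuple[str, float], ...]
    kind: str = "dish"

    def __post_init__(self) -> None:
        for ing, amount in self.composition:
            if amount <= 0:
                raise ValueError(
                    f"dish {self.name!r}: non-positive amount {amount} for {ing!r}"
                )


@dataclass(frozen=True)
class DietRecord:
    date: _dt.date
    food_name: str
    weight: float

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError(f"diet record weight must be positive, got {self.weight}")


class NutritionDB:
    """Indexed store over the three food tables plus the units manifest."""

    def __init__(self, ingredients, packaged, dishes, units: dict[str, str]):
        self.units = dict(units)
        self._tables: dict[str, dict[str, object]] = {
            "ingredient": {}, "packaged": {}, "dish": {},
        }
        for rec in ingredients:
            self._add("ingredient", rec)
        for rec in packaged:
            self._add("packaged", rec)
        for rec in dishes:
            self._add("dish", rec)
        self._check_units()

    def _add(self, table: str, rec) -> None:
        key = normalize_name(rec.name)
        if key in self._tables[table]:
            raise ConflictError(
                f"duplicate {table} name {rec.name!r} (normalised {key!r})"
            )
        self._tables[table][key] = rec

    def _check_units(self) -> None:
        for table in ("ingredient", "packaged"):
            for rec in self._tables[table].values():
                missing = [n for n in rec.nutrients.names() if n not in self.units]
                if missing:
                    raise ParseError(
                        f"{table} {rec.name!r}: nutrients {missing} missing from "
                        "the units manifest"
                    )

    @property
    def counts(self) -> tuple[int, int, int]:
        return (
            len(self._tables["ingredient"]),
            len(self._tables["packaged"]),
            len(self._tables["dish"]),
        )

    def ingredient(self, name: str) -> IngredientRecord:
        key = normalize_name(name)
        rec = self._tables["ingredient"].get(key)
        if rec is None:
            raise FoodLookupError(f"unknown ingredient {name!r}")
        return rec

    def lookup_exact(self, name: str):
        """Exact-tier lookup across all three tables (dish > packaged >
        ingredient precedence on the rare name collision)."""
        key = normalize_name(name)
        for table in ("dish", "packaged", "ingredient"):
            rec = self._tables[table].get(key)
            if rec is not None:
                return rec
        raise FoodLookupError(f"no exact match for food {name!r}")

    def all_records(self):
        for table in ("ingredient", "packaged", "dish"):
            yield from self._tables[table].values()

    def per_100g(self, record) -> NutrientVector:
        """Per-100 g nutrient vector for any record kind."""
        if isinstance(record, DishRecord):
            _, per100 = dish_nutrients(record, self)
            return per100
        return record.nutrients


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def _read_rows(path) -> tuple[list[str], list[tuple[int, list[str]]]]:
    with open(path, "r", encoding="utf-8", newline="") as fh:
        text = fh.read()
    rows: list[tuple[int, list[str]]] = []
    reader = pd.read_csv(
        io.StringIO(text), dtype=str, keep_default_na=False, skip_blank_lines=True
    )
    header = [c.strip() for c in reader.columns]
    for i, row in enumerate(reader.itertuples(index=False), start=2):
        rows.append((i, [str(v).strip() for v in row]))
    return header, rows


def _parse_amount(cell: str, path, line: int, column: str):
    if cell in ("-", ""):
        return ABSENT
    try:
        value = float(cell)
    except ValueError as exc:
        raise ParseError(
            f"{path}:{line}: column {column!r}: cannot parse {cell!r} as a number"
        ) from exc
    if value < 0 or math.isnan(value):
        raise ParseError(f"{path}:{line}: column {column!r}: invalid amount {value}")
    return value


def _vector_from_cells(header, cells, path, line) -> NutrientVector:
    amounts: dict[str, float] = {}
    absent: set[str] = set()
    for col, cell in zip(header, cells):
        v = _parse_amount(cell, path, line, col)
        if v is ABSENT:
            absent.add(col)
        else:
            amounts[col] = v
    return NutrientVector(amounts=amounts, absent=absent)


def _load_ingredients(path) -> list[IngredientRecord]:
    header, rows = _read_rows(path)
    if not header or normalize_name(header[0]) != "name":
        raise ParseError(f"{path}:1: first column must be 'name'")
    out = []
    for line, cells in rows:
        if len(cells) != len(header):
            raise ParseError(f"{path}:{line}: expected {len(header)} fields")
        if not cells[0]:
            raise ParseError(f"{path}:{line}: empty ingredient name")
        out.append(
            IngredientRecord(
                name=cells[0],
                nutrients=_vector_from_cells(header[1:], cells[1:], path, line),
            )
        )
    return out


def _load_packaged(path) -> list[PackagedFoodRecord]:
    header, rows = _read_rows(path)
    if not header or normalize_name(header[0]) != "name":
        raise ParseError(f"{path}:1: first column must be 'name'")
    if set(header[1:]) != set(CORE_NUTRIENTS):
        raise ParseError(
            f"{path}:1: packaged-food columns must be exactly {CORE_NUTRIENTS}"
        )
    out = []
    for line, cells in rows:
        if not cells[0]:
            raise ParseError(f"{path}:{line}: empty packaged-food name")
        try:
            out.append(
                PackagedFoodRecord(
                    name=cells[0],
                    nutrients=_vector_from_cells(header[1:], cells[1:], path, line),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{line}: {exc}") from exc
    return out


def _load_dishes(path) -> list[DishRecord]:
    header, rows = _read_rows(path)
    norm = [normalize_name(c) for c in header]
    if norm[:3] == ["dish", "ingredient", "amount_g"] and len(norm) == 3:
        return _load_dishes_long(path, rows)
    if not header or normalize_name(header[0]) != "name":
        raise ParseError(
            f"{path}:1: dish file must be long-format (dish,ingredient,amount_g) "
            "or wide-format starting with 'name'"
        )
    out = []
    for line, cells in rows:
        if not cells[0]:
            raise ParseError(f"{path}:{line}: empty dish name")
        pairs = []
        tail = cells[1:]
        for j in range(0, len(tail) - 1, 2):
            ing, amt = tail[j], tail[j + 1]
            if not ing and not amt:
                continue
            if not ing or not amt:
                raise ParseError(
                    f"{path}:{line}: unpaired ingredient/amount at column {j + 2}"
                )
            v = _parse_amount(amt, path, line, f"amount[{j // 2}]")
            if v is ABSENT or v <= 0:
                raise ParseError(f"{path}:{line}: invalid amount {amt!r} for {ing!r}")
            pairs.append((ing, float(v)))
        if not pairs:
            raise ParseError(f"{path}:{line}: dish {cells[0]!r} has no ingredients")
        out.append(DishRecord(name=cells[0], composition=tuple(pairs)))
    return out


def _load_dishes_long(path, rows) -> list[DishRecord]:
    grouped: dict[str, list[tuple[str, float]]] = {}
    order: list[str] = []
    for line, cells in rows:
        if len(cells) != 3 or not all(cells):
            raise ParseError(f"{path}:{line}: long-format row needs 3 non-empty fields")
        dish, ing, amt = cells
        v = _parse_amount(amt, path, line, "amount_g")
        if v is ABSENT or v <= 0:
            raise ParseError(f"{path}:{line}: invalid amount {amt!r}")
        if dish not in grouped:
            grouped[dish] = []
            order.append(dish)
        grouped[dish].append((ing, float(v)))
    return [DishRecord(name=d, composition=tuple(grouped[d])) for d in order]


def load_units_manifest(path) -> dict[str, str]:
    with open(path, "r", encoding="utf-8") as fh:
        units = yaml.safe_load(fh)
    if not isinstance(units, dict) or not all(
        isinstance(k, str) and isinstance(v, str) for k, v in units.items()
    ):
        raise ParseError(f"{path}: units manifest must map nutrient name -> unit")
    return units


def load_database(ingredient_file, packaged_file, dish_file, units_file) -> NutritionDB:
    """Load and index the three tables; the units manifest is mandatory."""
    units = load_units_manifest(units_file)
    db = NutritionDB(
        ingredients=_load_ingredients(ingredient_file),
        packaged=_load_packaged(packaged_file),
        dishes=_load_dishes(dish_file),
        units=units,
    )
    # dish compositions must resolve at aggregation time; validate eagerly
    for rec in db.all_records():
        if isinstance(rec, DishRecord):
            for ing, _ in rec.composition:
                db.ingredient(ing)
    return db


# ---------------------------------------------------------------------------
# lookup and aggregation
# ---------------------------------------------------------------------------

def match_food(query: str, db: NutritionDB, min_score: float = 0.0, limit: int | None = None):
    """Rank database records against ``query``.

    Exact normalised equality scores 1.0; otherwise the score is
    ``1 - levenshtein / max(len)`` over normalised strings.  Results are
    sorted by descending score with lexicographic tie-break, filtered at
    ``min_score``.
    """
    if not query or not query.strip():
        raise ValueError("empty food query")
    q = normalize_name(query)
    scored = []
    for rec in db.all_records():
        name = normalize_name(rec.name)
        if name == q:
            score = 1.0
        else:
            dist = edlib.align(q, name, task="distance")["editDistance"]
            score = 1.0 - dist / max(len(q), len(name))
        if score >= min_score:
            scored.append((rec, score))
    scored.sort(key=lambda t: (-t[1], normalize_name(t[0].name)))
    return scored[:limit] if limit is not None else scored


def dish_nutrients(dish: DishRecord, db: NutritionDB) -> tuple[NutrientVector, NutrientVector]:
    """Aggregate a dish linearly from its ingredients.

    Returns ``(whole_dish_totals, per_100g)``.  Per nutrient,
    total = sum_i amount_i * value_i / 100 over ingredients where the value
    is present; if any contributing ingredient marks the nutrient absent the
    output amount is flagged ``partially_known`` (and nutrients absent from
    *every* ingredient stay absent).
    """
    resolved = [(db.ingredient(ing), amount) for ing, amount in dish.composition]
    names: set[str] = set()
    for rec, _ in resolved:
        names |= set(rec.nutrients.names())
    totals: dict[str, float] = {}
    partial: set[str] = set()
    absent: set[str] = set()
    for nutrient in names:
        acc = 0.0
        n_present = 0
        n_absent = 0
        for rec, amount in resolved:
            v = rec.nutrients.get(nutrient)
            if v is ABSENT or v is None:
                n_absent += 1
                continue
            acc += amount * v / 100.0
            n_present += 1
        if n_present == 0:
            absent.add(nutrient)
        else:
            totals[nutrient] = acc
            if n_absent:
                partial.add(nutrient)
    total_mass = sum(amount for _, amount in resolved)
    whole = NutrientVector(amounts=totals, absent=absent, partially_known=partial)
    per100 = whole.scaled(100.0 / total_mass)
    return whole, per100


def intake_series(
    records,
    db: NutritionDB,
    start: _dt.date | None = None,
    days: int | None = None,
) -> pd.DataFrame:
    """Per-day nutrient totals from diet records.

    Every record's food must resolve at the exact tier.  The result is a
    date-indexed frame; when ``start``/``days`` delimit a range, days
    without records appear as explicit zero rows.
    """
    unresolved = []
    contributions: dict[_dt.date, dict[str, float]] = {}
    for rec in records:
        try:
            food = db.lookup_exact(rec.food_name)
        except FoodLookupError:
            unresolved.append(rec)
            continue
        per100 = db.per_100g(food)
        day = contributions.setdefault(rec.date, {})
        for nutrient, value in per100.amounts.items():
            day[nutrient] = day.get(nutrient, 0.0) + rec.weight * value / 100.0
    if unresolved:
        names = ", ".join(f"{r.food_name!r} ({r.date})" for r in unresolved)
        raise FoodLookupError(f"unresolved diet records: {names}")

    if start is not None and days is not None:
        index = [start + _dt.timedelta(d) for d in range(days)]
    else:
        index = sorted(contributions)
    nutrients = sorted({n for day in contributions.values() for n in day})
    frame = pd.DataFrame(0.0, index=pd.Index(index, name="date"), columns=nutrients)
    for date, day in contributions.items():
        if date in frame.index:
            for nutrient, value in day.items():
                frame.loc[date, nutrient] = value
    return frame


def mean_intake(series: pd.DataFrame, window: int = 14) -> pd.Series:
    """Arithmetic daily-mean nutrient vector over the first ``window`` days
    of the series (zero days included)."""
    if len(series) < window:
        raise ValueError(
            f"series covers {len(series)} days, shorter than the {window}-day window"
        )
    return series.iloc[:window].mean(axis=0)
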