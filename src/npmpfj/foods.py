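"""Domain types and CSV I/O for per-100 g/mL food-composition records.

A food is described by the seven components the profiling model scores:
energy (kcal), saturated fat (g), total sugars (g), sodium (mg), the
fruit/vegetable/nut/legume proportion (fvnl, % of product amount, with a
flag distinguishing concentrated fruit/vegetable products), protein (g) and
dietary fiber (g) — all per 100 g or 100 mL of product.

Japanese labels declare salt equivalent rather than sodium; a ``salt_g``
column, when present, is converted to mg sodium at read time
(1 g sodium = 2.54 g NaCl). Missing or malformed nutrient values are hard
errors collected into a row-level report — never imputed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

from ._rounding import round_half_up
from .errors import AlignmentError, RowValidationError, SchemaError

#: grams of NaCl per gram of sodium
SALT_G_PER_G_SODIUM = 2.54

BASIS_VALUES = ("per_100_g", "per_100_mL")

#: canonical field -> default CSV column name
DEFAULT_SCHEMA: dict[str, str] = {
    "food_id": "food_id",
    "name": "name",
    "family": "family",
    "basis": "basis",
    "energy": "energy_kcal",
    "saturated_fat": "satfat_g",
    "total_sugars": "sugars_g",
    "sodium": "sodium_mg",
    "salt": "salt_g",
    "fvnl_pct": "fvnl_pct",
    "fvnl_concentrated": "fvnl_concentrated",
    "protein": "protein_g",
    "dietary_fiber": "fiber_g",
    "category": "category",
}

_REQUIRED_NUTRIENTS = (
    "energy",
    "saturated_fat",
    "total_sugars",
    "fvnl_pct",
    "fvnl_concentrated",
    "protein",
    "dietary_fiber",
)

#: fixed column order of scored output tables
SCORED_COLUMNS = [
    "food_id",
    "name",
    "family",
    "basis",
    "energy_kcal",
    "satfat_g",
    "sugars_g",
    "sodium_mg",
    "fvnl_pct",
    "fvnl_concentrated",
    "protein_g",
    "fiber_g",
    "energy_pts",
    "satfat_pts",
    "sugars_pts",
    "sodium_pts",
    "v_pts",
    "p_pts",
    "f_pts",
    "baseline",
    "final",
    "category",
    "rating",
]


def salt_to_sodium(salt_g: float) -> int:
    """Convert grams of salt equivalent (NaCl) to mg sodium.

    7 g NaCl corresponds to 2756 mg sodium; the result is rounded half-up
    to the nearest integer milligram.
    """
    if salt_g < 0:
        raise ValueError(f"salt equivalent must be non-negative, got {salt_g}")
    return int(round_half_up(salt_g * 1000.0 / SALT_G_PER_G_SODIUM, 0))


@dataclass(frozen=True)
class NutrientProfile:
    """The seven per-100 g/mL component values a food is scored on."""

    energy: float  # kcal
    saturated_fat: float  # g
    total_sugars: float  # g
    sodium: float  # mg
    fvnl_pct: float  # % of total product amount, 0-100
    fvnl_concentrated: bool
    protein: float  # g
    dietary_fiber: float  # g

    def __post_init__(self):
        for name in ("energy", "saturated_fat", "total_sugars", "sodium",
                     "fvnl_pct", "protein", "dietary_fiber"):
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or isinstance(v, bool):
                raise ValueError(f"{name} must be numeric, got {v!r}")
            if v != v or v < 0:  # NaN or negative
                raise ValueError(f"{name} must be >= 0, got {v!r}")
        if self.fvnl_pct > 100:
            raise ValueError(f"fvnl_pct must be <= 100, got {self.fvnl_pct}")


@dataclass(frozen=True)
class FoodRecord:
    """One food-composition record: identity, family label, and profile."""

    food_id: str
    name: str
    profile: NutrientProfile
    family: Optional[str] = None
    basis: str = "per_100_g"
    category: Optional[int] = None

    def __post_init__(self):
        if not self.food_id:
            raise ValueError("food_id must be a non-empty string")
        if self.basis not in BASIS_VALUES:
            raise ValueError(f"basis must be one of {BASIS_VALUES}, got {self.basis!r}")
        if self.category is not None and self.category not in range(1, 7):
            raise ValueError(f"category must be in 1..6, got {self.category!r}")


@dataclass(frozen=True)
class PointVector:
    """A food's seven component points plus baseline and final score.

    baseline = energy + satfat + sugars + sodium points;
    final = baseline - V - P - F points. Both identities are enforced on
    construction, as are the per-component point ranges.
    """

    energy_pts: int
    satfat_pts: int
    sugars_pts: int
    sodium_pts: int
    v_pts: int
    p_pts: int
    f_pts: int
    baseline: int
    final: int

    _RANGES = {
        "energy_pts": (0, 11),
        "satfat_pts": (0, 30),
        "sugars_pts": (0, 25),
        "sodium_pts": (0, 30),
        "v_pts": (0, 8),
        "p_pts": (0, 15),
        "f_pts": (0, 15),
    }

    def __post_init__(self):
        for name, (lo, hi) in self._RANGES.items():
            v = getattr(self, name)
            if not isinstance(v, int) or isinstance(v, bool) or not lo <= v <= hi:
                raise ValueError(f"{name} must be an integer in [{lo}, {hi}], got {v!r}")
        if self.baseline != self.energy_pts + self.satfat_pts + self.sugars_pts + self.sodium_pts:
            raise ValueError("baseline must equal the sum of the four baseline components")
        if self.final != self.baseline - self.v_pts - self.p_pts - self.f_pts:
            raise ValueError("final must equal baseline minus V, P and F points")
        if not 0 <= self.baseline <= 96:
            raise ValueError(f"baseline out of range [0, 96]: {self.baseline}")
        if not -38 <= self.final <= 96:
            raise ValueError(f"final out of range [-38, 96]: {self.final}")

    @classmethod
    def from_points(cls, energy_pts: int, satfat_pts: int, sugars_pts: int,
                    sodium_pts: int, v_pts: int, p_pts: int, f_pts: int) -> "PointVector":
        baseline = energy_pts + satfat_pts + sugars_pts + sodium_pts
        final = baseline - v_pts - p_pts - f_pts
        return cls(energy_pts, satfat_pts, sugars_pts, sodium_pts,
                   v_pts, p_pts, f_pts, baseline, final)

    def components(self) -> tuple[int, ...]:
        """The 7-dimensional point vector used for clustering."""
        return (self.energy_pts, self.satfat_pts, self.sugars_pts,
                self.sodium_pts, self.v_pts, self.p_pts, self.f_pts)


@dataclass(frozen=True)
class RowError:
    """A per-row validation failure with enough context to locate it."""

    row: int
    food_id: Optional[str]
    message: str


_TRUE = {"true", "1", "yes", "y", "t"}
_FALSE = {"false", "0", "no", "n", "f", ""}


def _parse_bool(text: str) -> bool:
    t = text.strip().lower()
    if t in _TRUE:
        return True
    if t in _FALSE:
        return False
    raise ValueError(f"cannot interpret {text!r} as a boolean flag")


def _parse_number(text: str, field_name: str) -> float:
    t = text.strip()
    if t == "":
        raise ValueError(f"{field_name} is missing")
    try:
        v = float(t)
    except ValueError:
        raise ValueError(f"{field_name} is not numeric: {text!r}") from None
    if v != v:
        raise ValueError(f"{field_name} is missing (NaN)")
    if v < 0:
        raise ValueError(f"{field_name} is negative: {v}")
    return v


def read_food_table(
    path,
    schema: Optional[Mapping[str, str]] = None,
    errors: str = "raise",
) -> list[FoodRecord] | tuple[list[FoodRecord], list[RowError]]:
    """Read a food-composition CSV into validated ``FoodRecord`` objects.

    Parameters
    ----------
    path
        CSV file with a header row (UTF-8).
    schema
        Optional mapping from canonical field names (keys of
        ``DEFAULT_SCHEMA``) to the column names used in the file.
    errors
        ``"raise"`` (default): raise :class:`RowValidationError` if any row
        is invalid. ``"collect"``: return ``(records, row_errors)`` with
        invalid rows excluded from ``records``.

    Sodium may be supplied either as ``sodium_mg`` or as a salt-equivalent
    ``salt_g`` column (converted via :func:`salt_to_sodium`); when a row has
    both, sodium wins.
    """
    if errors not in ("raise", "collect"):
        raise ValueError("errors must be 'raise' or 'collect'")
    cols = dict(DEFAULT_SCHEMA)
    if schema:
        cols.update(schema)

    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for fld in ("food_id", "name", *_REQUIRED_NUTRIENTS):
            if cols[fld] not in header:
                raise SchemaError(cols[fld])
        has_sodium = cols["sodium"] in header
        has_salt = cols["salt"] in header
        if not has_sodium and not has_salt:
            raise SchemaError(cols["sodium"])

        records: list[FoodRecord] = []
        row_errors: list[RowError] = []
        seen_ids: set[str] = set()
        for i, row in enumerate(reader, start=2):  # header is line 1
            food_id = (row.get(cols["food_id"]) or "").strip()
            try:
                if not food_id:
                    raise ValueError("food_id is missing")
                if food_id in seen_ids:
                    raise ValueError(f"duplicate food_id {food_id!r}")
                sodium_text = (row.get(cols["sodium"]) or "").strip() if has_sodium else ""
                if sodium_text:
                    sodium = _parse_number(sodium_text, "sodium")
                elif has_salt and (row.get(cols["salt"]) or "").strip():
                    sodium = float(salt_to_sodium(_parse_number(row[cols["salt"]], "salt")))
                else:
                    raise ValueError("sodium (or salt equivalent) is missing")
                profile = NutrientProfile(
                    energy=_parse_number(row[cols["energy"]], "energy"),
                    saturated_fat=_parse_number(row[cols["saturated_fat"]], "saturated_fat"),
                    total_sugars=_parse_number(row[cols["total_sugars"]], "total_sugars"),
                    sodium=sodium,
                    fvnl_pct=_parse_number(row[cols["fvnl_pct"]], "fvnl_pct"),
                    fvnl_concentrated=_parse_bool(row[cols["fvnl_concentrated"]] or ""),
                    protein=_parse_number(row[cols["protein"]], "protein"),
                    dietary_fiber=_parse_number(row[cols["dietary_fiber"]], "dietary_fiber"),
                )
                family = (row.get(cols["family"]) or "").strip() or None
                basis = (row.get(cols["basis"]) or "").strip() or "per_100_g"
                cat_text = (row.get(cols["category"]) or "").strip()
                category = int(float(cat_text)) if cat_text else None
                records.append(FoodRecord(
                    food_id=food_id,
                    name=(row.get(cols["name"]) or "").strip(),
                    profile=profile,
                    family=family,
                    basis=basis,
                    category=category,
                ))
                seen_ids.add(food_id)
            except ValueError as exc:
                row_errors.append(RowError(row=i, food_id=food_id or None, message=str(exc)))

    if errors == "collect":
        return records, row_errors
    if row_errors:
        raise RowValidationError(row_errors)
    return records


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float) and value.is_integer() and abs(value) < 1e15:
        return str(int(value))
    return str(value)


def write_scored_table(
    records: Sequence[FoodRecord],
    points: Sequence[PointVector],
    path,
    ratings: Optional[Sequence[Optional[float]]] = None,
    categories: Optional[Sequence[Optional[int]]] = None,
) -> None:
    """Write foods with their point vectors (and optional categories/ratings)
    to a CSV in the fixed :data:`SCORED_COLUMNS` order.

    ``categories``, when given, overrides each record's own ``category``.
    """
    if len(records) != len(points):
        raise AlignmentError(f"{len(records)} records but {len(points)} point vectors")
    if ratings is not None and len(ratings) != len(records):
        raise AlignmentError(f"{len(records)} records but {len(ratings)} ratings")
    if categories is not None and len(categories) != len(records):
        raise AlignmentError(f"{len(records)} records but {len(categories)} categories")

    with open(Path(path), "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(SCORED_COLUMNS)
        for i, (rec, pv) in enumerate(zip(records, points)):
            cat = categories[i] if categories is not None else rec.category
            rating = ratings[i] if ratings is not None else None
            p = rec.profile
            writer.writerow([
                rec.food_id, rec.name, rec.family or "", rec.basis,
                _fmt(p.energy), _fmt(p.saturated_fat), _fmt(p.total_sugars),
                _fmt(p.sodium), _fmt(p.fvnl_pct), _fmt(p.fvnl_concentrated),
                _fmt(p.protein), _fmt(p.dietary_fiber),
                pv.energy_pts, pv.satfat_pts, pv.sugars_pts, pv.sodium_pts,
                pv.v_pts, pv.p_pts, pv.f_pts, pv.baseline, pv.final,
                _fmt(cat), _fmt(rating),
            ])


def read_scored_table(path) -> tuple[list[FoodRecord], list[PointVector], list[Optional[float]]]:
    """Read back a CSV produced by :func:`write_scored_table`."""
    records = read_food_table(path)
    points: list[PointVector] = []
    ratings: list[Optional[float]] = []
    with open(Path(path), newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            points.append(PointVector(
                energy_pts=int(row["energy_pts"]),
                satfat_pts=int(row["satfat_pts"]),
                sugars_pts=int(row["sugars_pts"]),
                sodium_pts=int(row["sodium_pts"]),
                v_pts=int(row["v_pts"]),
                p_pts=int(row["p_pts"]),
                f_pts=int(row["f_pts"]),
                baseline=int(row["baseline"]),
                final=int(row["final"]),
            ))
            ratings.append(float(row["rating"]) if row.get("rating") else None)
    return records, points, ratings
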