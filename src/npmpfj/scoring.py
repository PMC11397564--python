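"""Point scoring: ladder lookup, fvnl points, the protein cap, and the
baseline/final score arithmetic.

Baseline points = energy + saturated fat + total sugars + sodium points.
Final score = baseline - V - P - F points (lower is healthier).

Protein cap: a product with baseline points >= 13 scores no protein points
unless it earns at least 5 V (fvnl) points.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

from .bands import AT_LEAST, BandTable, canonical_npm_pfj_tables
from .errors import ConfigurationError
from .foods import FoodRecord, NutrientProfile, PointVector

#: exact-equality tolerance for the fvnl "=100" top rung
_TOP_EQ_TOL = 1e-9

#: baseline at or above which the protein cap engages
PROTEIN_CAP_BASELINE = 13
#: V points needed to lift the cap
PROTEIN_CAP_V_POINTS = 5

_REQUIRED_TABLES = (
    "energy", "satfat", "sugars", "sodium",
    "fvnl_concentrated", "fvnl_nonconcentrated", "protein", "fiber",
)


def lookup_points(value: float, table: BandTable) -> int:
    """Points awarded for ``value`` under a ladder.

    Strictly-greater ladders award the largest k with value > rung k;
    at-least ladders the largest k with value >= rung k. On a
    ``top_equality`` ladder the top rung is awarded only when the value
    equals it (within 1e-9).
    """
    if value < 0 or value != value:
        raise ValueError(f"component value must be non-negative, got {value!r}")
    points = 0
    n = table.max_points
    for k, rung in enumerate(table.thresholds, start=1):
        if table.boundary_mode == AT_LEAST:
            if table.top_equality and k == n:
                hit = abs(value - rung) <= _TOP_EQ_TOL
            else:
                hit = value >= rung
        else:
            hit = value > rung
        if hit:
            points = k
    return points


def fvnl_points(pct: float, concentrated: bool,
                tables: Optional[Mapping[str, BandTable]] = None) -> int:
    """V points for a fruit/vegetable/nut/legume proportion (% of product).

    A food contributes through exactly one fvnl ladder, selected by the
    concentrated flag.
    """
    if not 0 <= pct <= 100:
        raise ValueError(f"fvnl percentage must lie in [0, 100], got {pct!r}")
    tables = tables if tables is not None else canonical_npm_pfj_tables()
    key = "fvnl_concentrated" if concentrated else "fvnl_nonconcentrated"
    return lookup_points(pct, tables[key])


def score_food(profile: NutrientProfile,
               tables: Optional[Mapping[str, BandTable]] = None) -> PointVector:
    """Score one nutrient profile into a :class:`PointVector`.

    Applies the protein cap: raw protein points are voided when
    baseline >= 13 and V points < 5.
    """
    tables = tables if tables is not None else canonical_npm_pfj_tables()
    missing = [c for c in _REQUIRED_TABLES if c not in tables]
    if missing:
        raise ConfigurationError(f"missing band tables: {', '.join(missing)}")

    energy_pts = lookup_points(profile.energy, tables["energy"])
    satfat_pts = lookup_points(profile.saturated_fat, tables["satfat"])
    sugars_pts = lookup_points(profile.total_sugars, tables["sugars"])
    sodium_pts = lookup_points(profile.sodium, tables["sodium"])
    v_pts = fvnl_points(profile.fvnl_pct, profile.fvnl_concentrated, tables)
    f_pts = lookup_points(profile.dietary_fiber, tables["fiber"])
    p_pts = lookup_points(profile.protein, tables["protein"])

    baseline = energy_pts + satfat_pts + sugars_pts + sodium_pts
    if baseline >= PROTEIN_CAP_BASELINE and v_pts < PROTEIN_CAP_V_POINTS:
        p_pts = 0
    return PointVector.from_points(
        energy_pts, satfat_pts, sugars_pts, sodium_pts, v_pts, p_pts, f_pts)


def score_records(records: Sequence[FoodRecord],
                  tables: Optional[Mapping[str, BandTable]] = None) -> list[PointVector]:
    """Score a sequence of food records (tables resolved once)."""
    tables = tables if tables is not None else canonical_npm_pfj_tables()
    return [score_food(rec.profile, tables) for rec in records]
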