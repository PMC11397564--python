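"""Synthetic food-composition data.

The default archetypes mirror the signature scoring pattern of the six
food categories: one archetype is low in everything (beverage-like), one
is high in energy/protein/fiber (soybean- and seed-product-like), one high
in saturated fat (dairy/confectionery-like), one high in sodium
(pickle/dried-fish-like), one high in fvnl (vegetable/fruit-product-like),
and one high in total sugars (jam/confectionery-like). Nutrients are drawn
as independent clipped normals — adequate for planted-structure tests, with
no attempt to model real nutrient covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._rounding import round_half_up
from .foods import FoodRecord, NutrientProfile, PointVector

#: per-100 g physical upper bounds used to truncate draws
PHYSICAL_BOUNDS: dict[str, float] = {
    "energy": 900.0,
    "saturated_fat": 100.0,
    "total_sugars": 100.0,
    "sodium": 5000.0,
    "fvnl_pct": 100.0,
    "protein": 100.0,
    "dietary_fiber": 50.0,
}

#: decimal places values are emitted at (kcal/mg integers, grams/% one decimal)
_PRECISION = {
    "energy": 0,
    "saturated_fat": 1,
    "total_sugars": 1,
    "sodium": 0,
    "fvnl_pct": 1,
    "protein": 1,
    "dietary_fiber": 1,
}

_NUTRIENTS = tuple(PHYSICAL_BOUNDS)


@dataclass(frozen=True)
class ArchetypeSpec:
    """A planted food group: per-nutrient (mean, sd) plus metadata."""

    name: str
    n: int
    means: Mapping[str, float]
    sds: Mapping[str, float]
    fvnl_concentrated: bool = False
    families: tuple[str, ...] = ()

    def __post_init__(self):
        if self.n < 1:
            raise ValueError(f"archetype {self.name!r}: n must be >= 1")
        for nut in _NUTRIENTS:
            if nut not in self.means or nut not in self.sds:
                raise ValueError(f"archetype {self.name!r}: missing {nut!r}")
            m, s = self.means[nut], self.sds[nut]
            if not 0 <= m <= PHYSICAL_BOUNDS[nut]:
                raise ValueError(
                    f"archetype {self.name!r}: mean {nut}={m} outside "
                    f"[0, {PHYSICAL_BOUNDS[nut]}]")
            if s < 0:
                raise ValueError(f"archetype {self.name!r}: sd {nut}={s} negative")


def _arch(name, n, families, fvnl_concentrated=False, **mean_sd) -> ArchetypeSpec:
    means = {k: v[0] for k, v in mean_sd.items()}
    sds = {k: v[1] for k, v in mean_sd.items()}
    return ArchetypeSpec(name=name, n=n, means=means, sds=sds,
                         fvnl_concentrated=fvnl_concentrated,
                         families=tuple(families))


def default_archetypes(n_per: int = 30) -> list[ArchetypeSpec]:
    """Six archetypes matching the categories' signature point patterns."""
    return [
        _arch("low_everything", n_per, ("beverages", "breads", "yogurt"),
              energy=(40, 15), saturated_fat=(0.2, 0.1), total_sugars=(1.5, 0.6),
              sodium=(50, 25), fvnl_pct=(5, 3), protein=(1.5, 0.7),
              dietary_fiber=(0.3, 0.2)),
        _arch("high_protein_fiber", n_per, ("soybean products", "seed products"),
              energy=(480, 40), saturated_fat=(1.0, 0.3), total_sugars=(4, 1),
              sodium=(80, 30), fvnl_pct=(20, 8), protein=(25, 3),
              dietary_fiber=(9, 1.5)),
        _arch("high_satfat", n_per, ("cheeses", "western confectioneries", "pastries"),
              energy=(400, 50), saturated_fat=(20, 3), total_sugars=(18, 4),
              sodium=(400, 100), fvnl_pct=(0, 0), protein=(8, 2),
              dietary_fiber=(1, 0.5)),
        _arch("high_sodium", n_per, ("pickles", "dried fish", "dried noodles"),
              energy=(200, 50), saturated_fat=(0.8, 0.3), total_sugars=(3, 1),
              sodium=(2200, 300), fvnl_pct=(20, 10), protein=(12, 3),
              dietary_fiber=(2, 0.8)),
        _arch("high_fvnl", n_per, ("vegetable products", "fruit juices", "algae products"),
              energy=(60, 20), saturated_fat=(0.1, 0.1), total_sugars=(6, 2),
              sodium=(30, 15), fvnl_pct=(92, 4), protein=(1.5, 0.5),
              dietary_fiber=(2.5, 0.8)),
        _arch("high_sugars", n_per, ("jams", "japanese confectioneries", "candies"),
              energy=(300, 40), saturated_fat=(0.5, 0.2), total_sugars=(55, 8),
              sodium=(30, 15), fvnl_pct=(15, 8), protein=(2, 1),
              dietary_fiber=(2, 0.7)),
    ]


def generate_foods(archetypes: Sequence[ArchetypeSpec], seed: int) -> list[FoodRecord]:
    """Draw a reproducible synthetic food table.

    Each nutrient is drawn normal(mean, sd) and clipped to
    [max(0, mean - 2 sd), min(bound, mean + 2 sd)], then rounded to the
    declared precision (kcal and mg to integers, grams and % to one
    decimal). Family labels cycle through the archetype's list.
    """
    if not archetypes:
        raise ValueError("archetype list must be non-empty")
    rng = np.random.default_rng(seed)
    records: list[FoodRecord] = []
    for arch in archetypes:
        for i in range(arch.n):
            values = {}
            for nut in _NUTRIENTS:
                m, s = arch.means[nut], arch.sds[nut]
                lo = max(0.0, m - 2 * s)
                hi = min(PHYSICAL_BOUNDS[nut], m + 2 * s)
                v = float(np.clip(rng.normal(m, s), lo, hi))
                values[nut] = round_half_up(v, _PRECISION[nut])
            profile = NutrientProfile(
                energy=values["energy"],
                saturated_fat=values["saturated_fat"],
                total_sugars=values["total_sugars"],
                sodium=values["sodium"],
                fvnl_pct=values["fvnl_pct"],
                fvnl_concentrated=arch.fvnl_concentrated,
                protein=values["protein"],
                dietary_fiber=values["dietary_fiber"],
            )
            family = arch.families[i % len(arch.families)] if arch.families else None
            records.append(FoodRecord(
                food_id=f"{arch.name}-{i:03d}",
                name=f"{arch.name} food {i}",
                profile=profile,
                family=family,
            ))
    return records


def planted_labels(archetypes: Sequence[ArchetypeSpec]) -> np.ndarray:
    """Ground-truth archetype index (1-based) per generated record."""
    return np.concatenate([
        np.full(arch.n, i + 1, dtype=int) for i, arch in enumerate(archetypes)
    ])


@dataclass(frozen=True)
class WorkedExample:
    """A fixture food with its hand-computed point vector."""

    record: FoodRecord
    expected: PointVector


def _example(food_id, name, pts, *, energy=0.0, satfat=0.0, sugars=0.0,
             sodium=0.0, fvnl=0.0, conc=False, protein=0.0, fiber=0.0,
             family=None) -> WorkedExample:
    record = FoodRecord(
        food_id=food_id, name=name, family=family,
        profile=NutrientProfile(
            energy=energy, saturated_fat=satfat, total_sugars=sugars,
            sodium=sodium, fvnl_pct=fvnl, fvnl_concentrated=conc,
            protein=protein, dietary_fiber=fiber))
    return WorkedExample(record=record, expected=PointVector.from_points(*pts))


def worked_example_foods() -> list[WorkedExample]:
    """Fixture foods exercising every ladder boundary and the protein cap.

    Point vectors were walked by hand down the canonical ladders; the
    tuples are (energy, satfat, sugars, sodium, v, p, f) points.
    """
    return [
        _example("wx-zero", "all-zero profile", (0, 0, 0, 0, 0, 0, 0)),
        _example("wx-energy-at", "energy exactly at the 1-point rung",
                 (0, 0, 0, 0, 0, 0, 0), energy=83),
        _example("wx-energy-above", "energy just above the 1-point rung",
                 (1, 0, 0, 0, 0, 0, 0), energy=84),
        _example("wx-satfat-above", "saturated fat just above the 1-point rung",
                 (0, 1, 0, 0, 0, 0, 0), satfat=0.7),
        _example("wx-sugars-above", "sugars just above the 1-point rung",
                 (0, 0, 1, 0, 0, 0, 0), sugars=2.2),
        _example("wx-sodium-above", "sodium just above the 1-point rung",
                 (0, 0, 0, 1, 0, 0, 0), sodium=104),
        _example("wx-fvnl-below", "fvnl just below the non-concentrated start",
                 (0, 0, 0, 0, 0, 0, 0), fvnl=39.9),
        _example("wx-fvnl-at", "fvnl at the non-concentrated start (>= semantics)",
                 (0, 0, 0, 0, 1, 0, 0), fvnl=40),
        _example("wx-fvnl-99", "fvnl just below the equality-only top rung",
                 (0, 0, 0, 0, 7, 0, 0), fvnl=99),
        _example("wx-fvnl-100", "fvnl exactly 100 (top rung)",
                 (0, 0, 0, 0, 8, 0, 0), fvnl=100),
        _example("wx-fvnl-conc-25", "concentrated fvnl at its start",
                 (0, 0, 0, 0, 1, 0, 0), fvnl=25, conc=True),
        _example("wx-protein-above", "protein just above the 1-point rung",
                 (0, 0, 0, 0, 0, 1, 0), protein=3.1),
        _example("wx-fiber-above", "fiber just above the 1-point rung",
                 (0, 0, 0, 0, 0, 0, 1), fiber=0.8),
        # baseline 3+6+0+4 = 13, v 0 < 5: protein points voided
        _example("wx-cap-engaged", "protein cap engaged (baseline 13, V 0)",
                 (3, 6, 0, 4, 0, 0, 0),
                 energy=300, satfat=4.0, sodium=500, protein=10),
        # same baseline, fvnl 80 -> v 5: cap lifted, protein kept
        _example("wx-cap-lifted", "protein cap lifted by 5 V points",
                 (3, 6, 0, 4, 5, 3, 0),
                 energy=300, satfat=4.0, sodium=500, fvnl=80, protein=10),
        # hand-walked mixed profile: baseline 9, final 7
        _example("wx-mixed", "mixed profile across all ladders",
                 (2, 3, 2, 2, 0, 1, 1),
                 energy=200, satfat=2.0, sugars=5.0, sodium=300,
                 protein=4.0, fiber=1.0),
    ]
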