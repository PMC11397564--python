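"""Point-band ladders: canonical constants and their linear reconstruction.

Each scoring component has an ordered ladder of threshold values; a food's
value is converted to integer points by finding the highest rung it clears.
The four "negative" components (energy, saturated fat, total sugars,
sodium) and the two "positive" nutrient components (protein, fiber) use
strictly-greater semantics (value must exceed the rung); the two fvnl
ladders use at-least semantics, with the top rung (8 points) requiring the
product to be exactly 100% fvnl.

Band starts (the 1-point rung) derive from national reference values via a
3.75% rule: 3.75% of the daily reference amount of the component, rounded
half-up at the ladder's printed precision. %-of-energy references
(saturated fat at 7% of food energy, total sugars at 10%) are converted to
grams with the standard energy densities of 9 kcal/g (fat) and 4 kcal/g
(carbohydrate). Linearly extended segments place rung k at k times the
band start; the rounding happens BEFORE the multiplication (energy:
round(82.5) = 83, so rung 11 is 913 — multiplying first would give 908).

Segments marked "adjusted" (a weighted average with the reference model's
ladder, published only in the source dataset's appendix) are shipped as
constants and are not rebuilt.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal
from typing import Mapping, Optional

import yaml

from ._rounding import round_half_up
from .errors import ConfigurationError

STRICTLY_GREATER = "strictly_greater"
AT_LEAST = "at_least"

COMPONENTS = (
    "energy",
    "satfat",
    "sugars",
    "sodium",
    "fvnl_concentrated",
    "fvnl_nonconcentrated",
    "protein",
    "fiber",
)

#: decimal places of the printed threshold values
VALUE_PRECISION = {
    "energy": 0,
    "satfat": 1,
    "sugars": 1,
    "sodium": 0,
    "fvnl_concentrated": 0,
    "fvnl_nonconcentrated": 0,
    "protein": 1,
    "fiber": 1,
}

#: point range (first, last) of each component's linear segment
LINEAR_SEGMENTS = {
    "energy": (1, 11),
    "satfat": (1, 10),
    "sugars": (1, 10),
    "sodium": (1, 30),
    "protein": (1, 1),
    "fiber": (1, 5),
}

#: point range of each component's adjusted (weighted-average) segment
ADJUSTED_SEGMENTS = {
    "satfat": (11, 30),
    "sugars": (11, 25),
    "protein": (2, 15),
    "fiber": (6, 15),
}


@dataclass(frozen=True)
class ReferenceValues:
    """Daily reference amounts anchoring the band starts.

    energy_nrv
        2200 kcal/day (Japanese nutrient reference value, 2015).
    satfat_energy_frac
        saturated fat at 7% of food energy (Japanese DRIs, 2020).
    sugars_energy_frac
        total sugars at 10% of food energy (WHO recommendation, 2015).
    sodium_ref
        2756 mg/day (7 g NaCl, Health Japan 21 third term, 2023).
    protein_nrv / fiber_nrv
        81 g/day and 19 g/day (Japanese NRVs, 2015).
    band_fraction
        the 3.75% rule shared with the reference model.
    fat_energy_density / carb_energy_density
        9 and 4 kcal/g, used to convert %-of-energy references to grams.
    """

    energy_nrv: float = 2200.0
    satfat_energy_frac: float = 0.07
    sugars_energy_frac: float = 0.10
    sodium_ref: float = 2756.0
    protein_nrv: float = 81.0
    fiber_nrv: float = 19.0
    band_fraction: float = 0.0375
    fat_energy_density: float = 9.0
    carb_energy_density: float = 4.0

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.band_fraction < 1:
            raise ValueError("band_fraction must lie in (0, 1)")

    def daily_amount(self, component: str) -> float:
        """Daily reference amount of a component in the ladder's own unit."""
        if component == "energy":
            return self.energy_nrv
        if component == "satfat":
            return self.satfat_energy_frac * self.energy_nrv / self.fat_energy_density
        if component == "sugars":
            return self.sugars_energy_frac * self.energy_nrv / self.carb_energy_density
        if component == "sodium":
            return self.sodium_ref
        if component == "protein":
            return self.protein_nrv
        if component == "fiber":
            return self.fiber_nrv
        raise ValueError(f"no daily reference amount for component {component!r}")


@dataclass(frozen=True)
class BandTable:
    """An ordered threshold ladder mapping a component value to points.

    ``thresholds[k-1]`` is the rung for ``k`` points. ``top_equality``
    marks the fvnl ladders, whose 8-point rung requires exact equality
    (a product that is 100% fvnl) rather than ">=".
    """

    component: str
    thresholds: tuple[float, ...]
    boundary_mode: str
    value_precision: int
    top_equality: bool = False

    def __post_init__(self):
        if self.boundary_mode not in (STRICTLY_GREATER, AT_LEAST):
            raise ValueError(f"unknown boundary_mode {self.boundary_mode!r}")
        if not self.thresholds:
            raise ValueError("thresholds must be non-empty")
        if any(b <= a for a, b in zip(self.thresholds, self.thresholds[1:])):
            raise ValueError(f"thresholds must be strictly increasing: {self.thresholds}")
        object.__setattr__(self, "thresholds", tuple(float(t) for t in self.thresholds))

    @property
    def max_points(self) -> int:
        return len(self.thresholds)

    def to_dict(self) -> dict:
        return {
            "component": self.component,
            "thresholds": list(self.thresholds),
            "boundary_mode": self.boundary_mode,
            "value_precision": self.value_precision,
            "top_equality": self.top_equality,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "BandTable":
        return cls(
            component=d["component"],
            thresholds=tuple(d["thresholds"]),
            boundary_mode=d["boundary_mode"],
            value_precision=int(d["value_precision"]),
            top_equality=bool(d.get("top_equality", False)),
        )


# --- canonical ladders ------------------------------------------------------

_ENERGY = tuple(83 * k for k in range(1, 12))  # 83 ... 913 kcal
_SODIUM = tuple(103 * k for k in range(1, 31))  # 103 ... 3090 mg
_SATFAT = (
    0.6, 1.2, 1.8, 2.4, 3.0, 3.6, 4.2, 4.8, 5.4, 6.0,
    # adjusted segment (weighted average with the reference model)
    6.8, 7.7, 8.7, 9.8, 11.1, 12.5, 14.2, 16.1, 18.4, 21.0,
    24.1, 27.7, 31.9, 36.9, 42.8, 49.5, 57.4, 66.8, 77.4, 90.0,
)
_SUGARS = (
    2.1, 4.2, 6.3, 8.4, 10.5, 12.6, 14.7, 16.8, 18.9, 21.0,
    # adjusted segment
    24.6, 28.2, 32.2, 36.6, 40.8, 45.7, 50.7, 55.7, 61.3, 67.1,
    72.7, 79.1, 85.6, 92.0, 99.0,
)
_FVNL_CONC = (25, 43, 52, 63, 67, 80, 90, 100)
_FVNL_NONCONC = (40, 60, 67, 75, 80, 90, 95, 100)
_PROTEIN = (3.0, 5.8, 8.4, 10.8, 13.0, 15.0, 17.0, 19.0, 21.1, 23.6,
            26.6, 30.4, 35.3, 41.6, 50.0)  # points 2-15 adjusted
_FIBER = (0.7, 1.4, 2.1, 2.8, 3.5, 4.3, 5.2, 6.1, 7.1, 8.4,
          9.8, 11.6, 13.8, 16.6, 20.0)  # points 6-15 adjusted

_CANONICAL_THRESHOLDS = {
    "energy": _ENERGY,
    "satfat": _SATFAT,
    "sugars": _SUGARS,
    "sodium": _SODIUM,
    "fvnl_concentrated": _FVNL_CONC,
    "fvnl_nonconcentrated": _FVNL_NONCONC,
    "protein": _PROTEIN,
    "fiber": _FIBER,
}


def canonical_npm_pfj_tables() -> dict[str, BandTable]:
    """The eight canonical point ladders of the profiling model."""
    tables: dict[str, BandTable] = {}
    for comp, cuts in _CANONICAL_THRESHOLDS.items():
        fvnl = comp.startswith("fvnl")
        tables[comp] = BandTable(
            component=comp,
            thresholds=tuple(float(c) for c in cuts),
            boundary_mode=AT_LEAST if fvnl else STRICTLY_GREATER,
            value_precision=VALUE_PRECISION[comp],
            top_equality=fvnl,
        )
    return tables


# --- linear reconstruction --------------------------------------------------

def band_start(component: str, refs: Optional[ReferenceValues] = None) -> float:
    """The 1-point rung: band_fraction x daily amount, rounded half-up at
    the ladder's printed precision."""
    refs = refs or ReferenceValues()
    raw = refs.band_fraction * refs.daily_amount(component)
    return round_half_up(raw, VALUE_PRECISION[component])


def build_linear_band_table(
    component: str,
    refs: Optional[ReferenceValues] = None,
    n_points: Optional[int] = None,
) -> BandTable:
    """Rebuild a component's linear segment from reference values.

    Rung k = k x band start, computed in decimal so that e.g. fiber rung 3
    is exactly 2.1. ``n_points`` defaults to the full linear range and may
    not exceed it (beyond it the published ladder is an adjusted segment
    that cannot be derived from the reference values alone).
    """
    if component not in LINEAR_SEGMENTS:
        raise ValueError(f"component {component!r} has no linear segment")
    first, last = LINEAR_SEGMENTS[component]
    if n_points is None:
        n_points = last
    if not first <= n_points <= last:
        raise ValueError(
            f"{component}: linear segment covers points {first}-{last}, "
            f"requested {n_points}"
        )
    precision = VALUE_PRECISION[component]
    step = Decimal(repr(band_start(component, refs)))
    cuts = tuple(float(step * k) for k in range(1, n_points + 1))
    return BandTable(
        component=component,
        thresholds=cuts,
        boundary_mode=STRICTLY_GREATER,
        value_precision=precision,
    )


@dataclass(frozen=True)
class LinearityReport:
    """Result of checking one component's linear segment against the
    canonical ladder."""

    component: str
    linear_points: Optional[tuple[int, int]]
    matches: int
    total: int
    mismatches: tuple[tuple[int, float, float], ...]  # (point, built, canonical)
    note: str = ""

    @property
    def ok(self) -> bool:
        return self.matches == self.total


def verify_canonical_linearity(
    refs: Optional[ReferenceValues] = None,
) -> dict[str, LinearityReport]:
    """Rebuild every declared linear segment and compare it cut-for-cut with
    the canonical ladder; adjusted and empirical segments are reported as
    constants-only, never rebuilt."""
    refs = refs or ReferenceValues()
    canonical = canonical_npm_pfj_tables()
    reports: dict[str, LinearityReport] = {}
    for comp in COMPONENTS:
        if comp.startswith("fvnl"):
            reports[comp] = LinearityReport(
                comp, None, 0, 0, (), note="empirical ladder, constants only")
            continue
        first, last = LINEAR_SEGMENTS[comp]
        built = build_linear_band_table(comp, refs)
        mismatches = []
        for k in range(first, last + 1):
            b, c = built.thresholds[k - 1], canonical[comp].thresholds[k - 1]
            if abs(b - c) > 1e-9:
                mismatches.append((k, b, c))
        note = ""
        if comp in ADJUSTED_SEGMENTS:
            a0, a1 = ADJUSTED_SEGMENTS[comp]
            note = f"points {a0}-{a1}: adjusted segment, constants only"
        total = last - first + 1
        reports[comp] = LinearityReport(
            comp, (first, last), total - len(mismatches), total,
            tuple(mismatches), note=note)
    return reports


# --- serialization ----------------------------------------------------------

def band_tables_to_yaml(tables: Mapping[str, BandTable], path=None) -> str:
    """Serialize a set of ladders to YAML (returned, and written if a path
    is given), so user-supplied alternative ladders can drive the engine."""
    doc = {"band_tables": [tables[c].to_dict() for c in sorted(tables)]}
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def band_tables_from_yaml(source) -> dict[str, BandTable]:
    """Load ladders from a YAML string or file path."""
    if hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        text = str(source)
        if "\n" not in text and text.endswith((".yaml", ".yml")):
            with open(text, encoding="utf-8") as fh:
                doc = yaml.safe_load(fh)
        else:
            doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "band_tables" not in doc:
        raise ConfigurationError("expected a mapping with a 'band_tables' list")
    tables = {}
    for entry in doc["band_tables"]:
        bt = BandTable.from_dict(entry)
        tables[bt.component] = bt
    return tables
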