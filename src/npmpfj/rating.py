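"""Rating tables: canonical per-category score bands and their derivation
from final-score distributions.

Within each food category, final scores are banded into half-step ratings
from 5.0 (healthiest) down to 0.5. The 5.0 band covers the lowest decile
of the category's final-score distribution; each 0.5 decrease moves the
band's upper limit to the next 10th percentile, converted to an integer;
the 0.5 band is open-ended upward. When two adjacent percentile limits
land on the same integer the lower rating gets no band at all (an "NA"
rating) — narrow score distributions cannot support all ten levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

from ._rounding import round_half_up
from .errors import ConfigurationError

#: ratings that carry an upper limit, in scan order (healthiest first);
#: 0.5 is the open-ended bottom band and carries no upper limit.
LIMIT_RATINGS = (5.0, 4.5, 4.0, 3.5, 3.0, 2.5, 2.0, 1.5, 1.0)

#: score range reachable by the point arithmetic (all-max negative points
#: down to all-max modifying points)
SCORE_MIN, SCORE_MAX = -38, 96


@dataclass(frozen=True)
class RatingTable:
    """Ordered final-score bands for one category.

    ``upper_limits[i]`` is the inclusive upper final-score limit of
    ``LIMIT_RATINGS[i]``; None marks an NA rating (empty band). A score
    above the last non-NA limit rates 0.5.
    """

    category: int
    upper_limits: tuple[Optional[int], ...]

    def __post_init__(self):
        if len(self.upper_limits) != len(LIMIT_RATINGS):
            raise ValueError(
                f"expected {len(LIMIT_RATINGS)} upper limits, got {len(self.upper_limits)}")
        if self.upper_limits[0] is None:
            raise ValueError("the 5.0 band cannot be NA")
        present = [u for u in self.upper_limits if u is not None]
        if any(b < a for a, b in zip(present, present[1:])):
            raise ValueError(f"upper limits must be non-decreasing: {self.upper_limits}")
        if any(u is not None and u != int(u) for u in self.upper_limits):
            raise ValueError("upper limits must be integers")

    @property
    def na_ratings(self) -> tuple[float, ...]:
        """Ratings with no band (empty score range)."""
        return tuple(r for r, u in zip(LIMIT_RATINGS, self.upper_limits) if u is None)

    @property
    def open_lower(self) -> int:
        """Lowest score of the open-ended 0.5 band."""
        return max(u for u in self.upper_limits if u is not None) + 1

    def bands(self) -> list[tuple[float, Optional[int], Optional[int]]]:
        """(rating, lower, upper) per non-NA band; None bounds are open."""
        out: list[tuple[float, Optional[int], Optional[int]]] = []
        prev: Optional[int] = None
        for r, u in zip(LIMIT_RATINGS, self.upper_limits):
            if u is None:
                continue
            out.append((r, None if prev is None else prev + 1, u))
            prev = u
        out.append((0.5, self.open_lower, None))
        return out

    def to_dict(self) -> dict:
        return {"category": self.category,
                "upper_limits": [u if u is None else int(u) for u in self.upper_limits]}

    @classmethod
    def from_dict(cls, d: Mapping) -> "RatingTable":
        return cls(category=int(d["category"]),
                   upper_limits=tuple(None if u is None else int(u)
                                      for u in d["upper_limits"]))


#: canonical per-category bands; index i is the upper limit of LIMIT_RATINGS[i]
_CANONICAL_LIMITS: dict[int, tuple[Optional[int], ...]] = {
    1: (-2, 0, 1, 2, 3, 4, 5, None, 7),
    2: (-16, -13, -8, -6, -5, -4, -3, -1, 10),
    3: (6, 10, 15, 17, 20, 22, 25, 29, 32),
    4: (-4, -2, 1, 4, 14, 16, 18, 23, 29),
    5: (-12, -11, -9, -7, -6, -4, -2, None, 0),
    6: (0, 5, 8, 11, 13, 15, 18, 20, 22),
}


def canonical_rating_tables() -> dict[int, RatingTable]:
    """The six published category rating tables (including the NA bands of
    categories 1 and 5, whose score distributions were too narrow for ten
    levels)."""
    return {c: RatingTable(c, limits) for c, limits in _CANONICAL_LIMITS.items()}


def apply_rating(final_score: int, category: int,
                 tables: Optional[Mapping[int, RatingTable]] = None) -> float:
    """Rate an integer final score within its category.

    Scans bands from 5.0 downward, skipping NA bands; any score above the
    last limit falls into the open 0.5 band. Every integer score maps to
    exactly one rating.
    """
    if isinstance(final_score, float) and not final_score.is_integer():
        raise ValueError(f"final scores are integers by construction, got {final_score!r}")
    score = int(final_score)
    tables = tables if tables is not None else canonical_rating_tables()
    if category not in tables:
        raise ValueError(f"unknown category {category!r}; have {sorted(tables)}")
    table = tables[category]
    for rating, upper in zip(LIMIT_RATINGS, table.upper_limits):
        if upper is not None and score <= upper:
            return rating
    return 0.5


def derive_rating_table(
    final_scores: Sequence[int],
    category: int = 0,
    step_pct: float = 10.0,
    quantile_method: str = "linear",
    integer_mode: str = "floor",
) -> RatingTable:
    """Derive a category's rating table from its final-score distribution.

    The 5.0 band's upper limit is the ``step_pct``-th percentile of the
    scores as an integer; each 0.5 rating decrease advances the limit by
    another ``step_pct`` percentiles, through the 1.0 band at the
    (9 x step_pct)-th percentile. Consecutive limits landing on the same
    integer make the lower rating NA. The 0.5 band is open above the last
    limit.

    ``quantile_method`` is any numpy quantile method name (default
    ``"linear"``, the spreadsheet PERCENTILE convention); ``integer_mode``
    is ``"floor"`` (default, spreadsheet INT) or ``"half_up"``.
    """
    scores = list(final_scores)
    if len(scores) < 10:
        raise ValueError(f"need at least 10 scores to derive a rating table, got {len(scores)}")
    bad = [s for s in scores if float(s) != int(s)]
    if bad:
        raise ValueError(f"final scores must be integers, got e.g. {bad[0]!r}")
    if not 0 < step_pct <= 100 / len(LIMIT_RATINGS):
        raise ValueError(f"step_pct must lie in (0, {100 / len(LIMIT_RATINGS):.1f}], got {step_pct}")
    if integer_mode not in ("floor", "half_up"):
        raise ValueError("integer_mode must be 'floor' or 'half_up'")

    arr = np.asarray([int(s) for s in scores], dtype=float)
    pcts = [step_pct * (i + 1) for i in range(len(LIMIT_RATINGS))]
    raw = np.percentile(arr, pcts, method=quantile_method)
    if integer_mode == "floor":
        limits = [int(math.floor(v + 1e-12)) for v in raw]
    else:
        limits = [int(round_half_up(v, 0)) for v in raw]

    upper: list[Optional[int]] = [limits[0]]
    prev = limits[0]
    for v in limits[1:]:
        if v <= prev:  # percentiles are monotone; equal integers -> NA band
            upper.append(None)
        else:
            upper.append(v)
            prev = v
    return RatingTable(category=category, upper_limits=tuple(upper))


# --- serialization ----------------------------------------------------------

def rating_tables_to_yaml(tables: Mapping[int, RatingTable], path=None) -> str:
    doc = {"rating_tables": [tables[c].to_dict() for c in sorted(tables)]}
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def rating_tables_from_yaml(source) -> dict[int, RatingTable]:
    if hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        text = str(source)
        if "\n" not in text and text.endswith((".yaml", ".yml")):
            with open(text, encoding="utf-8") as fh:
                doc = yaml.safe_load(fh)
        else:
            doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "rating_tables" not in doc:
        raise ConfigurationError("expected a mapping with a 'rating_tables' list")
    out = {}
    for entry in doc["rating_tables"]:
        rt = RatingTable.from_dict(entry)
        out[rt.category] = rt
    return out
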