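"""Model/Results interface for deriving a rating model from a food table.

``NutrientProfilingModel`` holds a food-composition table and a set of
point ladders; ``fit()`` runs the development path — score every food,
discover categories by Ward clustering of the point vectors, unify
families into their modal cluster, then derive each category's rating
table from its final-score distribution at 10-percentile steps — and
returns a ``NutrientProfilingResults`` carrying the fitted category model,
the derived rating tables, per-food ratings, and summary diagnostics.

Applying the published canonical tables to new foods needs no fit; use
``scoring.score_food`` and ``rating.apply_rating`` directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .bands import BandTable, canonical_npm_pfj_tables
from .categories import (DEFAULT_CATEGORY_DESCRIPTIONS, WARD_D2, CategoryModel,
                         regroup_by_family, ward_cluster)
from .compare import ComparisonReport, compare_scores, cross_tabulate
from .errors import ConfigurationError
from .foods import (DEFAULT_SCHEMA, FoodRecord, NutrientProfile, PointVector,
                    SCORED_COLUMNS, read_food_table, write_scored_table)
from .rating import RatingTable, apply_rating, derive_rating_table, rating_tables_to_yaml
from .scoring import score_records


class NutrientProfilingModel:
    """A food table plus point ladders, ready to fit a rating model.

    Parameters
    ----------
    records
        Validated :class:`FoodRecord` sequence.
    band_tables
        Component -> :class:`BandTable`; defaults to the canonical ladders.
    """

    def __init__(self, records: Sequence[FoodRecord],
                 band_tables: Optional[Mapping[str, BandTable]] = None):
        self.records = list(records)
        if not self.records:
            raise ValueError("model needs at least one food record")
        self.band_tables = dict(band_tables) if band_tables is not None \
            else canonical_npm_pfj_tables()

    @classmethod
    def from_csv(cls, path, schema: Optional[Mapping[str, str]] = None,
                 band_tables: Optional[Mapping[str, BandTable]] = None
                 ) -> "NutrientProfilingModel":
        return cls(read_food_table(path, schema=schema), band_tables=band_tables)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       schema: Optional[Mapping[str, str]] = None,
                       band_tables: Optional[Mapping[str, BandTable]] = None
                       ) -> "NutrientProfilingModel":
        """Build a model from a DataFrame using the default (or a custom)
        column mapping."""
        cols = dict(DEFAULT_SCHEMA)
        if schema:
            cols.update(schema)
        records = []
        for _, row in df.iterrows():
            sodium = row.get(cols["sodium"])
            if sodium is None or (isinstance(sodium, float) and np.isnan(sodium)):
                from .foods import salt_to_sodium
                sodium = float(salt_to_sodium(float(row[cols["salt"]])))
            family = row.get(cols["family"])
            if isinstance(family, float) and np.isnan(family):
                family = None
            cat = row.get(cols["category"])
            if cat is None or (isinstance(cat, float) and np.isnan(cat)):
                cat = None
            else:
                cat = int(cat)
            records.append(FoodRecord(
                food_id=str(row[cols["food_id"]]),
                name=str(row[cols["name"]]),
                family=str(family) if family else None,
                basis=str(row.get(cols["basis"]) or "per_100_g"),
                category=cat,
                profile=NutrientProfile(
                    energy=float(row[cols["energy"]]),
                    saturated_fat=float(row[cols["saturated_fat"]]),
                    total_sugars=float(row[cols["total_sugars"]]),
                    sodium=float(sodium),
                    fvnl_pct=float(row[cols["fvnl_pct"]]),
                    fvnl_concentrated=bool(row[cols["fvnl_concentrated"]]) if not isinstance(
                        row[cols["fvnl_concentrated"]], str)
                    else row[cols["fvnl_concentrated"]].strip().lower() in ("true", "1", "yes"),
                    protein=float(row[cols["protein"]]),
                    dietary_fiber=float(row[cols["dietary_fiber"]]),
                )))
        return cls(records, band_tables=band_tables)

    def score(self) -> list[PointVector]:
        """Score every food under the model's ladders (no fitting)."""
        return score_records(self.records, self.band_tables)

    def fit(self, k: int = 6, linkage_variant: str = WARD_D2,
            standardize: bool = False, step_pct: float = 10.0,
            quantile_method: str = "linear", integer_mode: str = "floor",
            ) -> "NutrientProfilingResults":
        """Run the development path and return the fitted results.

        Raises when any discovered category holds fewer than 10 foods, as
        a decile-based rating table cannot be derived from fewer scores.
        """
        points = self.score()
        n = len(points)
        if n < k:
            raise ValueError(f"cannot cut {n} foods into {k} clusters")
        labels = ward_cluster(points, k=k, linkage_variant=linkage_variant,
                              standardize=standardize)
        families = [r.family for r in self.records]
        categories, regroup_map = regroup_by_family(labels, families)

        category_model = CategoryModel(
            k=k, linkage_variant=linkage_variant,
            cluster_labels=tuple(int(c) for c in labels),
            regroup_map=regroup_map,
            category_descriptions=dict(DEFAULT_CATEGORY_DESCRIPTIONS),
        )

        finals = np.asarray([p.final for p in points])
        rating_tables: dict[int, RatingTable] = {}
        for cat in sorted(set(int(c) for c in categories)):
            cat_scores = finals[categories == cat]
            if cat_scores.size < 10:
                raise ValueError(
                    f"category {cat} has only {cat_scores.size} foods; "
                    "at least 10 are needed to derive decile rating bands")
            rating_tables[cat] = derive_rating_table(
                [int(s) for s in cat_scores], category=cat, step_pct=step_pct,
                quantile_method=quantile_method, integer_mode=integer_mode)

        ratings = [apply_rating(int(f), int(c), rating_tables)
                   for f, c in zip(finals, categories)]
        return NutrientProfilingResults(
            model=self, points=points,
            cluster_labels=np.asarray(labels, dtype=int),
            categories=np.asarray(categories, dtype=int),
            category_model=category_model,
            rating_tables=rating_tables,
            ratings=ratings,
            params={"k": k, "linkage_variant": linkage_variant,
                    "standardize": standardize, "step_pct": step_pct,
                    "quantile_method": quantile_method,
                    "integer_mode": integer_mode},
        )


@dataclass
class NutrientProfilingResults:
    """Fitted scoring + categorization + rating results."""

    model: NutrientProfilingModel
    points: list[PointVector]
    cluster_labels: np.ndarray
    categories: np.ndarray
    category_model: CategoryModel
    rating_tables: dict[int, RatingTable]
    ratings: list[float]
    params: dict = field(default_factory=dict)

    @property
    def final_scores(self) -> np.ndarray:
        return np.asarray([p.final for p in self.points], dtype=int)

    @property
    def frame(self) -> pd.DataFrame:
        """All inputs and outputs as a tidy DataFrame (fixed column order)."""
        rows = []
        for rec, pv, cat, rating in zip(self.model.records, self.points,
                                        self.categories, self.ratings):
            p = rec.profile
            rows.append({
                "food_id": rec.food_id, "name": rec.name,
                "family": rec.family, "basis": rec.basis,
                "energy_kcal": p.energy, "satfat_g": p.saturated_fat,
                "sugars_g": p.total_sugars, "sodium_mg": p.sodium,
                "fvnl_pct": p.fvnl_pct, "fvnl_concentrated": p.fvnl_concentrated,
                "protein_g": p.protein, "fiber_g": p.dietary_fiber,
                "energy_pts": pv.energy_pts, "satfat_pts": pv.satfat_pts,
                "sugars_pts": pv.sugars_pts, "sodium_pts": pv.sodium_pts,
                "v_pts": pv.v_pts, "p_pts": pv.p_pts, "f_pts": pv.f_pts,
                "baseline": pv.baseline, "final": pv.final,
                "category": int(cat), "rating": rating,
            })
        return pd.DataFrame(rows, columns=SCORED_COLUMNS)

    def summary(self) -> str:
        """Per-category diagnostics: size, score distribution, rating bands."""
        finals = self.final_scores
        lines = [
            "Nutrient profiling rating model",
            "=" * 64,
            f"foods: {len(self.points)}    clusters (k): {self.params.get('k')}    "
            f"linkage: {self.params.get('linkage_variant')}",
            f"quantile method: {self.params.get('quantile_method')} "
            f"(integer mode: {self.params.get('integer_mode')}, "
            f"step: {self.params.get('step_pct')}%)",
            "",
            f"{'category':>8} {'n':>5} {'median':>7} {'min':>5} {'max':>5} "
            f"{'rate5<=':>8} {'open0.5>=':>10} {'NA bands':>12}",
        ]
        for cat in sorted(self.rating_tables):
            mask = self.categories == cat
            f = finals[mask]
            rt = self.rating_tables[cat]
            na = ",".join(f"{r:g}" for r in rt.na_ratings) or "-"
            lines.append(
                f"{cat:>8} {int(mask.sum()):>5} {np.median(f):>7.1f} "
                f"{f.min():>5d} {f.max():>5d} {rt.upper_limits[0]:>8d} "
                f"{rt.open_lower:>10d} {na:>12}")
        return "\n".join(lines)

    def compare(self, other_scores: Sequence[float],
                other_categories: Optional[Sequence] = None) -> ComparisonReport:
        """Compare fitted final scores (vector b) against another model's
        scores (vector a), optionally cross-tabulating categories."""
        report = compare_scores(other_scores, self.final_scores)
        if other_categories is not None:
            tab = cross_tabulate(other_categories, [int(c) for c in self.categories])
            report = ComparisonReport(
                n=report.n, median_a=report.median_a, median_b=report.median_b,
                pearson_r=report.pearson_r, p_value=report.p_value, cross_tab=tab)
        return report

    def to_csv(self, path) -> None:
        write_scored_table(self.model.records, self.points, path,
                           ratings=self.ratings,
                           categories=[int(c) for c in self.categories])

    def save_rating_tables(self, path) -> str:
        return rating_tables_to_yaml(self.rating_tables, path)

    def save_category_model(self, path) -> str:
        return self.category_model.to_yaml(path)
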