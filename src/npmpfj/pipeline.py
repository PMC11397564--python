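"""End-to-end pipeline: read -> score -> categorize -> rate -> report.

Two modes:

``derive``
    the development path — categories are discovered by Ward clustering
    with family-majority regrouping and rating tables are derived from the
    score distributions (via :class:`~npmpfj.model.NutrientProfilingModel`).
``canonical``
    the application path — categories come from the input table (or the
    descriptor lexicon applied to the family/name columns) and the
    published rating tables are applied as-is.

Every stage logs counts to the ``npmpfj.pipeline`` logger; any stage error
aborts with the stage name and the offending food ids. The pipeline is
deterministic: identical inputs and config give identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .bands import band_tables_from_yaml, canonical_npm_pfj_tables
from .categories import assign_category
from .compare import ComparisonReport, compare_scores
from .errors import ConfigurationError, PipelineStageError
from .foods import read_food_table, write_scored_table
from .model import NutrientProfilingModel, NutrientProfilingResults
from .rating import apply_rating, canonical_rating_tables, rating_tables_from_yaml
from .scoring import score_records

log = logging.getLogger("npmpfj.pipeline")


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_pipeline`."""

    input: str
    output_dir: Optional[str] = None
    schema: Optional[Mapping[str, str]] = None
    mode: str = "derive"  # "derive" | "canonical"
    band_tables: Optional[str] = None  # None/"npmpfj" or a YAML path
    rating_tables: Optional[str] = None  # canonical mode: None or a YAML path
    k: int = 6
    linkage_variant: str = "ward_d2"
    standardize: bool = False
    step_pct: float = 10.0
    quantile_method: str = "linear"
    integer_mode: str = "floor"
    #: optional column of precomputed scores from another model to compare
    #: final scores against (e.g. a reference model's final score column)
    compare_column: Optional[str] = None

    def __post_init__(self):
        if self.mode not in ("derive", "canonical"):
            raise ConfigurationError(f"mode must be 'derive' or 'canonical', got {self.mode!r}")


@dataclass
class PipelineResult:
    records: list
    points: list
    categories: list
    ratings: list
    report: Optional[ComparisonReport]
    outputs: dict[str, Path] = field(default_factory=dict)
    results: Optional[NutrientProfilingResults] = None


def _resolve_band_tables(spec: Optional[str]):
    if spec in (None, "npmpfj"):
        return canonical_npm_pfj_tables()
    return band_tables_from_yaml(spec)


def run_pipeline(config: PipelineConfig | Mapping) -> PipelineResult:
    """Run the full pipeline per ``config`` and return all stage outputs."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig(**dict(config))
    tables = _resolve_band_tables(config.band_tables)
    outdir = Path(config.output_dir) if config.output_dir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    # stage: read
    try:
        records = read_food_table(config.input, schema=config.schema)
    except Exception as exc:
        raise PipelineStageError("read", str(exc)) from exc
    log.info("read: %d foods from %s", len(records), config.input)

    results: Optional[NutrientProfilingResults] = None
    if config.mode == "derive":
        model = NutrientProfilingModel(records, band_tables=tables)
        try:
            results = model.fit(
                k=config.k, linkage_variant=config.linkage_variant,
                standardize=config.standardize, step_pct=config.step_pct,
                quantile_method=config.quantile_method,
                integer_mode=config.integer_mode)
        except Exception as exc:
            raise PipelineStageError("fit", str(exc)) from exc
        points = results.points
        categories = [int(c) for c in results.categories]
        ratings = list(results.ratings)
        log.info("fit: k=%d clusters, %d categories with rating tables",
                 config.k, len(results.rating_tables))
        if outdir:
            results.save_rating_tables(outdir / "rating_tables.yaml")
            results.save_category_model(outdir / "category_model.yaml")
            outputs["rating_tables"] = outdir / "rating_tables.yaml"
            outputs["category_model"] = outdir / "category_model.yaml"
    else:
        # stage: score
        points = score_records(records, tables)
        log.info("score: %d foods scored", len(points))
        # stage: categorize (input column, else descriptor lexicon)
        categories = []
        missing = []
        for rec in records:
            cat = rec.category
            if cat is None:
                cat = assign_category(rec.family or rec.name)
            if cat is None:
                missing.append(rec.food_id)
            categories.append(cat)
        if missing:
            raise PipelineStageError(
                "categorize", "uncategorized foods (no category column and no "
                "descriptor match)", missing)
        log.info("categorize: %d foods across %d categories",
                 len(categories), len(set(categories)))
        # stage: rate
        rtables = (canonical_rating_tables() if config.rating_tables is None
                   else rating_tables_from_yaml(config.rating_tables))
        try:
            ratings = [apply_rating(pv.final, cat, rtables)
                       for pv, cat in zip(points, categories)]
        except Exception as exc:
            raise PipelineStageError("rate", str(exc)) from exc
        log.info("rate: %d foods rated", len(ratings))

    report: Optional[ComparisonReport] = None
    if config.compare_column:
        import csv as _csv
        with open(config.input, newline="", encoding="utf-8") as fh:
            rows = list(_csv.DictReader(fh))
        if rows and config.compare_column not in rows[0]:
            raise PipelineStageError("compare",
                                     f"column {config.compare_column!r} not in input")
        by_id = {r["food_id"]: float(r[config.compare_column]) for r in rows}
        other = [by_id[rec.food_id] for rec in records]
        finals = [pv.final for pv in points]
        report = compare_scores(other, finals)
        log.info("compare: n=%d r=%s", report.n,
                 "undefined" if report.pearson_r is None else f"{report.pearson_r:.3f}")

    if outdir:
        rated = outdir / "rated.csv"
        write_scored_table(records, points, rated, ratings=ratings,
                           categories=categories)
        outputs["rated"] = rated
        if report is not None:
            report_path = outdir / "report.json"
            with open(report_path, "w", encoding="utf-8") as fh:
                json.dump(report.to_dict(), fh, indent=2)
            outputs["report"] = report_path

    return PipelineResult(records=records, points=points, categories=categories,
                          ratings=ratings, report=report, outputs=outputs,
                          results=results)
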