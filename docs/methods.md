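# Methods

This note documents the model implemented by `npmpfj`, the numerical
conventions chosen where the published tables leave them open, what the
synthetic generator does and does not emulate, and the known limits of
what the test suite shows.

## Scoring model

A food is described by seven per-100 g/mL components: energy (kcal),
saturated fat (g), total sugars (g), sodium (mg), fvnl (fruits,
vegetables, nuts and legumes, including coconut, herbs, fungi, seeds and
algae, as % of product amount, with a concentrated/non-concentrated flag),
protein (g) and dietary fiber (g). Each component is mapped to integer
points by an ordered threshold ladder:

- energy (0–11), saturated fat (0–30), total sugars (0–25), sodium (0–30),
  protein (0–15), fiber (0–15): strictly-greater semantics — point k is
  awarded when the value exceeds rung k;
- fvnl (0–8, one ladder per concentration flag): at-least semantics, with
  the 8-point rung awarded only for exactly 100% fvnl (tolerance 1e-9).

Baseline points are the sum of the four "negative" components; the final
score is baseline − V − P − F. The protein cap voids P points whenever
baseline ≥ 13 (inclusive) and V < 5. Both score identities and all point
ranges are enforced on every constructed `PointVector`, so a violation
anywhere in the pipeline is an immediate error rather than a silent wrong
number. Final scores are integers by construction and lie in [−38, 96].

Component values are compared against ladder cuts at full input precision:
the cuts are exact decimals and strictly-greater semantics make
pre-rounding of inputs both unnecessary and lossy. The basis
(per 100 g vs per 100 mL) is carried as metadata only; one ladder applies
to both.

Sodium is canonical; a salt-equivalent column is converted at read time as
`mg Na = g NaCl × 1000 / 2.54`, rounded half-up to integer mg (7 g NaCl →
2756 mg). Missing or malformed nutrient values are hard row-level errors,
never imputed.

## Band-start arithmetic

Band starts (the 1-point rungs) are 3.75% of a daily reference amount:
energy 2200 kcal, sodium 2756 mg, protein 81 g, fiber 19 g; saturated fat
7% and total sugars 10% of food energy, converted to grams with the
standard energy densities 9 kcal/g (fat) and 4 kcal/g (carbohydrate).
These densities reproduce the printed 0.6 g and 2.1 g starts exactly
(0.07 × 2200/9 × 0.0375 = 0.642 → 0.6; 0.10 × 2200/4 × 0.0375 =
2.0625 → 2.1).

Two conventions are pinned down empirically against the published ladder
and enforced by tests:

- **Rounding of band starts: half-up at the ladder's printed precision**
  (integer kcal/mg, one-decimal grams). This is the only convention that
  reproduces all six printed starts; the energy start is the
  discriminating case (0.0375 × 2200 = 82.5 → 83, where half-even gives
  82).
- **Round before multiplying.** Linear segments place rung k at
  k × (rounded start), computed in decimal arithmetic. Energy rung 11 is
  the discriminating case: 83 × 11 = 913 as published, whereas
  round(82.5 × 11) = 908. The test suite asserts the wrong order fails.

Ladder segments published as "adjusted" (a weighted average with the
reference model's ladder: saturated fat points 11–30, sugars 11–25,
protein 2–15, fiber 6–15) and the empirical fvnl ladders are shipped as
canonical constants and never rebuilt — the adjustment weights are not
part of the published tables. `verify_canonical_linearity()` rebuilds
every linear segment on import of the check and reports per-component
matches, so a regression in either the constants or the builder is caught.

Ladders serialize to YAML, so an alternative table set (for example a
user-supplied Health-Star-Rating ladder) can drive the same engine;
the package ships only its own canonical tables.

## Category discovery

Development-path categorization is agglomerative Ward clustering on the
raw 7-dimensional integer point vectors (Euclidean distances, no
standardization by default — the components already share a comparable
scale; a `standardize` flag exists). The tree is cut at k = 6. Because the
published analysis does not state which Ward convention its software used,
both are available: `ward_d2` (scipy's `ward`, the squared-distance
update) and `ward_d` (the classical update applied to unsquared distances,
emulated exactly by running scipy's ward on the square roots of the
pairwise distances); the default is `ward_d2`. On the synthetic archetypes
both variants recover the planted partition identically.

Family-majority regrouping then moves every food family wholesale to its
modal cluster, ties broken toward the lower cluster index (the published
example — minority breads joining the majority bread cluster — does not
exercise ties, so the tie-break is a documented package choice). Foods
without a family keep their cluster. Regrouping can only merge, never
split, so the number of categories never increases.

Integer point vectors produce exact distance ties, and agglomeration order
under ties is input-order dependent (true of any hierarchical clustering
implementation). Permutation stability is therefore guaranteed — and
tested — at the separation scale the model clusters at, not for arbitrary
cuts deep inside a tied subtree.

Application-path categorization never re-clusters: a descriptor lexicon
(the six published category descriptions) maps a food-type phrase to its
category by longest case-insensitive containment match, and a phrase with
no match is explicitly uncategorized rather than silently defaulted.

## Rating derivation and application

Within a category, ratings run 5.0, 4.5, …, 1.0, 0.5. The nine ratings
5.0–1.0 carry inclusive upper score limits at the 10th, 20th, …, 90th
percentiles of the category's final-score distribution; 0.5 is open-ended
above the last limit. Two conventions are configurable because the source
tables do not state them:

- **Quantile estimator**: any numpy method name; default `linear`
  (interpolation between order statistics — the spreadsheet PERCENTILE
  convention, matching the tooling the development analysis reports
  using).
- **"As an integer"**: default `floor` (spreadsheet INT). Under the linear
  estimator this is the combination that yields the expected decile limits
  10, 20, …, 90 on the uniform sample 1…100 (the 10th percentile of 1…100
  is 10.9; half-up would give 11). `half_up` is available behind a flag.

When consecutive percentile limits land on the same integer, the
lower-rating band becomes NA — exactly how the published tables show NA
at rating 1.5 for categories 1 and 5, whose score distributions are too
narrow for ten levels. A degenerate all-equal sample collapses to a single
5.0 band plus the open 0.5 band. Derivation requires at least 10 scores
per category and rejects non-integer scores.

One documented source conflict: the prose description of the rating
construction says rating 5 corresponds to the "90th percentile or lower",
while the rating table's own footnote places rating 5 at the 0–10
percentile of final scores. The footnote matches the table's structure
(lowest scores = best rating = healthiest) and is what this package
implements.

Application scans bands from 5.0 downward, skipping NA bands; enumeration
over all reachable integer scores (−38…96) in all six categories shows
total, non-overlapping coverage, and ratings are monotone non-increasing
in final score.

## Model/Results interface

`NutrientProfilingModel(records).fit()` packages the development path —
score, cluster, regroup, derive per-category rating tables, apply them —
and returns a results object carrying the point vectors, category model,
derived rating tables, per-food ratings, a per-category `summary()` table
(n, median/min/max final score, 5.0-band limit, open 0.5 floor, NA bands)
and a `compare()` method for paired-score comparison (medians, Pearson r
with the standard t-based p-value, category cross-tabulation). The fit is
fully deterministic given its inputs. Applying the canonical published
tables requires no fit and goes through `score_food` / `apply_rating`
directly.

## Synthetic data

The generator plants six archetypes mirroring the signature pattern of the
six categories: low-everything (beverage-like), high energy/protein/fiber
(soybean/seed-product-like), high saturated fat, high sodium, high fvnl,
and high total sugars, at 30 foods per archetype by default (180 foods —
of the same order as, though smaller than, a category of the 668-food
development set). Each nutrient is drawn independently as a normal
variate clipped to [mean − 2 sd, mean + 2 sd] and to physical bounds
(energy ≤ 900 kcal/100 g, fvnl ≤ 100%, all values ≥ 0), then rounded to
the declared precision. Archetype means were chosen once so that each
archetype's signature component dominates its point vector while baseline
points stay clear of unintended protein-cap flips near the 13-point
boundary.

What the generator does **not** emulate: nutrient covariance within a
food, the long right tails of real composition data, mixed and borderline
foods between categories, and the real-world family structure (each
archetype cycles through three clean family labels). Passing
planted-recovery tests therefore shows the clustering and regrouping
machinery is correct on well-separated structure; it does not show that
k = 6 or exact cluster recovery would hold on a real food database, where
categories are genuinely overlapping. Likewise the derived rating bands on
synthetic data demonstrate the derivation mechanics (including the
NA-collapse on the narrow low-everything archetype) rather than the
published band limits, which depend on the real 668-food distribution.

A fixed list of 16 hand-scored worked-example foods covers each ladder's
1-point boundary from both sides, the fvnl at-least and =100 semantics,
both protein-cap branches, and an all-zero profile; these serve as an
independent oracle for the scoring path everywhere, including through the
end-to-end pipeline.

## Numerical and degenerate-input choices

- Band-start rounding: decimal half-up (see above); threshold comparison
  at full float precision; fvnl top-rung equality tolerance 1e-9.
- Ladder thresholds must be strictly increasing; rating-table limits
  non-decreasing with NA holes; both validated on construction.
- Duplicate food ids, negative or missing nutrient values, fvnl > 100%:
  row-level hard errors with the offending ids collected into the report.
- Clustering requires at least k foods; rating derivation at least 10
  scores per category; comparison at least 2 pairs, with correlation
  reported as undefined (None) for constant vectors rather than 0.
- CSV output preserves values exactly (shortest round-trip decimal
  formatting), so write → read is an identity at any input precision.

## Known limitations

- The adjusted ladder segments and the fvnl ladders are constants; they
  cannot be re-derived from reference values by construction.
- The category lexicon resolves phrases, not free-form product names; a
  retail product name like "chocolate croissant 6-pack" needs a family
  label before it can be auto-categorized.
- The comparison path expects the reference model's scores as a
  precomputed column; this package does not ship the reference model's own
  point tables.
- Ward clustering under exact distance ties is input-order dependent at
  fine granularity (see above); published-scale results are unaffected,
  but cutting a tied subtree at large k may not be permutation-stable.
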