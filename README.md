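# npmpfj

A table-driven nutrient-profiling engine for packaged foods, built around
the scoring and rating algorithms of the NPM-PFJ (1.0) model — a
Health-Star-Rating-style, across-the-board profiling model adapted to
Japanese reference values. The package scores any per-100 g/mL
food-composition table, discovers food categories from scoring patterns,
and derives or applies percentile-based rating tables, so that the rating
model can be re-derived from any new score distribution.

## Who it is for

Nutrition scientists and food-industry analysts who need to

- score foods on the model's eight point ladders (energy, saturated fat,
  total sugars, sodium; fvnl %, protein, dietary fiber) per 100 g or
  100 mL,
- audit the ladders themselves: every linearly extended threshold is
  rebuilt live from its national reference value via the 3.75% rule and
  checked against the published table,
- rebuild the category structure and rating bands on a new food database.

## The model

Each component value is converted to integer points by a threshold ladder
(strictly-greater cuts for nutrients, at-least cuts for fvnl, with the top
fvnl rung requiring exactly 100%). Then

```
baseline points = energy pts + saturated fat pts + total sugars pts + sodium pts
final score     = baseline − V pts − P pts − F pts        (lower = healthier)
```

with the protein cap: a food with baseline ≥ 13 scores no protein (P)
points unless it earns at least 5 fvnl (V) points.

Categories are discovered by Ward hierarchical clustering of the
7-dimensional point vectors, followed by family-majority regrouping (every
food family moves wholesale to its modal cluster). Within each category,
final scores are banded into half-step ratings 5.0 … 0.5: the 5.0 band is
the lowest decile of the category's score distribution, each 0.5 decrease
advances the band's upper limit to the next 10th percentile (as an
integer), and coincident integer limits produce NA ratings — narrow
distributions cannot support all ten levels.

## Worked example

```python
from npmpfj import NutrientProfile, score_food, assign_category, apply_rating

profile = NutrientProfile(
    energy=250, saturated_fat=2.6, total_sugars=4.8, sodium=480,
    fvnl_pct=0, fvnl_concentrated=False, protein=9.0, dietary_fiber=5.6)

pv = score_food(profile)
print("points:", pv.components())          # (3, 4, 2, 4, 0, 0, 7)
print("baseline:", pv.baseline)            # 13
print("final:", pv.final)                  # 6

cat = assign_category("breads")            # 1
print("rating:", apply_rating(pv.final, cat))   # 1.0
```

This bread-like food collects 3+4+2+4 = 13 baseline points. Because the
baseline reaches 13 and it has no fvnl (V = 0), the protein cap voids its
3 raw protein points — only the 7 fiber points offset the baseline, so the
final score is 13 − 0 − 0 − 7 = 6. In category 1 a final score of 6 falls
in the 1.0 band (category 1 has no 1.5 band: its development-set score
distribution was too narrow to support all ten levels).

Re-deriving a rating model from data (statsmodels-style):

```python
from npmpfj import NutrientProfilingModel, default_archetypes, generate_foods

records = generate_foods(default_archetypes(30), seed=42)   # 180 synthetic foods
results = NutrientProfilingModel(records).fit(k=6)
print(results.summary())          # per-category n, score spread, band limits
results.to_csv("rated.csv")
results.save_rating_tables("rating_tables.yaml")
```

The same pipeline is scriptable from the shell:

```sh
npmpfj simulate --n-per 30 --seed 42 --output foods.csv
npmpfj pipeline --input foods.csv --output-dir out/ --mode derive
npmpfj compare --input out/rated.csv --scores-a baseline --scores-b final
```

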