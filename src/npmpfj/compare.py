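"""Score-comparison statistics: medians, Pearson correlation, and category
cross-tabulation between two profiling models run on the same foods."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError


@dataclass(frozen=True)
class ComparisonReport:
    """Summary of a paired comparison of two score vectors.

    ``pearson_r`` is None when either vector is constant (the correlation
    is undefined, not zero).
    """

    n: int
    median_a: float
    median_b: float
    pearson_r: Optional[float]
    p_value: Optional[float] = None
    cross_tab: Optional[pd.DataFrame] = None

    def to_dict(self) -> dict:
        d = {
            "n": self.n,
            "median_a": self.median_a,
            "median_b": self.median_b,
            "pearson_r": self.pearson_r,
            "p_value": self.p_value,
        }
        if self.cross_tab is not None:
            d["cross_tab"] = {
                str(row): {str(c): int(v) for c, v in cols.items()}
                for row, cols in self.cross_tab.to_dict(orient="index").items()
            }
        return d


def compare_scores(scores_a: Sequence[float], scores_b: Sequence[float]) -> ComparisonReport:
    """Medians of both vectors plus their sample Pearson correlation.

    Even-n medians are the mean of the two central values. A constant
    vector leaves the correlation undefined (reported as None).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise AlignmentError(f"score vectors must be 1-d and equal length, "
                             f"got {a.shape} and {b.shape}")
    if a.size < 2:
        raise ValueError("need at least 2 paired scores")
    median_a = float(np.median(a))
    median_b = float(np.median(b))
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        r, p = None, None
    else:
        res = stats.pearsonr(a, b)
        r, p = float(res.statistic), float(res.pvalue)
    return ComparisonReport(n=int(a.size), median_a=median_a, median_b=median_b,
                            pearson_r=r, p_value=p)


def cross_tabulate(categories_a: Sequence, categories_b: Sequence) -> pd.DataFrame:
    """Contingency table of two aligned category labelings, with margins."""
    if len(categories_a) != len(categories_b):
        raise AlignmentError(f"{len(categories_a)} labels vs {len(categories_b)} labels")
    if len(categories_a) == 0:
        raise ValueError("label vectors are empty")
    a = pd.Series(list(categories_a), name="a")
    b = pd.Series(list(categories_b), name="b")
    return pd.crosstab(a, b, margins=True, margins_name="Total")


def compare_with_crosstab(scores_a, scores_b, categories_a, categories_b) -> ComparisonReport:
    """Full report: medians, correlation, and the category cross-tabulation."""
    base = compare_scores(scores_a, scores_b)
    tab = cross_tabulate(categories_a, categories_b)
    if len(categories_a) != base.n:
        raise AlignmentError("category labels not aligned with score vectors")
    return ComparisonReport(n=base.n, median_a=base.median_a, median_b=base.median_b,
                            pearson_r=base.pearson_r, p_value=base.p_value,
                            cross_tab=tab)
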