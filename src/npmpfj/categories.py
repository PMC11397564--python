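"""Category discovery and assignment.

Food categories are discovered from scoring patterns: Ward hierarchical
clustering on the 7-dimensional point vectors (energy, saturated fat,
sugars, sodium, V, P, F points), cut at k clusters, followed by a
family-majority regrouping so that foods consumers compare directly (all
"breads", say) end up in one category even when the tree splits them.

Applying the model to new foods does not re-cluster: a descriptor lexicon
(the published category descriptions) maps a food-type phrase to its
category. Clustering is the development path; lexicon lookup is the
application path.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .errors import AlignmentError, ConfigurationError
from .foods import PointVector

WARD_D = "ward_d"
WARD_D2 = "ward_d2"

#: published category descriptions (application-path lexicon); phrases are
#: matched case-insensitively, longest match wins.
DEFAULT_CATEGORY_DESCRIPTIONS: dict[int, tuple[str, ...]] = {
    1: (
        "processed rice products",
        "processed wheat and other grain products",
        "processed corn products",
        "soy milk",
        "fish/mollusk/crustacean products (canned and paste products)",
        "processed egg products",
        "milk/dairy products and yogurt",
        "beverages",
        "breads",
        "noodles (uncooked/boiled)",
        "yogurt",
    ),
    2: (
        "soybean products (solid-form)",
        "seed products",
    ),
    3: (
        "meat products",
        "cheeses, milk powders, ice creams, creams",
        "western confectioneries and pastries",
        "ice creams",
        "pastries",
        "cheeses",
    ),
    4: (
        "noodles (dried)",
        "vegetable products (pickles)",
        "fish/mollusk/crustacean products (dried products and salted/simmered/pickled products)",
    ),
    5: (
        "potato/sweet potato/other potato products",
        "vegetable products (canned/frozen/100% juices)",
        "fruits products (canned/frozen/100% juices)",
        "mushroom products",
        "algae products",
        "vegetable juices (100%)",
        "fruits juices (100%)",
    ),
    6: (
        "fruits products (dried fruits, jams)",
        "japanese confectioneries and candies",
        "dried fruits",
        "jams",
        "candies",
    ),
}


@dataclass(frozen=True)
class CategoryModel:
    """A fitted categorization: cluster labels, regroup map, and the
    descriptor lexicon used to assign categories to new foods."""

    k: int
    linkage_variant: str
    cluster_labels: tuple[int, ...]
    regroup_map: Mapping[str, int]
    category_descriptions: Mapping[int, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_DESCRIPTIONS))

    def __post_init__(self):
        if self.linkage_variant not in (WARD_D, WARD_D2):
            raise ValueError(f"unknown linkage variant {self.linkage_variant!r}")
        bad = [c for c in self.cluster_labels if not 1 <= c <= self.k]
        if bad:
            raise ValueError(f"cluster labels outside 1..{self.k}: {sorted(set(bad))}")

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "linkage_variant": self.linkage_variant,
            "cluster_labels": list(self.cluster_labels),
            "regroup_map": dict(self.regroup_map),
            "category_descriptions": {
                int(c): list(d) for c, d in self.category_descriptions.items()
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "CategoryModel":
        return cls(
            k=int(d["k"]),
            linkage_variant=d["linkage_variant"],
            cluster_labels=tuple(int(x) for x in d["cluster_labels"]),
            regroup_map={str(f): int(c) for f, c in d.get("regroup_map", {}).items()},
            category_descriptions={
                int(c): tuple(desc) for c, desc in d["category_descriptions"].items()
            },
        )

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "CategoryModel":
        if hasattr(source, "read"):
            doc = yaml.safe_load(source)
        else:
            text = str(source)
            if "\n" not in text and text.endswith((".yaml", ".yml")):
                with open(text, encoding="utf-8") as fh:
                    doc = yaml.safe_load(fh)
            else:
                doc = yaml.safe_load(text)
        return cls.from_dict(doc)


def _point_matrix(points: Sequence) -> np.ndarray:
    """Coerce point vectors / 7-tuples / arrays to an (n, 7) float matrix."""
    rows = []
    for p in points:
        rows.append(p.components() if isinstance(p, PointVector) else tuple(p))
    x = np.asarray(rows, dtype=float)
    if x.ndim != 2 or x.shape[1] != 7:
        raise ValueError(f"expected 7-dimensional point vectors, got shape {x.shape}")
    if np.isnan(x).any():
        raise ValueError("point vectors contain missing components")
    return x


def ward_cluster(points: Sequence, k: int,
                 linkage_variant: str = WARD_D2,
                 standardize: bool = False) -> np.ndarray:
    """Ward hierarchical clustering of point vectors, cut at k clusters.

    Distances are Euclidean on the raw integer point vectors (the
    components already share a comparable scale); ``standardize=True``
    z-scores the columns first. ``ward_d2`` is the squared-distance update
    convention used by scipy; ``ward_d`` emulates the classical convention
    that applies the Ward update to unsquared distances (the two can merge
    in different orders). Returns integer labels 1..k, deterministic given
    the input.
    """
    x = _point_matrix(points)
    n = x.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must lie in 1..{n} (n foods), got {k}")
    if standardize:
        sd = x.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        x = (x - x.mean(axis=0)) / sd
    if n == 1:
        return np.ones(1, dtype=int)
    if linkage_variant == WARD_D2:
        z = linkage(x, method="ward")
    elif linkage_variant == WARD_D:
        # ward.D applies the Lance-Williams update to d directly, which
        # equals scipy's ward (= ward.D2) run on sqrt(d).
        z = linkage(np.sqrt(pdist(x)), method="ward")
    else:
        raise ValueError(f"unknown linkage variant {linkage_variant!r}")
    return fcluster(z, t=k, criterion="maxclust").astype(int)


def regroup_by_family(labels: Sequence[int],
                      families: Sequence[Optional[str]]) -> tuple[np.ndarray, dict[str, int]]:
    """Reassign every family wholesale to its modal cluster.

    Foods sharing a family label all receive the family's most frequent
    cluster (ties broken toward the lower cluster index); foods without a
    family keep their own cluster. Returns the regrouped labels and the
    family -> category map.
    """
    if len(labels) != len(families):
        raise AlignmentError(f"{len(labels)} labels but {len(families)} family labels")
    labels = np.asarray(labels, dtype=int)
    regrouped = labels.copy()
    regroup_map: dict[str, int] = {}
    fam_arr = [f if f else None for f in families]
    for fam in sorted({f for f in fam_arr if f is not None}):
        members = [i for i, f in enumerate(fam_arr) if f == fam]
        counts = Counter(labels[i] for i in members)
        top = max(counts.values())
        modal = min(c for c, n in counts.items() if n == top)
        regroup_map[fam] = int(modal)
        for i in members:
            regrouped[i] = modal
    return regrouped, regroup_map


_WS = re.compile(r"\s+")


def _norm(text: str) -> str:
    return _WS.sub(" ", text.strip().lower())


def assign_category(name_or_descriptor: str,
                    model: Optional[CategoryModel] = None) -> Optional[int]:
    """Assign a category from a food-type phrase via the descriptor lexicon.

    A descriptor matches when it contains the query or the query contains
    it (case-insensitive, whitespace-normalized); the longest matching
    descriptor wins. Returns None when nothing matches — never a silent
    default.
    """
    lexicon = (model.category_descriptions if model is not None
               else DEFAULT_CATEGORY_DESCRIPTIONS)
    if not lexicon or not any(lexicon.values()):
        raise ConfigurationError("category descriptor lexicon is empty")
    query = _norm(name_or_descriptor)
    if not query:
        return None
    best: tuple[int, int] | None = None  # (descriptor length, category)
    for cat, descriptors in lexicon.items():
        for desc in descriptors:
            d = _norm(desc)
            if d and (d in query or query in d):
                if best is None or len(d) > best[0]:
                    best = (len(d), int(cat))
    return None if best is None else best[1]
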