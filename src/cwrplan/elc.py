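"""Ecogeographic Land Characterization (ELC) zonation.

The non-collinear edaphic, geophysical and climatic variable sets are each
clustered independently (k-means over standardized cell values within the
species' native range) and the three cluster labels are combined into a
single composite category per cell.  Each composite category is one
"adaptive scenario" — an environmental zone used as a proxy unit of
potential genetic diversity.  Overlaying an ELC map with a binary range
yields the set of adaptive scenarios the range spans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .grids import VARIABLE_SETS, EnvStack

DEFAULT_K_PER_SET = 5
_KMEANS_RESTARTS = 10


@dataclass
class ELCMap:
    """Composite ecogeographic categories over a species' native range.

    ``categories`` holds positive integer codes for cells with complete
    data inside the native range and 0 elsewhere (category-null).  The
    codebook maps each composite code to its per-set cluster labels.
    """

    species_id: str
    categories: np.ndarray
    k_per_set: dict[str, int]
    codebook: pd.DataFrame  # category, edaphic, geophysical, climatic

    @property
    def category_codes(self) -> np.ndarray:
        return np.unique(self.categories[self.categories > 0])


def cluster_set(values: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Seeded k-means labels for one variable set's standardized cell values."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return np.zeros(len(values), dtype=int)
    distinct = np.unique(values, axis=0).shape[0]
    if k > distinct:
        raise ValueError(f"k={k} exceeds {distinct} distinct cell value vectors")
    km = KMeans(n_clusters=k, n_init=_KMEANS_RESTARTS, random_state=seed)
    return km.fit_predict(values)


def build_elc(
    env: EnvStack,
    retained_by_set: dict[str, list[str]],
    k_per_set: dict[str, int] | int = DEFAULT_K_PER_SET,
    native_range: np.ndarray | None = None,
    seed: int = 0,
    species_id: str = "",
) -> ELCMap:
    """Build the composite ELC map for one species.

    Each set's values are standardized over the native-range cells before
    clustering; the composite code is the mixed-radix encoding of the
    (edaphic, geophysical, climatic) label triple, plus 1 so 0 stays the
    null category.  Cells with any non-finite value are category-null.
    """
    if isinstance(k_per_set, int):
        k_per_set = {s: k_per_set for s in VARIABLE_SETS}
    for s in VARIABLE_SETS:
        if not retained_by_set.get(s):
            raise ValueError(f"variable set {s!r} has no retained variables")
    mask = native_range if native_range is not None else np.ones(env.grid.shape, dtype=bool)
    all_vars = [v for s in VARIABLE_SETS for v in retained_by_set[s]]
    values_all = env.values(all_vars, mask=mask)
    complete = np.isfinite(values_all).all(axis=1)
    labels_by_set = {}
    for i, s in enumerate(VARIABLE_SETS):
        vals = env.values(retained_by_set[s], mask=mask)[complete]
        sd = vals.std(axis=0)
        vals = (vals - vals.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
        labels_by_set[s] = cluster_set(vals, k_per_set[s], seed=seed + i)
    ke, kg, kc = (k_per_set[s] for s in VARIABLE_SETS)
    composite = (
        labels_by_set["edaphic"] * (kg * kc)
        + labels_by_set["geophysical"] * kc
        + labels_by_set["climatic"]
        + 1
    )
    categories = np.zeros(env.grid.shape, dtype=int)
    cell_idx = np.flatnonzero(mask.ravel())[complete]
    categories.ravel()[cell_idx] = composite
    codes = np.unique(composite)
    codebook = pd.DataFrame(
        {
            "category": codes,
            "edaphic": (codes - 1) // (kg * kc),
            "geophysical": ((codes - 1) // kc) % kg,
            "climatic": (codes - 1) % kc,
        }
    )
    return ELCMap(species_id=species_id, categories=categories, k_per_set=dict(k_per_set), codebook=codebook)


def scenarios_in_range(elc: ELCMap, range_mask: np.ndarray) -> set[int]:
    """Set of adaptive-scenario categories occurring in at least one range cell.

    Category-null cells never contribute; an empty range yields an empty set.
    """
    if range_mask.shape != elc.categories.shape:
        raise ValueError("range mask and ELC map are on mismatched grids")
    cats = elc.categories[range_mask]
    return set(int(c) for c in np.unique(cats[cats > 0]))
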