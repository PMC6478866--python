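"""Protected-area gap analysis for species ranges and adaptive scenarios.

Computes, per species: the percentage of the current (and climate-stable)
range inside protected areas, the percentage of current range lost by the
projection horizon, the percentage of adaptive scenarios represented in
protected areas and the loss of protected scenarios under climate change;
flags species whose protected scenario coverage falls below the 50%
adequacy rule; and consolidates everything by crop type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
import shapely

from .grids import GridSpec

#: scenario coverage below this percentage marks a species under-conserved
ADEQUACY_PCT = 50.0


def rasterize_pa(geometries, grid: GridSpec) -> tuple[np.ndarray, int]:
    """Presence/absence protection raster from protected-area polygons.

    A cell is protected iff its centre is covered by any polygon (cell-
    centre rule).  Point-type geometries are discarded; the count of
    dropped points is returned.  An already-rasterized boolean mask passes
    straight through.
    """
    if isinstance(geometries, np.ndarray) and geometries.dtype == bool:
        if geometries.shape != grid.shape:
            raise ValueError("mask shape does not match grid")
        return geometries.copy(), 0
    geoms = list(geometries)
    polys = [g for g in geoms if g.geom_type in ("Polygon", "MultiPolygon")]
    n_dropped = len(geoms) - len(polys)
    if not polys:
        warnings.warn("no polygon protected areas; protection raster is empty")
        return np.zeros(grid.shape, dtype=bool), n_dropped
    union = shapely.union_all(polys)
    xs, ys = grid.cell_centers()
    covered = shapely.intersects_xy(union, xs.ravel(), ys.ravel())
    return covered.reshape(grid.shape), n_dropped


def coverage(range_mask: np.ndarray, pa_mask: np.ndarray) -> float | None:
    """Percentage of range cells that are protected; None for an empty range."""
    if range_mask.shape != pa_mask.shape:
        raise ValueError("range and protection rasters are on mismatched grids")
    n = int(range_mask.sum())
    if n == 0:
        return None
    return 100.0 * int((range_mask & pa_mask).sum()) / n


def scenario_coverage(scenarios_current: set[int], scenarios_protected: set[int]) -> float | None:
    """Percentage of current adaptive scenarios represented in protected areas."""
    if not scenarios_current:
        return None
    if not scenarios_protected <= scenarios_current:
        raise ValueError("protected scenarios must be a subset of current scenarios")
    return 100.0 * len(scenarios_protected) / len(scenarios_current)


def scenario_loss(scenarios_protected_current: set[int], scenarios_protected_stable: set[int]) -> float | None:
    """Percentage of currently protected scenarios lost by the horizon.

    None when nothing is protected now (no basis for a loss percentage).
    """
    if not scenarios_protected_current:
        return None
    surviving = scenarios_protected_current & scenarios_protected_stable
    return 100.0 * (1.0 - len(surviving) / len(scenarios_protected_current))


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round half away from zero at the printed precision (reporting style)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def headline_percentages(numerator: int, denominator: int, decimals: int = 1) -> float:
    """Percentage 100*a/b rounded half-up at the printed precision.

    ``decimals=0`` reproduces integer-style figures; the result is then
    still returned as a float (e.g. 91.0).
    """
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0:
        raise ValueError("numerator must be non-negative")
    return round_half_up(100.0 * numerator / denominator, decimals)


@dataclass
class SpeciesGapRecord:
    """One species' in-situ conservation status."""

    species_id: str
    crops: list[str]
    n_occurrences: int
    pathway: str  # model | buffer | excluded
    pct_range_in_pa_current: float | None
    pct_range_loss: float | None  # None for buffer pathway
    pct_scenarios_in_pa_current: float | None
    pct_scenario_loss_in_pa: float | None
    pct_pa_cover_loss: float | None = None  # loss of protected range area, %

    @property
    def under_conserved(self) -> bool | None:
        if self.pct_scenarios_in_pa_current is None:
            return None
        return self.pct_scenarios_in_pa_current < ADEQUACY_PCT

    @property
    def exclusively_outside_pa(self) -> bool:
        return self.pct_range_in_pa_current == 0.0


def species_gap_record(
    species_id: str,
    crops: list[str],
    n_occurrences: int,
    pathway: str,
    current_mask: np.ndarray,
    pa_mask: np.ndarray,
    elc=None,
    stable_mask: np.ndarray | None = None,
    range_loss: float | None = None,
) -> SpeciesGapRecord:
    """Assemble the gap record for one species from its range/ELC layers."""
    from .elc import scenarios_in_range

    pct_pa = coverage(current_mask, pa_mask)
    pct_scen = pct_scen_loss = pa_cover_loss = None
    if elc is not None:
        scen_current = scenarios_in_range(elc, current_mask)
        scen_prot = scenarios_in_range(elc, current_mask & pa_mask)
        pct_scen = scenario_coverage(scen_current, scen_prot)
        if stable_mask is not None:
            scen_prot_stable = scenarios_in_range(elc, stable_mask & pa_mask)
            pct_scen_loss = scenario_loss(scen_prot, scen_prot_stable)
    if stable_mask is not None:
        n_prot_cur = int((current_mask & pa_mask).sum())
        if n_prot_cur > 0:
            pa_cover_loss = 100.0 * (1.0 - int((stable_mask & pa_mask).sum()) / n_prot_cur)
    return SpeciesGapRecord(
        species_id=species_id,
        crops=list(crops),
        n_occurrences=n_occurrences,
        pathway=pathway,
        pct_range_in_pa_current=pct_pa,
        pct_range_loss=None if range_loss is None else 100.0 * range_loss,
        pct_scenarios_in_pa_current=pct_scen,
        pct_scenario_loss_in_pa=pct_scen_loss,
        pct_pa_cover_loss=pa_cover_loss,
    )


def records_to_frame(records: list[SpeciesGapRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "species_id": r.species_id,
                "crops": ";".join(r.crops),
                "n_occurrences": r.n_occurrences,
                "pathway": r.pathway,
                "pct_range_in_pa_current": r.pct_range_in_pa_current,
                "pct_range_loss": r.pct_range_loss,
                "pct_scenarios_in_pa_current": r.pct_scenarios_in_pa_current,
                "pct_scenario_loss_in_pa": r.pct_scenario_loss_in_pa,
                "pct_pa_cover_loss": r.pct_pa_cover_loss,
                "under_conserved": r.under_conserved,
                "exclusively_outside_pa": r.exclusively_outside_pa,
            }
        )
    return pd.DataFrame(rows)


def summarize_by_crop_type(
    records: list[SpeciesGapRecord] | pd.DataFrame,
    crop_map: pd.DataFrame,
    loss_threshold_pct: float = 50.0,
) -> pd.DataFrame:
    """Consolidated gap statistics per crop type.

    ``crop_map`` needs columns ``species_id, crop, crop_type`` (a species
    may appear under several crops).  Within a crop type each species is
    counted once even if it belongs to several of the type's genepools;
    a species whose crops span types contributes to each type.  Range-loss
    means skip species without a modelled loss (buffer pathway), which
    still count toward the occurrence-class columns.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    for col in ("species_id", "crop", "crop_type"):
        if col not in crop_map.columns:
            raise ValueError(f"crop_map missing column {col!r}")
    unmapped = sorted(set(df["species_id"]) - set(crop_map["species_id"]))
    if unmapped:
        raise ValueError(f"species without crop mapping: {unmapped}")
    merged = crop_map.merge(df, on="species_id", how="inner")
    rows = []
    for crop_type, grp in merged.groupby("crop_type", sort=True):
        sp = grp.drop_duplicates("species_id")
        loss = sp["pct_range_loss"].dropna()
        rows.append(
            {
                "crop_type": crop_type,
                "n_crops": grp["crop"].nunique(),
                "n_cwr": len(sp),
                "n_no_occurrences": int((sp["n_occurrences"] == 0).sum()),
                "n_1_9_occurrences": int(sp["n_occurrences"].between(1, 9).sum()),
                "n_loss_over_50pct": int((loss > loss_threshold_pct).sum()),
                "mean_pct_pa_cover": sp["pct_range_in_pa_current"].dropna().mean(),
                "mean_pct_pa_cover_loss": sp["pct_pa_cover_loss"].dropna().mean()
                if "pct_pa_cover_loss" in sp.columns
                else float("nan"),
            }
        )
    return pd.DataFrame(rows)
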