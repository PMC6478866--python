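"""Occurrence-record cleaning and modelling-pathway assignment.

Raw records pass through a fixed sequence of filters — cultivated/non-target
flag, missing coordinates, coordinate uncertainty above 10 km (strictly
greater), points outside the species' native range, and exact-coordinate
duplicates — and each removal is attributed to the first failing rule so
the per-species counts reconcile.  Species are then routed to a modelling
pathway by their unique-record count: ten or more records go to the
distribution model, one to nine to the occurrence-buffer fallback, zero
means the species is excluded from analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import GridSpec

#: records with coordinate uncertainty strictly above this (km) are removed
DEFAULT_MAX_UNCERTAINTY_KM = 10.0
#: minimum unique records for the distribution-model pathway
DEFAULT_MIN_RECORDS_FOR_MODEL = 10

#: dedupe resolution: coordinates are compared after rounding to the nearest metre
_COORD_DECIMALS_KM = 3

REMOVAL_COLUMNS = [
    "removed_cultivated",
    "removed_no_coords",
    "removed_uncertain",
    "removed_out_of_range",
    "duplicates_removed",
]


@dataclass
class QCReport:
    """Per-species accounting of the cleaning filters."""

    species_id: str
    raw: int
    removed_cultivated: int = 0
    removed_no_coords: int = 0
    removed_uncertain: int = 0
    removed_out_of_range: int = 0
    duplicates_removed: int = 0
    missing_uncertainty_retained: int = 0
    final_unique: int = 0
    native_range_missing: bool = False
    pathway: str = "excluded"

    def reconciles(self) -> bool:
        return self.raw == self.final_unique + (
            self.removed_cultivated
            + self.removed_no_coords
            + self.removed_uncertain
            + self.removed_out_of_range
            + self.duplicates_removed
        )


def assign_pathway(final_unique: int, min_records_for_model: int = DEFAULT_MIN_RECORDS_FOR_MODEL) -> str:
    """Route a species by its cleaned unique-record count."""
    if final_unique >= min_records_for_model:
        return "model"
    if final_unique >= 1:
        return "buffer"
    return "excluded"


def clean(
    records: pd.DataFrame,
    native_range: dict[str, np.ndarray],
    grid: GridSpec,
    max_uncertainty_km: float = DEFAULT_MAX_UNCERTAINTY_KM,
    min_records_for_model: int = DEFAULT_MIN_RECORDS_FOR_MODEL,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Clean raw occurrence records and build a per-species QC report.

    Parameters
    ----------
    records : DataFrame
        Columns ``species_id, x_km, y_km`` and optionally ``uncertainty_km``
        (NaN allowed: records with missing uncertainty are retained but
        counted) and ``cultivated`` (boolean; flagged rows removed first).
    native_range : mapping species_id -> boolean mask
        Native-range masks on the analysis grid.  A species without a mask
        is flagged in the report (``native_range_missing``) and its records
        skip the range filter rather than being silently dropped or passed.

    Returns
    -------
    (clean records, report) — the report has one row per species with the
    counts of :class:`QCReport`.
    """
    df = records.copy()
    for col in ("species_id", "x_km", "y_km"):
        if col not in df.columns:
            raise ValueError(f"records missing required column {col!r}")
    if "uncertainty_km" not in df.columns:
        df["uncertainty_km"] = np.nan

    kept_frames, reports = [], []
    for sid, grp in df.groupby("species_id", sort=True):
        rep = QCReport(species_id=str(sid), raw=len(grp))
        g = grp
        if "cultivated" in g.columns:
            flag = g["cultivated"].fillna(False).astype(bool)
            rep.removed_cultivated = int(flag.sum())
            g = g[~flag]
        coords_ok = np.isfinite(g["x_km"]) & np.isfinite(g["y_km"])
        rep.removed_no_coords = int((~coords_ok).sum())
        g = g[coords_ok]
        unc = g["uncertainty_km"]
        too_uncertain = unc > max_uncertainty_km  # NaN compares False: retained
        rep.missing_uncertainty_retained = int(unc.isna().sum())
        rep.removed_uncertain = int(too_uncertain.sum())
        g = g[~too_uncertain]
        if sid in native_range:
            row, col = grid.xy_to_rowcol(g["x_km"].to_numpy(), g["y_km"].to_numpy())
            inside = row >= 0
            inside[inside] = native_range[sid][row[inside], col[inside]]
            rep.removed_out_of_range = int((~inside).sum())
            g = g[inside]
        else:
            rep.native_range_missing = True
        key = list(zip(g["x_km"].round(_COORD_DECIMALS_KM), g["y_km"].round(_COORD_DECIMALS_KM)))
        first = ~pd.Series(key, index=g.index).duplicated()
        rep.duplicates_removed = int((~first).sum())
        g = g[first.to_numpy()]
        rep.final_unique = len(g)
        rep.pathway = assign_pathway(rep.final_unique, min_records_for_model)
        kept_frames.append(g)
        reports.append(rep)

    clean_df = (
        pd.concat(kept_frames, ignore_index=True)
        if kept_frames
        else df.iloc[0:0].copy()
    )
    report = pd.DataFrame([vars(r) for r in reports])
    return clean_df, report
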