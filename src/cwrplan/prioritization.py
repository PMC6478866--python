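"""Greedy complementarity ranking of selected reserve sites.

Sites (planning units) are ordered by iterative complementarity: the
first site carries the most species x adaptive-scenario combinations,
each subsequent site adds the most combinations not yet represented.
Two modes:

* ``adaptive`` — pure greedy over all candidate sites;
* ``pragmatic`` — greedy over protected-area sites first (until no
  protected site adds coverage), then complementary greedy over sites
  outside protected areas for the combinations existing protection
  cannot supply.

Ties are broken by most unique species added, then lowest unit id, so
the ranking is deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gap_analysis import round_half_up

MODES = ("adaptive", "pragmatic")


@dataclass
class SiteRanking:
    """Ordered sites with marginal and cumulative coverage accounting."""

    table: pd.DataFrame  # rank, unit_id, pa, n_cwr, unique_cwr_added, combos_added, cum_combos
    mode: str
    n_combos_total: int
    uncoverable: list

    @property
    def covered_combos(self) -> int:
        return int(self.table["combos_added"].sum()) if len(self.table) else 0


def _greedy_phase(
    order_pool: list[int],
    unit_combos: dict[int, set],
    unit_species: dict[int, set],
    covered: set,
    covered_species: set,
    rows: list,
) -> None:
    pool = set(order_pool)
    while pool:
        best = None
        best_key = None
        for u in sorted(pool):
            gain = len(unit_combos[u] - covered)
            if gain == 0:
                continue
            sp_gain = len(unit_species[u] - covered_species)
            key = (-gain, -sp_gain, u)
            if best_key is None or key < best_key:
                best, best_key = u, key
        if best is None:
            return
        combos_added = unit_combos[best] - covered
        species_added = unit_species[best] - covered_species
        covered |= combos_added
        covered_species |= species_added
        rows.append(
            {
                "unit_id": best,
                "n_cwr": len(unit_species[best]),
                "unique_cwr_added": len(species_added),
                "combos_added": len(combos_added),
            }
        )
        pool.discard(best)


def greedy_rank(
    unit_ids: list[int],
    unit_combos: dict[int, set],
    pa_flags: dict[int, bool],
    mode: str = "pragmatic",
) -> SiteRanking:
    """Rank sites by greedy complementarity of combination coverage.

    ``unit_combos`` maps unit id to its set of (species, category)
    combinations; species sets are derived from the first element of each
    combination.  The ranking stops when no remaining site adds coverage.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if not unit_combos:
        raise ValueError("incidence is empty")
    unit_species = {u: {c[0] for c in unit_combos[u]} for u in unit_ids}
    universe = set().union(*unit_combos.values()) if unit_combos else set()
    covered: set = set()
    covered_species: set = set()
    rows: list[dict] = []
    if mode == "pragmatic":
        _greedy_phase([u for u in unit_ids if pa_flags[u]], unit_combos, unit_species, covered, covered_species, rows)
        _greedy_phase([u for u in unit_ids if not pa_flags[u]], unit_combos, unit_species, covered, covered_species, rows)
    else:
        _greedy_phase(list(unit_ids), unit_combos, unit_species, covered, covered_species, rows)
    uncoverable = sorted(universe - covered)
    if uncoverable:
        warnings.warn(f"{len(uncoverable)} combinations not coverable by the unit set")
    table = pd.DataFrame(rows)
    if len(table):
        table.insert(0, "rank", np.arange(1, len(table) + 1))
        table.insert(2, "pa", [bool(pa_flags[u]) for u in table["unit_id"]])
        table["cum_combos"] = table["combos_added"].cumsum()
    else:
        table = pd.DataFrame(
            columns=["rank", "unit_id", "pa", "n_cwr", "unique_cwr_added", "combos_added", "cum_combos"]
        )
    return SiteRanking(table=table, mode=mode, n_combos_total=len(universe), uncoverable=uncoverable)


def top_sites(ranking: SiteRanking, n_pa: int = 100, n_out: int = 50) -> pd.DataFrame:
    """First ``n_pa`` protected sites and first ``n_out`` outside sites, in rank order."""
    t = ranking.table
    pa_rows = t[t["pa"]].head(n_pa)
    out_rows = t[~t["pa"]].head(n_out)
    if len(pa_rows) < n_pa or len(out_rows) < n_out:
        warnings.warn(
            f"requested {n_pa}+{n_out} sites but ranking holds "
            f"{int(t['pa'].sum())} protected / {int((~t['pa']).sum())} outside"
        )
    return pd.concat([pa_rows, out_rows]).sort_values("rank").reset_index(drop=True)


def slice_stats(
    site_table: pd.DataFrame,
    unit_combos: dict[int, set],
) -> dict:
    """Combined unique species / combination totals over a slice of sites."""
    species: set = set()
    combos: set = set()
    for u in site_table["unit_id"]:
        combos |= unit_combos[u]
        species |= {c[0] for c in unit_combos[u]}
    return {"n_sites": len(site_table), "n_species": len(species), "n_combos": len(combos)}


def headline_stats(
    site_table: pd.DataFrame,
    unit_combos: dict[int, set],
    n_species_total: int,
    n_combos_total: int,
) -> dict:
    """Slice totals with percentages of the assessed species / combination pools."""
    if n_species_total <= 0 or n_combos_total <= 0:
        raise ValueError("totals must be positive")
    stats = slice_stats(site_table, unit_combos)
    stats["pct_species"] = round_half_up(100.0 * stats["n_species"] / n_species_total, 1)
    stats["pct_combos"] = round_half_up(100.0 * stats["n_combos"] / n_combos_total, 1)
    return stats
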