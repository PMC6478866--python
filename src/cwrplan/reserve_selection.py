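"""Minimum-set reserve selection by simulated annealing.

The planning problem follows the standard systematic-conservation-planning
formulation: planning units are grid cells, each carrying a cost (10 when
the cell overlaps a protected area, 50 otherwise, so existing protection
is preferred); the conservation features are species x adaptive-scenario
combinations, each requiring representation in at least one selected unit
(species penalty factor 1); and a boundary length modifier (0.001) weights
reserve compactness.  The objective of a selection S is

    sum(cost of S) + BLM * boundary(S) + sum over unmet features of
    SPF * penalty(feature)

with boundary(S) counted in exposed rook edges (grid-exterior edges count)
and penalty(feature) the cost of the cheapest unit containing it, so
penalties can always force coverage.  Annealing uses single-unit add/
remove proposals under a geometric cooling schedule, followed by a greedy
repair pass (all feasible targets met) and a greedy drop pass.  Runs are
ranked by fewest selected units, then lowest total cost, then run index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .grids import GridSpec

DEFAULT_COST_PA = 10.0
DEFAULT_COST_OUT = 50.0
DEFAULT_SPF = 1.0
DEFAULT_BLM = 0.001
DEFAULT_N_RUNS = 100


@dataclass
class PlanningProblem:
    """Immutable description of one minimum-set instance."""

    unit_cells: np.ndarray  # flat grid-cell index per planning unit
    costs: np.ndarray
    combo_keys: list[tuple[str, int]]  # (species_id, scenario category)
    combo_units: list[np.ndarray]  # units containing each combination
    unit_combos: list[np.ndarray]  # combinations present in each unit
    neighbors: list[np.ndarray]  # rook-adjacent planning units
    spf: float = DEFAULT_SPF
    blm: float = DEFAULT_BLM
    locked_in: np.ndarray | None = None  # units forced into every solution

    @property
    def n_units(self) -> int:
        return len(self.costs)

    @property
    def n_combos(self) -> int:
        return len(self.combo_keys)

    def penalties(self) -> np.ndarray:
        """Shortfall penalty per combination.

        The cheapest covering unit's cost plus the worst-case boundary
        increment (4 exposed edges x BLM), so covering a combination is
        never dearer than paying its penalty and penalties can always
        force coverage.
        """
        return np.array([self.costs[u].min() + 4.0 * self.blm for u in self.combo_units])

    def boundary_length(self, selected: np.ndarray) -> float:
        """Exposed rook edges of the selection (grid exterior counts)."""
        total = 0
        for u in np.flatnonzero(selected):
            total += 4 - int(selected[self.neighbors[u]].sum())
        return float(total)

    def objective(self, selected: np.ndarray) -> dict[str, float]:
        """Objective recomputed from scratch, decomposed."""
        selected = np.asarray(selected, dtype=bool)
        cost = float(self.costs[selected].sum())
        boundary = self.boundary_length(selected)
        pen = self.penalties()
        unmet = [
            i for i, units in enumerate(self.combo_units) if not selected[units].any()
        ]
        penalty = float(self.spf * pen[unmet].sum()) if unmet else 0.0
        return {
            "cost": cost,
            "boundary": boundary,
            "penalty": penalty,
            "total": cost + self.blm * boundary + penalty,
            "n_unmet": len(unmet),
        }


def build_problem(
    planning_masks: dict[str, np.ndarray],
    elc_maps: dict,
    pa_mask: np.ndarray,
    grid: GridSpec,
    cost_pa: float = DEFAULT_COST_PA,
    cost_out: float = DEFAULT_COST_OUT,
    spf: float = DEFAULT_SPF,
    blm: float = DEFAULT_BLM,
    lock_in_pa: bool = False,
) -> PlanningProblem:
    """Assemble the planning instance from per-species planning ranges.

    ``planning_masks`` maps species to the binary range used for planning
    (the climate-stable range when a valid future model exists, otherwise
    the current range).  Combinations are (species, ELC category) pairs;
    a combination's incidence is every cell where the planning range
    intersects that category.  Planning units are the cells carrying at
    least one combination; costs follow protected-area overlap.  With
    ``lock_in_pa`` protected units are forced into every solution.
    """
    from .elc import scenarios_in_range

    combo_cells: dict[tuple[str, int], np.ndarray] = {}
    for sid, mask in planning_masks.items():
        if mask.shape != grid.shape:
            raise ValueError(f"planning mask for {sid!r} does not match grid")
        elc = elc_maps[sid]
        cats = elc.categories
        for cat in sorted(scenarios_in_range(elc, mask)):
            combo_cells[(sid, int(cat))] = np.flatnonzero((mask & (cats == cat)).ravel())
    empty = [k for k, v in combo_cells.items() if v.size == 0]
    if empty:
        warnings.warn(f"dropping {len(empty)} combinations with no cells")
        for k in empty:
            del combo_cells[k]
    cells = np.unique(np.concatenate(list(combo_cells.values()))) if combo_cells else np.array([], int)
    cell_to_unit = {c: i for i, c in enumerate(cells)}
    combo_keys = sorted(combo_cells)
    combo_units = [
        np.array(sorted(cell_to_unit[c] for c in combo_cells[k]), dtype=int) for k in combo_keys
    ]
    unit_combos_lists: list[list[int]] = [[] for _ in cells]
    for ci, units in enumerate(combo_units):
        for u in units:
            unit_combos_lists[u].append(ci)
    costs = np.where(pa_mask.ravel()[cells], cost_pa, cost_out).astype(float)
    neighbors = []
    n_cols = grid.n_cols
    for c in cells:
        row, col = divmod(int(c), n_cols)
        nbr = []
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            r2, c2 = row + dr, col + dc
            if 0 <= r2 < grid.n_rows and 0 <= c2 < n_cols:
                flat = r2 * n_cols + c2
                if flat in cell_to_unit:
                    nbr.append(cell_to_unit[flat])
        neighbors.append(np.array(nbr, dtype=int))
    locked = np.flatnonzero(pa_mask.ravel()[cells]) if lock_in_pa else None
    return PlanningProblem(
        unit_cells=cells,
        costs=costs,
        combo_keys=combo_keys,
        combo_units=combo_units,
        unit_combos=[np.array(v, dtype=int) for v in unit_combos_lists],
        neighbors=neighbors,
        spf=spf,
        blm=blm,
        locked_in=locked,
    )


@dataclass
class ReserveSolution:
    selected_units: np.ndarray
    cost: float
    boundary: float
    penalty: float
    objective: float
    unmet: list[tuple[str, int]]
    run_index: int
    seed: int

    @property
    def n_units(self) -> int:
        return len(self.selected_units)


@dataclass
class RunEnsemble:
    solutions: list[ReserveSolution]
    best: ReserveSolution
    ranking_rule: str = "fewest units, then lowest cost, then lowest run index"


def _run_once(problem: PlanningProblem, n_iterations: int, rng: np.random.Generator) -> np.ndarray:
    n = problem.n_units
    pen = problem.spf * problem.penalties()
    selected = rng.random(n) < 0.3
    if problem.locked_in is not None:
        selected[problem.locked_in] = True
    cover = np.zeros(problem.n_combos, dtype=int)
    for u in np.flatnonzero(selected):
        cover[problem.unit_combos[u]] += 1
    t0 = float(problem.costs.max() + (pen.max() if len(pen) else 0.0))
    # final temperature far below the smallest meaningful objective delta
    # (BLM-scale boundary differences), so late annealing resolves them
    t_final = 1e-5 * max(problem.blm, 1e-3)
    alpha = (t_final / t0) ** (1.0 / max(n_iterations, 1))
    temp = t0
    lock = set(problem.locked_in.tolist()) if problem.locked_in is not None else set()
    for _ in range(n_iterations):
        u = int(rng.integers(n))
        if u in lock:
            temp *= alpha
            continue
        k = int(selected[problem.neighbors[u]].sum())
        combos = problem.unit_combos[u]
        if selected[u]:
            delta = -problem.costs[u] + problem.blm * (2 * k - 4)
            newly_unmet = combos[cover[combos] == 1]
            delta += pen[newly_unmet].sum()
        else:
            delta = problem.costs[u] + problem.blm * (4 - 2 * k)
            newly_met = combos[cover[combos] == 0]
            delta -= pen[newly_met].sum()
        if delta < 0 or rng.random() < np.exp(-delta / temp):
            if selected[u]:
                selected[u] = False
                cover[combos] -= 1
            else:
                selected[u] = True
                cover[combos] += 1
        temp *= alpha
    _repair(problem, selected, cover)
    _drop_pass(problem, selected, cover)
    return selected


def _repair(problem: PlanningProblem, selected: np.ndarray, cover: np.ndarray) -> None:
    """Add units until every coverable combination is met.

    Each still-unmet combination receives the covering unit with the
    smallest marginal objective increase (cost + BLM * boundary delta);
    because the penalty bounds that increase from above, repair never
    worsens the objective.
    """
    for c in np.flatnonzero(cover == 0):
        if cover[c] > 0:
            continue  # met by a unit added for an earlier combination
        cands = problem.combo_units[c]
        cands = cands[~selected[cands]]
        if cands.size == 0:
            continue  # infeasible combination
        k = np.array([int(selected[problem.neighbors[u]].sum()) for u in cands])
        marginal = problem.costs[cands] + problem.blm * (4 - 2 * k)
        best = cands[np.lexsort((cands, marginal))][0]
        selected[best] = True
        cover[problem.unit_combos[best]] += 1


def _drop_pass(problem: PlanningProblem, selected: np.ndarray, cover: np.ndarray) -> None:
    """Remove units whose removal keeps coverage and lowers the objective."""
    lock = set(problem.locked_in.tolist()) if problem.locked_in is not None else set()
    improved = True
    while improved:
        improved = False
        for u in np.flatnonzero(selected):
            if int(u) in lock:
                continue
            combos = problem.unit_combos[u]
            if (cover[combos] == 1).any():
                continue
            k = int(selected[problem.neighbors[u]].sum())
            delta = -problem.costs[u] + problem.blm * (2 * k - 4)
            if delta < 0:
                selected[u] = False
                cover[combos] -= 1
                improved = True


def anneal(
    problem: PlanningProblem,
    n_runs: int = DEFAULT_N_RUNS,
    n_iterations: int = 10_000,
    seed: int = 0,
) -> RunEnsemble:
    """Independent annealing runs; deterministic given the seed."""
    if problem.n_units == 0:
        raise ValueError("planning problem has no units")
    solutions = []
    for run in range(n_runs):
        rng = np.random.default_rng([seed, run])
        selected = _run_once(problem, n_iterations, rng)
        parts = problem.objective(selected)
        unmet = [
            problem.combo_keys[i]
            for i, units in enumerate(problem.combo_units)
            if not selected[units].any()
        ]
        if unmet:
            warnings.warn(f"run {run}: {len(unmet)} combinations unmet (infeasible targets)")
        solutions.append(
            ReserveSolution(
                selected_units=np.flatnonzero(selected),
                cost=parts["cost"],
                boundary=parts["boundary"],
                penalty=parts["penalty"],
                objective=parts["total"],
                unmet=unmet,
                run_index=run,
                seed=seed,
            )
        )
    return RunEnsemble(solutions=solutions, best=rank_runs(solutions))


def rank_runs(solutions: list[ReserveSolution]) -> ReserveSolution:
    """Best solution under (fewest units, lowest cost, lowest run index)."""
    if not solutions:
        raise ValueError("no solutions to rank")
    return min(solutions, key=lambda s: (s.n_units, s.cost, s.run_index))
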