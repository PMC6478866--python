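"""Minimum-set problem construction and the simulated-annealing solver."""

import numpy as np
import pytest

import cwrplan as cp
from cwrplan import reserve_selection as rs

from oracles import exhaustive_reserve_optimum, reserve_objective


def random_instance(rng, n_units=None, n_combos=None):
    """Random small planning instance on a ribbon grid (chain adjacency)."""
    n = n_units or int(rng.integers(4, 13))
    m = n_combos or int(rng.integers(2, 9))
    costs = rng.choice([10.0, 50.0], size=n)
    combo_units = []
    for _ in range(m):
        size = int(rng.integers(1, max(2, n // 2)))
        combo_units.append(np.sort(rng.choice(n, size=size, replace=False)))
    unit_combos = [[] for _ in range(n)]
    for ci, units in enumerate(combo_units):
        for u in units:
            unit_combos[u].append(ci)
    neighbors = [
        np.array([v for v in (u - 1, u + 1) if 0 <= v < n], dtype=int) for u in range(n)
    ]
    edges = [(u, u + 1) for u in range(n - 1)]
    blm = float(rng.choice([0.0, 0.001, 1.0]))
    problem = rs.PlanningProblem(
        unit_cells=np.arange(n),
        costs=costs,
        combo_keys=[("sp", c) for c in range(m)],
        combo_units=combo_units,
        unit_combos=[np.array(v, dtype=int) for v in unit_combos],
        neighbors=neighbors,
        spf=1.0,
        blm=blm,
    )
    return problem, edges


class TestBuildProblem:
    @pytest.fixture
    def toy(self):
        grid = cp.GridSpec(3, 3, 5.0)
        mask = np.zeros(grid.shape, dtype=bool)
        mask.ravel()[[0, 1, 4]] = True  # 3-cell planning range
        cats = np.zeros(grid.shape, dtype=int)
        cats.ravel()[[0, 1]] = 1
        cats.ravel()[[4]] = 2
        elc = cp.ELCMap("sp1", cats, {"edaphic": 1, "geophysical": 1, "climatic": 2}, None)
        pa = np.zeros(grid.shape, dtype=bool)
        pa.ravel()[0] = True
        return grid, mask, elc, pa

    def test_incidence_matches_cellwise_enumeration(self, toy):
        grid, mask, elc, pa = toy
        p = rs.build_problem({"sp1": mask}, {"sp1": elc}, pa, grid)
        assert p.combo_keys == [("sp1", 1), ("sp1", 2)]
        # units are cells 0,1,4 -> combo 1 in units {0,1}, combo 2 in {2}
        np.testing.assert_array_equal(p.unit_cells, [0, 1, 4])
        np.testing.assert_array_equal(p.combo_units[0], [0, 1])
        np.testing.assert_array_equal(p.combo_units[1], [2])

    def test_costs_follow_pa_overlap(self, toy):
        grid, mask, elc, pa = toy
        p = rs.build_problem({"sp1": mask}, {"sp1": elc}, pa, grid)
        np.testing.assert_array_equal(p.costs, [10.0, 50.0, 50.0])

    def test_adjacency_is_rook_and_symmetric(self, toy):
        grid, mask, elc, pa = toy
        p = rs.build_problem({"sp1": mask}, {"sp1": elc}, pa, grid)
        # cells 0-(0,0), 1-(0,1), 4-(1,1): 0~1, 1~4
        assert set(p.neighbors[0]) == {1}
        assert set(p.neighbors[1]) == {0, 2}
        assert set(p.neighbors[2]) == {1}

    def test_grid_mismatch_rejected(self, toy):
        grid, mask, elc, pa = toy
        with pytest.raises(ValueError):
            rs.build_problem({"sp1": mask[:2, :]}, {"sp1": elc}, pa, grid)


class TestAnneal:
    def test_forced_unit_always_selected(self):
        rng = np.random.default_rng(0)
        problem, _ = random_instance(rng, n_units=6, n_combos=3)
        # give combo 0 exactly one covering unit and rebuild the incidence
        problem.combo_units[0] = np.array([3])
        unit_combos = [[] for _ in range(6)]
        for ci, units in enumerate(problem.combo_units):
            for u in units:
                unit_combos[u].append(ci)
        problem.unit_combos = [np.array(v, dtype=int) for v in unit_combos]
        ens = rs.anneal(problem, n_runs=5, n_iterations=300, seed=1)
        for sol in ens.solutions:
            assert 3 in sol.selected_units
            assert not sol.unmet

    def test_toy_instance_attains_exhaustive_optimum(self):
        rng = np.random.default_rng(3)
        problem, edges = random_instance(rng, n_units=6, n_combos=4)
        opt, _ = exhaustive_reserve_optimum(
            problem.costs, problem.combo_units, edges, problem.spf, problem.blm
        )
        ens = rs.anneal(problem, n_runs=10, n_iterations=500, seed=2)
        assert ens.best.objective == pytest.approx(opt, rel=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_small_random_instances_reach_optimum(self, seed):
        rng = np.random.default_rng(100 + seed)
        problem, edges = random_instance(rng)
        opt, _ = exhaustive_reserve_optimum(
            problem.costs, problem.combo_units, edges, problem.spf, problem.blm
        )
        ens = rs.anneal(problem, n_runs=10, n_iterations=400, seed=seed)
        assert ens.best.objective <= opt * (1 + 1e-9) + 1e-9
        for sol in ens.solutions:
            assert not sol.unmet  # every feasible target met by repair

    def test_objective_decomposition_matches_recomputation(self):
        rng = np.random.default_rng(5)
        problem, _ = random_instance(rng, n_units=10, n_combos=5)
        ens = rs.anneal(problem, n_runs=4, n_iterations=300, seed=7)
        for sol in ens.solutions:
            sel = np.zeros(problem.n_units, dtype=bool)
            sel[sol.selected_units] = True
            parts = problem.objective(sel)
            assert sol.objective == pytest.approx(parts["total"])
            assert sol.objective == pytest.approx(
                sol.cost + problem.blm * sol.boundary + sol.penalty
            )

    def test_high_blm_produces_more_compact_solution(self):
        """Two clusters of combos: with a large BLM the solver should pick
        the configuration with strictly smaller boundary length."""
        n = 10
        costs = np.full(n, 10.0)
        # every combo coverable by either end of the chain; compactness decides
        combo_units = [np.array([0, 1, 8, 9]) for _ in range(3)] + [np.array([1, 9])]
        unit_combos = [[] for _ in range(n)]
        for ci, units in enumerate(combo_units):
            for u in units:
                unit_combos[u].append(ci)
        neighbors = [
            np.array([v for v in (u - 1, u + 1) if 0 <= v < n], dtype=int) for u in range(n)
        ]
        def make(blm):
            return rs.PlanningProblem(
                unit_cells=np.arange(n), costs=costs,
                combo_keys=[("s", c) for c in range(4)],
                combo_units=combo_units,
                unit_combos=[np.array(v, int) for v in unit_combos],
                neighbors=neighbors, spf=1.0, blm=blm,
            )
        lo = rs.anneal(make(0.0), n_runs=10, n_iterations=500, seed=3).best
        hi = rs.anneal(make(100.0), n_runs=10, n_iterations=500, seed=3).best
        p = make(0.0)
        sel_lo = np.zeros(n, bool); sel_lo[lo.selected_units] = True
        sel_hi = np.zeros(n, bool); sel_hi[hi.selected_units] = True
        assert p.boundary_length(sel_hi) <= p.boundary_length(sel_lo)

    def test_lowering_a_cost_never_raises_the_optimum(self):
        rng = np.random.default_rng(11)
        problem, edges = random_instance(rng, n_units=8, n_combos=4)
        opt, mask = exhaustive_reserve_optimum(
            problem.costs, problem.combo_units, edges, problem.spf, problem.blm
        )
        sel = np.flatnonzero(mask)
        if sel.size:
            costs2 = problem.costs.copy()
            costs2[sel[0]] = 10.0
            opt2, _ = exhaustive_reserve_optimum(
                costs2, problem.combo_units, edges, problem.spf, problem.blm
            )
            assert opt2 <= opt + 1e-9

    def test_lock_in_pa_forces_protected_units(self):
        rng = np.random.default_rng(4)
        problem, _ = random_instance(rng, n_units=6, n_combos=3)
        problem.locked_in = np.array([0, 2])
        ens = rs.anneal(problem, n_runs=3, n_iterations=200, seed=0)
        for sol in ens.solutions:
            assert {0, 2} <= set(sol.selected_units.tolist())


class TestRankRuns:
    def _sol(self, n_units, cost, run):
        return rs.ReserveSolution(
            selected_units=np.arange(n_units), cost=cost, boundary=0.0,
            penalty=0.0, objective=cost, unmet=[], run_index=run, seed=0,
        )

    def test_fewest_units_beats_lower_cost(self):
        best = rs.rank_runs([self._sol(10, 300.0, 0), self._sol(9, 500.0, 1)])
        assert best.run_index == 1

    def test_cost_breaks_unit_ties(self):
        best = rs.rank_runs([self._sol(9, 300.0, 0), self._sol(9, 280.0, 1)])
        assert best.cost == 280.0

    def test_identical_runs_pick_lowest_index(self):
        best = rs.rank_runs([self._sol(9, 300.0, 0), self._sol(9, 300.0, 1)])
        assert best.run_index == 0
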