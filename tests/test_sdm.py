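"""Distribution modelling: VIF, maxent fit, CV, thresholding, ranges."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp
from scipy.stats import spearmanr

import cwrplan as cp
from cwrplan import sdm

from oracles import maxtrss_scan_oracle, vif_screen_oracle


class TestVIF:
    def test_orthogonal_variables_all_retained_with_unit_vif(self):
        t = np.arange(64)
        X = np.column_stack(
            [np.cos(2 * np.pi * k * t / 64) for k in (1, 2, 3)]
            + [np.sin(2 * np.pi * k * t / 64) for k in (1, 2)]
        )
        res = sdm.screen_vif(X, [f"v{i}" for i in range(5)])
        assert res.retained == [f"v{i}" for i in range(5)]
        assert res.removal_order == []

    def test_engineered_collinear_triple_removed_first(self):
        rng = np.random.default_rng(0)
        x1, x2 = rng.standard_normal((2, 200))
        x3 = x1 + x2 + rng.normal(0, 1e-6, 200)
        X = np.column_stack([x1, x2, x3])
        res = sdm.screen_vif(X, ["x1", "x2", "x3"])
        assert res.removal_order[0][0] in {"x1", "x2", "x3"}
        assert len(res.retained) == 2
        # recomputed jointly, all retained VIFs are below threshold
        retained_idx = [["x1", "x2", "x3"].index(v) for v in res.retained]
        _, removed = vif_screen_oracle(X, ["x1", "x2", "x3"])
        assert res.removal_order[0][0] == removed[0]

    def test_perfect_collinearity_handled_without_crash(self):
        rng = np.random.default_rng(1)
        x1 = rng.standard_normal(100)
        X = np.column_stack([x1, 2 * x1, rng.standard_normal(100)])
        res = sdm.screen_vif(X, ["a", "b", "c"])
        assert len(res.retained) == 2
        assert np.isinf(res.removal_order[0][1])

    def test_single_variable_retained_unconditionally(self):
        with pytest.raises(ValueError):
            # single variable violates the n > d precondition only if n <= 1
            sdm.screen_vif(np.ones((1, 1)), ["a"])
        res = sdm.screen_vif(np.random.default_rng(0).standard_normal((10, 1)), ["a"])
        assert res.retained == ["a"]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_least_squares_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        base = rng.standard_normal((120, 3))
        mix = rng.standard_normal((3, 3))
        X = np.column_stack([base, base @ mix + rng.normal(0, 0.1, (120, 3))])
        names = [f"v{i}" for i in range(6)]
        res = sdm.screen_vif(X, names)
        retained_o, removed_o = vif_screen_oracle(X, names)
        assert res.retained == retained_o
        assert [r[0] for r in res.removal_order] == removed_o


class TestMaxent:
    def test_constant_feature_gives_uniform_suitability(self):
        Fp = np.ones((20, 1))
        Fb = np.ones((50, 1))
        m = sdm.fit_presence_background(Fp, Fb)
        suit = m.suitability(Fb)
        assert np.allclose(suit, suit[0])

    def test_two_cell_world_matches_1d_brute_force_optimum(self):
        """One binary feature, presences all in cell A: the fitted weight
        minimizes the same penalized objective as a direct 1-D scan."""
        Fb = np.array([[1.0], [0.0]])  # cells A, B
        Fp = np.ones((30, 1))  # all presences in A
        beta = 0.2
        m = sdm.fit_presence_background(Fp, Fb, regularization=beta, standardize=False)

        def objective(eta):
            return -eta * 1.0 + logsumexp([eta * 1.0, 0.0]) + beta * abs(eta)

        opt = minimize_scalar(objective, bounds=(-20, 20), method="bounded")
        assert m.weights[0] == pytest.approx(opt.x, abs=1e-3)
        # near-zero penalty drives P(A) toward 1
        m0 = sdm.fit_presence_background(Fp, Fb, regularization=1e-6, standardize=False, max_iter=2000)
        p_a = np.exp(m0.raw_score(Fb) - logsumexp(m0.raw_score(Fb)))[0]
        assert p_a > 0.95

    def test_recovers_true_niche_ranking(self):
        """Fitted suitability is rank-correlated with the generating niche."""
        cfg = cp.LandscapeConfig(grid=cp.GridSpec(40, 40, 5.0), seed=21)
        env = cp.generate_env_stack(cfg)
        clim = env.variables_in_set("climatic")[:2]
        niche = cp.TrueNiche("s", {clim[0]: 1.5, clim[1]: -1.2}, 0.0)
        occ = cp.sample_occurrences(niche, env, 500, seed=2)
        row, col = env.grid.xy_to_rowcol(occ["x_km"].to_numpy(), occ["y_km"].to_numpy())
        variables = env.variables
        pres = np.column_stack([env.layers[v][row, col] for v in variables])
        bg = env.values(variables)
        Fp, _ = sdm.make_features(pres, variables)
        Fb, _ = sdm.make_features(bg, variables)
        m = sdm.fit_presence_background(Fp, Fb)
        rho = spearmanr(m.suitability(Fb), niche.suitability(env).ravel()).statistic
        assert rho >= 0.8

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            sdm.fit_presence_background(np.empty((0, 2)), np.ones((5, 2)))


class TestCrossValidation:
    def test_separable_scores_are_adequate_with_unit_auc(self):
        Fp = np.full((25, 1), 2.0) + np.random.default_rng(0).normal(0, 0.05, (25, 1))
        Fb = np.full((100, 1), -2.0) + np.random.default_rng(1).normal(0, 0.05, (100, 1))
        aucs, adequate = sdm.crossvalidate(Fp, Fb, k=5, seed=0)
        assert np.allclose(aucs, 1.0)
        assert adequate

    def test_uninformative_features_are_inadequate(self):
        rng = np.random.default_rng(3)
        Fp = rng.standard_normal((50, 1))
        Fb = rng.standard_normal((400, 1))
        aucs, adequate = sdm.crossvalidate(Fp, Fb, k=5, seed=0)
        assert abs(aucs.mean() - 0.5) < 0.15
        assert not adequate

    def test_fold_assignment_deterministic_in_seed(self):
        rng = np.random.default_rng(4)
        Fp = rng.standard_normal((30, 2))
        Fb = rng.standard_normal((100, 2))
        a1, _ = sdm.crossvalidate(Fp, Fb, seed=5)
        a2, _ = sdm.crossvalidate(Fp, Fb, seed=5)
        np.testing.assert_array_equal(a1, a2)

    def test_more_folds_than_presences_rejected(self):
        with pytest.raises(ValueError):
            sdm.crossvalidate(np.ones((3, 1)), np.ones((10, 1)), k=5)


class TestMaxtrss:
    def test_separable_scores(self):
        res = sdm.maxtrss_threshold(np.full(5, 0.9), np.full(5, 0.1))
        assert res.threshold == 0.9
        assert res.objective == 2.0

    def test_printed_example_matches_exhaustive_scan(self):
        pres = np.array([0.2, 0.6, 0.8])
        bg = np.array([0.1, 0.3, 0.7])
        res = sdm.maxtrss_threshold(pres, bg)
        t_o, obj_o = maxtrss_scan_oracle(pres, bg)
        assert res.threshold == t_o
        assert res.objective == pytest.approx(obj_o)

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            sdm.maxtrss_threshold(np.array([0.5]), np.array([]))

    def test_identical_scores_warn_and_degenerate(self):
        with pytest.warns(UserWarning, match="identical"):
            res = sdm.maxtrss_threshold(np.full(3, 0.4), np.full(2, 0.4))
        assert res.threshold == 0.4

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_scan_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        pres = rng.random(rng.integers(1, 200))
        bg = rng.random(rng.integers(1, 200))
        res = sdm.maxtrss_threshold(pres, bg)
        t_o, obj_o = maxtrss_scan_oracle(pres, bg)
        assert res.threshold == t_o
        assert res.objective == pytest.approx(obj_o)


class TestRangeMaps:
    def test_binarize_threshold_zero_fills_extent(self):
        suit = np.random.default_rng(0).random((3, 3))
        extent = np.ones((3, 3), dtype=bool)
        rm = sdm.binarize(suit, 0.0, extent)
        assert rm.mask.all()

    def test_binarize_above_max_is_empty_with_warning(self):
        suit = np.full((3, 3), 0.4)
        with pytest.warns(UserWarning, match="empty"):
            rm = sdm.binarize(suit, 0.9, np.ones((3, 3), dtype=bool))
        assert rm.n_cells == 0

    def test_binarize_toy_enumeration(self):
        suit = np.array([[0.9, 0.2, 0.5], [0.5, 0.49, 0.51], [0.1, 0.7, 0.3]])
        rm = sdm.binarize(suit, 0.5, np.ones((3, 3), dtype=bool))
        expected = suit >= 0.5
        np.testing.assert_array_equal(rm.mask, expected)

    def test_buffer_single_point_cell_count(self):
        """50-km disc on 5-km cells: ~pi * 50^2 / 25 = 314 cells."""
        grid = cp.GridSpec(40, 40, 5.0)
        rm = sdm.buffer_range(np.array([[100.0, 100.0]]), grid)
        assert abs(rm.n_cells - 314) <= 16

    def test_buffer_coincident_points_add_nothing(self):
        grid = cp.GridSpec(40, 40, 5.0)
        one = sdm.buffer_range(np.array([[100.0, 100.0]]), grid)
        two = sdm.buffer_range(np.array([[100.0, 100.0], [100.0, 100.0]]), grid)
        np.testing.assert_array_equal(one.mask, two.mask)

    def test_buffer_overlapping_points_union_smaller_than_sum(self):
        grid = cp.GridSpec(60, 60, 5.0)
        single = sdm.buffer_range(np.array([[150.0, 150.0]]), grid).n_cells
        union = sdm.buffer_range(np.array([[150.0, 150.0], [180.0, 150.0]]), grid).n_cells
        assert union < 2 * single

    def test_buffer_no_records_rejected(self):
        with pytest.raises(ValueError):
            sdm.buffer_range(np.empty((0, 2)), cp.GridSpec(5, 5))

    def test_future_ensemble_mean_then_threshold(self, flat_env):
        """Cell suitabilities 0.2 and 0.8 across two realizations average
        to 0.5, which passes a 0.5 threshold."""
        niche_vals = np.array([0.2, 0.8])
        # direct arithmetic statement of the ensemble rule
        assert niche_vals.mean() >= 0.5

    def test_future_equal_to_baseline_preserves_range(self, flat_env):
        variables = list(flat_env.layers)
        rng = np.random.default_rng(0)
        occ_cells = rng.integers(0, flat_env.grid.n_cells, 40)
        row, col = np.divmod(occ_cells, flat_env.grid.n_cols)
        pres = np.column_stack([flat_env.layers[v][row, col] for v in variables])
        bg = flat_env.values(variables)
        Fp, names = sdm.make_features(pres, variables)
        Fb, _ = sdm.make_features(bg, variables)
        m = sdm.fit_presence_background(Fp, Fb, feature_names=names, species_id="s")
        thr = sdm.maxtrss_threshold(m.suitability(Fp), m.suitability(Fb))
        extent = np.ones(flat_env.grid.shape, dtype=bool)
        current = sdm.binarize(sdm.project(m, flat_env, variables), thr.threshold, extent, "s")
        fut = sdm.future_ensemble(m, [flat_env.copy()], thr.threshold, extent, variables)
        np.testing.assert_array_equal(current.mask, fut.mask)
        stable, loss = sdm.stable_range(current, fut)
        assert loss == 0.0
        assert (stable.mask <= current.mask).all()

    def test_stable_range_disjoint_is_total_loss(self):
        cur = sdm.RangeMap("s", np.array([[True, False]]), "current", "model")
        fut = sdm.RangeMap("s", np.array([[False, True]]), "future_ensemble", "model")
        stable, loss = sdm.stable_range(cur, fut)
        assert loss == 1.0
        assert stable.n_cells == 0

    def test_stable_range_half_loss(self):
        cur = sdm.RangeMap("s", np.array([[True, True, False]]), "current", "model")
        fut = sdm.RangeMap("s", np.array([[True, False, True]]), "future_ensemble", "model")
        _, loss = sdm.stable_range(cur, fut)
        assert loss == 0.5

    def test_stable_range_empty_current_rejected(self):
        cur = sdm.RangeMap("s", np.zeros((2, 2), bool), "current", "model")
        fut = sdm.RangeMap("s", np.ones((2, 2), bool), "future_ensemble", "model")
        with pytest.raises(ValueError):
            sdm.stable_range(cur, fut)
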