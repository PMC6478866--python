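"""Independent brute-force oracles used by the test suite.

Each function re-derives an expected result by direct enumeration or
first-principles computation, sharing no code path with the package
implementation it checks.
"""

from __future__ import annotations

import numpy as np


def morans_i_lag1(field: np.ndarray) -> float:
    """Lag-1 (rook) Moran's I of a 2-D field."""
    z = field - field.mean()
    num = (z[:-1, :] * z[1:, :]).sum() + (z[:, :-1] * z[:, 1:]).sum()
    n_pairs = z[:-1, :].size + z[:, :-1].size
    return float((num / n_pairs) / z.var())


def variogram_range(field: np.ndarray, cell_km: float, rng: np.random.Generator,
                    n_pairs: int = 200_000, max_lag_km: float = 150.0,
                    bin_km: float = 5.0) -> float:
    """Practical range from a direct pairwise-distance semivariogram.

    Range = centre of the first distance bin whose semivariance reaches
    95% of the field variance (the sill).
    """
    n_rows, n_cols = field.shape
    n = field.size
    i = rng.integers(0, n, n_pairs)
    j = rng.integers(0, n, n_pairs)
    ri, ci = np.divmod(i, n_cols)
    rj, cj = np.divmod(j, n_cols)
    d = np.hypot(ri - rj, ci - cj) * cell_km
    v = field.ravel()
    sq = 0.5 * (v[i] - v[j]) ** 2
    sill = v.var()
    bins = np.arange(0.0, max_lag_km, bin_km)
    which = np.digitize(d, bins)
    gamma = np.array(
        [sq[which == k].mean() if (which == k).any() else np.nan for k in range(1, len(bins))]
    )
    centers = bins[1:] - bin_km / 2
    above = np.flatnonzero(gamma >= 0.95 * sill)
    return float(centers[above[0]]) if above.size else float("inf")


def vif_screen_oracle(X: np.ndarray, names: list[str], threshold: float = 10.0):
    """From-scratch iterative VIF removal using direct least-squares R^2."""
    X = np.asarray(X, dtype=float)
    active = list(range(len(names)))
    removed = []
    while len(active) > 1:
        vifs = []
        for k, j in enumerate(active):
            y = X[:, j]
            others = [m for m in active if m != j]
            A = np.column_stack([np.ones(len(X))] + [X[:, m] for m in others])
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
            ss_res = np.sum((y - A @ coef) ** 2)
            ss_tot = np.sum((y - y.mean()) ** 2)
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
            vifs.append(np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2))
        vifs = np.array(vifs)
        if vifs.max() < threshold:
            break
        worst = int(np.flatnonzero(vifs == vifs.max())[-1])
        removed.append(names[active[worst]])
        del active[worst]
    return [names[i] for i in active], removed


def maxtrss_scan_oracle(pres: np.ndarray, bg: np.ndarray):
    """Exhaustive scan over every observed score as a candidate threshold."""
    best_t, best_obj = None, -np.inf
    for t in sorted(set(np.concatenate([pres, bg]).tolist())):
        sens = np.mean(pres >= t)
        spec = np.mean(bg < t)
        if sens + spec > best_obj + 1e-12:
            best_obj, best_t = sens + spec, t
    return best_t, best_obj


def reserve_objective(selected_mask: np.ndarray, costs: np.ndarray,
                      combo_units: list[np.ndarray], edges: list[tuple[int, int]],
                      spf: float, blm: float) -> float:
    """Objective of one subset, computed from the problem definition."""
    cost = costs[selected_mask].sum()
    n_sel = selected_mask.sum()
    within = sum(1 for a, b in edges if selected_mask[a] and selected_mask[b])
    boundary = 4 * n_sel - 2 * within
    penalty = sum(
        spf * (costs[u].min() + 4 * blm)
        for u in combo_units
        if not selected_mask[u].any()
    )
    return float(cost + blm * boundary + penalty)


def exhaustive_reserve_optimum(costs: np.ndarray, combo_units: list[np.ndarray],
                               edges: list[tuple[int, int]], spf: float, blm: float):
    """Vectorized enumeration of all 2^n subsets; returns (objective, mask)."""
    n = len(costs)
    subsets = np.arange(2**n, dtype=np.uint32)
    memb = ((subsets[:, None] >> np.arange(n)) & 1).astype(bool)
    cost = memb @ costs
    n_sel = memb.sum(axis=1)
    if edges:
        ea = np.array([e[0] for e in edges])
        eb = np.array([e[1] for e in edges])
        within = (memb[:, ea] & memb[:, eb]).sum(axis=1)
    else:
        within = np.zeros(len(subsets))
    boundary = 4 * n_sel - 2 * within
    penalty = np.zeros(len(subsets))
    for units in combo_units:
        uncovered = ~memb[:, units].any(axis=1)
        penalty[uncovered] += spf * (costs[units].min() + 4 * blm)
    obj = cost + blm * boundary + penalty
    best = int(np.argmin(obj))
    return float(obj[best]), memb[best]


def greedy_trace_oracle(unit_ids: list[int], unit_combos: dict[int, set],
                        pa_flags: dict[int, bool] | None = None,
                        pragmatic: bool = False):
    """Re-evaluating greedy complementarity trace with the stated tie rules
    (most combinations added, then most species added, then lowest id)."""
    covered, covered_sp = set(), set()
    order = []

    def phase(pool):
        pool = set(pool)
        while True:
            best, best_key = None, None
            for u in sorted(pool):
                gain = len(unit_combos[u] - covered)
                if gain == 0:
                    continue
                sp_gain = len({c[0] for c in unit_combos[u]} - covered_sp)
                key = (-gain, -sp_gain, u)
                if best_key is None or key < best_key:
                    best, best_key = u, key
            if best is None:
                return
            order.append(
                (best, len(unit_combos[best] - covered),
                 len({c[0] for c in unit_combos[best]} - covered_sp))
            )
            covered.update(unit_combos[best])
            covered_sp.update({c[0] for c in unit_combos[best]})
            pool.discard(best)

    if pragmatic:
        phase([u for u in unit_ids if pa_flags[u]])
        phase([u for u in unit_ids if not pa_flags[u]])
    else:
        phase(list(unit_ids))
    return order
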