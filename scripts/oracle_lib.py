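"""Brute-force reference computations for the acceptance script.

Self-contained enumeration/least-squares versions of the quantities the
package computes by smarter means; used only to measure agreement rates.
"""

from __future__ import annotations

import numpy as np


def maxtrss_scan(pres: np.ndarray, bg: np.ndarray):
    """Exhaustive scan over observed scores, smallest threshold on ties."""
    best_t, best_obj = None, -np.inf
    for t in sorted(set(np.concatenate([pres, bg]).tolist())):
        obj = np.mean(pres >= t) + np.mean(bg < t)
        if obj > best_obj + 1e-12:
            best_obj, best_t = obj, t
    return best_t, best_obj


def vif_screen(X: np.ndarray, names: list[str], threshold: float = 10.0):
    """Iterative VIF removal via direct least-squares R^2."""
    active = list(range(len(names)))
    removed = []
    while len(active) > 1:
        vifs = []
        for j in active:
            y = X[:, j]
            A = np.column_stack([np.ones(len(X))] + [X[:, m] for m in active if m != j])
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


def exhaustive_optimum(costs: np.ndarray, combo_units: list[np.ndarray],
                       edges: list[tuple[int, int]], spf: float, blm: float) -> float:
    """Minimum objective over all 2^n unit subsets (vectorized)."""
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
    return float((cost + blm * boundary + penalty).min())


def greedy_trace(unit_ids, unit_combos, pa_flags=None, pragmatic=False):
    """Re-evaluating greedy complementarity with the stated tie rules."""
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
            order.append((best, len(unit_combos[best] - covered)))
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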