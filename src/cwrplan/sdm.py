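"""Presence-background species distribution modelling.

The modelling chain mirrors standard conservation-assessment practice:

1.  collinearity screening of environmental variables by iterated
    variance-inflation-factor (VIF) removal;
2.  a presence-background maximum-entropy model: the Gibbs distribution
    over background cells whose feature expectations match the presence
    feature means, fitted as an L1-penalized convex optimization over
    linear + quadratic features;
3.  five-fold cross-validation with AUC-based adequacy criteria;
4.  binarization at the maximum training sensitivity plus specificity
    (MAXTRSS) threshold;
5.  a 50-km circular-buffer fallback for species that cannot support a
    model;
6.  future-climate ensembles (mean of per-realization continuous
    projections, re-thresholded at the current model's cut) and
    climate-stable ranges (current AND future).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from sklearn.metrics import roc_auc_score

from .grids import EnvStack, GridSpec

DEFAULT_VIF_THRESHOLD = 10.0
DEFAULT_N_BACKGROUND = 10_000
DEFAULT_BUFFER_RADIUS_KM = 50.0
DEFAULT_CV_FOLDS = 5
# Adequacy defaults: mean cross-validated AUC at least 0.7 with fold sd
# at most 0.15; both configurable.
DEFAULT_MIN_MEAN_AUC = 0.7
DEFAULT_MAX_AUC_SD = 0.15
DEFAULT_REGULARIZATION = 0.05


# ---------------------------------------------------------------------------
# VIF screening
# ---------------------------------------------------------------------------

@dataclass
class VariableScreenResult:
    retained: list[str]
    removal_order: list[tuple[str, float]]  # (variable, VIF at removal)
    threshold: float


def _vif_single(X: np.ndarray, j: int) -> float:
    """VIF of column j from the R^2 of regressing it on the other columns."""
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    A = np.column_stack([np.ones(len(X)), others])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return np.inf
    r2 = 1.0 - np.sum(resid**2) / ss_tot
    if r2 >= 1.0 - 1e-12:
        return np.inf
    return 1.0 / (1.0 - r2)


def screen_vif(
    X: np.ndarray,
    names: list[str],
    threshold: float = DEFAULT_VIF_THRESHOLD,
) -> VariableScreenResult:
    """Iteratively drop the highest-VIF variable until all VIF < threshold.

    VIF_j = 1/(1 - R^2_j) with R^2_j from an ordinary least-squares
    regression of variable j on the remaining variables.  Perfectly
    collinear variables have infinite VIF and are removed first; among
    equal VIFs the variable listed last is removed, so earlier-listed
    variables are kept.  A single variable is retained unconditionally
    (its VIF is defined as 1).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != len(names):
        raise ValueError("X must be (n_samples, n_variables) matching names")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more samples than variables for VIF screening")
    active = list(range(len(names)))
    removals: list[tuple[str, float]] = []
    while len(active) > 1:
        sub = X[:, active]
        vifs = np.array([_vif_single(sub, k) for k in range(len(active))])
        if np.nanmax(vifs) < threshold:
            break
        worst = int(np.flatnonzero(vifs == vifs.max())[-1])  # later column on ties
        removals.append((names[active[worst]], float(vifs[worst])))
        del active[worst]
    return VariableScreenResult(
        retained=[names[i] for i in active], removal_order=removals, threshold=threshold
    )


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------

def make_features(values: np.ndarray, names: list[str], quadratic: bool = True) -> tuple[np.ndarray, list[str]]:
    """Linear (+ optional quadratic) feature expansion of an (n, d) value matrix."""
    values = np.asarray(values, dtype=float)
    feats = [values]
    fnames = list(names)
    if quadratic:
        feats.append(values**2)
        fnames += [f"{n}^2" for n in names]
    return np.concatenate(feats, axis=1), fnames


# ---------------------------------------------------------------------------
# Maximum-entropy model
# ---------------------------------------------------------------------------

@dataclass
class NicheModel:
    """Fitted presence-background maximum-entropy model.

    ``weights`` act on features standardized by the stored background
    mean/sd.  ``suitability`` maps the relative occurrence rate r(x)
    (Gibbs density times the number of background cells, so mean 1 over
    background) through r/(1+r) into (0, 1).
    """

    species_id: str
    feature_names: list[str]
    weights: np.ndarray
    feature_mean: np.ndarray
    feature_sd: np.ndarray
    log_z: float  # logsumexp of scores over background (standardized scale)
    n_background: int
    regularization: float
    converged: bool = True
    fold_aucs: np.ndarray | None = None
    adequate: bool | None = None
    threshold: float | None = None

    def _standardize(self, F: np.ndarray) -> np.ndarray:
        return (F - self.feature_mean) / self.feature_sd

    def raw_score(self, F: np.ndarray) -> np.ndarray:
        return self._standardize(np.asarray(F, dtype=float)) @ self.weights

    def relative_rate(self, F: np.ndarray) -> np.ndarray:
        """Gibbs density times n_background: mean 1 over background cells."""
        return np.exp(self.raw_score(F) - self.log_z + np.log(self.n_background))

    def suitability(self, F: np.ndarray) -> np.ndarray:
        # r/(1+r) computed stably as expit(log r)
        log_r = self.raw_score(F) - self.log_z + np.log(self.n_background)
        return expit(log_r)


def fit_presence_background(
    presence_features: np.ndarray,
    background_features: np.ndarray,
    feature_names: list[str] | None = None,
    regularization: float = DEFAULT_REGULARIZATION,
    species_id: str = "",
    standardize: bool = True,
    max_iter: int = 500,
) -> NicheModel:
    """Fit the L1-penalized maximum-entropy (Gibbs) model.

    Minimizes  -mean_presence(eta . f) + log sum_background exp(eta . f)
    + beta * ||eta||_1  over feature weights eta — the convex dual of
    entropy maximization subject to relaxed presence feature-mean
    matching.  The L1 term is handled exactly by splitting eta into
    positive and negative parts and bounding both at zero (L-BFGS-B).
    """
    Fp = np.atleast_2d(np.asarray(presence_features, dtype=float))
    Fb = np.atleast_2d(np.asarray(background_features, dtype=float))
    if Fp.shape[0] < 1 or Fb.shape[0] < 1:
        raise ValueError("need at least one presence and one background point")
    if not (np.isfinite(Fp).all() and np.isfinite(Fb).all()):
        raise ValueError("features must be finite")
    d = Fp.shape[1]
    names = feature_names if feature_names is not None else [f"f{i}" for i in range(d)]
    if standardize:
        mean = Fb.mean(axis=0)
        sd = Fb.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)  # constant feature -> zero after centring
    else:
        mean = np.zeros(d)
        sd = np.ones(d)
    Zp = (Fp - mean) / sd
    Zb = (Fb - mean) / sd
    pbar = Zp.mean(axis=0)
    beta = float(regularization)

    def fun_grad(theta: np.ndarray):
        a, b = theta[:d], theta[d:]
        eta = a - b
        scores = Zb @ eta
        lz = logsumexp(scores)
        q = np.exp(scores - lz)
        val = -pbar @ eta + lz + beta * theta.sum()
        g = -pbar + q @ Zb
        return val, np.concatenate([g + beta, -g + beta])

    res = minimize(
        fun_grad,
        np.zeros(2 * d),
        jac=True,
        method="L-BFGS-B",
        bounds=[(0.0, None)] * (2 * d),
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-8},
    )
    converged = bool(res.success)
    if not converged:
        warnings.warn(f"maxent fit for {species_id or '<species>'} did not converge: {res.message}")
    eta = res.x[:d] - res.x[d:]
    log_z = float(logsumexp(Zb @ eta))
    return NicheModel(
        species_id=species_id,
        feature_names=names,
        weights=eta,
        feature_mean=mean,
        feature_sd=sd,
        log_z=log_z,
        n_background=Fb.shape[0],
        regularization=beta,
        converged=converged,
    )


def sample_background(
    grid: GridSpec,
    native_range: np.ndarray,
    n: int = DEFAULT_N_BACKGROUND,
    seed: int = 0,
) -> np.ndarray:
    """Flat cell indices of background points: uniform without replacement
    from the native-range mask (all cells if fewer than n available)."""
    cells = np.flatnonzero(native_range.ravel())
    if cells.size == 0:
        raise ValueError("native range is empty")
    if cells.size <= n:
        return cells
    rng = np.random.default_rng(seed)
    return np.sort(rng.choice(cells, size=n, replace=False))


def crossvalidate(
    presence_features: np.ndarray,
    background_features: np.ndarray,
    k: int = DEFAULT_CV_FOLDS,
    seed: int = 0,
    regularization: float = DEFAULT_REGULARIZATION,
    min_mean_auc: float = DEFAULT_MIN_MEAN_AUC,
    max_auc_sd: float = DEFAULT_MAX_AUC_SD,
) -> tuple[np.ndarray, bool]:
    """k-fold cross-validation of the maxent fit.

    Presences are shuffled (seeded) and split into k folds; each fold's
    model is trained on the remaining presences against the full
    background and scored by AUC of held-out presences versus background
    (background points as pseudo-absences).  Adequacy requires mean AUC
    >= ``min_mean_auc`` and fold-AUC sd <= ``max_auc_sd``.
    """
    Fp = np.atleast_2d(np.asarray(presence_features, dtype=float))
    n = Fp.shape[0]
    if k > n:
        raise ValueError(f"k={k} folds but only {n} presences")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    aucs = []
    for fold in folds:
        train = np.setdiff1d(order, fold)
        model = fit_presence_background(
            Fp[train], background_features, regularization=regularization
        )
        scores = np.concatenate([model.suitability(Fp[fold]), model.suitability(background_features)])
        labels = np.concatenate([np.ones(len(fold)), np.zeros(len(background_features))])
        aucs.append(roc_auc_score(labels, scores))
    aucs = np.array(aucs)
    adequate = bool(aucs.mean() >= min_mean_auc and aucs.std(ddof=0) <= max_auc_sd)
    return aucs, adequate


# ---------------------------------------------------------------------------
# Thresholding and range maps
# ---------------------------------------------------------------------------

@dataclass
class ThresholdResult:
    threshold: float
    sensitivity: float
    specificity: float

    @property
    def objective(self) -> float:
        return self.sensitivity + self.specificity


def maxtrss_threshold(presence_scores: np.ndarray, background_scores: np.ndarray) -> ThresholdResult:
    """Maximum training sensitivity plus specificity threshold.

    Candidates are the observed score values; a presence counts as
    predicted-present when its score is >= t.  Ties in the objective are
    broken toward the smallest threshold (the largest, most conservative
    range).
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("presence and background scores must be non-empty")
    cand = np.unique(np.concatenate([p, b]))
    if cand.size == 1:
        warnings.warn("all scores identical; threshold degenerate")
        return ThresholdResult(float(cand[0]), 1.0, 0.0)
    sens = (p[:, None] >= cand[None, :]).mean(axis=0)
    spec = (b[:, None] < cand[None, :]).mean(axis=0)
    obj = sens + spec
    best = int(np.flatnonzero(obj == obj.max())[0])  # smallest candidate on ties
    return ThresholdResult(float(cand[best]), float(sens[best]), float(spec[best]))


@dataclass
class RangeMap:
    """Binary species range on the analysis grid."""

    species_id: str
    mask: np.ndarray
    epoch: str  # current | future_ensemble | stable
    origin: str  # model | buffer

    @property
    def n_cells(self) -> int:
        return int(self.mask.sum())


def binarize(
    suitability: np.ndarray,
    threshold: float,
    extent_mask: np.ndarray,
    species_id: str = "",
    epoch: str = "current",
) -> RangeMap:
    """Model range: cells inside the background extent with suitability >= t*."""
    mask = extent_mask & (suitability >= threshold)
    if not mask.any():
        warnings.warn(f"binarized range for {species_id or '<species>'} is empty")
    return RangeMap(species_id=species_id, mask=mask, epoch=epoch, origin="model")


def buffer_range(
    occurrences_xy: np.ndarray,
    grid: GridSpec,
    radius_km: float = DEFAULT_BUFFER_RADIUS_KM,
    native_range: np.ndarray | None = None,
    species_id: str = "",
) -> RangeMap:
    """Union of circular buffers around occurrence points.

    A cell belongs to the range iff its centre lies within ``radius_km``
    of at least one record; the result is clipped to the native range.
    """
    pts = np.atleast_2d(np.asarray(occurrences_xy, dtype=float))
    if pts.size == 0:
        raise ValueError("buffer_range needs at least one occurrence")
    xs, ys = grid.cell_centers()
    mask = np.zeros(grid.shape, dtype=bool)
    r2 = radius_km**2
    for x, y in pts:
        # restrict the distance test to the bounding window of the disc
        row0, col0 = grid.xy_to_rowcol(np.array([x - radius_km]), np.array([y - radius_km]))
        row1, col1 = grid.xy_to_rowcol(np.array([x + radius_km]), np.array([y + radius_km]))
        rlo = 0 if row0[0] < 0 else row0[0]
        clo = 0 if col0[0] < 0 else col0[0]
        rhi = grid.n_rows if row1[0] < 0 else row1[0] + 1
        chi = grid.n_cols if col1[0] < 0 else col1[0] + 1
        win = (xs[rlo:rhi, clo:chi] - x) ** 2 + (ys[rlo:rhi, clo:chi] - y) ** 2 <= r2
        mask[rlo:rhi, clo:chi] |= win
    if native_range is not None:
        mask &= native_range
    return RangeMap(species_id=species_id, mask=mask, epoch="current", origin="buffer")


def project(model: NicheModel, env: EnvStack, variables: list[str], quadratic: bool = True) -> np.ndarray:
    """Continuous suitability raster of a fitted model on an environment stack."""
    F, _ = make_features(env.values(variables), variables, quadratic=quadratic)
    return model.suitability(F).reshape(env.grid.shape)


def future_ensemble(
    model: NicheModel,
    futures: list[EnvStack],
    threshold: float,
    extent_mask: np.ndarray,
    variables: list[str],
    quadratic: bool = True,
) -> RangeMap:
    """Mean continuous projection over future realizations, binarized at
    the current model's MAXTRSS threshold."""
    if not futures:
        raise ValueError("need at least one future realization")
    grid = futures[0].grid
    for f in futures[1:]:
        if f.grid != grid:
            raise ValueError("future stacks are on mismatched grids")
    mean_suit = np.mean([project(model, f, variables, quadratic) for f in futures], axis=0)
    rm = binarize(mean_suit, threshold, extent_mask, species_id=model.species_id, epoch="future_ensemble")
    return rm


def stable_range(current: RangeMap, future: RangeMap) -> tuple[RangeMap, float]:
    """Climate-stable range (current AND future) and the range-loss fraction."""
    if current.species_id != future.species_id:
        raise ValueError("range maps are for different species")
    if current.mask.shape != future.mask.shape:
        raise ValueError("range maps are on mismatched grids")
    n_current = current.n_cells
    if n_current == 0:
        raise ValueError("current range is empty")
    stable = RangeMap(
        species_id=current.species_id,
        mask=current.mask & future.mask,
        epoch="stable",
        origin=current.origin,
    )
    loss = 1.0 - stable.n_cells / n_current
    return stable, loss
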