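"""Per-voxel ridge encoding models with cross-set cross-validation.

Each voxel's response magnitude to an action video is modeled as a
weighted sum of that video's feature vector, fit by L2 (ridge) regression.
The regularization coefficient lambda is chosen per voxel from 100
candidates (0 up to the largest value that still yields a non-null model)
by minimizing 10-fold cross-validated MSE on the *other* video set.
Generalization is scored by training on all 60 videos of one set,
predicting the other set, and correlating predicted with actual responses
(r_CV).  Voxels are screened by requiring positive r_CV with FDR-corrected
q < 0.01 in both sets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import DataError

logger = logging.getLogger(__name__)

NONNULL_RTOL = 1e-6   # |w|_max threshold relative to the OLS solution
DEFAULT_N_LAMBDAS = 100
DEFAULT_FOLDS = 10


class _RidgeSolver:
    """Eigendecomposition-backed ridge solver for one design matrix.

    Solves (X'X + lam I) w = X'y for many (y, lam) cheaply; lam = 0 on a
    rank-deficient design falls back to the minimum-norm (pseudoinverse)
    solution.
    """

    def __init__(self, X: np.ndarray):
        self.X = np.asarray(X, dtype=float)
        s, V = np.linalg.eigh(self.X.T @ self.X)
        self.s = np.clip(s, 0.0, None)
        self.V = V
        self.tol = max(self.s.max(), 0.0) * np.finfo(float).eps * len(s)

    def coef(self, y: np.ndarray, lam: float) -> np.ndarray:
        c = self.V.T @ (self.X.T @ y)
        denom = self.s + lam
        if lam == 0 and np.any(self.s <= self.tol):
            logger.info("lambda=0 on rank-deficient design: "
                        "minimum-norm solution")
            inv = np.where(self.s > self.tol, 1.0 / np.maximum(denom, 1e-300),
                           0.0)
        else:
            inv = 1.0 / denom
        return self.V @ (c * inv)

    def coef_grid(self, y: np.ndarray, lams: np.ndarray) -> np.ndarray:
        """Weights for a whole lambda grid at once: F x L."""
        c = self.V.T @ (self.X.T @ y)
        denom = self.s[:, None] + np.asarray(lams)[None, :]
        inv = np.where(denom > self.tol, 1.0 / np.maximum(denom, 1e-300), 0.0)
        return self.V @ (c[:, None] * inv)


def fit_ridge(X: np.ndarray, y: np.ndarray, lam: float) -> np.ndarray:
    """Closed-form ridge solution w = argmin ||y - Xw||^2 + lam ||w||^2."""
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    return _RidgeSolver(X).coef(np.asarray(y, dtype=float), lam)


def lambda_grid(X: np.ndarray, y: np.ndarray,
                n: int = DEFAULT_N_LAMBDAS,
                solver: _RidgeSolver | None = None) -> np.ndarray:
    """Candidate regularization grid: 0 plus n-1 log-spaced values up to
    the largest lambda that still produces a non-null model.

    A lambda is non-null while the largest absolute weight exceeds
    1e-6 times the largest absolute unregularized weight; lambda_max is
    located by doubling then bisection, making the grid deterministic and
    scale-aware (rescaling y rescales the grid consistently).
    """
    if n < 2:
        raise ValueError("need at least 2 candidate lambdas")
    solver = solver or _RidgeSolver(X)
    y = np.asarray(y, dtype=float)
    w0max = float(np.max(np.abs(solver.coef(y, 0.0))))
    if w0max == 0.0:
        warnings.warn("all-zero response: degenerate single-lambda grid",
                      RuntimeWarning, stacklevel=2)
        return np.array([0.0])
    thresh = NONNULL_RTOL * w0max

    def nonnull(lam: float) -> bool:
        return float(np.max(np.abs(solver.coef(y, lam)))) > thresh

    hi = max(float(solver.s.max()), 1.0)
    while nonnull(hi) and hi < 1e30:
        hi *= 2.0
    lo = hi / 2.0
    while not nonnull(lo) and lo > 1e-30:
        lo /= 2.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if nonnull(mid):
            lo = mid
        else:
            hi = mid
    lam_max = lo
    return np.concatenate([[0.0],
                           np.geomspace(lam_max * 1e-5, lam_max, n - 1)])


def select_lambda(grid: np.ndarray, other_design: np.ndarray,
                  other_y: np.ndarray, folds: int = DEFAULT_FOLDS,
                  fold_solvers: list | None = None) -> float:
    """Pick the grid lambda minimizing mean held-fold MSE on the other set.

    The other set's conditions are partitioned into ``folds`` contiguous
    blocks in their fixed condition order (deterministic, no seed); ties
    go to the smallest lambda.
    """
    grid = np.asarray(grid, dtype=float)
    X, y = np.asarray(other_design, float), np.asarray(other_y, float)
    n = X.shape[0]
    if folds > n:
        raise DataError(f"{folds} folds exceed {n} conditions")
    if grid.size == 1:
        return float(grid[0])
    blocks = np.array_split(np.arange(n), folds)
    mse = np.zeros(grid.size)
    for f, te in enumerate(blocks):
        tr = np.setdiff1d(np.arange(n), te, assume_unique=True)
        if fold_solvers is not None:
            solver = fold_solvers[f]
        else:
            solver = _RidgeSolver(X[tr])
        W = solver.coef_grid(y[tr], grid)          # F x L
        resid = X[te] @ W - y[te][:, None]
        mse += (resid ** 2).mean(axis=0)
    order = np.argsort(grid, kind="stable")
    best = order[int(np.argmin(mse[order]))]
    return float(grid[best])


def crossval_r(train: tuple[np.ndarray, np.ndarray],
               test: tuple[np.ndarray, np.ndarray],
               lam: float) -> tuple[float, np.ndarray]:
    """Train on one set, predict the held-out set, correlate.

    Returns (r_CV, weights).  A zero-variance prediction (or response)
    yields NaN, which excludes the voxel downstream.
    """
    X_tr, y_tr = train
    X_te, y_te = test
    if X_tr.shape[1] != X_te.shape[1]:
        raise DataError("train and test designs differ in features")
    w = fit_ridge(X_tr, y_tr, lam)
    pred = X_te @ w
    if np.std(pred) == 0 or np.std(y_te) == 0:
        return float("nan"), w
    return float(np.corrcoef(pred, y_te)[0, 1]), w


def _pearson_pvalue_onesided(r: np.ndarray, n: int) -> np.ndarray:
    """One-sided p for H1: rho > 0, via the exact t-transform."""
    r = np.clip(np.nan_to_num(r, nan=0.0), -0.999999, 0.999999)
    t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    return stats.t.sf(t, df=n - 2)


def screen_voxels(r_cv_by_set: dict[int, np.ndarray], n_conditions: int,
                  q_threshold: float = 0.01
                  ) -> tuple[np.ndarray, dict[int, np.ndarray]]:
    """Keep voxels predicted well by both sets' models.

    Per set, one-sided p-values for r_CV > 0 are Benjamini-Hochberg
    corrected across voxels; a voxel is included iff its r_CV is positive
    and q < threshold in both sets.  NaN r_CV always excludes.
    Returns (included_mask, q-values per set).
    """
    qs: dict[int, np.ndarray] = {}
    mask = None
    for s, r in r_cv_by_set.items():
        r = np.asarray(r, dtype=float)
        p = _pearson_pvalue_onesided(r, n_conditions)
        p[np.isnan(r)] = 1.0
        _, q, _, _ = multipletests(p, method="fdr_bh")
        qs[s] = q
        ok = (r > 0) & (q < q_threshold) & ~np.isnan(r)
        mask = ok if mask is None else (mask & ok)
    return mask, qs


@dataclass
class EncodingFit:
    """Per-voxel ridge fits trained on one video set.

    weights are fit on the full training set at each voxel's selected
    lambda; r_cv is the cross-set prediction correlation on the held-out
    set.  q_values and included_mask are filled by screening across both
    sets' fits.
    """

    train_set: int
    test_set: int
    weights: np.ndarray
    lambda_per_voxel: np.ndarray
    r_cv: np.ndarray
    q_values: np.ndarray | None = None
    included_mask: np.ndarray | None = None
    column_means: np.ndarray = field(default_factory=lambda: np.zeros(0))
    column_sds: np.ndarray = field(default_factory=lambda: np.zeros(0))


def _zscore_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise DataError("zero-variance design column cannot be z-scored")
    return (X - mu) / sd, mu, sd


def fit_encoding(design_by_set: dict[int, np.ndarray],
                 responses_by_set: dict[int, np.ndarray],
                 n_lambdas: int = DEFAULT_N_LAMBDAS,
                 folds: int = DEFAULT_FOLDS,
                 q_threshold: float = 0.01,
                 ) -> dict[int, EncodingFit]:
    """Fit the full cross-set encoding analysis for every voxel.

    design_by_set: set -> conditions x F feature scores.
    responses_by_set: set -> voxels x conditions response magnitudes
    (run splits already averaged).

    For each training set: design columns are z-scored with training-set
    statistics (applied unchanged to the held-out design) and responses
    centered per voxel; the lambda grid is built from the training data
    and the winning lambda minimizes 10-fold CV MSE on the other set.
    """
    sets = sorted(design_by_set)
    if len(sets) != 2:
        raise DataError("cross-set encoding needs exactly two sets")
    fits: dict[int, EncodingFit] = {}
    for s in sets:
        o = sets[1] if s == sets[0] else sets[0]
        Xs_raw, Xo_raw = design_by_set[s], design_by_set[o]
        Ys, Yo = (np.asarray(responses_by_set[k], float) for k in (s, o))
        Xs, mu, sd = _zscore_fit(np.asarray(Xs_raw, float))
        Xo = (np.asarray(Xo_raw, float) - mu) / sd
        n_vox = Ys.shape[0]
        n_cond = Xo.shape[0]
        solver = _RidgeSolver(Xs)
        blocks = np.array_split(np.arange(n_cond), folds)
        fold_solvers = [
            _RidgeSolver(Xo[np.setdiff1d(np.arange(n_cond), te,
                                         assume_unique=True)])
            for te in blocks]
        W = np.zeros((n_vox, Xs.shape[1]))
        lams = np.zeros(n_vox)
        r_cv = np.full(n_vox, np.nan)
        for v in range(n_vox):
            ys = Ys[v] - Ys[v].mean()
            yo = Yo[v] - Yo[v].mean()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                grid = lambda_grid(Xs, ys, n_lambdas, solver=solver)
            lam = select_lambda(grid, Xo, yo, folds=folds,
                                fold_solvers=fold_solvers)
            w = solver.coef(ys, lam)
            pred = Xo @ w
            if np.std(pred) > 0 and np.std(yo) > 0:
                r_cv[v] = np.corrcoef(pred, yo)[0, 1]
            W[v] = w
            lams[v] = lam
        fits[s] = EncodingFit(train_set=s, test_set=o, weights=W,
                              lambda_per_voxel=lams, r_cv=r_cv,
                              column_means=mu, column_sds=sd)
    mask, qs = screen_voxels({s: fits[s].r_cv for s in sets},
                             n_conditions=design_by_set[sets[0]].shape[0],
                             q_threshold=q_threshold)
    for s in sets:
        fits[s].q_values = qs[s]
        fits[s].included_mask = mask
    return fits
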