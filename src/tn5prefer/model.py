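"""Elastic-net logistic classification of insertion sites vs controls.

The model is the penalized logistic likelihood

    (1/n) * sum_i loss(y_i, x_i'b + b0)
        + lambda * ( alpha * |b|_1 + (1 - alpha)/2 * |b|_2^2 )

fit on features min-max standardized to [0, 1] so coefficients are directly
comparable as importance measures.  Lambda is selected on a log-spaced grid
from lambda_max (the smallest penalty that zeroes all coefficients) by
K-fold cross-validation minimizing the CV deviance; the CV accuracy at the
selected lambda is the headline metric, with accuracy defined as
(TP + TN) / (TP + TN + FP + FN) at a 0.5 probability threshold.
The optimizer is an accelerated proximal-gradient (FISTA) scheme,
warm-started along the lambda path; convergence is declared when the
maximum coefficient change falls below the tolerance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold
from scipy.special import expit

from tn5prefer.encoding import FeatureMatrix, standardize

log = logging.getLogger(__name__)


@dataclass
class ModelFit:
    coef: np.ndarray
    intercept: float
    alpha: float
    lambda_: float
    bounds: tuple[np.ndarray, np.ndarray]
    feature_names: list[str]
    blocks: dict[str, slice]
    positions: np.ndarray | None
    window: int
    seed: int
    cv_accuracy: float
    lambdas: np.ndarray = field(default_factory=lambda: np.zeros(0))
    cv_deviance: np.ndarray = field(default_factory=lambda: np.zeros(0))


@dataclass
class ModelMetrics:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n if self.n else float("nan")


@dataclass
class ImportanceMap:
    """Parameter x window-position map of absolute coefficient mass."""

    rows: list[str]
    matrix: np.ndarray  # len(rows) x window, NaN where a row has no feature
    row_importance: np.ndarray
    column_importance: np.ndarray


def _lambda_grid(
    X01: np.ndarray, y: np.ndarray, alpha: float, n_lambda: int, decades: float
) -> np.ndarray:
    n = X01.shape[0]
    resid = y - y.mean()
    grad = np.abs(X01.T @ resid) / n
    lam_max = grad.max() / max(alpha, 1e-3)
    lam_max = max(lam_max, 1e-6)
    return np.logspace(np.log10(lam_max), np.log10(lam_max) - decades, n_lambda)


def _spectral_norm_sq(X: np.ndarray, iters: int = 30) -> float:
    """Squared spectral norm of [X, 1] by power iteration (deterministic)."""
    n, p = X.shape
    v = np.full(p + 1, 1.0 / np.sqrt(p + 1))
    for _ in range(iters):
        u = X @ v[:p] + v[p]
        w = np.empty(p + 1)
        w[:p] = X.T @ u
        w[p] = u.sum()
        norm = np.linalg.norm(w)
        if norm == 0:
            return 1.0
        v = w / norm
    u = X @ v[:p] + v[p]
    return float(u @ u)


def _soft_threshold(x: np.ndarray, t: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def _path_models(
    X: np.ndarray, y: np.ndarray, lambdas: np.ndarray, alpha: float, seed: int,
    tol: float, max_iter: int, s_sq: float | None = None,
):
    """Warm-started FISTA fits along a descending lambda path.

    Proximal-gradient (FISTA) on the elastic-net logistic objective: the
    smooth part (mean log-loss + ridge term) is handled by gradient steps
    at the fixed step 1/L, L = sigma_max([X,1])^2/(4n) + lambda(1-alpha);
    the L1 part by soft-thresholding.  The intercept is unpenalized.
    Yields (lambda, coef, intercept) per lambda; warm starts make later
    (smaller) lambdas cheap.
    """
    n, p = X.shape
    if s_sq is None:
        s_sq = _spectral_norm_sq(X)
    XT = np.ascontiguousarray(X.T)
    L_logistic = s_sq / (4.0 * n)
    coef = np.zeros(p)
    b0 = 0.0
    for lam in lambdas:
        L = L_logistic + lam * (1.0 - alpha)
        step = 1.0 / L
        thr = step * lam * alpha
        z_coef, z_b0 = coef.copy(), b0
        t_momentum = 1.0
        prev_coef, prev_b0 = coef.copy(), b0
        for _ in range(max_iter):
            prob = expit(X @ z_coef + z_b0)
            resid = (prob - y) / n
            grad = XT @ resid + lam * (1.0 - alpha) * z_coef
            new_coef = _soft_threshold(z_coef - step * grad, thr)
            new_b0 = z_b0 - step * float(resid.sum())
            t_next = (1.0 + np.sqrt(1.0 + 4.0 * t_momentum**2)) / 2.0
            gamma = (t_momentum - 1.0) / t_next
            z_coef = new_coef + gamma * (new_coef - prev_coef)
            z_b0 = new_b0 + gamma * (new_b0 - prev_b0)
            t_momentum = t_next
            delta = max(
                np.abs(new_coef - prev_coef).max(initial=0.0), abs(new_b0 - prev_b0)
            )
            prev_coef, prev_b0 = new_coef, new_b0
            if delta < tol:
                break
        coef, b0 = prev_coef, prev_b0
        yield lam, coef.copy(), float(b0)


def fit_elastic_net(
    fm: FeatureMatrix,
    alpha: float = 0.5,
    folds: int = 10,
    seed: int = 0,
    n_lambda: int = 12,
    lambda_decades: float = 3.0,
    tol: float = 1e-5,
    max_iter: int = 300,
) -> ModelFit:
    """Fit with CV lambda selection; deterministic given the seed.

    Fold assignment is a seeded stratified shuffle of row indices, so the
    fit is reproducible for a fixed matrix and seed.
    """
    classes = np.unique(fm.y)
    if classes.size != 2:
        raise ValueError("training matrix must contain exactly two classes")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if not np.isfinite(fm.X).all():
        raise ValueError("non-finite feature values")

    X01, bounds = standardize(fm.X)
    y = fm.y.astype(int)
    lambdas = _lambda_grid(X01, y, alpha, n_lambda, lambda_decades)

    kf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    dev = np.zeros((folds, lambdas.size))
    acc = np.zeros((folds, lambdas.size))
    for f, (tr, va) in enumerate(kf.split(X01, y)):
        s_sq = _spectral_norm_sq(X01[tr])
        for li, (_lam, coef, b0) in enumerate(
            _path_models(X01[tr], y[tr], lambdas, alpha, seed, tol, max_iter, s_sq)
        ):
            z = X01[va] @ coef + b0
            prob = expit(z)
            dev[f, li] = log_loss(y[va], prob, labels=[0, 1])
            acc[f, li] = float(((prob >= 0.5).astype(int) == y[va]).mean())

    best = int(dev.mean(axis=0).argmin())
    cv_accuracy = float(acc[:, best].mean())
    for _lam, coef, b0 in _path_models(
        X01, y, lambdas[: best + 1], alpha, seed, tol, max_iter
    ):
        pass
    return ModelFit(
        coef=coef,
        intercept=b0,
        alpha=alpha,
        lambda_=float(lambdas[best]),
        bounds=bounds,
        feature_names=fm.names,
        blocks=fm.blocks,
        positions=fm.positions,
        window=fm.window,
        seed=seed,
        cv_accuracy=cv_accuracy,
        lambdas=lambdas,
        cv_deviance=dev.mean(axis=0),
    )


def predict_proba(fit: ModelFit, fm: FeatureMatrix) -> np.ndarray:
    if fm.X.shape[1] != fit.coef.size:
        raise ValueError(
            f"matrix has {fm.X.shape[1]} features, fit expects {fit.coef.size}"
        )
    X01, _ = standardize(fm.X, fit.bounds)
    z = X01 @ fit.coef + fit.intercept
    return expit(z)


def evaluate(fit: ModelFit, fm: FeatureMatrix) -> ModelMetrics:
    """Confusion counts and accuracy at the 0.5 threshold, applying the
    training standardization bounds to the (held-out) matrix."""
    prob = predict_proba(fit, fm)
    pred = (prob >= 0.5).astype(int)
    y = fm.y.astype(int)
    return ModelMetrics(
        tp=int(((pred == 1) & (y == 1)).sum()),
        tn=int(((pred == 0) & (y == 0)).sum()),
        fp=int(((pred == 1) & (y == 0)).sum()),
        fn=int(((pred == 0) & (y == 1)).sum()),
    )


def compare_vector_sets(
    matrices: dict[str, FeatureMatrix],
    alpha: float = 0.5,
    folds: int = 10,
    seed: int = 0,
    **fit_kwargs,
) -> dict[str, ModelFit]:
    """One CV fit per named block set (same sites/controls throughout);
    the caller compares ``cv_accuracy`` across entries."""
    fits = {}
    for name, fm in matrices.items():
        fits[name] = fit_elastic_net(fm, alpha=alpha, folds=folds, seed=seed, **fit_kwargs)
        log.info("block set %-24s CV accuracy %.3f", name, fits[name].cv_accuracy)
    return fits


def train_test_split_rows(
    fm: FeatureMatrix, split: float, seed: int
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Seeded stratified row split into (train, test) at the given ratio."""
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for cls in np.unique(fm.y):
        rows = np.nonzero(fm.y == cls)[0]
        rng.shuffle(rows)
        cut = int(round(split * rows.size))
        train_idx.append(rows[:cut])
        test_idx.append(rows[cut:])
    return (
        fm.subset_rows(np.sort(np.concatenate(train_idx))),
        fm.subset_rows(np.sort(np.concatenate(test_idx))),
    )


def cross_sample_validation(
    samples: dict[str, FeatureMatrix],
    split: float = 0.7,
    alpha: float = 0.5,
    folds: int = 10,
    seed: int = 0,
    **fit_kwargs,
) -> "pd.DataFrame":
    """Train on each sample's train split, evaluate on every sample's test
    split (including its own); returns the accuracy matrix (train x test)."""
    import pandas as pd

    names = list(samples)
    splits = {
        name: train_test_split_rows(fm, split, seed + i)
        for i, (name, fm) in enumerate(samples.items())
    }
    for name, (tr, te) in splits.items():
        if np.unique(tr.y).size < 2 or np.unique(te.y).size < 2:
            raise ValueError(f"sample {name!r} too small for a {split:.0%} split")
    acc = np.zeros((len(names), len(names)))
    for i, name_i in enumerate(names):
        fit = fit_elastic_net(
            splits[name_i][0], alpha=alpha, folds=folds, seed=seed, **fit_kwargs
        )
        for j, name_j in enumerate(names):
            acc[i, j] = evaluate(fit, splits[name_j][1]).accuracy
    return pd.DataFrame(acc, index=names, columns=names)


def importance_map(fit: ModelFit) -> ImportanceMap:
    """Reshape |coefficients| into parameter rows x window positions.

    Each block is one row (k-mer blocks sum the letter indicators at each
    position); rows with no feature at a position hold NaN there, excluded
    from the sums.  Row importance is the total absolute coefficient mass
    per parameter, column importance the per-position total.
    """
    if fit.positions is None:
        raise ValueError("fit carries no positional metadata")
    rows = list(fit.blocks)
    mat = np.full((len(rows), fit.window), np.nan)
    for r, name in enumerate(rows):
        sl = fit.blocks[name]
        coefs = np.abs(fit.coef[sl])
        poss = fit.positions[sl]
        for pos in np.unique(poss):
            mat[r, pos] = coefs[poss == pos].sum()
    row_imp = np.nansum(mat, axis=1)
    col_imp = np.nansum(mat, axis=0)
    return ImportanceMap(rows, mat, row_imp, col_imp)


def permuted_label_matrix(fm: FeatureMatrix, seed: int) -> FeatureMatrix:
    """Null control: same features, labels randomly permuted (seeded)."""
    rng = np.random.default_rng(seed)
    y = fm.y.copy()
    rng.shuffle(y)
    return FeatureMatrix(fm.X, y, fm.names, fm.blocks, fm.positions, fm.window)
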