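"""L1-penalized binomial classifier with cross-validated penalty selection.

The objective, on internally standardized features, is lasso logistic
regression in the glmnet parametrization

    min_{b0, b}  -(1/n) * loglik(b0, b)  +  lambda * ||b||_1

solved by iteratively reweighted least squares with cyclic coordinate
descent (soft thresholding, active-set sweeps, warm starts) down a
log-spaced lambda grid from the analytic lambda_max — the smallest
penalty at which every gene coefficient is exactly zero. Lambda is
chosen by minimum mean cross-validated binomial deviance. Coefficients
are reported on the original expression scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["LassoFit", "RocResult", "fit_lasso_path", "predict_prob", "roc_auc"]

log = logging.getLogger(__name__)

# Probability clip inside IRLS; keeps working weights bounded away from 0
# under (near-)perfect separation.
_P_CLIP = 1e-9


@dataclass
class LassoFit:
    feature_names: list[str]
    coef: np.ndarray  # original-scale coefficients at lambda_selected
    intercept: float
    lambda_path: np.ndarray
    lambda_selected: float
    cv_deviance: np.ndarray  # mean held-out binomial deviance per lambda
    coef_path: np.ndarray  # (n_lambda, n_features), original scale
    intercept_path: np.ndarray | None = None
    classes: tuple[str, str] = ("control", "case")
    dropped_constant: list[str] = field(default_factory=list)

    @property
    def selected_genes(self) -> dict[str, float]:
        return {g: float(c) for g, c in zip(self.feature_names, self.coef) if c != 0.0}

    def to_dict(self) -> dict:
        return {
            "genes": self.selected_genes,
            "intercept": self.intercept,
            "lambda": float(self.lambda_selected),
        }


def _binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _soft(x: float, t: float) -> float:
    if x > t:
        return x - t
    if x < -t:
        return x + t
    return 0.0


def _wls_cd(
    X: np.ndarray,
    w: np.ndarray,
    z: np.ndarray,
    lam: float,
    beta: np.ndarray,
    b0: float,
    tol: float,
) -> tuple[np.ndarray, float]:
    """Penalized weighted least squares by cyclic coordinate descent.

    Solves min (1/2n) sum w_i (z_i - b0 - x_i b)^2 + lam * ||b||_1 in
    place, sweeping the active set to convergence then confirming with a
    full sweep (new entrants trigger another round).
    """
    n, p = X.shape
    wsum = w.sum()
    r = z - b0 - X @ beta  # residual kept current
    den = (w[:, None] * X * X).sum(axis=0) / n
    wX = w[:, None] * X  # reused by sweeps and the KKT check

    def sweep(indices) -> float:
        nonlocal b0, r
        max_delta = 0.0
        for j in indices:
            if den[j] <= 0:
                continue
            bj = beta[j]
            num = wX[:, j] @ r / n + den[j] * bj
            new = _soft(num, lam) / den[j]
            if new != bj:
                beta[j] = new
                r += X[:, j] * (bj - new)
                max_delta = max(max_delta, abs(new - bj))
        # unpenalized intercept
        delta0 = (w * r).sum() / wsum
        if delta0 != 0.0:
            b0 += delta0
            r -= delta0
            max_delta = max(max_delta, abs(delta0))
        return max_delta

    # active-set CD with a vectorized KKT check over inactive features
    active = list(np.nonzero(beta)[0])
    for _ in range(1000):
        for _ in range(10_000):
            if sweep(active) < tol:
                break
        grad = (wX.T @ r) / n  # KKT: inactive j must satisfy |grad_j| <= lam
        inactive = beta == 0.0
        violators = np.nonzero(inactive & (np.abs(grad) > lam * (1 + 1e-12) + tol * 0.01))[0]
        violators = [j for j in violators if j not in set(active)]
        if not violators:
            break
        active.extend(violators)
    return beta, b0


def _logistic_lasso_path(
    Xs: np.ndarray, y: np.ndarray, lambdas: np.ndarray, tol: float = 1e-8
) -> tuple[np.ndarray, np.ndarray]:
    """Warm-started IRLS/CD solution path on standardized features."""
    n, p = Xs.shape
    beta = np.zeros(p)
    ybar = y.mean()
    b0 = float(np.log(ybar / (1 - ybar)))
    coefs = np.zeros((len(lambdas), p))
    intercepts = np.zeros(len(lambdas))
    for i, lam in enumerate(lambdas):
        for _ in range(200):  # IRLS outer loop
            eta = b0 + Xs @ beta
            pr = np.clip(1.0 / (1.0 + np.exp(-eta)), _P_CLIP, 1 - _P_CLIP)
            w = pr * (1.0 - pr)
            z = eta + (y - pr) / w
            beta_prev, b0_prev = beta.copy(), b0
            beta, b0 = _wls_cd(Xs, w, z, lam, beta, b0, tol)
            if max(np.max(np.abs(beta - beta_prev), initial=0.0), abs(b0 - b0_prev)) < tol * 10:
                break
        coefs[i] = beta
        intercepts[i] = b0
    return coefs, intercepts


def _stratified_folds(y: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Class-stratified fold labels, reproducible for a fixed seed.

    Leave-one-out (n_folds == n) gives every sample its own fold;
    otherwise samples are shuffled within class and dealt round-robin,
    with the second class offset so small folds stay balanced.
    """
    n = len(y)
    if n_folds >= n:
        return np.arange(n)
    rng = np.random.default_rng(seed)
    fold = np.empty(n, dtype=int)
    start = 0
    for cls in (0, 1):
        idx = np.where(y == cls)[0]
        rng.shuffle(idx)
        fold[idx] = (np.arange(len(idx)) + start) % n_folds
        start += len(idx)
    return fold


def fit_lasso_path(
    X: pd.DataFrame,
    y,
    n_folds: int | None = None,
    seed: int = 0,
    n_lambda: int = 100,
    lambda_min_ratio: float = 0.001,
    case_label: str | None = None,
    tol: float = 1e-7,
) -> LassoFit:
    """Fit the lasso-logistic path and select lambda by CV deviance.

    Parameters
    ----------
    X
        samples x genes expression (DataFrame, columns = gene ids).
    y
        two-level labels; ``case_label`` (default: lexicographically
        larger level) is encoded 1 so positive coefficients mean
        case-elevated.
    n_folds
        Defaults to leave-one-out when n <= 20, else 10-fold,
        stratified by class.
    """
    X = pd.DataFrame(X)
    y = pd.Series(list(y))
    levels = sorted(y.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two classes, got {levels}")
    if case_label is None:
        case_label = levels[1]
    yb = (y == case_label).to_numpy(dtype=float)
    n = len(yb)
    if min(int(yb.sum()), int(n - yb.sum())) < 2:
        raise ValueError("need >= 2 samples per class")

    sd = X.std(axis=0, ddof=0)
    constant = list(X.columns[sd == 0])
    if constant:
        log.warning("dropping %d constant feature(s): %s", len(constant), constant[:5])
        X = X.drop(columns=constant)
        sd = sd.drop(constant)
    names = list(X.columns)
    mu = X.mean(axis=0)
    Xs = ((X - mu) / sd).to_numpy()
    sd_arr, mu_arr = sd.to_numpy(), mu.to_numpy()

    # smallest lambda with all-zero coefficients: max null-model score
    lambda_max = float(np.max(np.abs(Xs.T @ (yb - yb.mean())))) / n
    grid = np.geomspace(lambda_max, lambda_min_ratio * lambda_max, n_lambda)

    if n_folds is None:
        n_folds = n if n <= 20 else 10
    n_folds = min(n_folds, n)
    fold = _stratified_folds(yb, n_folds, seed)

    cv_dev = np.zeros(n_lambda)
    for f in range(n_folds):
        tr, te = fold != f, fold == f
        if te.sum() == 0:
            continue
        if yb[tr].min() == yb[tr].max():  # one-class training fold
            p0 = float(yb[tr].mean())
            for j in range(n_lambda):
                cv_dev[j] += _binomial_deviance(yb[te], np.full(te.sum(), p0)) * te.sum()
            continue
        coefs, intercepts = _logistic_lasso_path(Xs[tr], yb[tr], grid, tol)
        eta = intercepts[:, None] + coefs @ Xs[te].T  # (n_lambda, n_te)
        probs = 1.0 / (1.0 + np.exp(-eta))
        for j in range(n_lambda):
            cv_dev[j] += _binomial_deviance(yb[te], probs[j]) * te.sum()
    cv_dev /= n

    j_best = int(np.argmin(cv_dev))
    coefs_s, intercepts_s = _logistic_lasso_path(Xs, yb, grid, tol)
    coef_path = coefs_s / sd_arr
    intercepts = intercepts_s - coef_path @ mu_arr

    return LassoFit(
        feature_names=names,
        coef=coef_path[j_best].copy(),
        intercept=float(intercepts[j_best]),
        lambda_path=grid,
        lambda_selected=float(grid[j_best]),
        cv_deviance=cv_dev,
        coef_path=coef_path,
        intercept_path=intercepts,
        classes=(next(l for l in levels if l != case_label), case_label),
        dropped_constant=constant,
    )


def predict_prob(fit: LassoFit, X: pd.DataFrame) -> np.ndarray:
    """Case probability = inverse logit of the linear predictor."""
    X = pd.DataFrame(X)
    missing = [g for g in fit.feature_names if g not in X.columns]
    if missing:
        raise KeyError(f"missing feature(s): {missing[:5]}")
    eta = fit.intercept + X[fit.feature_names].to_numpy() @ fit.coef
    return 1.0 / (1.0 + np.exp(-eta))


@dataclass
class RocResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float

    def trapezoid_auc(self) -> float:
        fpr = 1.0 - self.specificity
        return float(np.trapezoid(self.sensitivity, fpr))


def roc_auc(scores, labels) -> RocResult:
    """ROC curve and AUC with ties counted as half-concordant.

    AUC comes from the rank (Mann–Whitney) formula, identical to pair
    counting with ties at 0.5; curve points sit at every distinct score
    threshold, swept from high to low (score >= threshold calls a case).
    """
    from scipy.stats import rankdata

    s = np.asarray(scores, dtype=float)
    yb = np.asarray(labels)
    if yb.dtype.kind in "OUS":
        levels = sorted(pd.unique(yb))
        if len(levels) != 2:
            raise ValueError("need exactly two classes")
        yb = (yb == levels[1]).astype(int)
    else:
        yb = yb.astype(int)
    n_pos, n_neg = int(yb.sum()), int((1 - yb).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    ranks = rankdata(s)
    auc = (ranks[yb == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    thresholds = np.concatenate([[np.inf], np.unique(s)[::-1]])
    sens = np.array([(s[yb == 1] >= t).mean() for t in thresholds])
    spec = np.array([(s[yb == 0] < t).mean() for t in thresholds])
    return RocResult(thresholds=thresholds, sensitivity=sens,
                     specificity=spec, auc=float(auc))
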