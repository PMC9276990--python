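"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive — full enumeration, hand-rolled
step-up, literal running sums — and shares no code with the package.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import numpy as np


def hypergeom_upper_tail_enum(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by enumerating every n-subset of an N-element population."""
    population = [1] * K + [0] * (N - K)
    hits = total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(population[i] for i in draw) >= k:
            hits += 1
    return hits / total if total else 1.0


def hypergeom_upper_tail_exact(k: int, K: int, n: int, N: int) -> float:
    """Same tail by exact rational combinatorics (fast closed form)."""
    denom = math.comb(N, n)
    acc = Fraction(0)
    for i in range(k, min(K, n) + 1):
        acc += Fraction(math.comb(K, i) * math.comb(N - K, n - i), denom)
    return float(acc)


def bh_stepup(p: list[float]) -> list[float]:
    """Hand BH: sort, p_(i) * m / i, cumulative min from the right, cap."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = min(running, 1.0)
    return adj


def pooled_t_two_sample(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Textbook equal-variance two-sample t statistic and two-sided P."""
    from scipy import stats

    n1, n2 = len(x), len(y)
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    t = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), df=n1 + n2 - 2)
    return t, p


def gsea_running_sum(scores: list[float], hits: list[bool], weight: float) -> float:
    """Literal step-by-step running sum; ES = extremum by |value|."""
    n = len(scores)
    n_hit = sum(hits)
    denom = sum(abs(s) ** weight for s, h in zip(scores, hits) if h)
    running, best = 0.0, 0.0
    for s, h in zip(scores, hits):
        if h:
            running += (abs(s) ** weight) / denom
        else:
            running -= 1.0 / (n - n_hit)
        if abs(running) > abs(best):
            best = running
    return best


def ks_statistic_signed(hits: list[bool]) -> float:
    """Classic unweighted two-sample KS statistic on the hit indicator,
    signed by the direction of the largest excursion."""
    return gsea_running_sum([1.0] * len(hits), hits, 0.0)


def mwu_greater_enum(a: np.ndarray, b: np.ndarray) -> float:
    """Exact one-sided rank test by enumerating every group split."""
    from scipy.stats import rankdata

    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    m = len(a)
    u_obs = ranks[:m].sum()
    ge = total = 0
    for comb in itertools.combinations(range(len(pooled)), m):
        total += 1
        if ranks[list(comb)].sum() >= u_obs - 1e-9:
            ge += 1
    return ge / total


def auc_pair_counting(scores: np.ndarray, labels: np.ndarray) -> float:
    """Exhaustive concordant/discordant pair counting, ties = 0.5."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = conc = 0.0
    for sp in pos:
        for sn in neg:
            total += 1
            if sp > sn:
                conc += 1
            elif sp == sn:
                conc += 0.5
    return conc / total


def lasso_logistic_objective(
    X: np.ndarray, y: np.ndarray, b0: float, beta: np.ndarray, lam: float
) -> float:
    """glmnet-form objective: -(1/n) loglik + lam * ||beta||_1."""
    eta = b0 + X @ beta
    loglik = np.sum(y * eta - np.log1p(np.exp(eta)))
    return -loglik / len(y) + lam * np.abs(beta).sum()


def lasso_logistic_grid_search(
    X: np.ndarray, y: np.ndarray, lam: float, n_zoom: int = 14, half_width: float = 4.0
) -> tuple[float, np.ndarray]:
    """Minimize the penalized likelihood by iterative grid refinement.

    Cycles coordinate-wise 1-D grid refinement over (b0, beta), shrinking
    the bracket each zoom level; independent of any gradient machinery.
    """
    p = X.shape[1]
    params = np.zeros(p + 1)  # [b0, beta...]

    def obj(v: np.ndarray) -> float:
        return lasso_logistic_objective(X, y, v[0], v[1:], lam)

    width = half_width
    for _ in range(n_zoom):
        for j in range(p + 1):
            grid = params[j] + np.linspace(-width, width, 41)
            if j > 0:
                grid = np.append(grid, 0.0)  # the kink is always a candidate
            vals = []
            for g in grid:
                trial = params.copy()
                trial[j] = g
                vals.append(obj(trial))
            params[j] = grid[int(np.argmin(vals))]
        width *= 0.35
    return params[0], params[1:]
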