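"""Empirical-Bayes moderated two-group differential expression.

The per-gene two-sample contrast is stabilized by shrinking residual
variances toward a common prior: the prior degrees of freedom ``d0`` and
prior variance ``s0_sq`` are estimated by moment matching on the log
sample variances (the scaled-F fit used by the standard moderated-t
methodology), the posterior variance is the df-weighted blend

    s2_post = (d0 * s0_sq + d_g * s_g^2) / (d0 + d_g)

and the moderated t statistic log2FC / sqrt(s2_post * (1/n1 + 1/n2)) is
referred to a t distribution with d0 + d_g degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionData

__all__ = [
    "ModeratedTestParams",
    "THRESHOLD_PROFILES",
    "collapse_probes",
    "fit_moderated_test",
    "adjust_bh",
    "call_degs",
]

# (lfc_threshold, alpha) presets for DEG calling; the strict profile is
# typical for small discovery cohorts, the relaxed one for larger
# validation cohorts where fold changes attenuate.
THRESHOLD_PROFILES: dict[str, tuple[float, float]] = {
    "strict": (1.0, 0.05),
    "relaxed": (0.5, 0.05),
}

# Relative floor applied to zero residual variances (fraction of the
# smallest positive observed variance) so statistics stay finite.
_ZERO_VAR_FLOOR = 1e-8


@dataclass(frozen=True)
class ModeratedTestParams:
    """Shrinkage hyperparameters of the moderated test."""

    d0: float  # prior degrees of freedom; math.inf allowed
    s0_sq: float  # prior variance, log2 units squared

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValueError("d0 must be >= 0")
        if not self.s0_sq > 0:
            raise ValueError("s0_sq must be positive")


def collapse_probes(data: ExpressionData, probe_to_gene: dict[str, str]) -> ExpressionData:
    """Collapse probe-level rows to one row per gene by arithmetic mean.

    Probes absent from the mapping are dropped; output rows are ordered
    lexicographically by gene id.
    """
    keep = [p for p in data.values.index if p in probe_to_gene]
    if not keep:
        raise ValueError("no probe in the matrix is covered by the annotation")
    sub = data.values.loc[keep]
    gene_of = pd.Series([probe_to_gene[p] for p in keep], index=sub.index)
    collapsed = sub.groupby(gene_of).mean().sort_index()
    collapsed.index.name = "gene"
    return ExpressionData(values=collapsed, groups=data.groups.copy(), case=data.case)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone, convex)."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if -dif / x < 1e-10:
            break
    return float(x)


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled F prior to observed variances on log scale.

    Returns (d0, s0_sq); d0 = inf when the log-variance spread is no
    larger than expected from the residual degrees of freedom alone.
    """
    ok = s2 > 0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(e.mean())
    if len(e) < 2:
        return math.inf, float(math.exp(emean))
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar <= 0:
        return math.inf, float(math.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_sq = math.exp(
        emean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
    )
    return float(d0), float(s0_sq)


def fit_moderated_test(
    data: ExpressionData, params: ModeratedTestParams | None = None
) -> tuple[pd.DataFrame, ModeratedTestParams]:
    """Per-gene moderated two-group test.

    Parameters
    ----------
    data
        Expression with exactly two groups, >= 2 samples each.
    params
        Optional fixed hyperparameters. ``d0=0`` reproduces the ordinary
        pooled-variance t-test; ``d0=inf`` uses the prior variance alone,
        ranking genes exactly by \\|log2FC\\|. When omitted, (d0, s0_sq)
        are estimated from the data by moment matching.

    Returns
    -------
    (table, params) where table has columns gene, log2fc, t, p, p_adj
    (p_adj filled by :func:`call_degs` later; here a plain BH pass),
    and zero_var flags genes whose residual variance was floored.
    """
    case = data.case_matrix().to_numpy()
    ctrl = data.control_matrix().to_numpy()
    n1, n2 = case.shape[1], ctrl.shape[1]
    d_g = float(n1 + n2 - 2)

    log2fc = case.mean(axis=1) - ctrl.mean(axis=1)
    ss = case.var(axis=1, ddof=1) * (n1 - 1) + ctrl.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / d_g

    zero_var = s2 <= 0
    if zero_var.any():
        positive = s2[~zero_var]
        floor = (positive.min() * _ZERO_VAR_FLOOR) if positive.size else _ZERO_VAR_FLOOR
        s2 = np.where(zero_var, floor, s2)

    if params is None:
        d0, s0_sq = _fit_f_dist(s2, d_g)
        params = ModeratedTestParams(d0=d0, s0_sq=s0_sq)
    d0, s0_sq = params.d0, params.s0_sq

    if math.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + d_g * s2) / (d0 + d_g)
        df_total = d0 + d_g

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    t_mod = log2fc / se
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_mod), df=df_total)

    table = pd.DataFrame(
        {
            "gene": data.values.index.to_numpy(),
            "log2fc": log2fc,
            "t": t_mod,
            "p": p,
            "p_adj": adjust_bh(p),
            "zero_var": zero_var,
        }
    ).reset_index(drop=True)
    return table, params


def adjust_bh(p_raw) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment (stable among ties)."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any():
        raise ValueError("NaN p-values are not allowed")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(table: pd.DataFrame, lfc_threshold: float, alpha: float) -> pd.DataFrame:
    """Call up/down/none with strict thresholds on |log2FC| and adjusted P."""
    if lfc_threshold <= 0 or alpha <= 0:
        raise ValueError("thresholds must be positive")
    out = table.copy()
    sig = out["p_adj"] < alpha
    out["call"] = "none"
    out.loc[sig & (out["log2fc"] > lfc_threshold), "call"] = "up"
    out.loc[sig & (out["log2fc"] < -lfc_threshold), "call"] = "down"
    return out


def deg_counts(table: pd.DataFrame) -> dict[str, int]:
    c = table["call"].value_counts()
    up, down = int(c.get("up", 0)), int(c.get("down", 0))
    return {"up": up, "down": down, "total": up + down}
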