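"""Relative qPCR quantification by 2^-ddCt with two-group testing.

Per sample, dCt = Ct(target) - Ct(reference); ddCt subtracts the
control-group mean dCt, and the relative quantity is 2^-ddCt, so the
control group's geometric-mean fold change is exactly 1. The two-group
comparison runs on the ddCt (log) scale, where the measurements are
approximately normal, with an unpaired Student t-test; verdicts use a
significance band (P < 0.05) and a tendency band (0.05 < P < 0.15).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ddct_fold_change", "group_test", "quantify_and_test"]

log = logging.getLogger(__name__)


def ddct_fold_change(
    table: pd.DataFrame,
    target: str,
    reference: str = "GAPDH",
    control_group: str = "control",
) -> pd.DataFrame:
    """Per-sample ddCt and fold change for one target gene.

    ``table`` is long-format with columns (sample, group, gene, ct);
    technical replicates are averaged on the Ct scale. Samples missing a
    reference or target Ct are dropped with a warning.
    """
    ct = (
        table.groupby(["sample", "group", "gene"])["ct"].mean().reset_index()
        .pivot_table(index=["sample", "group"], columns="gene", values="ct")
        .reset_index()
    )
    for col in (target, reference):
        if col not in ct.columns:
            raise KeyError(f"gene {col!r} absent from Ct table")
    ok = ct[[target, reference]].notna().all(axis=1)
    if (~ok).any():
        log.warning("dropping %d sample(s) with missing Ct", int((~ok).sum()))
        ct = ct[ok]
    if (ct["group"] == control_group).sum() < 2:
        raise ValueError("need >= 2 control samples")

    ct = ct.copy()
    ct["dct"] = ct[target] - ct[reference]
    control_mean = ct.loc[ct["group"] == control_group, "dct"].mean()
    ct["ddct"] = ct["dct"] - control_mean
    ct["fold_change"] = 2.0 ** (-ct["ddct"])
    return ct[["sample", "group", "dct", "ddct", "fold_change"]].reset_index(drop=True)


def group_test(
    values,
    groups,
    control_group: str = "control",
    scale: str = "log",
) -> tuple[float, str]:
    """Unpaired two-sided Student t-test with banded verdicts.

    ``values`` are ddCt values when scale='log' (default) or raw fold
    changes when scale='raw' (log2-transformed internally is NOT applied;
    the raw option tests fold changes directly). Returns (p, verdict)
    with verdict in {'significant', 'tendency', 'none'}.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    a, b = v[g != control_group], v[g == control_group]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need >= 2 values")
    if scale not in ("log", "raw"):
        raise ValueError("scale must be 'log' or 'raw'")
    if np.var(a) == 0 and np.var(b) == 0:
        p = 1.0 if a.mean() == b.mean() else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
    if p < 0.05:
        verdict = "significant"
    elif 0.05 < p < 0.15:
        verdict = "tendency"
    else:
        verdict = "none"
    return p, verdict


def quantify_and_test(
    table: pd.DataFrame,
    targets: list[str],
    reference: str = "GAPDH",
    control_group: str = "control",
) -> pd.DataFrame:
    """Fold change + verdict per target gene (one row each)."""
    rows = []
    for gene in targets:
        fc = ddct_fold_change(table, gene, reference, control_group)
        p, verdict = group_test(fc["ddct"], fc["group"], control_group)
        case_fc = fc.loc[fc["group"] != control_group, "fold_change"]
        geo_mean = float(2.0 ** np.mean(np.log2(case_fc)))
        rows.append((gene, geo_mean, p, verdict))
    return pd.DataFrame(rows, columns=["gene", "case_fold_change", "p", "verdict"])
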