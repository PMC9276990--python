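"""Regulator–module enrichment, regulator–TF cross-links, and W-scored key genes.

Regulators (miRNAs, lncRNAs, TFs) are mapped onto detected network
modules by an exact hypergeometric over-representation test of their
target sets, after confidence filtering and a minimum-module-coverage
pre-filter. Genes are ranked by the weight score

    W = |log2FC| * (-log10 P) * degree

which combines effect size, significance, and network centrality.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .datatypes import Module, WeightedNetwork
from .enrichment import hypergeom_upper_tail

__all__ = [
    "load_regulator_db",
    "filter_regulator_pairs",
    "regulator_module_enrichment",
    "regulator_tf_network",
    "select_promising_candidates",
    "w_score",
    "rank_key_genes",
    "cross_dataset_validation",
]

log = logging.getLogger(__name__)

REGULATOR_CLASSES = ("miRNA", "lncRNA", "TF")

# Floor applied to P before the log so W stays finite.
P_FLOOR = 1e-300


def load_regulator_db(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a (regulator, class, target, score) table.

    Duplicate (regulator, target) pairs keep the maximum score; class
    labels must be miRNA, lncRNA or TF; scores must lie in [0,1].
    """
    db = table.copy()
    db.columns = ["regulator", "class", "target", "score"]
    bad = ~db["class"].isin(REGULATOR_CLASSES)
    if bad.any():
        raise ValueError(f"invalid regulator classes: {sorted(db.loc[bad, 'class'].unique())}")
    if ((db["score"] < 0) | (db["score"] > 1)).any():
        raise ValueError("scores must lie in [0,1]")
    db = (
        db.sort_values("score", ascending=False, kind="stable")
        .drop_duplicates(["regulator", "target"], keep="first")
        .sort_values(["regulator", "target"], kind="stable")
        .reset_index(drop=True)
    )
    return db


def filter_regulator_pairs(db: pd.DataFrame, min_score: float = 0.5) -> pd.DataFrame:
    """Keep interaction pairs with score strictly above ``min_score``."""
    kept = db[db["score"] > min_score].reset_index(drop=True)
    for cls in REGULATOR_CLASSES:
        log.info(
            "filter_regulator_pairs: %s %d -> %d",
            cls, int((db["class"] == cls).sum()), int((kept["class"] == cls).sum()),
        )
    return kept


def regulator_module_enrichment(
    db: pd.DataFrame,
    modules: list[Module],
    universe,
    min_modules: int = 2,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment of each regulator's targets in each module.

    A regulator is tested only if its targets hit at least ``min_modules``
    distinct modules. For each surviving (regulator, module) pair with
    overlap k >= 1, P = P(X >= k) under Hypergeometric(N = |universe|,
    K = module size, n = |targets ∩ universe|); pairs with P < ``alpha``
    are retained.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    module_sets = {f"M{i+1}": set(m.members) for i, m in enumerate(modules)}
    for mod_id, members in module_sets.items():
        missing = members - universe
        if missing:
            raise ValueError(
                f"module {mod_id} genes absent from universe (e.g. {sorted(missing)[:3]})"
            )
    cols = ["regulator", "class", "module", "k", "module_size",
            "n_targets", "universe_size", "p"]
    if db.empty or not module_sets:
        return pd.DataFrame(columns=cols)

    N = len(universe)
    rows = []
    for (reg, cls), sub in db.groupby(["regulator", "class"], sort=True):
        targets = set(sub["target"]) & universe
        hits = {mid for mid, mem in module_sets.items() if targets & mem}
        if len(hits) < min_modules:
            continue
        n = len(targets)
        for mid in sorted(hits):
            mem = module_sets[mid]
            k = len(targets & mem)
            p = hypergeom_upper_tail(k, len(mem), n, N)
            if p < alpha:
                rows.append((reg, cls, mid, k, len(mem), n, N, p))
    return pd.DataFrame(rows, columns=cols)


def regulator_tf_network(
    db: pd.DataFrame,
    enrichment_results: pd.DataFrame,
    min_score: float = 0.3,
) -> pd.DataFrame:
    """ncRNA–TF cross-links among module-enriched regulators.

    Keeps db rows whose regulator is an ncRNA and whose target is a TF,
    with score strictly above ``min_score``, restricted to regulators and
    TFs that appear in the module-enrichment output; duplicates collapse
    to one row. Also reports per-node partner counts.
    """
    tested = set(enrichment_results["regulator"]) if len(enrichment_results) else set()
    tfs = set(
        enrichment_results.loc[enrichment_results["class"] == "TF", "regulator"]
    ) if len(enrichment_results) else set()
    rows = db[
        db["class"].isin(["miRNA", "lncRNA"])
        & (db["score"] > min_score)
        & db["regulator"].isin(tested)
        & db["target"].isin(tfs)
    ]
    pairs = (
        rows[["regulator", "class", "target", "score"]]
        .sort_values("score", ascending=False, kind="stable")
        .drop_duplicates(["regulator", "target"])
        .sort_values(["regulator", "target"], kind="stable")
        .reset_index(drop=True)
        .rename(columns={"target": "tf"})
    )
    return pairs


def partner_counts(tf_pairs: pd.DataFrame) -> pd.DataFrame:
    """Per-node link counts of the ncRNA–TF network (tabular Sankey)."""
    nc = tf_pairs.groupby("regulator").size().rename("n_partners").reset_index()
    nc["role"] = "ncRNA"
    nc = nc.rename(columns={"regulator": "node"})
    tf = tf_pairs.groupby("tf").size().rename("n_partners").reset_index()
    tf["role"] = "TF"
    tf = tf.rename(columns={"tf": "node"})
    out = pd.concat([nc, tf], ignore_index=True)
    return out.sort_values(["role", "node"], kind="stable").reset_index(drop=True)[
        ["node", "role", "n_partners"]
    ]


def select_promising_candidates(
    results: pd.DataFrame, min_modules_promising: int = 3
) -> list[str]:
    """Regulators linked to >= ``min_modules_promising`` retained modules."""
    if results.empty:
        return []
    counts = results.groupby("regulator")["module"].nunique()
    keep = counts[counts >= min_modules_promising]
    return [reg for reg, _ in sorted(keep.items(), key=lambda kv: (-kv[1], kv[0]))]


def w_score(log2fc: float, p_value: float, degree: int, p_floor: float = P_FLOOR) -> float:
    """W = |log2FC| * (-log10 P) * degree, with P floored before the log."""
    if degree < 0:
        raise ValueError("degree must be >= 0")
    if not (0.0 <= p_value <= 1.0):
        raise ValueError("p_value must lie in [0,1]")
    if p_value == 0 and (p_floor is None or p_floor <= 0):
        raise ValueError("p_value = 0 requires a positive floor")
    p = max(p_value, p_floor)
    return abs(log2fc) * (-np.log10(p)) * degree


def rank_key_genes(
    de_table: pd.DataFrame,
    network: WeightedNetwork,
    top_n: int = 15,
    use_adjusted: bool = False,
) -> pd.DataFrame:
    """Rank genes present in both the DE table and the network by W.

    Degree is taken from the full filtered interaction network. Ties in W
    break by larger |log2FC| then gene id. Returns the top ``top_n`` rows
    with columns (gene, log2fc, p, degree, w).
    """
    p_col = "p_adj" if use_adjusted else "p"
    sub = de_table[de_table["gene"].isin(network.graph.nodes)].copy()
    if sub.empty:
        return pd.DataFrame(columns=["gene", "log2fc", "p", "degree", "w"])
    sub["degree"] = [network.degree(g) for g in sub["gene"]]
    sub["w"] = [
        w_score(lfc, p, d)
        for lfc, p, d in zip(sub["log2fc"], sub[p_col], sub["degree"])
    ]
    sub["abs_lfc"] = sub["log2fc"].abs()
    sub = sub.sort_values(["w", "abs_lfc", "gene"],
                          ascending=[False, False, True], kind="stable")
    out = sub.head(top_n)[["gene", "log2fc", p_col, "degree", "w"]]
    return out.rename(columns={p_col: "p"}).reset_index(drop=True)


def cross_dataset_validation(
    training_calls: pd.DataFrame, validation_de_table: pd.DataFrame
) -> pd.DataFrame:
    """Check training key genes against an independent validation DE table.

    For each training gene: whether it is present in the validation
    table, whether it is called differentially expressed there, and
    whether the direction agrees. Genes missing from the validation table
    are marked not evaluable and excluded from the concordant count.
    """
    val = validation_de_table.set_index("gene")
    rows = []
    for _, r in training_calls.iterrows():
        gene = r["gene"]
        train_call = r.get("call", "up" if r["log2fc"] > 0 else "down")
        if gene not in val.index:
            rows.append((gene, train_call, "absent", "not_evaluable", False))
            continue
        v_call = val.loc[gene].get("call", "none")
        status = "concordant" if (v_call == train_call and v_call != "none") else (
            "discordant" if v_call in ("up", "down") else "not_called"
        )
        rows.append((gene, train_call, v_call, status, status == "concordant"))
    out = pd.DataFrame(
        rows, columns=["gene", "training_call", "validation_call", "status", "concordant"]
    )
    return out
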