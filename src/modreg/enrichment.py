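"""Over-representation analysis and preranked GSEA over GMT collections.

The hypergeometric upper-tail kernel here is also the test used for
regulator–module enrichment, so the whole pipeline shares one exact
implementation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import adjust_bh

__all__ = [
    "GeneSetCollection",
    "hypergeom_upper_tail",
    "ora",
    "gsea",
    "read_gmt",
    "write_gmt",
]

log = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions (GMT semantics)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path) -> GeneSetCollection:
    sets, desc = {}, {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            sets[fields[0]] = [g for g in fields[2:] if g]
            desc[fields[0]] = fields[1]
    return GeneSetCollection(sets=sets, descriptions=desc)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            desc = collection.descriptions.get(name, "na")
            fh.write("\t".join([name, desc, *collection.sets[name]]) + "\n")


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws).

    Exact tail probability; no normal approximation.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v}")
    if K > N or n > N:
        raise ValueError("K and n must not exceed N")
    if k > min(K, n):
        raise ValueError(f"impossible overlap: k={k} > min(K={K}, n={n})")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def ora(
    query_genes,
    collection: GeneSetCollection,
    universe,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query list in each set.

    Query genes outside the universe are dropped (count logged); set
    membership is intersected with the universe before testing. BH
    adjustment runs across all tested sets.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query_genes)
    dropped = query - universe
    if dropped:
        log.info("ora: dropped %d query genes outside the universe", len(dropped))
    query &= universe
    N, n = len(universe), len(query)

    rows = []
    for name in sorted(collection.sets):
        members = set(collection.sets[name]) & universe
        K = len(members)
        k = len(members & query)
        p = hypergeom_upper_tail(k, K, n, N) if K else 1.0
        rows.append((name, k, K, n, N, p))
    table = pd.DataFrame(rows, columns=["set_name", "k", "K", "n", "N", "p"])
    table["p_adj"] = adjust_bh(table["p"]) if len(table) else []
    table["significant"] = table["p_adj"] < alpha
    return table.sort_values(["p_adj", "p", "set_name"], kind="stable").reset_index(drop=True)


def _es(ranked_abs_scores: np.ndarray, hit_mask: np.ndarray, weight: float) -> float:
    """Weighted Kolmogorov–Smirnov enrichment score for one set.

    Hits increment the running sum proportionally to |score|^weight
    (normalized); misses decrement uniformly; ES is the extremum of the
    running sum by absolute value.
    """
    n = len(hit_mask)
    n_hit = int(hit_mask.sum())
    if n_hit == 0 or n_hit == n:
        raise ValueError("set must hit a strict subset of the ranking")
    w = np.abs(ranked_abs_scores) ** weight
    hit_w = np.where(hit_mask, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all hit scores zero: fall back to uniform increments
        hit_w = hit_mask.astype(float)
        denom = float(n_hit)
    steps = hit_w / denom - (~hit_mask) / float(n - n_hit)
    running = np.cumsum(steps)
    return float(running[np.argmax(np.abs(running))])


def gsea(
    ranked_genes: pd.Series,
    collection: GeneSetCollection,
    weight_exponent: float = 1.0,
    n_permutations: int = 1000,
    seed: int = 0,
    min_size: int = 2,
    max_size: int = 500,
    alpha: float = 0.05,
    min_abs_nes: float = 1.0,
) -> pd.DataFrame:
    """Preranked GSEA with a gene-permutation null.

    ``ranked_genes`` maps gene id -> ranking score; genes are ordered by
    decreasing score (ties broken by original order). For each set the
    null is built by drawing random same-sized gene sets; NES divides ES
    by the mean |permutation ES| of the same sign, and the empirical P is
    computed within the same-sign permutations. A set is flagged
    significant when \\|NES\\| >= ``min_abs_nes`` and BH-adjusted P <
    ``alpha``.
    """
    scores = ranked_genes.to_numpy(dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("ranking scores must be finite")
    order = np.argsort(-scores, kind="stable")
    genes = ranked_genes.index.to_numpy()[order]
    scores = scores[order]
    pos = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    rng = np.random.default_rng(seed)

    rows = []
    for name in sorted(collection.sets):
        members = [g for g in set(collection.sets[name]) if g in pos]
        size = len(members)
        if size < min_size or size > max_size or size == n:
            log.info("gsea: skipping set %s (effective size %d)", name, size)
            continue
        hit = np.zeros(n, dtype=bool)
        hit[[pos[g] for g in members]] = True
        es = _es(scores, hit, weight_exponent)

        perm_es = np.empty(n_permutations)
        for b in range(n_permutations):
            ph = np.zeros(n, dtype=bool)
            ph[rng.choice(n, size=size, replace=False)] = True
            perm_es[b] = _es(scores, ph, weight_exponent)
        same = perm_es[perm_es >= 0] if es >= 0 else perm_es[perm_es < 0]
        if same.size == 0:
            nes, p = np.nan, 1.0 / (n_permutations + 1)
        else:
            nes = es / float(np.abs(same).mean())
            p = (1.0 + float((np.abs(same) >= abs(es)).sum())) / (1.0 + same.size)
        rows.append((name, size, es, nes, p))

    table = pd.DataFrame(rows, columns=["set_name", "size", "es", "nes", "p"])
    table["p_adj"] = adjust_bh(table["p"]) if len(table) else []
    table["significant"] = (table["nes"].abs() >= min_abs_nes) & (table["p_adj"] < alpha)
    return table.sort_values(["p_adj", "p", "set_name"], kind="stable").reset_index(drop=True)
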