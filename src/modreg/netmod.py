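"""Score-filtered interaction networks and cohesiveness-based modules.

Overlapping functional modules are grown greedily from seed nodes so as
to locally maximize cohesiveness

    f(V) = w_in(V) / (w_in(V) + w_bound(V) + penalty * |V|)

where w_in is the total weight of edges inside V and w_bound the total
weight of edges crossing its boundary. Highly overlapping candidates are
merged by the match score |A∩B|^2/(|A||B|), each surviving module gets a
one-sided rank-test P that its members' internal edge weight exceeds
their boundary weight, and modules smaller than the size floor or not
significant are discarded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import Module, WeightedNetwork

__all__ = [
    "ModuleDetectionConfig",
    "build_network",
    "cohesiveness",
    "grow_module",
    "merge_overlapping",
    "module_significance",
    "detect_modules",
]

log = logging.getLogger(__name__)

# STRING-style confidence bands: "medium confidence" = 0.400.
MEDIUM_CONFIDENCE = 0.400


@dataclass(frozen=True)
class ModuleDetectionConfig:
    """Knobs of the greedy module detector.

    penalty: per-member denominator penalty discouraging sprawling,
    weakly attached modules (default 2, standard for this algorithm
    family). overlap_threshold: match-score level at or above which two
    candidate modules merge. min_size / max_p: retention filters.
    """

    penalty: float = 2.0
    overlap_threshold: float = 0.8
    min_edge_score: float = MEDIUM_CONFIDENCE
    min_size: int = 5
    max_p: float = 0.05

    def __post_init__(self) -> None:
        if self.penalty < 0:
            raise ValueError("penalty must be non-negative")
        if not (0.0 <= self.overlap_threshold <= 1.0):
            raise ValueError("overlap_threshold must be in [0,1]")
        if not (0.0 <= self.min_edge_score <= 1.0):
            raise ValueError("min_edge_score must be in [0,1]")


def build_network(edge_table: pd.DataFrame, min_edge_score: float = MEDIUM_CONFIDENCE) -> WeightedNetwork:
    """Filter an edge list by confidence and drop disconnected nodes.

    Expects columns (node_a, node_b, score) or the first three columns in
    that order. Malformed rows (self-loops, non-numeric or out-of-range
    scores) are logged and skipped; duplicate edges keep the maximum
    score. Edges below ``min_edge_score`` are removed, and with them any
    node left without a neighbor.
    """
    cols = list(edge_table.columns[:3])
    g = nx.Graph()
    bad = 0
    for a, b, s in edge_table[cols].itertuples(index=False):
        try:
            s = float(s)
        except (TypeError, ValueError):
            bad += 1
            continue
        if not (0.0 <= s <= 1.0) or pd.isna(s) or a == b or pd.isna(a) or pd.isna(b):
            bad += 1
            continue
        if s < min_edge_score:
            continue
        a, b = str(a), str(b)
        if g.has_edge(a, b):
            g[a][b]["weight"] = max(g[a][b]["weight"], s)
        else:
            g.add_edge(a, b, weight=s)
    if bad:
        log.warning("build_network: skipped %d malformed rows", bad)
    if bad == len(edge_table) and len(edge_table) > 0:
        raise ValueError("every edge row was malformed")
    return WeightedNetwork(graph=g)


def _in_bound_weights(graph: nx.Graph, members: frozenset[str]) -> tuple[float, float]:
    w_in = w_bound = 0.0
    for v in members:
        for _, nbr, d in graph.edges(v, data=True):
            if nbr in members:
                w_in += d["weight"]  # counted from both endpoints; halved below
            else:
                w_bound += d["weight"]
    return w_in / 2.0, w_bound


def cohesiveness(network: WeightedNetwork, node_set, penalty: float) -> float:
    """f(V) = w_in / (w_in + w_bound + penalty*|V|); 0 when edgeless."""
    members = frozenset(node_set)
    unknown = [v for v in members if v not in network.graph]
    if unknown:
        raise KeyError(f"nodes not in network: {sorted(unknown)[:5]}")
    w_in, w_bound = _in_bound_weights(network.graph, members)
    denom = w_in + w_bound + penalty * len(members)
    return 0.0 if denom == 0 else w_in / denom


def grow_module(network: WeightedNetwork, seed_node: str, config: ModuleDetectionConfig) -> Module:
    """Greedy local search from a single seed.

    At each step the single boundary-node addition or member removal with
    the largest strict cohesiveness gain is applied; additions are
    preferred over removals on equal gain and ties within a move type go
    to the lexicographically smaller node id. Stops at a local maximum.
    """
    g = network.graph
    if seed_node not in g:
        raise KeyError(f"seed node {seed_node!r} not in network")
    members = {seed_node}
    current = cohesiveness(network, members, config.penalty)
    while True:
        # candidates scanned in lexicographic order with strict-improvement
        # replacement, so equal gains keep the earlier (smaller-id) move and
        # additions are preferred over removals on exact ties
        best_gain, best_move = 0.0, None  # (kind, node); kind 0=add, 1=remove
        boundary = sorted({u for v in members for u in g[v]} - members)
        for u in boundary:
            gain = cohesiveness(network, members | {u}, config.penalty) - current
            if gain > best_gain + 1e-12:
                best_gain, best_move = gain, (0, u)
        if len(members) > 1:
            for u in sorted(members):
                gain = cohesiveness(network, members - {u}, config.penalty) - current
                if gain > best_gain + 1e-12:
                    best_gain, best_move = gain, (1, u)
        if best_move is None:
            break
        kind, node = best_move
        if kind == 0:
            members.add(node)
        else:
            members.discard(node)
        current = cohesiveness(network, members, config.penalty)
    return Module(members=frozenset(members), cohesiveness=current)


def match_score(a: frozenset[str], b: frozenset[str]) -> float:
    """Overlap score |A∩B|^2 / (|A|·|B|)."""
    inter = len(a & b)
    return (inter * inter) / (len(a) * len(b))


def merge_overlapping(
    modules: list[Module], network: WeightedNetwork, config: ModuleDetectionConfig
) -> list[Module]:
    """Union any module pair with match score >= threshold, to fixpoint.

    Processing order is descending cohesiveness then member tuple, so
    merging is deterministic.
    """
    mods = sorted(modules, key=lambda m: (-m.cohesiveness, m.sorted_members()))
    changed = True
    while changed:
        changed = False
        out: list[Module] = []
        while mods:
            m = mods.pop(0)
            for i, other in enumerate(mods):
                if match_score(m.members, other.members) >= config.overlap_threshold:
                    union = m.members | other.members
                    merged = Module(
                        members=union,
                        cohesiveness=cohesiveness(network, union, config.penalty),
                    )
                    mods.pop(i)
                    mods.append(merged)
                    mods.sort(key=lambda x: (-x.cohesiveness, x.sorted_members()))
                    changed = True
                    break
            else:
                out.append(m)
        mods = out
        if changed:
            mods.sort(key=lambda x: (-x.cohesiveness, x.sorted_members()))
    # drop exact duplicates
    seen: set[frozenset[str]] = set()
    uniq = []
    for m in mods:
        if m.members not in seen:
            seen.add(m.members)
            uniq.append(m)
    return uniq


def module_significance(network: WeightedNetwork, module: Module) -> tuple[float, bool]:
    """One-sided rank test that members are internally dominated.

    Compares, across member vertices, each vertex's internal edge weight
    against its boundary edge weight with a one-sided Mann–Whitney test
    (exact enumeration up to 10 members, normal approximation beyond).
    Returns (p_value, degenerate) where degenerate marks the all-tied
    case, reported as P = 0.5.
    """
    members = module.members
    if len(members) < 2:
        raise ValueError("module needs >= 2 members")
    g = network.graph
    in_w, bound_w = [], []
    for v in sorted(members):
        wi = sum(d["weight"] for _, u, d in g.edges(v, data=True) if u in members)
        wb = sum(d["weight"] for _, u, d in g.edges(v, data=True) if u not in members)
        in_w.append(wi)
        bound_w.append(wb)
    in_w, bound_w = np.asarray(in_w), np.asarray(bound_w)
    if np.allclose(in_w, bound_w):
        return 0.5, True
    if len(members) <= 10:
        return _exact_mwu_greater(in_w, bound_w), False
    res = stats.mannwhitneyu(in_w, bound_w, alternative="greater", method="asymptotic")
    return float(res.pvalue), False


def _exact_mwu_greater(a: np.ndarray, b: np.ndarray) -> float:
    """Exact one-sided Mann–Whitney P by full split enumeration.

    Ties (common here: several members share a zero boundary weight) are
    handled through midranks, so the null is the permutation distribution
    of the tie-adjusted U statistic.
    """
    import itertools

    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    m, total_n = len(a), len(pooled)
    u_obs = ranks[:m].sum()
    ge = total = 0
    for comb in itertools.combinations(range(total_n), m):
        total += 1
        if ranks[list(comb)].sum() >= u_obs - 1e-9:
            ge += 1
    return ge / total


def detect_modules(
    network: WeightedNetwork, config: ModuleDetectionConfig | None = None
) -> list[Module]:
    """Grow, merge, score, and filter modules over the whole network.

    Seeds are taken in descending weighted-degree order (ties by node
    id); a node already inside a grown candidate is not reseeded.
    Retained modules have size >= ``config.min_size`` and P <
    ``config.max_p``, sorted by cohesiveness descending.
    """
    if config is None:
        config = ModuleDetectionConfig()
    g = network.graph
    if g.number_of_nodes() == 0:
        return []
    seeds = sorted(g.nodes, key=lambda v: (-g.degree(v, weight="weight"), v))
    covered: set[str] = set()
    candidates: list[Module] = []
    for s in seeds:
        if s in covered:
            continue
        m = grow_module(network, s, config)
        if m.size >= 2:
            candidates.append(m)
            covered |= m.members
    merged = merge_overlapping(candidates, network, config)
    retained = []
    for m in merged:
        if m.size < config.min_size:
            continue
        p, degenerate = module_significance(network, m)
        if p < config.max_p:
            retained.append(Module(m.members, m.cohesiveness, p, degenerate))
    retained.sort(key=lambda m: (-m.cohesiveness, m.sorted_members()))
    return retained


def modules_to_frame(modules: list[Module]) -> pd.DataFrame:
    rows = [
        (f"M{i+1}", m.size, m.cohesiveness, m.p_value, ";".join(m.sorted_members()))
        for i, m in enumerate(modules)
    ]
    return pd.DataFrame(rows, columns=["module", "size", "cohesiveness", "p_value", "members"])
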