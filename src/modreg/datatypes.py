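"""Core in-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd


@dataclass
class ExpressionData:
    """Normalized log2 expression (rows = probes or genes, cols = samples).

    ``groups`` maps each sample to one of exactly two levels; ``case``
    names the level whose mean enters log2 fold changes with a plus sign.
    """

    values: pd.DataFrame
    groups: pd.Series
    case: str

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.groups.index):
            self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            raise ValueError("every sample column needs a group label")
        levels = self.groups.unique()
        if len(levels) != 2:
            raise ValueError(f"expected exactly two group levels, got {list(levels)}")
        if self.case not in levels:
            raise ValueError(f"case level {self.case!r} not among groups {list(levels)}")
        counts = self.groups.value_counts()
        if counts.min() < 2:
            raise ValueError("both groups need >= 2 samples")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression matrix contains non-finite values")

    @property
    def control(self) -> str:
        return next(g for g in self.groups.unique() if g != self.case)

    def case_matrix(self) -> pd.DataFrame:
        return self.values.loc[:, self.groups == self.case]

    def control_matrix(self) -> pd.DataFrame:
        return self.values.loc[:, self.groups == self.control]


@dataclass
class WeightedNetwork:
    """Undirected interaction graph with edge confidence scores in [0,1]."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self, node: str) -> int:
        return int(self.graph.degree(node))

    def edge_table(self) -> pd.DataFrame:
        rows = sorted(
            (min(a, b), max(a, b), float(d["weight"]))
            for a, b, d in self.graph.edges(data=True)
        )
        return pd.DataFrame(rows, columns=["node_a", "node_b", "score"])


@dataclass
class Module:
    """Candidate or retained functional module."""

    members: frozenset[str]
    cohesiveness: float
    p_value: float = float("nan")
    degenerate: bool = False

    @property
    def size(self) -> int:
        return len(self.members)

    def sorted_members(self) -> list[str]:
        return sorted(self.members)
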