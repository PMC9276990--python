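import sys
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from modreg.datatypes import ExpressionData, WeightedNetwork


@pytest.fixture
def small_expression() -> ExpressionData:
    """6 genes x 8 samples, fixed values, no planted signal."""
    rng = np.random.default_rng(42)
    genes = [f"g{i}" for i in range(6)]
    samples = [f"case_{i}" for i in range(4)] + [f"ctrl_{i}" for i in range(4)]
    values = pd.DataFrame(
        rng.normal(8, 1, size=(6, 8)), index=genes, columns=samples
    )
    groups = pd.Series(["case"] * 4 + ["control"] * 4, index=samples)
    return ExpressionData(values=values, groups=groups, case="case")


@pytest.fixture
def triangle_network() -> WeightedNetwork:
    g = nx.Graph()
    g.add_weighted_edges_from([("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0)])
    return WeightedNetwork(graph=g)


@pytest.fixture
def triangle_with_pendant() -> WeightedNetwork:
    g = nx.Graph()
    g.add_weighted_edges_from(
        [("a", "b", 1.0), ("b", "c", 1.0), ("a", "c", 1.0), ("c", "d", 1.0)]
    )
    return WeightedNetwork(graph=g)
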