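"""Synthetic data with planted, recorded ground truth.

Every structure the downstream analysis assumes — group shifts in a log2
expression matrix, cohesive interaction-network modules, module-specific
regulators, and qPCR fold changes — is planted here with known parameters
and recorded in a :class:`GroundTruth` object, so each stage of the
pipeline can be checked against what was actually put in.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import ExpressionData, WeightedNetwork

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_expression",
    "simulate_network",
    "simulate_regulator_db",
    "simulate_ct_table",
]

# Plausible log2 microarray intensity range for per-gene baselines.
_BASELINE_RANGE = (4.0, 12.0)

# Stream offsets so each generator draws from its own deterministic
# substream of the config seed; adding a stage never perturbs another.
_STREAM_EXPRESSION = 1
_STREAM_NETWORK = 2
_STREAM_REGULATORS = 3


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the planted-structure generator.

    Defaults emulate the shape of a two-group aortic-valve microarray
    study: two groups of 5 samples, 2000 genes, 10% of genes shifted by
    |log2FC| = 2 with residual noise SD 0.5 log2 units, three planted
    8-node network modules with dense internal wiring, and one planted
    regulator per class per module.
    """

    n_genes: int = 2000
    n_per_group: int = 5
    de_fraction: float = 0.10
    lfc_magnitude: float = 2.0
    noise_sd: float = 0.5
    module_sizes: tuple[int, ...] = (8, 8, 8)
    p_within: float = 0.9
    p_between: float = 0.02
    edge_score_range: tuple[float, float] = (0.4, 1.0)
    n_regulators_per_class: int = 1
    n_background_regulators: int = 1
    modules_per_regulator: int = 3
    target_rate_in_module: float = 0.8
    background_target_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("de_fraction", "p_within", "p_between",
                     "target_rate_in_module", "background_target_rate"):
            v = getattr(self, name)
            if not (math.isfinite(v) and 0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a finite probability, got {v}")
        for name in ("lfc_magnitude", "noise_sd"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        lo, hi = self.edge_score_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("edge_score_range must be within [0,1] with lo <= hi")
        if self.n_genes < 10:
            raise ValueError("n_genes must be >= 10")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if any(m < 2 for m in self.module_sizes):
            raise ValueError("module sizes must be >= 2")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("sum of module sizes exceeds n_genes")


@dataclass
class GroundTruth:
    """Record of everything that was planted."""

    de_up: dict[str, float] = field(default_factory=dict)
    de_down: dict[str, float] = field(default_factory=dict)
    module_membership: dict[str, str] = field(default_factory=dict)
    enriched_pairs: set[tuple[str, str]] = field(default_factory=set)

    @property
    def de_genes(self) -> set[str]:
        return set(self.de_up) | set(self.de_down)

    def modules(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for gene, mod in self.module_membership.items():
            out.setdefault(mod, set()).add(gene)
        return out

    def to_json(self) -> str:
        payload = {
            "de_up": self.de_up,
            "de_down": self.de_down,
            "module_membership": self.module_membership,
            "enriched_pairs": sorted(list(p) for p in self.enriched_pairs),
        }
        return json.dumps(payload, sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            de_up=d["de_up"],
            de_down=d["de_down"],
            module_membership=d["module_membership"],
            enriched_pairs={tuple(p) for p in d["enriched_pairs"]},
        )


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def simulate_expression(config: SimulationConfig) -> tuple[ExpressionData, GroundTruth]:
    """Normalized log2 expression matrix with planted two-group shifts.

    Each gene gets a baseline drawn once from a uniform log2-intensity
    range; planted DE genes add a signed ``lfc_magnitude`` to the case
    group; every entry then receives independent Gaussian noise of SD
    ``noise_sd``. Half of the planted genes (rounded up) shift up.
    """
    rng = np.random.default_rng([config.seed, _STREAM_EXPRESSION])
    genes = _gene_ids(config.n_genes)
    n = config.n_per_group
    samples = [f"case_{i+1}" for i in range(n)] + [f"ctrl_{i+1}" for i in range(n)]
    groups = pd.Series(["case"] * n + ["control"] * n, index=samples, name="group")

    baseline = rng.uniform(*_BASELINE_RANGE, size=config.n_genes)
    n_de = int(round(config.de_fraction * config.n_genes))
    de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
    n_up = (n_de + 1) // 2
    shifts = np.zeros(config.n_genes)
    shifts[de_idx[:n_up]] = config.lfc_magnitude
    shifts[de_idx[n_up:]] = -config.lfc_magnitude

    mat = np.tile(baseline[:, None], (1, 2 * n))
    mat[:, :n] += shifts[:, None]
    mat += rng.normal(0.0, config.noise_sd, size=mat.shape)

    truth = GroundTruth(
        de_up={genes[i]: float(shifts[i]) for i in de_idx[:n_up]},
        de_down={genes[i]: float(shifts[i]) for i in de_idx[n_up:]},
    )
    values = pd.DataFrame(mat, index=pd.Index(genes, name="gene"), columns=samples)
    return ExpressionData(values=values, groups=groups, case="case"), truth


def _module_nodes(config: SimulationConfig, truth: GroundTruth) -> list[list[str]]:
    """Assign planted-module member genes, preferring planted DE genes.

    The downstream network is built over differentially expressed genes
    only, so modules must live inside the DE set for end-to-end recovery;
    when too few DE genes were planted, fall back to the first gene ids.
    """
    need = sum(config.module_sizes)
    pool = sorted(truth.de_up) + sorted(truth.de_down)
    if len(pool) < need:
        pool = _gene_ids(config.n_genes)
    out, k = [], 0
    for size in config.module_sizes:
        out.append(pool[k:k + size])
        k += size
    return out


def simulate_network(
    config: SimulationConfig, truth: GroundTruth | None = None
) -> tuple[WeightedNetwork, GroundTruth]:
    """Planted-partition weighted interaction network.

    Within-module node pairs get an edge with probability ``p_within``,
    cross-module pairs with ``p_between``; edge confidence scores are
    uniform on ``edge_score_range``, independent of membership.
    """
    if truth is None:
        truth = GroundTruth()
    rng = np.random.default_rng([config.seed, _STREAM_NETWORK])
    blocks = _module_nodes(config, truth)
    for j, block in enumerate(blocks, start=1):
        for gene in block:
            truth.module_membership[gene] = f"M{j}"

    g = nx.Graph()
    nodes = [v for block in blocks for v in block]
    membership = {v: i for i, block in enumerate(blocks) for v in block}
    lo, hi = config.edge_score_range
    for a_i in range(len(nodes)):
        for b_i in range(a_i + 1, len(nodes)):
            a, b = nodes[a_i], nodes[b_i]
            p = config.p_within if membership[a] == membership[b] else config.p_between
            if rng.random() < p:
                g.add_edge(a, b, weight=float(rng.uniform(lo, hi)))
    return WeightedNetwork(graph=g), truth


def simulate_regulator_db(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[pd.DataFrame, GroundTruth]:
    """Scored directed regulator→target table with planted enrichments.

    For each regulator class (miRNA, lncRNA, TF), ``n_regulators_per_class``
    planted regulators are each assigned ``modules_per_regulator`` modules
    round-robin (clipped to the number of planted modules); a planted
    regulator hits genes of its assigned modules at
    ``target_rate_in_module`` and all other genes at
    ``background_target_rate``. Background regulators hit every gene at
    the background rate only. Pairs with the two rates equal are never
    recorded as enriched (exchangeable null).
    """
    modules = truth.modules()
    if not modules:
        raise ValueError("ground truth contains no module membership")
    rng = np.random.default_rng([config.seed, _STREAM_REGULATORS])
    universe = _gene_ids(config.n_genes)
    lo, hi = config.edge_score_range
    module_ids = sorted(modules)
    n_assigned = max(1, min(config.modules_per_regulator, len(module_ids)))
    rows: list[tuple[str, str, str, float]] = []

    planted = config.target_rate_in_module != config.background_target_rate
    for cls, prefix in (("miRNA", "miR"), ("lncRNA", "lnc"), ("TF", "TF")):
        for r in range(config.n_regulators_per_class):
            reg = f"{prefix}-{r+1:02d}"
            assigned = [module_ids[(r + i) % len(module_ids)] for i in range(n_assigned)]
            members = set().union(*(modules[m] for m in assigned))
            for gene in universe:
                rate = (config.target_rate_in_module if gene in members
                        else config.background_target_rate)
                if rng.random() < rate:
                    rows.append((reg, cls, gene, float(rng.uniform(lo, hi))))
            if planted:
                truth.enriched_pairs.update((reg, m) for m in assigned)
        for r in range(config.n_background_regulators):
            reg = f"{prefix}-bg-{r+1:02d}"
            for gene in universe:
                if rng.random() < config.background_target_rate:
                    rows.append((reg, cls, gene, float(rng.uniform(lo, hi))))

    # ncRNA -> TF cross-links (each planted ncRNA hits each planted TF
    # with probability 1/2), emulating the regulator-on-regulator rows of
    # interaction databases
    tf_ids = [f"TF-{r+1:02d}" for r in range(config.n_regulators_per_class)]
    for cls, prefix in (("miRNA", "miR"), ("lncRNA", "lnc")):
        for r in range(config.n_regulators_per_class):
            reg = f"{prefix}-{r+1:02d}"
            for tf in tf_ids:
                if rng.random() < 0.5:
                    rows.append((reg, cls, tf, float(rng.uniform(lo, hi))))

    db = pd.DataFrame(rows, columns=["regulator", "class", "target", "score"])
    return db, truth


def simulate_ct_table(
    n_case: int,
    n_control: int,
    true_fold_change: float,
    ct_noise_sd: float,
    seed: int,
    target: str = "TARGET",
    reference: str = "GAPDH",
) -> pd.DataFrame:
    """qPCR Ct table (long format) with a planted case fold change.

    Case-group target Ct is lowered by log2(fold change) relative to the
    control group so that the expected relative quantity 2^-ddCt in cases
    equals ``true_fold_change``. Gaussian noise of SD ``ct_noise_sd``
    cycles is added to every Ct measurement.
    """
    if n_case < 2 or n_control < 2:
        raise ValueError("both groups need >= 2 samples")
    if not (math.isfinite(true_fold_change) and true_fold_change > 0):
        raise ValueError("true_fold_change must be positive and finite")
    rng = np.random.default_rng(seed)
    ref_ct, target_ct_control = 18.0, 25.0
    rows = []
    for i in range(n_case + n_control):
        is_case = i < n_case
        group = "case" if is_case else "control"
        sample = f"{group}_{i+1 if is_case else i - n_case + 1}"
        t_ct = target_ct_control - (math.log2(true_fold_change) if is_case else 0.0)
        rows.append((sample, group, target,
                     t_ct + float(rng.normal(0, ct_noise_sd))))
        rows.append((sample, group, reference,
                     ref_ct + float(rng.normal(0, ct_noise_sd))))
    return pd.DataFrame(rows, columns=["sample", "group", "gene", "ct"])


def config_to_json(config: SimulationConfig) -> str:
    return json.dumps(dataclasses.asdict(config), sort_keys=True, indent=2)
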