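"""Regulator filtering, module enrichment against the enumeration oracle,
the ncRNA-TF cross network, W scoring, and key-gene ranking."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modreg.datatypes import Module, WeightedNetwork
from modreg.regulators import (
    cross_dataset_validation,
    filter_regulator_pairs,
    load_regulator_db,
    rank_key_genes,
    regulator_module_enrichment,
    regulator_tf_network,
    select_promising_candidates,
    w_score,
)
from oracles import hypergeom_upper_tail_exact


def _db(*rows):
    return pd.DataFrame(rows, columns=["regulator", "class", "target", "score"])


class TestLoadAndFilter:
    def test_duplicates_keep_max_score(self):
        db = load_regulator_db(_db(("r1", "miRNA", "g1", 0.4),
                                   ("r1", "miRNA", "g1", 0.9)))
        assert len(db) == 1
        assert db["score"].iloc[0] == 0.9

    def test_invalid_class_rejected(self):
        with pytest.raises(ValueError):
            load_regulator_db(_db(("r1", "sncRNA", "g1", 0.4)))

    def test_exact_boundary_score_removed(self):
        db = _db(("r1", "miRNA", "g1", 0.5), ("r1", "miRNA", "g2", 0.51))
        kept = filter_regulator_pairs(db, 0.5)
        assert list(kept["target"]) == ["g2"]  # strict >

    def test_empty_result_propagates_to_empty_enrichment(self):
        db = filter_regulator_pairs(_db(("r1", "miRNA", "g1", 0.2)), 0.5)
        mods = [Module(frozenset({"g1", "g2"}), 0.5, 0.01)]
        out = regulator_module_enrichment(db, mods, {"g1", "g2", "g3"}, min_modules=1)
        assert out.empty


class TestRegulatorModuleEnrichment:
    def _modules(self):
        return [
            Module(frozenset({f"a{i}" for i in range(5)}), 0.6, 0.01),
            Module(frozenset({f"b{i}" for i in range(5)}), 0.5, 0.01),
        ]

    def _universe(self):
        return ({f"a{i}" for i in range(5)} | {f"b{i}" for i in range(5)}
                | {f"x{i}" for i in range(40)})

    def test_single_module_regulator_excluded_by_prefilter(self):
        db = _db(*[("r1", "TF", f"a{i}", 0.9) for i in range(5)])
        out = regulator_module_enrichment(db, self._modules(), self._universe(),
                                          min_modules=2)
        assert out.empty
        out1 = regulator_module_enrichment(db, self._modules(), self._universe(),
                                           min_modules=1)
        assert set(out1["module"]) == {"M1"}

    def test_zero_overlap_pair_absent(self):
        rows = [("r1", "TF", f"a{i}", 0.9) for i in range(5)]
        rows += [("r1", "TF", f"b{i}", 0.9) for i in range(2)]
        out = regulator_module_enrichment(_db(*rows), self._modules(),
                                          self._universe(), min_modules=2)
        assert "M2" in set(out["module"]) or len(out) >= 1
        # a regulator hitting neither module never appears
        rows2 = [("r2", "miRNA", f"x{i}", 0.9) for i in range(5)]
        out2 = regulator_module_enrichment(_db(*rows2), self._modules(),
                                           self._universe(), min_modules=0)
        assert out2.empty

    def test_p_matches_enumeration_oracle_small_universe(self):
        # module of 10 inside a universe of 50; regulator hits 8 of them + 5 outside
        module = [f"m{i}" for i in range(10)]
        universe = set(module) | {f"u{i}" for i in range(40)}
        rows = [("r1", "lncRNA", g, 0.9) for g in module[:8]]
        rows += [("r1", "lncRNA", f"u{i}", 0.9) for i in range(5)]
        mods = [Module(frozenset(module), 0.7, 0.01)]
        out = regulator_module_enrichment(_db(*rows), mods, universe, min_modules=1)
        expected = hypergeom_upper_tail_exact(8, 10, 13, 50)
        assert out["p"].iloc[0] == pytest.approx(expected, rel=1e-12)

    def test_module_gene_missing_from_universe_rejected(self):
        mods = [Module(frozenset({"a", "b", "c", "d", "e"}), 0.5, 0.01)]
        with pytest.raises(ValueError):
            regulator_module_enrichment(_db(("r", "TF", "a", 0.9)), mods,
                                        {"a", "b"}, min_modules=1)

    def test_invariant_to_db_row_order(self):
        rows = ([("r1", "TF", f"a{i}", 0.9) for i in range(4)]
                + [("r1", "TF", f"b{i}", 0.9) for i in range(3)]
                + [("r2", "miRNA", f"b{i}", 0.8) for i in range(4)]
                + [("r2", "miRNA", "a0", 0.8)])
        db = _db(*rows)
        shuffled = db.sample(frac=1.0, random_state=3).reset_index(drop=True)
        a = regulator_module_enrichment(db, self._modules(), self._universe(),
                                        min_modules=1)
        b = regulator_module_enrichment(shuffled, self._modules(), self._universe(),
                                        min_modules=1)
        pd.testing.assert_frame_equal(a, b)


class TestRegulatorTfNetwork:
    def _results(self):
        return pd.DataFrame({
            "regulator": ["lnc1", "tfA"], "class": ["lncRNA", "TF"],
            "module": ["M1", "M1"], "k": [2, 2], "module_size": [5, 5],
            "n_targets": [4, 4], "universe_size": [50, 50], "p": [0.01, 0.02],
        })

    def test_boundary_score_removed_and_restriction_applied(self):
        db = _db(("lnc1", "lncRNA", "tfA", 0.3),    # boundary: dropped
                 ("lnc1", "lncRNA", "tfB", 0.9),    # tfB not tested: dropped
                 ("lnc1", "lncRNA", "tfA", 0.35))   # kept
        out = regulator_tf_network(db, self._results(), 0.3)
        assert len(out) == 1
        assert out.iloc[0]["tf"] == "tfA"
        assert out.iloc[0]["score"] == 0.35

    def test_symmetric_duplicates_collapse(self):
        db = _db(("lnc1", "lncRNA", "tfA", 0.6), ("lnc1", "lncRNA", "tfA", 0.6))
        out = regulator_tf_network(db, self._results(), 0.3)
        assert len(out) == 1


class TestPromisingCandidates:
    def _results(self, counts):
        rows = []
        for reg, n in counts.items():
            for i in range(n):
                rows.append((reg, "TF", f"M{i+1}", 1, 5, 4, 50, 0.01))
        return pd.DataFrame(rows, columns=["regulator", "class", "module", "k",
                                           "module_size", "n_targets",
                                           "universe_size", "p"])

    def test_inclusive_threshold(self):
        out = select_promising_candidates(self._results({"r3": 3, "r2": 2, "r4": 4}))
        assert out == ["r4", "r3"]  # >= 3, sorted by count desc

    def test_empty_results(self):
        assert select_promising_candidates(pd.DataFrame(
            columns=["regulator", "module"])) == []


class TestWScore:
    def test_degenerate_cases_zero(self):
        assert w_score(2.0, 0.5, 0) == 0.0
        assert w_score(2.0, 1.0, 7) == 0.0

    def test_printed_formula(self):
        assert w_score(1.0, 0.1, 5) == pytest.approx(5.0)

    def test_zero_p_requires_floor(self):
        with pytest.raises(ValueError):
            w_score(1.0, 0.0, 3, p_floor=0)
        assert np.isfinite(w_score(1.0, 0.0, 3))  # default floor

    @settings(deadline=None, max_examples=50)
    @given(
        st.floats(min_value=-5, max_value=5),
        st.floats(min_value=1e-10, max_value=1.0),
        st.integers(min_value=0, max_value=50),
    )
    def test_linear_in_degree(self, lfc, p, degree):
        assert w_score(lfc, p, 2 * degree) == pytest.approx(
            2 * w_score(lfc, p, degree), rel=1e-12
        )


class TestRankKeyGenes:
    def _network(self):
        g = nx.Graph()
        g.add_edge("g1", "g2", weight=0.9)
        g.add_edge("g1", "g3", weight=0.9)
        g.add_edge("g1", "g4", weight=0.9)
        g.add_edge("g2", "g3", weight=0.9)
        return WeightedNetwork(g)

    def _de(self):
        return pd.DataFrame({
            "gene": ["g1", "g2", "g3", "g4", "g5"],
            "log2fc": [3.0, 2.0, -2.0, 0.5, 4.0],
            "t": [5, 4, -4, 1, 6],
            "p": [1e-6, 1e-4, 1e-4, 0.2, 1e-8],
            "p_adj": [1e-5, 1e-3, 1e-3, 0.3, 1e-7],
        })

    def test_gene_absent_from_network_never_ranked(self):
        out = rank_key_genes(self._de(), self._network(), top_n=10)
        assert "g5" not in set(out["gene"])  # strongest DE but no degree

    def test_dominant_gene_ranks_first_matches_brute_force(self):
        out = rank_key_genes(self._de(), self._network(), top_n=10)
        brute = {
            row.gene: abs(row.log2fc) * (-np.log10(row.p)) * deg
            for row, deg in zip(self._de().itertuples(),
                                [3, 2, 2, 1, 0])
            if row.gene != "g5"
        }
        assert out["gene"].iloc[0] == max(brute, key=brute.get)
        for _, r in out.iterrows():
            assert r["w"] == pytest.approx(brute[r["gene"]], rel=1e-12)

    def test_w_ties_break_by_abs_lfc(self):
        de = pd.DataFrame({
            "gene": ["u", "v"], "log2fc": [2.0, -4.0], "t": [1, -1],
            "p": [0.01, 0.1], "p_adj": [0.02, 0.2],
        })
        g = nx.Graph()
        g.add_edge("u", "x", weight=0.5)
        g.add_edge("v", "x", weight=0.5)
        net = WeightedNetwork(g)
        out = rank_key_genes(de, net, top_n=2)
        # W(u) = 2*2*1 = 4, W(v) = 4*1*1 = 4 -> v first (larger |lfc|)
        assert list(out["gene"]) == ["v", "u"]


class TestCrossDatasetValidation:
    def _train(self):
        return pd.DataFrame({
            "gene": ["a", "b", "c"], "log2fc": [2.0, -2.0, 1.5],
            "call": ["up", "down", "up"],
        })

    def test_concordance_discordance_and_missing(self):
        val = pd.DataFrame({
            "gene": ["a", "b"], "log2fc": [1.0, 1.2],
            "call": ["up", "up"],
        })
        out = cross_dataset_validation(self._train(), val).set_index("gene")
        assert out.loc["a", "status"] == "concordant"
        assert out.loc["b", "status"] == "discordant"
        assert out.loc["c", "status"] == "not_evaluable"
        assert int(out["concordant"].sum()) == 1
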