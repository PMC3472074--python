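from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from apmsflow import network as net
from apmsflow.model import GeneSet
from apmsflow.terms import TermAnnotation

from _oracles import closure_by_joins


def enrich_with_calls(calls):
    """calls: {gene: {cell_line: bool}} over all three lines."""
    rows = []
    for gene, by_line in calls.items():
        for cl, spec in by_line.items():
            rows.append(
                {
                    "accession": gene,
                    "gene_symbol": gene,
                    "cell_line": cl,
                    "bait_mean": 1.0,
                    "control_mean": 1.0,
                    "ratio": 5.0 if spec else 1.0,
                    "specific": spec,
                }
            )
    return pd.DataFrame(rows)


ALL = ("A4", "X4C0", "A4P_A5L")


class TestMergeInteractomes:
    def test_duplicate_edge_merges_sources(self):
        out = net.merge_interactomes(
            [[("TLN1", "ITGB1", "db1")], [("TLN1", "ITGB1", "db2")]]
        )
        assert out.edges() == [("ITGB1", "TLN1", frozenset({"db1", "db2"}))]

    def test_reversed_endpoints_canonicalized(self):
        out = net.merge_interactomes([[("A", "B", "x"), ("B", "A", "y")]])
        assert out.n_edges == 1
        assert out.edges()[0][2] == frozenset({"x", "y"})

    def test_empty_input(self):
        assert net.merge_interactomes([[]]).n_edges == 0

    def test_no_edge_lists_rejected(self):
        with pytest.raises(ValueError):
            net.merge_interactomes([])


class TestMapCoverage:
    def setup_method(self):
        self.net = net.merge_interactomes([[("A", "B", "x"), ("B", "C", "x")]])

    def test_full(self):
        mapped, frac = net.map_coverage({"A", "B"}, self.net)
        assert (mapped, frac) == ({"A", "B"}, 1.0)

    def test_none(self):
        mapped, frac = net.map_coverage({"Z"}, self.net)
        assert (mapped, frac) == (set(), 0.0)

    def test_published_scale_arithmetic(self):
        # 338 of 350 mapped -> 96.6%
        nodes = [(f"N{i}", f"N{i + 1}", "x") for i in range(400)]
        inter = net.merge_interactomes([nodes])
        prots = {f"N{i}" for i in range(338)} | {f"M{i}" for i in range(12)}
        mapped, frac = net.map_coverage(prots, inter)
        assert len(mapped) == 338
        assert frac == pytest.approx(0.966, abs=5e-4)

    def test_empty_protein_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            net.map_coverage(set(), self.net)


class TestInducedSubnetwork:
    def triangle(self):
        return net.merge_interactomes(
            [[("A", "B", "x"), ("B", "C", "x"), ("A", "C", "x")]]
        )

    def test_identity_on_all_nodes(self):
        inter = self.triangle()
        sub = net.induced_subnetwork(inter, {"A", "B", "C"})
        assert sub.nodes == inter.nodes
        assert sub.n_edges == inter.n_edges

    def test_edge_subset(self):
        sub = net.induced_subnetwork(self.triangle(), {"A", "B"})
        assert [e[:2] for e in sub.edges()] == [("A", "B")]

    def test_isolated_nodes_retained(self):
        inter = net.merge_interactomes([[("A", "B", "x"), ("C", "D", "x")]])
        sub = net.induced_subnetwork(inter, {"A", "C"})
        assert sub.nodes == {"A", "C"}
        assert sub.n_edges == 0

    def test_idempotent_and_monotone(self):
        rng = np.random.default_rng(0)
        nodes = [f"N{i}" for i in range(20)]
        edges = [
            (a, b, "x")
            for a, b in itertools.combinations(nodes, 2)
            if rng.random() < 0.2
        ]
        inter = net.merge_interactomes([edges])
        for _ in range(10):
            q = {n for n in nodes if rng.random() < 0.6}
            p = {n for n in q if rng.random() < 0.6}
            sub_q = net.induced_subnetwork(inter, q)
            sub_p = net.induced_subnetwork(inter, p)
            again = net.induced_subnetwork(sub_q, q)
            assert again.nodes == sub_q.nodes
            assert again.edges() == sub_q.edges()
            assert set(e[:2] for e in sub_p.edges()) <= set(
                e[:2] for e in sub_q.edges()
            )


class TestVennPartition:
    def test_exact_subsets(self):
        enrich = enrich_with_calls(
            {
                "ITGB1": {cl: True for cl in ALL},
                "MYO18A": {"A4": False, "X4C0": True, "A4P_A5L": False},
                "HSPA9": {cl: False for cl in ALL},
            }
        )
        part = net.venn_partition(enrich)
        assert part["ITGB1"] == frozenset(ALL)
        assert part["MYO18A"] == frozenset({"X4C0"})
        assert "HSPA9" not in part

    def test_partition_invariants(self):
        rng = np.random.default_rng(1)
        calls = {
            f"G{i}": {cl: bool(rng.random() < 0.4) for cl in ALL}
            for i in range(50)
        }
        part = net.venn_partition(enrich_with_calls(calls))
        expected_universe = {
            g for g, by in calls.items() if any(by.values())
        }
        assert set(part) == expected_universe
        for g, subset in part.items():
            assert subset == frozenset(cl for cl in ALL if calls[g][cl])
            assert subset  # non-empty by construction

    def test_missing_cell_line_rejected(self):
        enrich = enrich_with_calls({"A": {"A4": True, "X4C0": True}})
        with pytest.raises(ValueError, match="A4P_A5L"):
            net.venn_partition(enrich)

    def test_missing_calls_rejected(self):
        enrich = enrich_with_calls({"A": {cl: True for cl in ALL}})
        enrich["specific"] = enrich["specific"].astype(object)
        enrich.loc[0, "specific"] = pd.NA
        with pytest.raises(ValueError, match="missing"):
            net.venn_partition(enrich)


class TestGenesetFilter:
    def test_intersection(self):
        gs = GeneSet("adhesome", ["TLN1", "VCL", "PXN"])
        assert net.geneset_filter({"TLN1", "MYO18A"}, gs) == {"TLN1"}

    def test_disjoint(self):
        gs = GeneSet("adhesome", ["TLN1"])
        assert net.geneset_filter({"MYO18A"}, gs) == set()


class TestAnnotateLocalization:
    @staticmethod
    def annotation():
        gene_terms = [
            ("G1", "GO:0030054"),
            ("G2", "T:CHILD"),
            ("G4", "T:GRANDCHILD"),
        ]
        relations = [
            ("T:CHILD", "GO:0005622"),
            ("T:GRANDCHILD", "T:CHILD"),
        ] + [
            (t, "T:ROOT")
            for ts in net.DEFAULT_LOCALIZATION_ROOTS.values()
            for t in ts
        ]
        return TermAnnotation(gene_terms, relations)

    def test_root_annotation(self):
        out = net.annotate_localization(["G1"], self.annotation())
        assert out["G1"] == {"cell_periphery"}

    def test_child_rollup(self):
        out = net.annotate_localization(["G2", "G4"], self.annotation())
        assert out["G2"] == {"intracellular"}
        assert out["G4"] == {"intracellular"}

    def test_unannotated_empty(self):
        out = net.annotate_localization(["G3"], self.annotation())
        assert out["G3"] == set()

    def test_unknown_root_rejected(self):
        with pytest.raises(ValueError, match="unknown term"):
            net.annotate_localization(
                ["G1"], self.annotation(), {"cat": ("T:NOPE",)}
            )

    def test_rollup_matches_join_closure_on_random_dags(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n_terms = int(rng.integers(5, 50))
            terms = [f"T{i}" for i in range(n_terms)]
            # random DAG: edges only from higher to lower index
            relations = {
                (terms[i], terms[j])
                for i in range(n_terms)
                for j in range(i)
                if rng.random() < 0.1
            }
            genes = [f"G{i}" for i in range(30)]
            gene_terms = [
                (g, terms[int(rng.integers(n_terms))]) for g in genes
            ]
            ann = TermAnnotation(gene_terms, relations)
            closure = closure_by_joins(relations)
            root = sorted(ann.terms)[0]  # must exist in the universe
            descendants = {a for a, b in closure if b == root}
            expected = {
                g
                for g, t in gene_terms
                if t == root or t in descendants
            }
            out = net.annotate_localization(genes, ann, {"cat": (root,)})
            assert {g for g, cats in out.items() if cats} == expected


class TestPlantedModuleDensity:
    def test_modules_denser_than_rewired_controls(self):
        from apmsflow.synthetic import SimulationConfig, simulate_counts, simulate_interactome

        cfg = SimulationConfig(
            seed=5,
            n_planted_per_region=6,
            n_background=5,
            n_reagent=5,
            n_other=30,
            n_extra_nodes=40,
            p_background_edge=0.02,
        )
        matrix, truth = simulate_counts(cfg)
        sources = simulate_interactome(cfg, truth)
        inter = net.merge_interactomes(sources)

        def internal_edges(graph: nx.Graph, members: set[str]) -> int:
            return sum(
                1 for a, b in graph.edges if a in members and b in members
            )

        g = inter.graph
        n_swaps = 2 * g.number_of_edges()
        wins = 0
        trials = 100
        observed = {
            key: internal_edges(g, members)
            for key, members in truth.modules.items()
        }
        for i in range(trials):
            shuffled = g.copy()
            nx.double_edge_swap(
                shuffled, nswap=n_swaps, max_tries=20 * n_swaps, seed=i
            )
            if all(
                internal_edges(shuffled, members) < observed[key]
                for key, members in truth.modules.items()
            ):
                wins += 1
        assert wins >= 95
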