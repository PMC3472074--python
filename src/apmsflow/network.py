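"""Interactome assembly, subnetworks, Venn partitioning and annotation.

The interactome is an undirected graph of upper-cased gene symbols whose
edges carry provenance tags from the contributing source databases.
Enriched proteins are mapped onto it, induced subnetworks extracted, and
nodes partitioned by the exact subset of cell lines in which each
protein was called specifically enriched (the "Venn set" of the network
figure). Subcellular-localization categories are assigned by ontology
rollup from a small set of root terms.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .model import CELL_LINES, GeneSet
from .terms import TermAnnotation

__all__ = [
    "Interactome",
    "merge_interactomes",
    "map_coverage",
    "induced_subnetwork",
    "venn_partition",
    "geneset_filter",
    "annotate_localization",
    "DEFAULT_LOCALIZATION_ROOTS",
    "write_graphml",
    "write_sif",
    "write_venn_table",
]

#: Root term ids per subcellular-localization category; a protein is
#: assigned a category when annotated with a root or any of its
#: descendant terms.
DEFAULT_LOCALIZATION_ROOTS: dict[str, tuple[str, ...]] = {
    "extracellular": ("GO:0005576",),
    "cell_periphery": ("GO:0009986", "GO:0030054", "GO:0071944"),
    "transmembrane": ("GO:0031226",),
    "intracellular": ("GO:0005622",),
}


class Interactome:
    """Undirected gene-symbol graph with per-edge provenance tags."""

    def __init__(self, graph: nx.Graph | None = None) -> None:
        self.graph = graph if graph is not None else nx.Graph()

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edges(self) -> list[tuple[str, str, frozenset[str]]]:
        """Canonicalized (sorted-endpoint) edges with source tags."""
        out = []
        for a, b, data in self.graph.edges(data=True):
            a, b = sorted((a, b))
            out.append((a, b, frozenset(data.get("sources", ()))))
        return sorted(out)

    def add_edge(self, a: str, b: str, source: str) -> None:
        a, b = a.upper(), b.upper()
        if a == b:
            return
        if self.graph.has_edge(a, b):
            self.graph[a][b]["sources"].add(source)
        else:
            self.graph.add_edge(a, b, sources={source})

    def degree(self, node: str) -> int:
        return self.graph.degree(node)


def merge_interactomes(
    edge_lists: Sequence[Iterable[tuple[str, str, str]]]
) -> Interactome:
    """Union of edge lists; duplicate pairs merge their provenance."""
    if len(edge_lists) < 1:
        raise ValueError("need at least one edge list")
    net = Interactome()
    for edges in edge_lists:
        for a, b, tag in edges:
            net.add_edge(a, b, tag)
    return net


def map_coverage(
    proteins: Iterable[str], interactome: Interactome
) -> tuple[set[str], float]:
    """Which proteins are interactome nodes, and what fraction."""
    prots = {p.upper() for p in proteins}
    if not prots:
        raise ValueError("empty protein set")
    mapped = prots & interactome.nodes
    return mapped, len(mapped) / len(prots)


def induced_subnetwork(
    interactome: Interactome, proteins: Iterable[str]
) -> Interactome:
    """Subgraph on ``proteins``; isolated mapped nodes are retained."""
    prots = {p.upper() for p in proteins} & interactome.nodes
    sub = nx.Graph()
    sub.add_nodes_from(prots)
    for a, b, data in interactome.graph.edges(data=True):
        if a in prots and b in prots:
            sub.add_edge(a, b, sources=set(data["sources"]))
    return Interactome(sub)


def venn_partition(enrich: pd.DataFrame) -> dict[str, frozenset[str]]:
    """Assign each specific protein the exact cell-line subset where it
    was called specific.

    Requires specificity calls for every canonical cell line; proteins
    specific in no line are absent from the partition. Keys are gene
    symbols (the network join key).
    """
    if enrich["specific"].isna().any():
        raise ValueError("specificity calls missing; run call_specific first")
    present = set(enrich["cell_line"])
    missing = [cl for cl in CELL_LINES if cl not in present]
    if missing:
        raise ValueError(f"missing cell-line calls for {missing}")
    assignment: dict[str, set[str]] = {}
    for _, row in enrich.iterrows():
        if bool(row["specific"]):
            assignment.setdefault(str(row["gene_symbol"]), set()).add(
                str(row["cell_line"])
            )
    return {g: frozenset(s) for g, s in assignment.items()}


def geneset_filter(proteins: Iterable[str], gene_set: GeneSet) -> set[str]:
    """Intersection of the protein symbols with a curated gene set."""
    return {p.upper() for p in proteins} & set(gene_set.members)


def annotate_localization(
    proteins: Iterable[str],
    annotations: TermAnnotation,
    category_roots: Mapping[str, Sequence[str]] | None = None,
) -> dict[str, set[str]]:
    """Roll annotations up to localization categories.

    A protein receives category ``c`` iff it is annotated with one of
    the category's root terms or any descendant of a root. Unannotated
    proteins get an empty category set.
    """
    roots = (
        {c: tuple(ts) for c, ts in category_roots.items()}
        if category_roots is not None
        else DEFAULT_LOCALIZATION_ROOTS
    )
    universe = annotations.terms
    for cat, terms in roots.items():
        if not terms:
            raise ValueError(f"category {cat!r} has no root terms")
        for t in terms:
            if t not in universe:
                raise ValueError(f"unknown term id {t!r} for category {cat!r}")
    category_terms = {
        cat: set(ts) | set().union(*(annotations.descendants(t) for t in ts))
        for cat, ts in roots.items()
    }
    out: dict[str, set[str]] = {}
    for p in proteins:
        sym = p.upper()
        direct = annotations.gene_to_terms.get(sym, set())
        out[sym] = {
            cat for cat, terms in category_terms.items() if direct & terms
        }
    return out


# -- persistence -----------------------------------------------------------


def write_graphml(
    net: Interactome,
    path: str | Path,
    node_attrs: Mapping[str, Mapping[str, object]] | None = None,
) -> None:
    """GraphML with stringified provenance and optional node attributes."""
    # sorted insertion keeps the serialization byte-stable across runs
    g = nx.Graph()
    g.add_nodes_from(sorted(net.graph.nodes))
    for a, b, sources in net.edges():
        g.add_edge(a, b, sources=",".join(sorted(sources)))
    if node_attrs:
        for node in g.nodes:
            for key, values in node_attrs.items():
                if node in values:
                    val = values[node]
                    if isinstance(val, (set, frozenset, list, tuple)):
                        val = ",".join(sorted(str(v) for v in val))
                    g.nodes[node][key] = val
    nx.write_graphml(g, str(path))


def write_sif(net: Interactome, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b, _ in net.edges():
            fh.write(f"{a} pp {b}\n")


def write_venn_table(
    partition: Mapping[str, frozenset[str]], path: str | Path
) -> None:
    rows = [
        {
            "gene_symbol": g,
            "venn_set": "+".join(cl for cl in CELL_LINES if cl in s),
        }
        for g, s in sorted(partition.items())
    ]
    pd.DataFrame(rows, columns=["gene_symbol", "venn_set"]).to_csv(
        path, sep="\t", index=False
    )
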