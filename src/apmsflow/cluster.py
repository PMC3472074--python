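"""Hierarchical clustering of enrichment profiles and cluster selection.

Profiles (per-cell-line log2 bait/control mean counts) are clustered
agglomeratively under the correlation distance d = 1 - r with average
linkage (UPGMA). Clusters of interest are the maximal dendrogram nodes
whose merge correlation is at least ``min_corr`` and whose members are
absent or lowly detected in the control samples; "background" clusters
are the converse pattern (strong control detection, no enrichment).

Determinism: profiles are ordered by lexicographic protein sort and tied
merges pick the pair containing the lowest member index, so the tree is
invariant to input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import CELL_LINES

__all__ = [
    "Profile",
    "Dendrogram",
    "DendroNode",
    "SelectedCluster",
    "ClusterSelection",
    "pearson_distance",
    "build_profiles",
    "hclust",
    "select_clusters",
    "flag_background_clusters",
    "write_newick",
    "write_cluster_table",
]

_TIE_TOL = 1e-12


def pearson_distance(a: Sequence[float], b: Sequence[float]) -> float:
    """Correlation distance d = 1 - r, in [0, 2].

    A constant (zero-variance) vector has undefined correlation; it is
    treated as r = 0 (distance 1) against any vector so that all-zero
    background rows stay clusterable.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need vectors of length >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = float(np.sqrt(np.dot(xc, xc)))
    sy = float(np.sqrt(np.dot(yc, yc)))
    if sx == 0.0 or sy == 0.0:
        return 1.0
    r = float(np.dot(xc, yc) / (sx * sy))
    r = max(-1.0, min(1.0, r))
    return 1.0 - r


@dataclass(frozen=True)
class Profile:
    """One protein's ordered abundance vector across sample groups."""

    protein: str
    values: tuple[float, ...]


def build_profiles(
    enrich: pd.DataFrame, pseudocount: float = 1.0
) -> list[Profile]:
    """Per-protein log2(mean count + pseudocount) profiles.

    Columns are (bait_mean, control_mean) per cell line, concatenated in
    canonical cell-line order, so bait and control lanes both shape the
    correlation structure.
    """
    lines = [cl for cl in CELL_LINES if cl in set(enrich["cell_line"])]
    profiles = []
    for acc, grp in enrich.groupby("accession", sort=True):
        by_line = grp.set_index("cell_line")
        values: list[float] = []
        for cl in lines:
            row = by_line.loc[cl]
            values.append(float(np.log2(row["bait_mean"] + pseudocount)))
            values.append(float(np.log2(row["control_mean"] + pseudocount)))
        profiles.append(Profile(protein=str(acc), values=tuple(values)))
    return profiles


@dataclass(frozen=True)
class DendroNode:
    """Internal merge node; ``members`` are leaf indices."""

    node_id: int
    left: int
    right: int
    height: float
    members: frozenset[int]

    @property
    def node_correlation(self) -> float:
        return 1.0 - self.height


@dataclass
class Dendrogram:
    """Binary merge tree over proteins under correlation distance.

    Leaves are numbered ``0..n-1`` (lexicographic protein order);
    internal nodes ``n..2n-2`` in merge order. Each node's correlation
    is ``1 - height``.
    """

    leaves: list[str]
    nodes: list[DendroNode]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def root_id(self) -> int:
        return self.n_leaves + len(self.nodes) - 1

    def node(self, node_id: int) -> DendroNode:
        return self.nodes[node_id - self.n_leaves]

    def is_leaf(self, node_id: int) -> bool:
        return node_id < self.n_leaves

    def members(self, node_id: int) -> frozenset[int]:
        if self.is_leaf(node_id):
            return frozenset([node_id])
        return self.node(node_id).members

    def member_proteins(self, node_id: int) -> list[str]:
        return sorted(self.leaves[i] for i in self.members(node_id))

    def height(self, node_id: int) -> float:
        return 0.0 if self.is_leaf(node_id) else self.node(node_id).height

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""

        def render(node_id: int, parent_height: float) -> str:
            length = parent_height - self.height(node_id)
            if self.is_leaf(node_id):
                return f"{self.leaves[node_id]}:{length:.6g}"
            nd = self.node(node_id)
            inner = ",".join(
                render(c, nd.height) for c in (nd.left, nd.right)
            )
            return f"({inner}):{length:.6g}"

        root = self.root_id
        if self.is_leaf(root):  # degenerate single-leaf tree
            return f"{self.leaves[root]}:0;"
        nd = self.node(root)
        inner = ",".join(render(c, nd.height) for c in (nd.left, nd.right))
        return f"({inner});"


def hclust(profiles: Sequence[Profile], linkage: str = "average") -> Dendrogram:
    """Agglomerative clustering under correlation distance.

    Only average linkage (UPGMA, via the exact Lance-Williams update) is
    supported; merge heights are checked to be non-decreasing on every
    run.
    """
    if linkage != "average":
        raise ValueError(f"unsupported linkage {linkage!r}")
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    ordered = sorted(profiles, key=lambda p: p.protein)
    names = [p.protein for p in ordered]
    if len(set(names)) != len(names):
        raise ValueError("duplicate protein names in profiles")
    n = len(ordered)

    total = 2 * n - 1
    dist = np.full((total, total), np.inf)
    for i in range(n):
        for j in range(i + 1, n):
            d = pearson_distance(ordered[i].values, ordered[j].values)
            dist[i, j] = dist[j, i] = d

    active: list[int] = list(range(n))
    members: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    min_leaf: dict[int, int] = {i: i for i in range(n)}
    nodes: list[DendroNode] = []
    last_height = 0.0

    for new_id in range(n, total):
        # locate the minimal-distance active pair, breaking ties by the
        # lowest member leaf index (then the partner's lowest index)
        act = np.array(active)
        sub = dist[np.ix_(act, act)]
        np.fill_diagonal(sub, np.inf)
        best_d = float(sub.min())
        ii, jj = np.nonzero(sub <= best_d + _TIE_TOL)
        best: tuple[int, int] | None = None
        best_key: tuple[int, int] | None = None
        for i, j in zip(act[ii], act[jj]):
            if i >= j:
                continue
            key = tuple(sorted((min_leaf[i], min_leaf[j])))
            if best_key is None or key < best_key:
                best, best_key = (int(i), int(j)), key
        assert best is not None
        u, v = best
        best_d = float(dist[u, v])
        merged = members[u] | members[v]
        height = float(best_d)
        if height < last_height - 1e-9:
            raise AssertionError(
                f"non-monotone merge heights: {height} after {last_height}"
            )
        height = max(height, last_height)
        last_height = height
        # deterministic child order: lower min leaf index on the left
        left, right = (u, v) if min_leaf[u] <= min_leaf[v] else (v, u)
        nodes.append(
            DendroNode(
                node_id=new_id,
                left=left,
                right=right,
                height=height,
                members=merged,
            )
        )
        # Lance-Williams average-linkage update
        su, sv = len(members[u]), len(members[v])
        for w in active:
            if w in (u, v):
                continue
            d_new = (su * dist[u, w] + sv * dist[v, w]) / (su + sv)
            dist[new_id, w] = dist[w, new_id] = d_new
        active.remove(u)
        active.remove(v)
        active.append(new_id)
        members[new_id] = merged
        min_leaf[new_id] = min(min_leaf[u], min_leaf[v])

    return Dendrogram(leaves=names, nodes=nodes)


# -- cluster selection -----------------------------------------------------


@dataclass(frozen=True)
class SelectedCluster:
    node_id: int
    members: tuple[str, ...]
    node_correlation: float
    max_control_mean: float


@dataclass
class ClusterSelection:
    clusters: list[SelectedCluster]

    def membership(self) -> dict[str, int]:
        return {
            m: c.node_id for c in self.clusters for m in c.members
        }


def _protein_stats(enrich: pd.DataFrame) -> pd.DataFrame:
    """Per-protein mean control count and maximal ratio across lines."""
    return enrich.groupby("accession").agg(
        control_mean=("control_mean", "mean"), max_ratio=("ratio", "max")
    )


def select_clusters(
    dend: Dendrogram,
    enrich: pd.DataFrame,
    min_corr: float = 0.6,
    control_cap: float = 1.0,
) -> ClusterSelection:
    """Maximal internal nodes with high merge correlation and low control.

    A node qualifies when its correlation (1 - height) is at least
    ``min_corr`` and every member's mean control count is at most
    ``control_cap``; qualifying nodes are reported maximally (no
    reported node is an ancestor of another).
    """
    stats = _protein_stats(enrich)
    missing = set(dend.leaves) - set(stats.index)
    if missing:
        raise ValueError(
            f"dendrogram leaves absent from enrichment table: {sorted(missing)[:5]}"
        )
    ctrl = stats["control_mean"]

    selected: list[SelectedCluster] = []

    def visit(node_id: int) -> None:
        if dend.is_leaf(node_id):
            return
        nd = dend.node(node_id)
        prots = dend.member_proteins(node_id)
        max_ctrl = float(ctrl.loc[prots].max())
        if nd.node_correlation >= min_corr and max_ctrl <= control_cap:
            selected.append(
                SelectedCluster(
                    node_id=node_id,
                    members=tuple(prots),
                    node_correlation=nd.node_correlation,
                    max_control_mean=max_ctrl,
                )
            )
            return
        visit(nd.left)
        visit(nd.right)

    visit(dend.root_id)
    return ClusterSelection(clusters=selected)


def flag_background_clusters(
    dend: Dendrogram,
    enrich: pd.DataFrame,
    ratio_threshold: float,
    control_cap: float = 1.0,
) -> set[int]:
    """Maximal nodes dominated by control detection without enrichment.

    A node is flagged when the median member mean control count exceeds
    ``control_cap`` and the median member best ratio (max across cell
    lines) stays below ``ratio_threshold``.
    """
    stats = _protein_stats(enrich)
    flagged: set[int] = set()

    def visit(node_id: int) -> None:
        if dend.is_leaf(node_id):
            return
        prots = dend.member_proteins(node_id)
        sub = stats.loc[prots]
        if (
            float(sub["control_mean"].median()) > control_cap
            and float(sub["max_ratio"].median()) < ratio_threshold
        ):
            flagged.add(node_id)
            return
        nd = dend.node(node_id)
        visit(nd.left)
        visit(nd.right)

    visit(dend.root_id)
    return flagged


# -- persistence -----------------------------------------------------------


def write_newick(dend: Dendrogram, path: str | Path) -> None:
    Path(path).write_text(dend.to_newick() + "\n", encoding="utf-8")


def write_cluster_table(selection: ClusterSelection, path: str | Path) -> None:
    rows = [
        {
            "cluster_id": c.node_id,
            "protein": m,
            "node_correlation": c.node_correlation,
            "max_control_mean": c.max_control_mean,
        }
        for c in selection.clusters
        for m in c.members
    ]
    pd.DataFrame(
        rows,
        columns=["cluster_id", "protein", "node_correlation", "max_control_mean"],
    ).to_csv(path, sep="\t", index=False)
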