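"""Independent brute-force oracles used by unit and acceptance tests.

Each function recomputes a quantity by the most direct method available
(two-pass statistics, exhaustive merges, enumeration, repeated joins)
without touching the implementation under test.
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence


def two_pass_mean_sd(values: Sequence[float]) -> tuple[float, float]:
    """Textbook two-pass mean and sample (n-1) standard deviation."""
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var)


def pearson_r(a: Sequence[float], b: Sequence[float]) -> float:
    """Covariance-formula correlation, computed longhand."""
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    cov = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    va = sum((x - ma) ** 2 for x in a)
    vb = sum((y - mb) ** 2 for y in b)
    return cov / math.sqrt(va * vb)


def naive_average_linkage(
    names: Sequence[str], dist: dict[tuple[str, str], float]
) -> list[tuple[frozenset[str], float]]:
    """Exhaustive agglomerative clustering with average linkage.

    Cluster-to-cluster distance is recomputed from scratch each step as
    the mean of all original pairwise distances. Ties are broken by the
    lowest contained name under the sorted order of ``names``, matching
    the implementation's documented rule. Returns the merge sequence as
    (merged member set, merge height) pairs.
    """
    order = {name: i for i, name in enumerate(sorted(names))}
    clusters: list[frozenset[str]] = [frozenset([n]) for n in names]

    def d(x: str, y: str) -> float:
        return dist[(x, y)] if (x, y) in dist else dist[(y, x)]

    def cluster_dist(a: frozenset[str], b: frozenset[str]) -> float:
        pairs = [(x, y) for x in a for y in b]
        return sum(d(x, y) for x, y in pairs) / len(pairs)

    merges: list[tuple[frozenset[str], float]] = []
    while len(clusters) > 1:
        best = None
        best_d = None
        best_key = None
        for a, b in itertools.combinations(clusters, 2):
            cd = cluster_dist(a, b)
            key = tuple(sorted(min(order[m] for m in c) for c in (a, b)))
            if (
                best_d is None
                or cd < best_d - 1e-12
                or (abs(cd - best_d) <= 1e-12 and key < best_key)
            ):
                best, best_d, best_key = (a, b), cd, key
        a, b = best
        clusters.remove(a)
        clusters.remove(b)
        merged = a | b
        clusters.append(merged)
        merges.append((merged, best_d))
    return merges


def hypergeom_tail_exact(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) by exact integer combinatorics."""
    total = math.comb(N, n)
    acc = 0
    for i in range(k, min(n, K) + 1):
        acc += math.comb(K, i) * math.comb(N - K, n - i)
    return acc / total


def hypergeom_tail_by_enumeration(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) by literally enumerating all C(N, n) draws.

    Only feasible for tiny N; used to anchor the combinatorial oracle.
    """
    carriers = set(range(K))
    hits = 0
    total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if len(carriers.intersection(draw)) >= k:
            hits += 1
    return hits / total


def closure_by_joins(relations: set[tuple[str, str]]) -> set[tuple[str, str]]:
    """Transitive closure of child->parent pairs by repeated joins."""
    closure = set(relations)
    while True:
        extra = {
            (a, d)
            for a, b in closure
            for c, d in closure
            if b == c and (a, d) not in closure
        }
        if not extra:
            return closure
        closure |= extra


def scan_peptide(sequence: str, peptide: str) -> list[tuple[int, int]]:
    """Naive O(L*p) occurrence scan, 1-based inclusive intervals."""
    out = []
    for i in range(len(sequence) - len(peptide) + 1):
        if sequence[i : i + len(peptide)] == peptide:
            out.append((i + 1, i + len(peptide)))
    return out
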