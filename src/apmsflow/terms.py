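"""Term annotations and overrepresentation analysis.

Annotations are a gene -> term map plus an acyclic child -> parent term
relation. A gene annotated with a term is also retrievable under every
ancestor of that term ("rollup"), which is how category assignment and
set enrichment both interpret the ontology.

Overrepresentation is tested one-sided hypergeometrically (equivalent to
Fisher's exact test, alternative "greater") with Bonferroni correction
over the terms actually tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy.stats import hypergeom

from .model import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "TermAnnotation",
    "TermResult",
    "hypergeom_p",
    "fold_enrichment",
    "enrich_set",
]


class TermAnnotation:
    """Gene/term annotation maps with an acyclic parent relation.

    Parameters
    ----------
    gene_terms:
        Iterable of ``(gene_symbol, term_id)`` direct annotations.
    relations:
        Iterable of ``(child_term, parent_term)`` pairs. Must be acyclic.
    """

    def __init__(
        self,
        gene_terms: Iterable[tuple[str, str]],
        relations: Iterable[tuple[str, str]] = (),
    ) -> None:
        self.gene_to_terms: dict[str, set[str]] = {}
        self.term_to_genes: dict[str, set[str]] = {}
        self.parents: dict[str, set[str]] = {}

        for gene, term in gene_terms:
            gene = gene.upper()
            self.gene_to_terms.setdefault(gene, set()).add(term)
            self.term_to_genes.setdefault(term, set()).add(gene)
        for child, parent in relations:
            self.parents.setdefault(child, set()).add(parent)
            self.parents.setdefault(parent, set())
        cycle = self._find_cycle()
        if cycle is not None:
            raise ValidationError(
                "term relations contain a cycle: " + " -> ".join(cycle)
            )

    # -- structure ---------------------------------------------------------

    @property
    def terms(self) -> set[str]:
        """Term universe: union of annotated terms and relation terms."""
        return set(self.term_to_genes) | set(self.parents)

    @property
    def background(self) -> set[str]:
        """All genes with at least one annotation."""
        return set(self.gene_to_terms)

    def _find_cycle(self) -> list[str] | None:
        WHITE, GREY, BLACK = 0, 1, 2
        color = {t: WHITE for t in self.parents}
        stack: list[str] = []

        def visit(t: str) -> list[str] | None:
            color[t] = GREY
            stack.append(t)
            for p in self.parents.get(t, ()):
                if color.get(p, WHITE) == GREY:
                    i = stack.index(p)
                    return stack[i:] + [p]
                if color.get(p, WHITE) == WHITE:
                    found = visit(p)
                    if found:
                        return found
            stack.pop()
            color[t] = BLACK
            return None

        for t in list(color):
            if color[t] == WHITE:
                found = visit(t)
                if found:
                    return found
        return None

    def ancestors(self, term: str) -> set[str]:
        """All strict ancestors of ``term`` under the relation closure."""
        out: set[str] = set()
        frontier = list(self.parents.get(term, ()))
        while frontier:
            t = frontier.pop()
            if t not in out:
                out.add(t)
                frontier.extend(self.parents.get(t, ()))
        return out

    def descendants(self, term: str) -> set[str]:
        """All strict descendants of ``term``."""
        children: dict[str, set[str]] = {}
        for c, ps in self.parents.items():
            for p in ps:
                children.setdefault(p, set()).add(c)
        out: set[str] = set()
        frontier = list(children.get(term, ()))
        while frontier:
            t = frontier.pop()
            if t not in out:
                out.add(t)
                frontier.extend(children.get(t, ()))
        return out

    def genes_for(self, term: str, rollup: bool = True) -> set[str]:
        """Genes annotated with ``term`` (including descendants if rollup)."""
        genes = set(self.term_to_genes.get(term, ()))
        if rollup:
            for d in self.descendants(term):
                genes |= self.term_to_genes.get(d, set())
        return genes

    def terms_for(self, gene: str, rollup: bool = True) -> set[str]:
        """Terms annotating ``gene`` (including ancestors if rollup)."""
        terms = set(self.gene_to_terms.get(gene.upper(), ()))
        if rollup:
            for t in list(terms):
                terms |= self.ancestors(t)
        return terms


# -- statistics ------------------------------------------------------------


def hypergeom_p(k: int, n: int, K: int, N: int) -> float:
    """One-sided overrepresentation p-value, P(X >= k).

    X follows a hypergeometric distribution for drawing ``n`` genes
    without replacement from a background of ``N`` genes of which ``K``
    carry the term; ``k`` of the drawn genes carry it.
    """
    if not (0 <= k <= n <= N):
        raise ValueError(f"need 0 <= k <= n <= N, got k={k}, n={n}, N={N}")
    if not (k <= K <= N):
        raise ValueError(f"need k <= K <= N, got k={k}, K={K}, N={N}")
    # survival function at k-1 gives P(X >= k); scipy evaluates the tail
    # stably in log space internally.
    return float(hypergeom.sf(k - 1, N, K, n))


def fold_enrichment(k: int, n: int, K: int, N: int) -> float:
    """(k/n) / (K/N): set prevalence over background prevalence."""
    if n <= 0 or K <= 0 or N <= 0:
        raise ValueError("n, K and N must be positive")
    return (k / n) / (K / N)


@dataclass(frozen=True)
class TermResult:
    term: str
    k: int
    n: int
    K: int
    N: int
    fold: float
    p: float
    p_bonferroni: float
    overrepresented: bool


def enrich_set(
    genes: Iterable[str],
    annotation: TermAnnotation,
    min_fold: float = 5.0,
    max_p_bonf: float = 0.1,
    background: Iterable[str] | None = None,
) -> list[TermResult]:
    """Test a gene set for term overrepresentation.

    Terms are counted after rollup (a gene annotated with a child term
    counts toward every ancestor). Genes outside the background are
    logged and dropped. One result per term with at least one query-set
    gene; Bonferroni ``m`` is the number of such terms. Results are
    sorted by p-value.
    """
    universe = (
        {g.upper() for g in background}
        if background is not None
        else annotation.background
    )
    if not universe:
        raise ValueError("empty background universe")
    query = {g.upper() for g in genes}
    outside = query - universe
    if outside:
        logger.warning(
            "dropping %d query genes absent from the background: %s",
            len(outside),
            sorted(outside)[:10],
        )
    query &= universe
    n = len(query)
    N = len(universe)

    counts: list[tuple[str, int, int]] = []
    for term in sorted(annotation.terms):
        carriers = annotation.genes_for(term, rollup=True) & universe
        k = len(carriers & query)
        if k >= 1:
            counts.append((term, k, len(carriers)))
    m = len(counts)

    results = []
    for term, k, K in counts:
        p = hypergeom_p(k, n, K, N)
        p_bonf = min(1.0, m * p)
        fold = fold_enrichment(k, n, K, N)
        results.append(
            TermResult(
                term=term,
                k=k,
                n=n,
                K=K,
                N=N,
                fold=fold,
                p=p,
                p_bonferroni=p_bonf,
                overrepresented=(fold > min_fold and p_bonf < max_p_bonf),
            )
        )
    results.sort(key=lambda r: (r.p, r.term))
    return results
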