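"""Hypergeometric over-representation analysis and the enrichment network map.

Each term's enrichment p-value is the exact hypergeometric upper tail
P(X >= k) for drawing k annotated genes in a query of size n from a
background of N genes of which K are annotated.  P-values are adjusted by
Benjamini-Hochberg step-up; a term is significant when p_adj < 0.05 and at
least two query genes hit it.  Significant terms form a graph in which edges
connect terms sharing genes, weighted by the overlap coefficient
|A & B| / min(|A|, |B|).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import networkx as nx
import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .sumstats import GeneSet

__all__ = [
    "TermAnnotation",
    "EnrichmentRow",
    "hypergeom_enrich",
    "bh_adjust",
    "enrichment_map",
    "P_ADJ_MAX",
    "MIN_GENE_COUNT",
]

P_ADJ_MAX = 0.05
MIN_GENE_COUNT = 2
NAMESPACES = ("BP", "MF", "CC", "pathway")
DEFAULT_OVERLAP_THRESHOLD = 0.2


@dataclass(frozen=True)
class TermAnnotation:
    term_id: str
    term_name: str
    genes: frozenset
    namespace: str = "BP"

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"term {self.term_id} has no annotated genes")
        if self.namespace not in NAMESPACES:
            raise ValueError(f"namespace must be one of {NAMESPACES}")


@dataclass(frozen=True)
class EnrichmentRow:
    term: TermAnnotation
    k: int  # query genes annotated to the term
    K: int  # background genes annotated to the term
    n: int  # query size
    N: int  # background size
    p: float
    p_adj: float
    genes_hit: frozenset

    def __post_init__(self):
        if self.k > min(self.K, self.n):
            raise ValueError("k cannot exceed min(K, n)")
        if not (0.0 < self.p <= 1.0):
            raise ValueError("p must be in (0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_adj < P_ADJ_MAX and self.k >= MIN_GENE_COUNT


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must be in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrich(
    query: GeneSet,
    annotations: Iterable[TermAnnotation],
    background: GeneSet,
) -> list:
    """Over-representation of the query gene set against annotated terms.

    Annotations are intersected with the background before testing; the
    query must be contained in the background.  Returns one
    :class:`EnrichmentRow` per term with at least one query hit (k >= 1),
    with BH adjustment across all such rows.  Terms with no background genes
    are skipped; significance additionally requires k >= 2.
    """
    q = set(query.genes)
    bg = set(background.genes)
    if not q:
        raise ValueError("empty query gene set")
    if not q <= bg:
        raise ValueError("query genes must be a subset of the background")
    N, n = len(bg), len(q)
    hits = []
    for term in annotations:
        term_bg = term.genes & bg
        K = len(term_bg)
        if K == 0:
            continue
        genes_hit = term_bg & q
        k = len(genes_hit)
        if k == 0:
            continue
        # upper tail P(X >= k): sf at k-1
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        hits.append((term, k, K, frozenset(genes_hit), min(p, 1.0)))
    if not hits:
        return []
    p_adj = bh_adjust([h[4] for h in hits])
    rows = [
        EnrichmentRow(
            term=term, k=k, K=K, n=n, N=N, p=p, p_adj=float(adj),
            genes_hit=genes_hit,
        )
        for (term, k, K, genes_hit, p), adj in zip(hits, p_adj)
    ]
    rows.sort(key=lambda r: (r.p, r.term.term_id))
    return rows


def enrichment_map(
    rows: Sequence[EnrichmentRow],
    overlap_threshold: float = DEFAULT_OVERLAP_THRESHOLD,
    focus_gene: Optional[str] = None,
) -> nx.Graph:
    """Graph of significant terms: node size = gene count, node weight =
    -log10(p); edges connect terms whose hit-gene overlap coefficient
    |A & B| / min(|A|, |B|) reaches ``overlap_threshold``, weighted by that
    coefficient.  Nodes containing ``focus_gene`` are marked so the focal
    gene's terms can be drawn distinctly."""
    graph = nx.Graph()
    significant = [r for r in rows if r.significant]
    for row in significant:
        graph.add_node(
            row.term.term_id,
            name=row.term.term_name,
            namespace=row.term.namespace,
            size=row.k,
            weight=float(-np.log10(row.p)),
            p_adj=row.p_adj,
            genes=sorted(row.genes_hit),
            has_focus_gene=bool(focus_gene and focus_gene in row.genes_hit),
        )
    for i, a in enumerate(significant):
        for b in significant[i + 1 :]:
            inter = a.genes_hit & b.genes_hit
            if not inter:
                continue
            coef = len(inter) / min(len(a.genes_hit), len(b.genes_hit))
            if coef >= overlap_threshold:
                graph.add_edge(
                    a.term.term_id, b.term.term_id,
                    weight=coef, shared_genes=sorted(inter),
                )
    return graph
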