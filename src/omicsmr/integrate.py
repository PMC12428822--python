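"""Evidence integration across omics layers and phenotypes.

Reproduces the study-level summary layer: per-phenotype significant
probe/gene sets (p_SMR < 0.05 and p_HEIDI > 0.05), the cross-omics
convergence list (genes significant independently in mQTL, eQTL *and* pQTL
for a phenotype), per-gene odds-ratio summaries for the methylation layer
(median across probes when n >= 3, mean otherwise), and UpSet-style
exclusive-intersection counts of integrated genes across phenotypes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Iterable, Sequence

import numpy as np
import pandas as pd

from .smr import SmrResult

__all__ = [
    "PhenotypeSummary",
    "GeneEffectSummary",
    "significant_set",
    "integrate_genes",
    "summarize_gene_or",
    "overlap_matrix",
    "phenotype_summary_table",
]

P_SMR_MAX = 0.05
P_HEIDI_MIN = 0.05
REQUIRED_LAYERS = ("mQTL", "eQTL", "pQTL")


@dataclass(frozen=True)
class PhenotypeSummary:
    phenotype: str
    n_cpg_sites: int
    n_genes_mqtl: int
    n_genes_eqtl: int
    n_genes_pqtl: int
    integrated_genes: frozenset
    strong_coloc_genes: frozenset


@dataclass(frozen=True)
class GeneEffectSummary:
    gene: str
    layer: str
    n_probes: int
    or_values: tuple
    summary_or: float
    summary_label: str  # "Med" when n_probes >= 3, else "Mean"

    def __post_init__(self):
        expected = "Med" if self.n_probes >= 3 else "Mean"
        if self.summary_label != expected:
            raise ValueError("summary_label inconsistent with probe count")


def significant_set(
    results: Iterable[SmrResult],
    layer: str,
    strict_heidi: bool = False,
):
    """Probe count and unique gene set passing p_SMR < 0.05 and p_HEIDI > 0.05.

    A not-evaluable HEIDI passes unless ``strict_heidi``; each significant
    probe-level row counts once.
    """
    probes, genes = 0, set()
    for res in results:
        if res.layer != layer:
            continue
        if res.p_smr < P_SMR_MAX and res.heidi_pass(P_HEIDI_MIN, strict_heidi):
            probes += 1
            genes.add(res.gene)
    return probes, genes


def integrate_genes(layer_sets: Dict[str, set]) -> set:
    """Exact three-way intersection across mQTL, eQTL and pQTL gene sets.

    The convergence criterion requires evidence from all three molecular
    layers, so a missing layer is an error rather than an empty set.
    """
    missing = [l for l in REQUIRED_LAYERS if l not in layer_sets]
    if missing:
        raise ValueError(
            f"cross-omics convergence needs all three layers; missing {missing}"
        )
    out = set(layer_sets[REQUIRED_LAYERS[0]])
    for layer in REQUIRED_LAYERS[1:]:
        out &= set(layer_sets[layer])
    return out


def summarize_gene_or(
    results: Sequence[SmrResult], gene: str, layer: str = "mQTL"
) -> GeneEffectSummary:
    """Summary odds ratio over a gene's significant probes in one layer.

    Median of the per-probe ORs (exp(b_smr)) when the gene has three or more
    significant probes, arithmetic mean when fewer.
    """
    ors = [
        res.or_smr
        for res in results
        if res.gene == gene
        and res.layer == layer
        and res.p_smr < P_SMR_MAX
        and res.heidi_pass(P_HEIDI_MIN)
    ]
    n = len(ors)
    if n == 0:
        raise ValueError(f"{gene}: no significant {layer} probes to summarize")
    if n >= 3:
        return GeneEffectSummary(
            gene, layer, n, tuple(ors), float(np.median(ors)), "Med"
        )
    return GeneEffectSummary(gene, layer, n, tuple(ors), float(np.mean(ors)), "Mean")


def overlap_matrix(phenotype_sets: Dict[str, set]) -> pd.DataFrame:
    """UpSet-style exclusive intersections of gene sets across phenotypes.

    For every nonempty combination of phenotypes, the row lists the genes
    belonging to *exactly* that combination, so exclusive sizes sum to the
    size of the union.
    """
    if len(phenotype_sets) < 2:
        raise ValueError("need at least two phenotype sets")
    names = sorted(phenotype_sets)
    membership = {}
    for gene in set().union(*phenotype_sets.values()):
        key = frozenset(n for n in names if gene in phenotype_sets[n])
        membership.setdefault(key, set()).add(gene)
    rows = []
    for size in range(len(names), 0, -1):
        for combo in combinations(names, size):
            genes = membership.get(frozenset(combo), set())
            if genes:
                rows.append(
                    {
                        "phenotypes": "&".join(combo),
                        "degree": size,
                        "n_genes": len(genes),
                        "genes": ",".join(sorted(genes)),
                    }
                )
    df = pd.DataFrame(rows, columns=["phenotypes", "degree", "n_genes", "genes"])
    df.attrs["set_sizes"] = {n: len(phenotype_sets[n]) for n in names}
    return df


def phenotype_summary_table(summaries: Sequence[PhenotypeSummary]) -> pd.DataFrame:
    """The per-phenotype summary table (one row per phenotype): probe and
    unique-gene counts per layer, the integrated gene list, and which of the
    integrated genes show strong colocalization."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "phenotype": s.phenotype,
                "n_mqtl_cpg_sites": s.n_cpg_sites,
                "n_mqtl_genes": s.n_genes_mqtl,
                "n_eqtl_genes": s.n_genes_eqtl,
                "n_pqtl_genes": s.n_genes_pqtl,
                "integrated_genes": ",".join(sorted(s.integrated_genes)),
                "strong_coloc": ",".join(sorted(s.strong_coloc_genes)) or "No",
            }
        )
    return pd.DataFrame(rows)
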