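"""Five-hypothesis Bayesian colocalization with Wakefield approximate Bayes
factors, evaluated entirely in log space.

Given per-variant summary statistics for two traits over one locus, the
method compares five mutually exclusive hypotheses under the one-causal-
variant-per-trait assumption:

    H0  no association with either trait
    H1  association with trait 1 only
    H2  association with trait 2 only
    H3  distinct causal variants for each trait
    H4  a single shared causal variant

Each variant's evidence is the Wakefield approximate Bayes factor: with
V = se^2, W = prior_sd^2, r = W/(V+W) and z = beta/se,

    log ABF = 0.5 * (log(1 - r) + r * z^2).

Hypothesis weights combine per-variant ABFs with the prior probabilities
p1, p2 (single-trait association) and p12 (shared association); posteriors
are normalized with log-sum-exp so loci with |z| in the hundreds do not
overflow.  PP.H4 > 0.7 is reported as strong evidence for colocalization.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .sumstats import AssocRecord, QtlRecord

__all__ = [
    "ColocPriors",
    "AbfParams",
    "ColocResult",
    "wakefield_labf",
    "coloc_posteriors",
    "coloc_locus",
    "LAYER_WINDOW_KB",
]

HYPOTHESES = ("PP.H0", "PP.H1", "PP.H2", "PP.H3", "PP.H4")

# locus window half-width by molecular layer: +/-500 kb for methylation QTLs,
# +/-1000 kb for expression and protein QTLs
LAYER_WINDOW_KB = {"mQTL": 500, "eQTL": 1000, "pQTL": 1000}

STRONG_H4 = 0.7
MIN_LOCUS_SNPS = 25


@dataclass(frozen=True)
class ColocPriors:
    p1: float = 1e-4  # a variant associates with trait 1 only
    p2: float = 1e-4  # with trait 2 only
    p12: float = 1e-5  # with both (shared causal variant)

    def __post_init__(self):
        if not (0 < self.p12 <= min(self.p1, self.p2)):
            raise ValueError("need 0 < p12 <= p1, p2")
        if max(self.p1, self.p2) >= 1:
            raise ValueError("priors must be below 1")

    def check_locus_size(self, m: int) -> None:
        if m * (self.p1 + self.p2 + self.p12) >= 1:
            warnings.warn(
                f"locus of {m} variants makes per-locus prior mass >= 1; "
                "priors are likely too large for this locus size"
            )


@dataclass(frozen=True)
class AbfParams:
    prior_sd_quant: float = 0.15  # per-SD effect prior, quantitative trait
    prior_sd_cc: float = 0.2  # log-odds effect prior, case-control trait

    def __post_init__(self):
        if self.prior_sd_quant <= 0 or self.prior_sd_cc <= 0:
            raise ValueError("prior SDs must be positive")


@dataclass(frozen=True)
class ColocResult:
    pp: tuple  # (PP.H0, ..., PP.H4)
    n_snps: int
    labf1: tuple
    labf2: tuple
    priors: ColocPriors
    window_kb: Optional[int] = None
    gene: str = ""
    layer: str = ""
    phenotype: str = ""
    low_coverage: bool = False

    def __post_init__(self):
        if abs(sum(self.pp) - 1.0) > 1e-12:
            raise ValueError("posterior probabilities must sum to 1")
        if any(not (0.0 <= x <= 1.0) for x in self.pp):
            raise ValueError("posterior probabilities must lie in [0, 1]")

    @property
    def pp_h4(self) -> float:
        return self.pp[4]

    @property
    def strong_colocalization(self) -> bool:
        return self.pp[4] > STRONG_H4

    def as_dict(self) -> dict:
        out = dict(zip(HYPOTHESES, self.pp))
        out.update(
            n_snps=self.n_snps,
            gene=self.gene,
            layer=self.layer,
            phenotype=self.phenotype,
            window_kb=self.window_kb,
            strong_coloc=self.strong_colocalization,
            low_coverage=self.low_coverage,
        )
        return out


def wakefield_labf(beta, se, prior_sd: float):
    """Wakefield log approximate Bayes factor (vectorized over beta/se)."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("se must be positive")
    V = se**2
    W = prior_sd**2
    r = W / (V + W)
    z = beta / se
    return 0.5 * (np.log1p(-r) + r * z**2)


def coloc_posteriors(
    labf1: Sequence[float],
    labf2: Sequence[float],
    priors: ColocPriors = ColocPriors(),
    **result_fields,
) -> ColocResult:
    """Posterior probabilities of H0-H4 from per-variant log-ABF vectors.

    All sums run in log space: with L1 = logsum(labf1), L2 = logsum(labf2)
    and L12 = logsum(labf1 + labf2), the unnormalized log weights are

        H0: 0
        H1: log p1 + L1
        H2: log p2 + L2
        H3: log p1 + log p2 + logsum over pairs i != j of labf1_i + labf2_j
        H4: log p12 + L12

    The H3 cross-product excludes the same-variant diagonal.  It is summed
    directly over the off-diagonal pairs (leave-one-out log-sum-exp) rather
    than as the log-difference logdiff(L1 + L2, L12), which cancels
    catastrophically when a single shared variant dominates both traits.  A
    single-variant locus has PP.H3 = 0 exactly.
    """
    l1 = np.asarray(labf1, dtype=float)
    l2 = np.asarray(labf2, dtype=float)
    if l1.shape != l2.shape or l1.ndim != 1:
        raise ValueError("labf1 and labf2 must be equal-length 1-d vectors")
    m = l1.size
    if m == 0:
        raise ValueError("empty locus")
    priors.check_locus_size(m)
    L1 = float(logsumexp(l1))
    L2 = float(logsumexp(l2))
    L12 = float(logsumexp(l1 + l2))
    if m == 1:
        h3 = -np.inf  # structural zero: no two distinct variants exist
    else:
        cross = l1[:, None] + l2[None, :]
        np.fill_diagonal(cross, -np.inf)
        h3 = float(logsumexp(cross))
    logw = np.array(
        [
            0.0,
            math.log(priors.p1) + L1,
            math.log(priors.p2) + L2,
            math.log(priors.p1) + math.log(priors.p2) + h3,
            math.log(priors.p12) + L12,
        ]
    )
    norm = logsumexp(logw)
    pp = np.exp(logw - norm)
    pp = pp / pp.sum()  # exact renormalization to absorb rounding
    return ColocResult(
        pp=tuple(float(x) for x in pp),
        n_snps=m,
        labf1=tuple(map(float, l1)),
        labf2=tuple(map(float, l2)),
        priors=priors,
        **result_fields,
    )


def coloc_locus(
    qtl_records: Sequence[QtlRecord],
    gwas_records: Sequence[AssocRecord],
    probe_pos: int,
    layer: str,
    priors: ColocPriors = ColocPriors(),
    abf: AbfParams = AbfParams(),
    window_kb: Optional[int] = None,
    gwas_trait_type: str = "cc",
    **result_fields,
) -> ColocResult:
    """Colocalize one molecular trait against the outcome over a cis locus.

    The window half-width defaults by layer (mQTL 500 kb, e/pQTL 1000 kb
    around the probe).  Records must already be harmonized to a common
    allele orientation; variants present for both traits inside the window
    are intersected, the QTL trait uses the quantitative effect prior and the
    GWAS the case-control (log-odds) prior unless ``gwas_trait_type`` is
    ``"quant"``.  Loci with fewer than 25 shared variants carry a
    low-coverage flag rather than an error.
    """
    if window_kb is None:
        window_kb = LAYER_WINDOW_KB[layer]
    half = window_kb * 1000
    qtl_in = {
        r.variant.id: r
        for r in qtl_records
        if abs(r.variant.pos - probe_pos) <= half
    }
    gwas_in = {
        r.variant.id: r
        for r in gwas_records
        if abs(r.variant.pos - probe_pos) <= half
    }
    shared = [vid for vid in qtl_in if vid in gwas_in]
    if not shared:
        raise ValueError("no shared variants in the locus window")
    shared.sort(key=lambda vid: (qtl_in[vid].variant.pos, vid))
    labf1 = wakefield_labf(
        [qtl_in[v].assoc.beta for v in shared],
        [qtl_in[v].assoc.se for v in shared],
        abf.prior_sd_quant,
    )
    gwas_sd = abf.prior_sd_cc if gwas_trait_type == "cc" else abf.prior_sd_quant
    labf2 = wakefield_labf(
        [gwas_in[v].beta for v in shared],
        [gwas_in[v].se for v in shared],
        gwas_sd,
    )
    return coloc_posteriors(
        labf1,
        labf2,
        priors,
        window_kb=window_kb,
        layer=layer,
        low_coverage=len(shared) < MIN_LOCUS_SNPS,
        **result_fields,
    )
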