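"""Instrument quality control and exposure/outcome harmonization.

Implements the six-step QC funnel applied to candidate cis instruments before
SMR, plus the LD clumping used to select independent mQTL instruments:

1.  cis-region selection: variants within a closed +/- window of the gene.
2.  significance: p < 5e-8 for mQTL/eQTL, p < 1.8e-9 for pQTL (strict "<").
3.  LD clumping (mQTL by default): greedy p-ordered index selection removing
    variants within clump_kb and with r^2 > clump_r2 (defaults 10,000 kb and
    0.001), then LD pruning for all layers excluding r^2 > 0.9.
4.  weak-instrument removal: single-SNP F = (beta/se)^2; F < 10 removed.
5.  allele-frequency concordance: drop when any pairwise EAF difference among
    {LD reference, QTL, GWAS} exceeds 0.2.
6.  harmonization: align outcome effect alleles (and sizes) to the exposure
    orientation; palindromic variants with ambiguous frequency are dropped.

Each dropped record carries exactly one :class:`DropReason`; the per-stage
funnel is returned so survivor counts can be audited.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

from .sumstats import (
    COMPLEMENT,
    AssocRecord,
    LdPanel,
    QtlRecord,
    UndefinedLdError,
    Variant,
)

logger = logging.getLogger(__name__)

__all__ = [
    "QcConfig",
    "DropReason",
    "HarmonizedPair",
    "QcFunnel",
    "select_cis",
    "filter_significance",
    "clump",
    "prune",
    "filter_weak",
    "harmonize",
    "filter_af_concordance",
    "run_qc",
]


@dataclass(frozen=True)
class QcConfig:
    cis_window_kb: int = 1000
    p_threshold_meqtl: float = 5e-8
    p_threshold_pqtl: float = 1.8e-9
    prune_r2: float = 0.9
    f_min: float = 10.0
    af_max_diff: float = 0.2
    clump_kb: int = 10_000
    clump_r2: float = 0.001
    palindromic_eaf_band: tuple = (0.42, 0.58)
    clump_layers: tuple = ("mQTL",)  # layers that get the clumping step

    def __post_init__(self):
        positive = (
            self.cis_window_kb,
            self.p_threshold_meqtl,
            self.p_threshold_pqtl,
            self.prune_r2,
            self.f_min,
            self.af_max_diff,
            self.clump_kb,
            self.clump_r2,
        )
        if any(x <= 0 for x in positive):
            raise ValueError("all QC thresholds must be positive")
        if not self.clump_r2 < self.prune_r2:
            raise ValueError("clump_r2 must be below prune_r2")

    def p_threshold(self, layer: str) -> float:
        return self.p_threshold_pqtl if layer == "pQTL" else self.p_threshold_meqtl


class DropReason(enum.Enum):
    allele_mismatch = "allele_mismatch"
    palindromic_ambiguous = "palindromic_ambiguous"
    af_discordant = "af_discordant"
    af_missing = "af_missing"
    weak_instrument = "weak_instrument"
    not_cis = "not_cis"
    not_significant = "not_significant"
    pruned = "pruned"
    no_outcome_match = "no_outcome_match"
    no_reference_ld = "no_reference_ld"


@dataclass(frozen=True)
class HarmonizedPair:
    """An exposure instrument with its outcome association on the same
    variant, oriented to the exposure's effect allele."""

    exposure: QtlRecord
    outcome: Optional[AssocRecord]
    flipped: bool = False
    dropped_reason: Optional[DropReason] = None

    def __post_init__(self):
        if self.dropped_reason is None:
            if self.outcome is None:
                raise ValueError("surviving pair must carry an outcome record")
            ve, vo = self.exposure.variant, self.outcome.variant
            if ve.id != vo.id or (ve.a1, ve.a2) != (vo.a1, vo.a2):
                raise ValueError(
                    f"{ve.id}: surviving pair is not allele-aligned"
                )

    @property
    def dropped(self) -> bool:
        return self.dropped_reason is not None


@dataclass
class QcFunnel:
    """Per-stage survivor counts and per-reason drop tallies."""

    stages: list = field(default_factory=list)  # (stage, n_in, n_out)
    reasons: dict = field(default_factory=dict)  # DropReason -> count

    def record(self, stage: str, n_in: int, n_out: int, reason: DropReason):
        self.stages.append((stage, n_in, n_out))
        if n_in != n_out:
            self.reasons[reason] = self.reasons.get(reason, 0) + (n_in - n_out)

    def total_dropped(self) -> int:
        return sum(self.reasons.values())


# ---------------------------------------------------------------------------
# Individual QC steps
# ---------------------------------------------------------------------------


def select_cis(
    qtls: Iterable[QtlRecord],
    gene_pos: int,
    window_kb: int = 1000,
    gene_chrom: Optional[str] = None,
) -> list:
    """Keep records with |pos - gene_pos| <= window_kb*1000 (closed interval).

    Records on a different chromosome than ``gene_chrom`` (when given) are
    excluded with a logged diagnostic.
    """
    out = []
    half = window_kb * 1000
    for rec in qtls:
        v = rec.variant
        if gene_chrom is not None and v.chrom != gene_chrom:
            logger.debug("select_cis: %s on chr%s, gene on chr%s — excluded",
                         v.id, v.chrom, gene_chrom)
            continue
        if abs(v.pos - gene_pos) <= half:
            out.append(rec)
    return out


def filter_significance(
    records: Iterable[QtlRecord], layer: str, config: QcConfig = QcConfig()
) -> list:
    """Strict p < threshold: 5e-8 for mQTL/eQTL, 1.8e-9 for pQTL."""
    thr = config.p_threshold(layer)
    return [r for r in records if r.assoc.p < thr]


def _sorted_by_p(records: Sequence[QtlRecord]) -> list:
    # ties on p broken by position then id, so output is order-invariant
    return sorted(records, key=lambda r: (r.assoc.p, r.variant.pos, r.variant.id))


def clump(
    records: Sequence[QtlRecord],
    panel: LdPanel,
    clump_kb: Optional[int] = 10_000,
    clump_r2: float = 0.001,
) -> list:
    """Greedy p-value-ordered clumping.

    Repeatedly take the smallest-p remaining record as an index and remove
    records within ``clump_kb``*1000 bp **and** with r^2 > ``clump_r2`` to it.
    ``clump_kb=None`` disables the distance condition (pure LD pruning).
    A pair with undefined reference LD is conservatively treated as r^2 = 1
    (removed) with a warning.
    """
    remaining = _sorted_by_p(records)
    kept = []
    half = None if clump_kb is None else clump_kb * 1000
    while remaining:
        index = remaining.pop(0)
        kept.append(index)
        survivors = []
        for rec in remaining:
            near = half is None or abs(rec.variant.pos - index.variant.pos) <= half
            if not near or rec.variant.chrom != index.variant.chrom:
                survivors.append(rec)
                continue
            try:
                r2 = panel.r2(index.variant.id, rec.variant.id)
            except (UndefinedLdError, KeyError):
                warnings.warn(
                    f"undefined reference LD for ({index.variant.id}, "
                    f"{rec.variant.id}); treating as r2=1"
                )
                r2 = 1.0
            if r2 > clump_r2:
                continue  # clumped away
            survivors.append(rec)
        remaining = survivors
    return kept


def prune(
    records: Sequence[QtlRecord], panel: LdPanel, prune_r2: float = 0.9
) -> list:
    """Exclude variants in strong LD (r^2 > prune_r2) with a better instrument;
    greedy in p-value order with no distance condition."""
    return clump(records, panel, clump_kb=None, clump_r2=prune_r2)


def filter_weak(records: Iterable[QtlRecord], f_min: float = 10.0) -> list:
    """Single-instrument F = (beta/se)^2; keep F >= f_min (F < 10 removed)."""
    return [r for r in records if (r.assoc.beta / r.assoc.se) ** 2 >= f_min]


def _oriented(variant: Variant, a1: str, a2: str):
    """How (a1, a2) relates to variant's alleles: 'same', 'swapped', or None.

    Strand complements are resolved first, so e.g. outcome C/T matches
    exposure G/A as 'same' after complementing.
    """
    if (a1, a2) == (variant.a1, variant.a2):
        return "same"
    if (a1, a2) == (variant.a2, variant.a1):
        return "swapped"
    ca1, ca2 = COMPLEMENT[a1], COMPLEMENT[a2]
    if (ca1, ca2) == (variant.a1, variant.a2):
        return "same"
    if (ca1, ca2) == (variant.a2, variant.a1):
        return "swapped"
    return None


def harmonize(
    exposure: QtlRecord,
    outcome: AssocRecord,
    palindromic_eaf_band: tuple = (0.42, 0.58),
) -> HarmonizedPair:
    """Align the outcome record to the exposure's effect-allele orientation.

    If the outcome's alleles are swapped relative to the exposure (directly or
    after strand complementing), the outcome beta is negated and its EAF
    replaced by 1 - EAF.  Palindromic variants (A/T, C/G) whose EAF falls in
    the ambiguity band on either side are dropped; outside the band their
    orientation is resolved by frequency agreement.  SE and p are never
    altered.
    """
    ve, vo = exposure.variant, outcome.variant
    if ve.id != vo.id:
        raise ValueError(f"variant ids differ: {ve.id} vs {vo.id}")
    lo, hi = palindromic_eaf_band
    if ve.is_palindromic or vo.is_palindromic:
        for eaf in (ve.eaf, vo.eaf):
            if np.isnan(eaf) or lo <= eaf <= hi:
                return HarmonizedPair(
                    exposure, None,
                    dropped_reason=DropReason.palindromic_ambiguous,
                )
        # both informative: same strand orientation iff frequencies agree in side
        same_side = (ve.eaf < 0.5) == (vo.eaf < 0.5)
        orientation = "same" if same_side else "swapped"
        if {vo.a1, vo.a2} != {ve.a1, ve.a2} and \
                {COMPLEMENT[vo.a1], COMPLEMENT[vo.a2]} != {ve.a1, ve.a2}:
            return HarmonizedPair(
                exposure, None, dropped_reason=DropReason.allele_mismatch
            )
    else:
        orientation = _oriented(ve, vo.a1, vo.a2)
        if orientation is None:
            return HarmonizedPair(
                exposure, None, dropped_reason=DropReason.allele_mismatch
            )
    if orientation == "same":
        aligned = replace(
            outcome, variant=replace(vo, a1=ve.a1, a2=ve.a2, eaf=vo.eaf)
        )
        return HarmonizedPair(exposure, aligned, flipped=False)
    aligned = replace(
        outcome,
        beta=-outcome.beta,
        variant=replace(vo, a1=ve.a1, a2=ve.a2, eaf=1.0 - vo.eaf),
    )
    return HarmonizedPair(exposure, aligned, flipped=True)


def filter_af_concordance(
    pair: HarmonizedPair, panel: LdPanel, af_max_diff: float = 0.2
) -> HarmonizedPair:
    """Drop when any pairwise EAF difference among {reference, exposure,
    outcome} strictly exceeds ``af_max_diff`` (a difference of exactly 0.2 is
    kept); a missing EAF in any source is its own drop reason."""
    if pair.dropped:
        return pair
    vid = pair.exposure.variant.id
    ref_eaf = panel.eaf(vid) if vid in panel else np.nan
    eafs = (ref_eaf, pair.exposure.variant.eaf, pair.outcome.variant.eaf)
    if any(np.isnan(e) for e in eafs):
        return replace(pair, dropped_reason=DropReason.af_missing)
    if max(eafs) - min(eafs) > af_max_diff:
        return replace(pair, dropped_reason=DropReason.af_discordant)
    return pair


# ---------------------------------------------------------------------------
# The full funnel
# ---------------------------------------------------------------------------


def run_qc(
    qtls: Sequence[QtlRecord],
    gwas: Sequence[AssocRecord],
    panel: LdPanel,
    gene_pos: int,
    layer: str,
    config: QcConfig = QcConfig(),
    gene_chrom: Optional[str] = None,
):
    """Run the full QC funnel for one probe/gene and one outcome.

    Order: cis window -> layer significance -> clumping (configured layers)
    -> r^2 > 0.9 pruning -> weak-instrument filter -> harmonization ->
    allele-frequency concordance.

    Returns ``(pairs, funnel)`` where ``pairs`` are the surviving
    :class:`HarmonizedPair` instruments and ``funnel`` audits every stage.
    """
    funnel = QcFunnel()
    dropped_pairs = []

    def drop_all(records, reason):
        for rec in records:
            logger.debug("qc drop %s: %s", reason.value, rec.variant.id)
            dropped_pairs.append(
                HarmonizedPair(rec, None, dropped_reason=reason)
            )

    n0 = len(qtls)
    cis = select_cis(qtls, gene_pos, config.cis_window_kb, gene_chrom)
    drop_all([r for r in qtls if r not in cis], DropReason.not_cis)
    funnel.record("cis_window", n0, len(cis), DropReason.not_cis)

    sig = filter_significance(cis, layer, config)
    drop_all([r for r in cis if r not in sig], DropReason.not_significant)
    funnel.record("significance", len(cis), len(sig), DropReason.not_significant)

    if layer in config.clump_layers:
        clumped = clump(sig, panel, config.clump_kb, config.clump_r2)
    else:
        clumped = list(sig)
    drop_all([r for r in sig if r not in clumped], DropReason.pruned)
    funnel.record("clump", len(sig), len(clumped), DropReason.pruned)

    pruned = prune(clumped, panel, config.prune_r2)
    drop_all([r for r in clumped if r not in pruned], DropReason.pruned)
    funnel.record("prune", len(clumped), len(pruned), DropReason.pruned)

    strong = filter_weak(pruned, config.f_min)
    drop_all([r for r in pruned if r not in strong], DropReason.weak_instrument)
    funnel.record("weak_instrument", len(pruned), len(strong),
                  DropReason.weak_instrument)

    outcome_by_id = {rec.variant.id: rec for rec in gwas}
    matched, unmatched = [], []
    for rec in strong:
        (matched if rec.variant.id in outcome_by_id else unmatched).append(rec)
    drop_all(unmatched, DropReason.no_outcome_match)
    funnel.record("outcome_match", len(strong), len(matched),
                  DropReason.no_outcome_match)

    harmonized = [
        harmonize(rec, outcome_by_id[rec.variant.id], config.palindromic_eaf_band)
        for rec in matched
    ]
    surviving = [p for p in harmonized if not p.dropped]
    for p in harmonized:
        if p.dropped:
            dropped_pairs.append(p)
            funnel.reasons[p.dropped_reason] = (
                funnel.reasons.get(p.dropped_reason, 0) + 1
            )
    funnel.stages.append(("harmonize", len(matched), len(surviving)))

    checked = [
        filter_af_concordance(p, panel, config.af_max_diff) for p in surviving
    ]
    final = [p for p in checked if not p.dropped]
    for p in checked:
        if p.dropped:
            dropped_pairs.append(p)
            funnel.reasons[p.dropped_reason] = (
                funnel.reasons.get(p.dropped_reason, 0) + 1
            )
    funnel.stages.append(("af_concordance", len(surviving), len(final)))

    assert funnel.total_dropped() == n0 - len(final)
    return final, funnel
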