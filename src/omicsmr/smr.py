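"""Summary-data Mendelian randomization (Wald ratio) and the HEIDI test.

SMR estimates the causal effect of a molecular exposure on an outcome from
two independent sets of summary statistics through a single genetic
instrument: b_smr = beta_outcome / beta_exposure at the top cis SNP.  The
test statistic is

    T_SMR = z_exp^2 * z_out^2 / (z_exp^2 + z_out^2)  ~  chi^2_1,

and the delta-method standard error is |b_smr| / sqrt(T_SMR).

HEIDI (heterogeneity in dependent instruments) asks whether the Wald ratios
at SNPs in LD with the top instrument are homogeneous.  Under a single
shared causal variant all ratios estimate the same quantity; under linkage
(two distinct causal variants) they diverge.  The statistic sums the squared
standardized differences d_i = b_xy(i) - b_xy(top), whose covariance is
assembled by the first-order delta method from the reference-panel LD
correlations (exposure and outcome samples are independent, so no
cross-trait covariance term arises).  The null distribution, a weighted sum
of chi-square(1) variables with weights equal to the eigenvalues of the
correlation matrix of d, is approximated by the Satterthwaite two-moment
scaled chi-square.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .qc import HarmonizedPair
from .sumstats import LdPanel, UndefinedLdError

__all__ = [
    "HeidiConfig",
    "SmrResult",
    "smr_test",
    "select_heidi_snps",
    "heidi_test",
    "heidi_test_arrays",
    "smr_analysis",
]


@dataclass(frozen=True)
class HeidiConfig:
    r2_min: float = 0.05
    r2_max: float = 0.9
    exposure_p_max: float = 1.57e-3
    max_snps: int = 20
    min_snps: int = 3
    ridge: float = 1e-8  # diagonal regularization before eigendecomposition
    eig_floor: float = 1e-10  # eigenvalues below this are discarded

    def __post_init__(self):
        if not self.r2_min < self.r2_max:
            raise ValueError("r2_min must be below r2_max")


@dataclass(frozen=True)
class SmrResult:
    """Per probe x outcome SMR/HEIDI summary."""

    probe_id: str
    gene: str
    layer: str
    top_snp: str
    b_smr: float
    se_smr: float
    p_smr: float
    p_heidi: Optional[float]  # None = not evaluable
    n_heidi_snps: int
    phenotype: str = ""

    @property
    def or_smr(self) -> float:
        return math.exp(self.b_smr)

    def heidi_pass(self, alpha: float = 0.05, strict: bool = False) -> bool:
        """p_HEIDI > alpha; a not-evaluable HEIDI passes unless ``strict``."""
        if self.p_heidi is None:
            return not strict
        return self.p_heidi > alpha


def smr_test(b_exp: float, se_exp: float, b_out: float, se_out: float):
    """Wald-ratio estimate, its delta-method SE, and the 1-df chi-square p.

    Returns ``(b_smr, se_smr, p_smr)``.  A zero outcome effect gives
    b_smr = 0, T = 0, p = 1; a zero exposure effect is an error (QC
    guarantees a genome-wide-significant instrument).
    """
    if b_exp == 0:
        raise ZeroDivisionError("exposure effect is zero; Wald ratio undefined")
    b_smr = b_out / b_exp
    z_exp, z_out = b_exp / se_exp, b_out / se_out
    denom = z_exp**2 + z_out**2
    t_smr = (z_exp**2 * z_out**2) / denom if denom > 0 else 0.0
    p_smr = float(stats.chi2.sf(t_smr, df=1))
    se_smr = abs(b_smr) / math.sqrt(t_smr) if t_smr > 0 else float("inf")
    return b_smr, se_smr, p_smr


def select_heidi_snps(
    pairs: Sequence[HarmonizedPair],
    top: HarmonizedPair,
    panel: LdPanel,
    config: HeidiConfig = HeidiConfig(),
) -> Optional[list]:
    """Pick the dependent instruments for HEIDI.

    Candidates must pass the exposure significance cap (p < exposure_p_max)
    and have reference r^2 to the top SNP inside [r2_min, r2_max]; they are
    ranked by descending r^2 and truncated at max_snps.  Returns None
    (not evaluable) when fewer than min_snps qualify.
    """
    top_id = top.exposure.variant.id
    if top_id not in panel:
        raise KeyError(f"top SNP {top_id} absent from LD panel")
    scored = []
    for pair in pairs:
        vid = pair.exposure.variant.id
        if vid == top_id or pair.exposure.assoc.p >= config.exposure_p_max:
            continue
        try:
            r2 = panel.r2(top_id, vid)
        except (UndefinedLdError, KeyError):
            continue
        if config.r2_min <= r2 <= config.r2_max:
            scored.append((r2, vid, pair))
    scored.sort(key=lambda t: (-t[0], t[1]))
    selected = [pair for _, _, pair in scored[: config.max_snps]]
    if len(selected) < config.min_snps:
        return None
    return selected


def heidi_test_arrays(
    b_exp: np.ndarray,
    se_exp: np.ndarray,
    b_out: np.ndarray,
    se_out: np.ndarray,
    R: np.ndarray,
    config: HeidiConfig = HeidiConfig(),
) -> Optional[float]:
    """HEIDI p-value from aligned arrays; index 0 is the top SNP.

    ``R`` is the signed LD correlation matrix over [top] + candidates.
    Returns None when the covariance of d is not usable after
    regularization.
    """
    b_exp = np.asarray(b_exp, dtype=float)
    se_exp = np.asarray(se_exp, dtype=float)
    b_out = np.asarray(b_out, dtype=float)
    se_out = np.asarray(se_out, dtype=float)
    m = b_exp.size
    if m < 2:
        return None
    b_xy = b_out / b_exp
    # delta-method covariance of the Wald ratios (independent samples):
    # cov(b_xy_i, b_xy_j) = r_ij se_out_i se_out_j / (b_exp_i b_exp_j)
    #                     + b_xy_i b_xy_j r_ij se_exp_i se_exp_j / (b_exp_i b_exp_j)
    be_outer = np.outer(b_exp, b_exp)
    C = R * np.outer(se_out, se_out) / be_outer + (
        np.outer(b_xy, b_xy) * R * np.outer(se_exp, se_exp) / be_outer
    )
    # inclusion-exclusion for d_i = b_xy(i) - b_xy(top), i >= 1
    d = b_xy[1:] - b_xy[0]
    Cd = C[1:, 1:] - C[1:, [0]] - C[[0], 1:] + C[0, 0]
    Cd = Cd + config.ridge * np.eye(m - 1)
    var_d = np.diag(Cd)
    if np.any(var_d <= 0) or not np.all(np.isfinite(Cd)):
        return None
    sd = np.sqrt(var_d)
    t_heidi = float(np.sum((d / sd) ** 2))
    corr = Cd / np.outer(sd, sd)
    eigvals = np.linalg.eigvalsh((corr + corr.T) / 2.0)
    eigvals = eigvals[eigvals > config.eig_floor]
    if eigvals.size == 0:
        return None
    s1, s2 = eigvals.sum(), float(np.sum(eigvals**2))
    scale = s2 / s1  # Satterthwaite: T/scale ~ chi^2_df
    df = s1**2 / s2
    p = float(stats.chi2.sf(t_heidi / scale, df=df))
    return min(max(p, np.nextafter(0, 1)), 1.0)


def heidi_test(
    top: HarmonizedPair,
    candidates: Sequence[HarmonizedPair],
    panel: LdPanel,
    config: HeidiConfig = HeidiConfig(),
) -> Optional[float]:
    """HEIDI p-value for a top instrument and its dependent candidates."""
    ordered = [top] + list(candidates)
    ids = [p.exposure.variant.id for p in ordered]
    R = panel.corr_matrix(ids)
    return heidi_test_arrays(
        np.array([p.exposure.assoc.beta for p in ordered]),
        np.array([p.exposure.assoc.se for p in ordered]),
        np.array([p.outcome.beta for p in ordered]),
        np.array([p.outcome.se for p in ordered]),
        R,
        config,
    )


def smr_analysis(
    pairs: Sequence[HarmonizedPair],
    panel: LdPanel,
    config: HeidiConfig = HeidiConfig(),
    cis_pairs: Optional[Sequence[HarmonizedPair]] = None,
    phenotype: str = "",
) -> SmrResult:
    """Full SMR + HEIDI for one probe.

    ``pairs`` are the QC-surviving instruments; the one with the smallest
    exposure p becomes the top SNP.  ``cis_pairs`` (default: ``pairs``) is
    the wider harmonized cis set from which HEIDI candidates are drawn —
    HEIDI deliberately uses SNPs in LD with the top instrument, which
    clumping would have removed from the instrument list.
    """
    if not pairs:
        raise ValueError("no surviving instruments")
    pool = list(cis_pairs) if cis_pairs is not None else list(pairs)
    top = min(
        pairs,
        key=lambda p: (p.exposure.assoc.p, p.exposure.variant.pos,
                       p.exposure.variant.id),
    )
    e, o = top.exposure.assoc, top.outcome
    b_smr, se_smr, p_smr = smr_test(e.beta, e.se, o.beta, o.se)
    candidates = select_heidi_snps(pool, top, panel, config)
    if candidates is None:
        p_heidi, n_heidi = None, 0
    else:
        p_heidi = heidi_test(top, candidates, panel, config)
        n_heidi = len(candidates) if p_heidi is not None else 0
    return SmrResult(
        probe_id=top.exposure.probe_id,
        gene=top.exposure.gene,
        layer=top.exposure.layer,
        top_snp=top.exposure.variant.id,
        b_smr=b_smr,
        se_smr=se_smr,
        p_smr=p_smr,
        p_heidi=p_heidi,
        n_heidi_snps=n_heidi,
        phenotype=phenotype,
    )
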