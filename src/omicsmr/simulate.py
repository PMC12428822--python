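"""Synthetic LD panels and QTL/GWAS summary statistics under H0-H4 scenarios.

The generator emulates the statistical structure of the real inputs the
pipeline was designed for — cis-window molecular QTL associations (CpG
methylation probes, transcripts, plasma proteins) and case-control GWAS of
binary pain phenotypes — without any external download:

* Genotypes are drawn as two haplotypes per individual.  Each haplotype comes
  from a latent Gaussian AR(1) process along the locus (correlation
  ``ld_rho``, optionally per-adjacent-pair), thresholded at the quantile that
  yields each variant's target allele frequency.  This gives direct control
  of MAF and LD decay, which is all the downstream statistics consume.
* Exposure (molecular trait) and outcome (disease) samples are *independent*
  draws from the same generative law — never the reference panel itself —
  matching the two-sample design with no sample overlap.
* Summary statistics are produced by actual marginal per-variant regressions
  on the simulated individuals (linear for molecular traits, logistic score
  test for the binary outcome), so finite-sample noise is realistic.

The five generative hypotheses mirror colocalization's H0-H4: no causal
variant (H0), exposure-only (H1), outcome-only (H2), two distinct causal
variants (H3), one shared causal variant (H4).

Seeds: per-component generators are derived from the master seed by fixed
offsets (law +0, panel +1, exposure +2, outcome +3, modulo 2^31), so each
stage can be regenerated independently and bundles are byte-identical under
the same seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, special, stats

from .sumstats import AssocRecord, LdPanel, QtlRecord, Variant

__all__ = [
    "ScenarioConfig",
    "GeneSpec",
    "StudyConfig",
    "StudyBundle",
    "simulate_panel",
    "simulate_exposure_sumstats",
    "simulate_outcome_sumstats",
    "simulate_multiomics_study",
    "default_study_config",
    "exposure_marginals",
    "outcome_marginals",
]

HYPOTHESES = ("H0", "H1", "H2", "H3", "H4")

_SEED_MOD = 2**31
_OFF_LAW, _OFF_PANEL, _OFF_EXPOSURE, _OFF_OUTCOME = 0, 1, 2, 3

# non-palindromic allele partners: a2 may not be the strand complement of a1
_ALLELE_PARTNERS = {"A": ("C", "G"), "C": ("A", "T"), "G": ("A", "T"), "T": ("C", "G")}


class ConfigError(ValueError):
    """Invalid generative configuration."""


@dataclass(frozen=True)
class ScenarioConfig:
    """Generative specification for one cis locus.

    Defaults are desk-scale stand-ins for the study's data sources: a
    methylation-panel-sized exposure cohort, a biobank-style common binary
    outcome, and a common-variant cis locus with moderate LD decay.
    """

    m_variants: int = 60
    maf_range: tuple = (0.15, 0.45)
    ld_rho: object = 0.8  # scalar, or sequence of length m_variants - 1
    n_ref: int = 4000
    n_exposure: int = 1980
    n_outcome: int = 20000
    hypothesis: str = "H4"
    causal_idx_exposure: Optional[int] = None
    causal_idx_outcome: Optional[int] = None
    var_explained_exposure: float = 0.10
    outcome_prevalence: float = 0.25
    outcome_log_or: float = 0.35
    n_probes_per_gene: int = 1
    seed: int = 0
    # the locus law (frequencies, alleles, positions, LD) is drawn from
    # law_seed when set, so several cohorts can share one locus while their
    # sample draws (seed + offsets) differ; defaults to seed
    law_seed: Optional[int] = None
    # locus layout / identity (cosmetic; positions are build-agnostic)
    gene: str = "GENE1"
    layer: str = "eQTL"
    chrom: str = "1"
    locus_start: int = 1_000_000
    spacing_bp: int = 2_000
    variant_prefix: str = "rs"
    outcome_method: str = "score"  # or "logistic"

    def __post_init__(self):
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if self.hypothesis not in HYPOTHESES:
            raise ConfigError(f"hypothesis must be one of {HYPOTHESES}")
        if min(self.n_ref, self.n_exposure, self.n_outcome) < 2:
            raise ConfigError("all sample sizes must be >= 2")
        if self.m_variants < 1:
            raise ConfigError("m_variants must be >= 1")
        if not (0.0 < self.var_explained_exposure < 1.0):
            raise ConfigError("var_explained_exposure must be in (0, 1)")
        if not (0.0 < self.outcome_prevalence < 1.0):
            raise ConfigError("outcome_prevalence must be in (0, 1)")
        if self.n_probes_per_gene < 1:
            raise ConfigError("n_probes_per_gene must be >= 1")
        rho = np.atleast_1d(np.asarray(self.ld_rho, dtype=float))
        if np.any(rho < 0.0) or np.any(rho >= 1.0):
            raise ConfigError("ld_rho values must lie in [0, 1)")
        if rho.size not in (1, max(self.m_variants - 1, 1)):
            raise ConfigError("ld_rho must be scalar or have length m_variants - 1")
        e, o = self.causal_idx_exposure, self.causal_idx_outcome
        h = self.hypothesis
        if h == "H0" and (e is not None or o is not None):
            raise ConfigError("H0 admits no causal variant")
        if h == "H1" and (e is None or o is not None):
            raise ConfigError("H1 needs an exposure causal variant only")
        if h == "H2" and (o is None or e is not None):
            raise ConfigError("H2 needs an outcome causal variant only")
        if h == "H3" and (e is None or o is None or e == o):
            raise ConfigError("H3 needs distinct exposure and outcome causal variants")
        if h == "H4" and (e is None or o is None or e != o):
            raise ConfigError("H4 needs a single shared causal variant")
        for idx in (e, o):
            if idx is not None and not (0 <= idx < self.m_variants):
                raise ConfigError(f"causal index {idx} out of range")
        if h in ("H2", "H3", "H4"):
            if self.outcome_prevalence * self.n_outcome < 50:
                raise ConfigError(
                    "expected case count below 50; outcome scenario degenerate"
                )

    @property
    def probe_pos(self) -> int:
        return self.locus_start + (self.m_variants // 2) * self.spacing_bp

    def component_seed(self, offset: int) -> int:
        if offset == _OFF_LAW and self.law_seed is not None:
            return self.law_seed % _SEED_MOD
        return (self.seed + offset) % _SEED_MOD


# ---------------------------------------------------------------------------
# Locus law: frequencies, alleles, positions (shared by panel and samples)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _LocusLaw:
    freqs: np.ndarray  # target effect-allele frequencies
    thresholds: np.ndarray  # latent-Gaussian quantiles Phi^-1(freq)
    rho: np.ndarray  # AR(1) correlations, length m-1
    variants: tuple  # Variant templates (eaf = target frequency)


def _locus_law(config: ScenarioConfig) -> _LocusLaw:
    rng = np.random.default_rng(config.component_seed(_OFF_LAW))
    m = config.m_variants
    lo, hi = config.maf_range
    freqs = rng.uniform(lo, hi, size=m)
    rho = np.broadcast_to(
        np.atleast_1d(np.asarray(config.ld_rho, dtype=float)), (max(m - 1, 1),)
    ).copy()
    a1s = rng.choice(list("ACGT"), size=m)
    variants = []
    for j in range(m):
        a1 = str(a1s[j])
        a2 = _ALLELE_PARTNERS[a1][rng.integers(2)]
        variants.append(
            Variant(
                id=f"{config.variant_prefix}{j + 1}",
                chrom=config.chrom,
                pos=config.locus_start + j * config.spacing_bp,
                a1=a1,
                a2=a2,
                eaf=float(freqs[j]),
            )
        )
    return _LocusLaw(
        freqs=freqs,
        thresholds=stats.norm.ppf(freqs),
        rho=rho,
        variants=tuple(variants),
    )


def _draw_dosages(law: _LocusLaw, n: int, rng: np.random.Generator) -> np.ndarray:
    """n individuals x m variants dosage matrix from the two-haplotype model."""
    m = law.freqs.size
    dosage = np.zeros((n, m))
    scale = np.sqrt(1.0 - law.rho**2)
    for _ in range(2):  # two haplotypes
        z = np.empty((n, m))
        z[:, 0] = rng.standard_normal(n)
        innov = rng.standard_normal((n, max(m - 1, 0)))
        for j in range(1, m):
            z[:, j] = law.rho[j - 1] * z[:, j - 1] + scale[j - 1] * innov[:, j - 1]
        dosage += z < law.thresholds
    return dosage


# ---------------------------------------------------------------------------
# Marginal summary statistics
# ---------------------------------------------------------------------------


def _marginal_linear(G: np.ndarray, y: np.ndarray):
    """Per-variant OLS of y on each dosage column; exact t-distribution p."""
    n = y.size
    Gc = G - G.mean(axis=0)
    yc = y - y.mean()
    sgg = np.einsum("ij,ij->j", Gc, Gc)
    sgy = Gc.T @ yc
    syy = float(yc @ yc)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(sgg > 0, sgy / np.where(sgg > 0, sgg, 1.0), 0.0)
        rss = np.maximum(syy - beta * sgy, 0.0)
        sigma2 = rss / max(n - 2, 1)
        se = np.sqrt(np.where(sgg > 0, sigma2 / np.where(sgg > 0, sgg, 1.0), np.inf))
        tstat = np.where(se > 0, beta / se, 0.0)
    p = 2.0 * stats.t.sf(np.abs(tstat), df=max(n - 2, 1))
    return beta, se, np.clip(p, np.nextafter(0, 1), 1.0)


def _marginal_score(G: np.ndarray, y: np.ndarray):
    """Per-variant logistic score test; beta approximated by U/V (log-odds)."""
    ybar = y.mean()
    Gc = G - G.mean(axis=0)
    U = Gc.T @ (y - ybar)
    V = ybar * (1.0 - ybar) * np.einsum("ij,ij->j", Gc, Gc)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(V > 0, U / np.where(V > 0, V, 1.0), 0.0)
        se = np.where(V > 0, 1.0 / np.sqrt(np.where(V > 0, V, 1.0)), np.inf)
        z = np.where(V > 0, U / np.sqrt(np.where(V > 0, V, 1.0)), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return beta, se, np.clip(p, np.nextafter(0, 1), 1.0)


def _marginal_logistic(G: np.ndarray, y: np.ndarray):
    """Per-variant logistic ML fits (slow; for small loci / validation)."""
    import statsmodels.api as sm

    m = G.shape[1]
    beta = np.zeros(m)
    se = np.full(m, np.inf)
    p = np.ones(m)
    for j in range(m):
        x = sm.add_constant(G[:, j])
        try:
            fit = sm.Logit(y, x).fit(disp=0)
            beta[j], se[j], p[j] = fit.params[1], fit.bse[1], fit.pvalues[1]
        except Exception:
            pass
    return beta, se, np.clip(p, np.nextafter(0, 1), 1.0)


# ---------------------------------------------------------------------------
# Public generators
# ---------------------------------------------------------------------------


def simulate_panel(config: ScenarioConfig) -> LdPanel:
    """Draw the LD reference panel (n_ref individuals) for a locus."""
    law = _locus_law(config)
    rng = np.random.default_rng(config.component_seed(_OFF_PANEL))
    dosage = _draw_dosages(law, config.n_ref, rng)
    variants = [replace(v, eaf=float(np.nan)) for v in law.variants]
    return LdPanel(variants, dosage)  # panel fills eaf from its own counts


def _exposure_effect(config: ScenarioConfig, law: _LocusLaw) -> float:
    """Per-allele effect b such that the causal variant explains the target
    fraction of molecular-trait variance (theoretical var(g) = 2f(1-f))."""
    f = law.freqs[config.causal_idx_exposure]
    return math.sqrt(config.var_explained_exposure / (2.0 * f * (1.0 - f)))


def exposure_marginals(config: ScenarioConfig, probe: int = 0):
    """Array-level exposure summary statistics for one probe.

    Returns ``(beta, se, p, eaf)`` over the locus's variants, from a fresh
    genotype sample of ``n_exposure`` individuals.  Probe replicates share
    the genotype sample but have independent trait noise.
    """
    law = _locus_law(config)
    rng = np.random.default_rng(config.component_seed(_OFF_EXPOSURE))
    G = _draw_dosages(law, config.n_exposure, rng)
    has_causal = config.hypothesis in ("H1", "H3", "H4")
    b = _exposure_effect(config, law) if has_causal else 0.0
    noise_sd = math.sqrt(1.0 - config.var_explained_exposure) if has_causal else 1.0
    for _ in range(probe + 1):  # independent noise per probe, deterministic order
        eps = rng.standard_normal(config.n_exposure)
    y = noise_sd * eps
    if has_causal:
        y = y + b * G[:, config.causal_idx_exposure]
    beta, se, p = _marginal_linear(G, y)
    return beta, se, p, G.mean(axis=0) / 2.0


def simulate_exposure_sumstats(config: ScenarioConfig) -> list:
    """QtlRecord list over the locus: one record per variant per probe.

    A fresh exposure-cohort genotype sample is drawn from the locus law (the
    reference panel itself is never reused), the molecular trait is
    ``y = b * g_causal + noise`` under H1/H3/H4 (pure noise under H0/H2), and
    each variant's marginal linear regression supplies beta/se/p.
    """
    law = _locus_law(config)
    rng = np.random.default_rng(config.component_seed(_OFF_EXPOSURE))
    G = _draw_dosages(law, config.n_exposure, rng)
    has_causal = config.hypothesis in ("H1", "H3", "H4")
    b = _exposure_effect(config, law) if has_causal else 0.0
    noise_sd = math.sqrt(1.0 - config.var_explained_exposure) if has_causal else 1.0
    eaf = G.mean(axis=0) / 2.0
    records = []
    for probe in range(config.n_probes_per_gene):
        y = noise_sd * rng.standard_normal(config.n_exposure)
        if has_causal:
            y = y + b * G[:, config.causal_idx_exposure]
        beta, se, p = _marginal_linear(G, y)
        probe_id = (
            config.gene if config.n_probes_per_gene == 1
            else f"{config.gene}_probe{probe + 1}"
        )
        for j, v in enumerate(law.variants):
            if not np.isfinite(se[j]):
                continue  # monomorphic in this sample
            records.append(
                QtlRecord(
                    assoc=AssocRecord(
                        variant=replace(v, eaf=float(eaf[j])),
                        beta=float(beta[j]),
                        se=float(se[j]),
                        p=float(p[j]),
                        n=config.n_exposure,
                    ),
                    probe_id=probe_id,
                    gene=config.gene,
                    layer=config.layer,
                    probe_pos=config.probe_pos,
                )
            )
    return records


def _solve_intercept(prevalence: float, lor: float, g: np.ndarray) -> float:
    def gap(alpha):
        return special.expit(alpha + lor * g).mean() - prevalence

    return optimize.brentq(gap, -30.0, 30.0)


def outcome_marginals(config: ScenarioConfig):
    """Array-level outcome summary statistics ``(beta, se, p, eaf, n_cases)``."""
    law = _locus_law(config)
    rng = np.random.default_rng(config.component_seed(_OFF_OUTCOME))
    G = _draw_dosages(law, config.n_outcome, rng)
    has_causal = config.hypothesis in ("H2", "H3", "H4")
    if has_causal:
        g = G[:, config.causal_idx_outcome]
        alpha = _solve_intercept(config.outcome_prevalence, config.outcome_log_or, g)
        prob = special.expit(alpha + config.outcome_log_or * g)
    else:
        prob = np.full(config.n_outcome, config.outcome_prevalence)
    y = (rng.random(config.n_outcome) < prob).astype(float)
    if config.outcome_method == "logistic":
        beta, se, p = _marginal_logistic(G, y)
    else:
        beta, se, p = _marginal_score(G, y)
    return beta, se, p, G.mean(axis=0) / 2.0, int(y.sum())


def simulate_outcome_sumstats(config: ScenarioConfig) -> list:
    """AssocRecord list for the binary outcome over the locus.

    An independent outcome-cohort sample is drawn; case status follows a
    logistic model whose intercept is solved so the sample-average risk
    matches ``outcome_prevalence``, with ``outcome_log_or`` per effect-allele
    copy at the outcome causal variant (H2/H3/H4).  Marginal statistics use
    the logistic score test by default (``outcome_method="logistic"`` fits
    per-variant ML instead).
    """
    law = _locus_law(config)
    beta, se, p, eaf, _ = outcome_marginals(config)
    records = []
    for j, v in enumerate(law.variants):
        if not np.isfinite(se[j]):
            continue
        records.append(
            AssocRecord(
                variant=replace(v, eaf=float(eaf[j])),
                beta=float(beta[j]),
                se=float(se[j]),
                p=float(p[j]),
                n=config.n_outcome,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Multi-gene, multi-layer study bundles
# ---------------------------------------------------------------------------

LAYER_SAMPLE_SIZES = {"mQTL": 1980, "eQTL": 6000, "pQTL": 6000}
_BACKGROUND_RHO = 0.2
_LINKED_RHO = 0.75  # latent AR(1) at the causal pair -> dosage r^2 ~ 0.2


@dataclass(frozen=True)
class GeneSpec:
    """Architecture of one gene region in a study bundle.

    ``layer_var_explained`` maps each layer with a cis signal to the variance
    explained by its causal variant; layers absent from the mapping have no
    signal.  ``layer_causal_idx`` places each layer's causal variant.
    ``outcome_causal_idx`` (with ``outcome_log_or``) places the disease
    signal; None means the region does not affect the outcome.
    """

    gene: str
    role: str
    layer_var_explained: dict
    layer_causal_idx: dict
    outcome_causal_idx: Optional[int]
    outcome_log_or: float = 0.0
    ld_rho: object = _BACKGROUND_RHO


@dataclass(frozen=True)
class StudyConfig:
    genes: tuple
    phenotypes: tuple = ("synthetic_pain",)
    m_variants: int = 60
    maf_range: tuple = (0.15, 0.45)
    n_ref: int = 4000
    n_outcome: int = 20000
    outcome_prevalence: float = 0.25
    n_probes_mqtl: int = 4
    layer_sample_sizes: dict = field(default_factory=lambda: dict(LAYER_SAMPLE_SIZES))
    seed: int = 0


def default_study_config(
    seed: int = 0, n_true: int = 3, n_decoy: int = 7, **overrides
) -> StudyConfig:
    """The bundled synthetic study: planted true genes vs decoys.

    True genes carry concordant cis signals in all three molecular layers plus
    a disease signal.  One ("shared" role) is driven by a single causal
    variant common to all layers and the outcome — the planted
    shared-causal-variant (H4) locus.  The remaining true genes ("linked"
    role) have the outcome signal at a *distinct* variant in LD r^2 ~ 0.2
    with the molecular causal variant, an architecture that yields a genuine
    SMR association driven by linkage (colocalization resolves it as H3).
    Decoys cover the failure modes the integration stage must reject: no
    disease signal, signals in only a subset of layers, outcome-only signal,
    sub-threshold instruments, or nothing at all.
    """
    if n_true < 0 or n_decoy < 0:
        raise ConfigError("gene counts must be nonnegative")
    m = overrides.get("m_variants", 60)
    center = m // 2
    genes = []
    # spread the per-layer causal variants for decoys so their null SMR
    # p-values are independent across layers (the three-layer convergence
    # filter then admits them with probability ~ 0.05^3)
    spread = {"mQTL": m // 6, "eQTL": center, "pQTL": m - 1 - m // 6}
    all_layers = {"mQTL": 0.10, "eQTL": 0.10, "pQTL": 0.10}
    for t in range(n_true):
        name = f"GENE{t + 1:02d}"
        if t == 0:
            genes.append(
                GeneSpec(
                    gene=name,
                    role="shared",
                    layer_var_explained=dict(all_layers),
                    layer_causal_idx={k: center for k in all_layers},
                    outcome_causal_idx=center,
                    outcome_log_or=0.35,
                )
            )
        else:
            rho = np.full(m - 1, _BACKGROUND_RHO)
            rho[center] = _LINKED_RHO  # couples variants center and center+1
            genes.append(
                GeneSpec(
                    gene=name,
                    role="linked",
                    layer_var_explained=dict(all_layers),
                    layer_causal_idx={k: center for k in all_layers},
                    outcome_causal_idx=center + 1,
                    outcome_log_or=0.45,
                    ld_rho=tuple(rho),
                )
            )
    decoy_roles = [
        ("decoy_no_outcome", dict(all_layers), None, 0.0),
        ("decoy_two_layers", {"mQTL": 0.10, "eQTL": 0.10}, center, 0.35),
        ("decoy_eqtl_only", {"eQTL": 0.10}, None, 0.0),
        ("decoy_null", {}, None, 0.0),
        ("decoy_outcome_only", {}, center, 0.35),
        ("decoy_two_layers_b", {"eQTL": 0.10, "pQTL": 0.10}, None, 0.0),
        ("decoy_weak", {"mQTL": 0.006, "eQTL": 0.002, "pQTL": 0.002}, None, 0.0),
    ]
    for d in range(n_decoy):
        role, layers, out_idx, lor = decoy_roles[d % len(decoy_roles)]
        genes.append(
            GeneSpec(
                gene=f"GENE{n_true + d + 1:02d}",
                role=role,
                layer_var_explained=dict(layers),
                layer_causal_idx={k: spread[k] for k in layers},
                outcome_causal_idx=out_idx,
                outcome_log_or=lor,
            )
        )
    return StudyConfig(genes=tuple(genes), seed=seed % _SEED_MOD, **overrides)


@dataclass
class StudyBundle:
    """In-memory multi-omics study: QTL records per layer, GWAS per phenotype,
    a combined LD panel over all gene regions, and planted-truth metadata."""

    config: StudyConfig
    qtl: dict  # layer -> list[QtlRecord]
    gwas: dict  # phenotype -> list[AssocRecord]
    panel: LdPanel
    gene_table: list  # (gene, chrom, probe_pos)
    truth: dict
    metadata: dict

    def write(self, outdir) -> dict:
        """Write the bundle as the pipeline's text inputs; returns the paths."""
        import json
        from pathlib import Path

        from .sumstats import write_panel, write_sumstats

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for layer, records in self.qtl.items():
            paths[layer] = outdir / f"{layer.lower()}.tsv"
            write_sumstats(records, paths[layer])
        for phen, records in self.gwas.items():
            paths[phen] = outdir / f"gwas_{phen}.tsv"
            write_sumstats(records, paths[phen])
        paths["panel_dosage"] = outdir / "panel.dosage.tsv"
        paths["panel_varmap"] = outdir / "panel.varmap.tsv"
        write_panel(self.panel, paths["panel_dosage"], paths["panel_varmap"])
        paths["genes"] = outdir / "genes.tsv"
        with open(paths["genes"], "w") as fh:
            fh.write("GENE\tCHR\tBP\n")
            for gene, chrom, pos in self.gene_table:
                fh.write(f"{gene}\t{chrom}\t{pos}\n")
        paths["manifest"] = outdir / "scenario_manifest.json"
        with open(paths["manifest"], "w") as fh:
            json.dump(
                {"truth": self.truth, "metadata": self.metadata}, fh, indent=2,
                default=str,
            )
        return paths


def _gene_scenario(
    study: StudyConfig, spec: GeneSpec, region: int, layer: str, **kw
) -> ScenarioConfig:
    """ScenarioConfig for one gene region x one role (exposure layer or outcome)."""
    ve = spec.layer_var_explained.get(layer)
    exp_idx = spec.layer_causal_idx.get(layer)
    out_idx = spec.outcome_causal_idx
    base = dict(
        m_variants=study.m_variants,
        maf_range=study.maf_range,
        ld_rho=spec.ld_rho,
        n_ref=study.n_ref,
        n_outcome=study.n_outcome,
        outcome_prevalence=study.outcome_prevalence,
        outcome_log_or=spec.outcome_log_or,
        gene=spec.gene,
        chrom=str(region + 1),
        variant_prefix=f"rs{region + 1}_",
        # region seed: gene index and layer get fixed sub-offsets; the locus
        # law is shared across layers/outcome/panel via law_seed
        seed=(study.seed + 1000 * (region + 1) + 10 * _layer_code(layer)) % _SEED_MOD,
        law_seed=(study.seed + 1000 * (region + 1)) % _SEED_MOD,
    )
    if layer in ("mQTL", "eQTL", "pQTL"):
        base["layer"] = layer
    base.update(kw)
    if exp_idx is None and out_idx is None:
        hyp = "H0"
    elif exp_idx is None:
        hyp = "H2"
    elif out_idx is None:
        hyp = "H1"
    elif exp_idx == out_idx:
        hyp = "H4"
    else:
        hyp = "H3"
    return ScenarioConfig(
        hypothesis=hyp,
        causal_idx_exposure=exp_idx,
        causal_idx_outcome=out_idx,
        var_explained_exposure=ve if ve is not None else 0.10,
        **base,
    )


def _layer_code(layer: str) -> int:
    return {"mQTL": 1, "eQTL": 2, "pQTL": 3, "GWAS": 4, "panel": 5}[layer]


def simulate_multiomics_study(study: StudyConfig) -> StudyBundle:
    """Generate the full study bundle: per-layer QTL summary statistics for
    every gene region, a case-control GWAS per phenotype over all regions,
    and one combined LD reference panel.

    Gene regions sit on separate chromosomes and are simulated independently
    (valid because unlinked regions contribute independent summary
    statistics).  Exposure, outcome and reference samples within a region are
    independent draws from the region's genotype law.
    """
    qtl = {layer: [] for layer in ("mQTL", "eQTL", "pQTL")}
    gwas = {phen: [] for phen in study.phenotypes}
    panel_variants, panel_columns = [], []
    gene_table, truth_genes = [], {}
    for region, spec in enumerate(study.genes):
        # reference panel slice for this region
        pconf = _gene_scenario(study, spec, region, "panel")
        pan = simulate_panel(pconf)
        panel_variants.extend(pan.variants)
        panel_columns.append(pan.genotypes)
        gene_table.append((spec.gene, pconf.chrom, pconf.probe_pos))
        # exposure layers
        for layer in ("mQTL", "eQTL", "pQTL"):
            if layer not in spec.layer_var_explained:
                continue
            econf = _gene_scenario(
                study,
                spec,
                region,
                layer,
                n_exposure=study.layer_sample_sizes[layer],
                n_probes_per_gene=study.n_probes_mqtl if layer == "mQTL" else 1,
            )
            # exposure-only view: outcome index irrelevant to this draw
            econf = replace(
                econf,
                hypothesis="H1",
                causal_idx_exposure=spec.layer_causal_idx[layer],
                causal_idx_outcome=None,
            )
            qtl[layer].extend(simulate_exposure_sumstats(econf))
        # outcome per phenotype
        for pi, phen in enumerate(study.phenotypes):
            oconf = _gene_scenario(
                study, spec, region, "GWAS", seed=(
                    study.seed + 1000 * (region + 1) + 10 * _layer_code("GWAS") + pi
                ) % _SEED_MOD,
            )
            if spec.outcome_causal_idx is None:
                oconf = replace(
                    oconf, hypothesis="H0", causal_idx_exposure=None,
                    causal_idx_outcome=None,
                )
            else:
                oconf = replace(
                    oconf, hypothesis="H2", causal_idx_exposure=None,
                    causal_idx_outcome=spec.outcome_causal_idx,
                )
            gwas[phen].extend(simulate_outcome_sumstats(oconf))
        truth_genes[spec.gene] = {
            "role": spec.role,
            "integrated_expected": spec.role in ("shared", "linked"),
            "outcome_causal_idx": spec.outcome_causal_idx,
            "layer_causal_idx": dict(spec.layer_causal_idx),
        }
    panel = LdPanel(panel_variants, np.column_stack(panel_columns))
    true_genes = sorted(g for g, t in truth_genes.items() if t["integrated_expected"])
    shared = sorted(
        g for g, t in truth_genes.items() if t["role"] == "shared"
    )
    truth = {
        "true_genes": true_genes,
        "shared_causal_gene": shared[0] if shared else None,
        "genes": truth_genes,
    }
    metadata = {
        "seed": study.seed,
        "outcome_method": "score",
        "m_variants": study.m_variants,
        "n_ref": study.n_ref,
        "n_outcome": study.n_outcome,
        "layer_sample_sizes": dict(study.layer_sample_sizes),
        "outcome_prevalence": study.outcome_prevalence,
    }
    return StudyBundle(
        config=study,
        qtl=qtl,
        gwas=gwas,
        panel=panel,
        gene_table=gene_table,
        truth=truth,
        metadata=metadata,
    )
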