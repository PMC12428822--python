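# Methods

This note documents the statistical machinery the package implements, the
assumptions behind each stage, the synthetic data model used to exercise it,
and the numerical and design choices a maintainer should know about.

## The analysis in one paragraph

The pipeline asks whether genetically predicted variation in a molecular
trait — CpG methylation (mQTL), transcript abundance (eQTL), or protein
abundance (pQTL) — causally influences a binary disease phenotype, using
only summary statistics from two non-overlapping samples. For each gene it
(1) selects and harmonizes cis instruments, (2) estimates the Wald-ratio
causal effect (SMR) and screens it with the HEIDI heterogeneity test,
(3) requires convergent significant evidence in all three molecular layers,
(4) colocalizes the surviving loci against the disease GWAS under the
five-hypothesis Bayesian framework, and (5) summarizes the resulting gene
lists with hypergeometric over-representation against term annotations.

## Instrument QC and harmonization

Candidate instruments are cis SNPs within ±1000 kb of the gene (closed
interval, 1-based coordinates). The funnel applies, in order:

1. **Significance** — strict `p < 5e-8` for mQTL/eQTL and `p < 1.8e-9` for
   pQTL instruments.
2. **Clumping** (mQTL by default; configurable) — greedy p-value-ordered
   index selection removing variants within 10,000 kb and `r² > 0.001`,
   giving effectively independent instruments. Ties on p break by position
   then id, so the output is invariant to input order. Pairs with undefined
   reference LD are conservatively treated as `r² = 1` and removed.
3. **Pruning** — exclusion of residual strong LD, `r² > 0.9`, applied to
   all layers.
4. **Instrument strength** — the single-SNP approximation `F = (β/se)²`;
   variants with `F < 10` are removed (so `F = 10` exactly is kept). With
   one instrument per test this is the squared Wald z; no formula beyond
   that is assumed.
5. **Allele-frequency concordance** — a variant is dropped when any pairwise
   effect-allele-frequency difference among the LD reference, the QTL
   sample and the GWAS sample strictly exceeds 0.2; a missing frequency is
   its own drop reason.
6. **Harmonization** — outcome records are aligned to the exposure's effect
   allele: a swapped pair (directly or after strand complementing) negates
   the outcome β and replaces its EAF by 1−EAF; SE and p are never touched.
   Palindromic variants (A/T, C/G) with EAF in [0.42, 0.58] on either side
   are dropped as strand-ambiguous; outside that band orientation is
   resolved by which side of 0.5 the two frequencies fall on. The band is
   the common two-sample-MR safeguard and is exposed in `QcConfig`.

Every dropped record carries exactly one machine-readable reason, and
per-stage survivor counts chain exactly (`n_in` of each stage equals
`n_out` of the previous), which the funnel report asserts.

## SMR and HEIDI

With a single instrument, the causal effect of exposure on outcome is the
Wald ratio `b_smr = β_out / β_exp` at the top cis SNP (smallest exposure
p). The test statistic is

```
T_SMR = z_exp² z_out² / (z_exp² + z_out²),   z = β/se,
```

referred to a 1-df chi-square; the delta-method standard error is
`|b_smr| / sqrt(T_SMR)`. `T_SMR ≤ min(z_exp², z_out²)`, so the SMR p-value
can never beat the weaker of the two marginal associations.

HEIDI distinguishes a single shared causal variant (vertical pleiotropy)
from linkage between two distinct causal variants. Candidate SNPs must pass
`p_exposure < 1.57e-3` and have `r²` to the top SNP in `[0.05, 0.9]`; the
top 20 by `r²` are used and fewer than 3 renders the test not evaluable.
For each candidate, `d_i = b_xy(i) − b_xy(top)`. Under two-sample
independence the first-order delta-method covariance is

```
cov(b_xy(i), b_xy(j)) = r_ij se_out(i) se_out(j) / (β_exp(i) β_exp(j))
          + b_xy(i) b_xy(j) r_ij se_exp(i) se_exp(j) / (β_exp(i) β_exp(j)),
```

with `r_ij` the signed reference-panel dosage correlation; `cov(d)` follows
by inclusion–exclusion with the top term. The statistic
`T_HEIDI = Σ (d_i / sd(d_i))²` is a weighted sum of 1-df chi-squares with
weights equal to the eigenvalues of the correlation matrix of `d`; its tail
is approximated by the Satterthwaite two-moment scaled chi-square
(`scale = Σλ²/Σλ`, `df = (Σλ)²/Σλ²`). The covariance is ridge-regularized
(1e-8 on the diagonal) and eigenvalues below 1e-10 discarded; a
non-positive variance after regularization yields "not evaluable".

Calibration rather than exactness is the design goal: under a simulated
shared-causal-variant scenario the rejection rate at α = 0.05 stays within
[0.03, 0.08] over 2000 replicates, while a matched linkage scenario
(distinct causal variants at dosage r² ≈ 0.5) is rejected more than five
times as often. A not-evaluable HEIDI passes the downstream
`p_HEIDI > 0.05` filter by default but is flagged (strict mode drops it);
loci with sparse LD genuinely give HEIDI nothing to work with, and
discarding them would silently bias the gene lists.

## Colocalization

Each locus (±500 kb around the probe for mQTL, ±1000 kb for eQTL/pQTL) is
summarized per variant by the Wakefield log approximate Bayes factor

```
log ABF = 0.5 (log(1 − r) + r z²),   r = W/(V + W),  V = se²,
```

with prior effect SD `W^0.5` = 0.15 for quantitative traits and 0.2 on the
log-odds scale for the case-control GWAS (the framework's published
defaults, exposed in `AbfParams`). Under the one-causal-variant-per-trait
assumption the five hypothesis masses combine per-variant ABFs with priors
`p1 = p2 = 1e-4` and `p12 = 1e-5`; `PP.H4 > 0.7` is reported as strong
colocalization. All sums run in log space, so `|z|` in the hundreds cannot
overflow.

One numerical choice matters: the H3 (two distinct variants) mass is the
cross-product of the two traits' ABF sums *minus the diagonal*. Computing
it as a log-difference cancels catastrophically when one shared variant
dominates both traits; the implementation instead sums the off-diagonal
pairs directly with a leave-one-out log-sum-exp, which reproduces explicit
enumeration of all (m+1)² causal configurations to below 1e-12 relative
error. A single-variant locus has `PP.H3 = 0` identically. Loci with fewer
than 25 shared variants are flagged low-coverage rather than refused.

## Integration and enrichment

Per phenotype and layer, significance means `p_SMR < 0.05` and
`p_HEIDI > 0.05` (both strict); probe-level rows are counted as well as
unique genes, since one gene may carry several CpG probes. The integrated
(convergent) set is the exact three-way intersection of the mQTL, eQTL and
pQTL gene sets — a missing layer is an error, not an empty set, because
the convergence criterion is meaningless without all three. The
probability of a null gene surviving this filter by chance is
`0.05³ = 1.25e-4`, which the acceptance harness confirms by Monte Carlo.

Methylation effect sizes are summarized per gene as odds ratios
(`exp(b_smr)`): the median across probes when a gene has ≥ 3 significant
probes, the arithmetic mean otherwise, with the label (`Med`/`Mean`)
carried in the output; text output rounds ORs to 3 decimals. Overlaps of
integrated genes across phenotypes use UpSet (exclusive-intersection)
semantics, so exclusive cell sizes sum to the union size.

Enrichment is the exact hypergeometric upper tail `P(X ≥ k)` per term
(no normal approximation — the universes here are small), BH-adjusted
across all terms with at least one query hit; significance requires
`p_adj < 0.05` *and* `k ≥ 2`. The background universe defaults to the
annotation's gene universe intersected with the study gene list (plus the
query), and is overridable. The enrichment map connects significant terms
whose hit-set overlap coefficient `|A∩B|/min(|A|,|B|)` reaches 0.2 (the
threshold is configurable; the choice of the overlap coefficient keeps a
small term nested in a large one visibly connected), with node size `k`,
node weight `−log10 p`, and focus-gene marking.

## The synthetic data model

The generator exists so every stage can be exercised end to end at desk
scale, with known ground truth, in seconds.

* **Genotypes.** Each individual is two haplotypes; each haplotype is a
  latent Gaussian AR(1) process along the locus (per-gap correlation
  `ld_rho`, scalar or vector) thresholded at the quantile matching the
  variant's target allele frequency (drawn uniformly from `maf_range`).
  This gives direct, independent control of MAF and LD decay — which is
  all the downstream statistics consume — at a fraction of the cost of a
  coalescent simulation. Note that thresholding attenuates correlation:
  latent ρ = 0.8 yields dosage r ≈ 0.66 at MAF 0.3 (the exact value is
  `(Φ₂(t,t,ρ) − f²)/(f(1−f))`), and scenario documentation quotes realized
  dosage r², not latent ρ.
* **Exposures.** A fresh cohort (never the reference panel) is drawn; the
  molecular trait is `y = b·g_causal + ε` with `b` set so the causal
  variant explains the target variance fraction against theoretical
  dosage variance `2f(1−f)`. Each CpG probe of a gene shares the genotype
  sample but has independent noise. Summary statistics are real marginal
  OLS fits per variant with exact t-tail p-values, so finite-sample noise
  and LD-induced correlation between neighbouring statistics arise
  naturally.
* **Outcomes.** An independent cohort; case status is Bernoulli under a
  logistic model whose intercept is solved (Brent) so the sample-average
  risk equals the target prevalence, with the per-allele log-OR at the
  outcome causal variant. Marginal statistics use the logistic score test
  (`β ≈ U/V`, `se = V^{-1/2}`), recorded in bundle metadata; per-variant
  logistic ML fits are available and are used where exact log-OR recovery
  is measured, since the one-step score estimator is mildly biased for
  larger effects.
* **Hypotheses.** H0–H4 mirror colocalization's hypothesis space: no
  causal variant, exposure-only, outcome-only, two distinct causal
  variants, one shared. H3 couples the two causal variants through a local
  LD step so their dosage r² lands near a chosen value (≈ 0.2 in the
  bundled scenarios).
* **Seeds.** Component generators derive from the master seed by fixed
  offsets (law +0, panel +1, exposure +2, outcome +3); replicate studies
  stride seeds by 10 so component streams never collide across replicates.
  Same seed ⇒ byte-identical bundle files.

**The bundled planted-truth study** (3 true + 7 decoy genes, one binary
phenotype, ~25% prevalence, n_outcome = 20,000; exposure cohorts of 1,980
(mQTL, 4 probes/gene), 6,000 (eQTL) and 6,000 (pQTL); 60 variants per gene
region on separate chromosomes) is designed so the integration outcome is
deterministic across seeds. One true gene is driven by a single variant
shared across all three layers and the outcome — the planted H4 locus the
pipeline must flag as strongly colocalized. The other two true genes carry
their disease signal at a *distinct* variant in LD r² ≈ 0.2 with the
molecular causal variant: a genuine, strongly significant SMR association
that colocalization resolves as H3, reproducing the common real-data
landscape in which most convergent genes do not colocalize. Their regions
use sparse background LD, so HEIDI has fewer than the minimum three
dependent instruments and reports not-evaluable (passing, flagged) — at
these loci the planted outcome is then a deterministic function of strong
signals rather than of HEIDI's 5% null rejection lottery, which is
exercised separately at dense-LD settings. Decoys cover every rejection
path: cis signals without any disease signal, signals in only one or two
layers, outcome-only signals, sub-threshold instruments, and empty
regions. A decoy with instruments in all three layers sneaks through only
with probability ≈ 0.05³.

Exposure sample sizes are desk-scale stand-ins chosen to keep instrument
z-scores in the range real QTL consortia deliver (the mQTL cohort size
matches a published methylation meta-analysis; the e/pQTL cohorts are
scaled down from consortium scale, with the full-scale power property
checked separately at n = 31,684). What the generator does **not**
emulate: genome-wide scale, covariate and batch structure, upstream
normalization pipelines, population stratification, sample overlap, indels
and multi-allelic variation, allelic heterogeneity, and tissue
specificity. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated model, not robustness to those
real-data complications.

## Evaluation harness and problem sizes

`omicsmr.experiments` re-runs the statistics on freshly simulated data and
measures operating characteristics; `scripts/acceptance.py` reports them
as JSON. Documented replicate studies (all sizes are the package's chosen
desk-scale conditions):

| study | scenario | replicates |
|---|---|---|
| joint-null false positive | 3 independent uniforms | 10⁷ draws |
| coloc oracle agreement | m ∈ {1, 5, 50}, z ∈ [0, 40] | ~100 loci |
| coloc H4 recovery | 60 SNPs, n_exp 4k, n_out 12k | 200 |
| coloc H3 vs H4 | same, distinct variants r² ≈ 0.2 | 200 |
| SMR recovery | 20 SNPs, n_exp 4k, n_out 12k, logistic ML at causal | 500 |
| HEIDI size (H4) | 25 SNPs, dense LD, n_exp 3k, n_out 8k | 2000 |
| HEIDI power (linkage) | same, r² ≈ 0.5 between causal pair | 1000 |
| end-to-end study | 3 true + 7 decoy genes | 1 |

## Known limitations

* Single-instrument SMR only; no multi-SNP SMR, conditional F statistics,
  Steiger directionality, or mediation decomposition.
* Colocalization inherits the one-causal-variant-per-trait assumption; no
  SuSiE-style multi-signal decomposition or credible sets.
* The HEIDI tail uses the Satterthwaite two-moment approximation, bounded
  by simulation calibration rather than claimed exact; equivalence with
  any particular external implementation's tail is not claimed.
* The GWAS is treated as case-control on the log-odds scale; an option
  treats trait 2 as quantitative for linear-model binary GWAS sources.
* Coordinates are build-agnostic; no liftover, imputation or multi-allelic
  handling.
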