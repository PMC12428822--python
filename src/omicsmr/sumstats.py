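"""Domain types and I/O for GWAS/QTL summary statistics and the LD reference panel.

Summary statistics are the atoms of the whole pipeline: one marginal
(single-variant) association per row, on the per-allele scale, with a
log-odds-scale ``beta`` for binary outcomes.  The LD reference panel supplies
signed dosage correlations between variants; it stands in for an external
reference cohort (e.g. 1000 Genomes EUR) and is the backbone of clumping,
pruning, HEIDI and the synthetic generator.

Conventions
-----------
* Coordinates are 1-based and windows are closed intervals.
* Alleles are single nucleotides (A/C/G/T); indels are rejected.
* ``eaf`` is the frequency of the effect allele ``a1``; dosages in the panel
  count copies of ``a1``.
* p-values are stored as given, never recomputed from beta/se; a mild
  consistency check (|z| vs p within 10%) only warns.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "Variant",
    "AssocRecord",
    "QtlRecord",
    "LdPanel",
    "GeneSet",
    "SumstatsFormatError",
    "SumstatsRowError",
    "UndefinedLdError",
    "read_sumstats",
    "write_sumstats",
    "read_gene_sets",
    "read_term_annotations",
    "read_panel",
    "write_panel",
]

_NUCLEOTIDES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

GWAS_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "FREQ", "BETA", "SE", "P", "N"]
QTL_COLUMNS = GWAS_COLUMNS + ["PROBE", "GENE", "LAYER", "PROBE_BP"]
LAYERS = ("mQTL", "eQTL", "pQTL")


class SumstatsFormatError(ValueError):
    """File-level format problem (e.g. a required column is missing)."""


class SumstatsRowError(ValueError):
    """Row-level problem; carries the 1-based line number of the offending row."""

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"line {line}: {message}")


class UndefinedLdError(ValueError):
    """LD is undefined for a pair (zero variance or too few shared calls)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Variant:
    """A biallelic SNP with its effect-allele frequency."""

    id: str
    chrom: str
    pos: int
    a1: str
    a2: str
    eaf: float

    def __post_init__(self):
        if self.a1 not in _NUCLEOTIDES or self.a2 not in _NUCLEOTIDES:
            raise ValueError(
                f"{self.id}: alleles must be single nucleotides A/C/G/T, "
                f"got {self.a1!r}/{self.a2!r}"
            )
        if self.a1 == self.a2:
            raise ValueError(f"{self.id}: effect and other allele are identical")
        if self.pos < 1:
            raise ValueError(f"{self.id}: position must be >= 1")
        if not (np.isnan(self.eaf) or 0.0 <= self.eaf <= 1.0):
            raise ValueError(f"{self.id}: eaf {self.eaf} outside [0, 1]")

    @property
    def is_palindromic(self) -> bool:
        """A/T or C/G pairs, where strand cannot be resolved from alleles alone."""
        return COMPLEMENT[self.a1] == self.a2


@dataclass(frozen=True)
class AssocRecord:
    """One variant's marginal association with one trait.

    ``beta`` is per effect-allele copy; for binary traits it is on the
    log-odds scale.
    """

    variant: Variant
    beta: float
    se: float
    p: float
    n: int

    def __post_init__(self):
        if not self.se > 0:
            raise ValueError(f"{self.variant.id}: se must be > 0, got {self.se}")
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"{self.variant.id}: p must be in (0, 1], got {self.p}")
        _check_p_consistency(self)

    @property
    def z(self) -> float:
        return self.beta / self.se


def _check_p_consistency(rec: "AssocRecord") -> None:
    # |z| implied by p vs |beta/se|; warn (never mutate) when off by >10%.
    # Tiny p underflows isf; skip the check out in the extreme tail.
    if rec.p < 1e-300 or rec.p >= 1.0:
        return
    z_from_p = stats.norm.isf(rec.p / 2.0)
    z_obs = abs(rec.beta / rec.se)
    if z_from_p > 0.5 and z_obs > 0 and abs(z_obs - z_from_p) / z_from_p > 0.10:
        warnings.warn(
            f"{rec.variant.id}: |beta/se|={z_obs:.3f} inconsistent with "
            f"p={rec.p:.3g} (implies |z|={z_from_p:.3f})",
            stacklevel=3,
        )


@dataclass(frozen=True)
class QtlRecord:
    """A molecular-trait association: one variant x one probe of one gene."""

    assoc: AssocRecord
    probe_id: str
    gene: str
    layer: str
    probe_pos: int

    def __post_init__(self):
        if self.layer not in LAYERS:
            raise ValueError(f"layer must be one of {LAYERS}, got {self.layer!r}")
        if self.probe_pos < 1:
            raise ValueError("probe_pos must be >= 1")

    @property
    def variant(self) -> Variant:
        return self.assoc.variant


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols (e.g. a mitochondrial gene catalogue)."""

    name: str
    genes: frozenset

    def __post_init__(self):
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


class LdPanel:
    """Reference genotypes giving signed dosage correlations between variants.

    Parameters
    ----------
    variants
        Ordered variants; ``eaf`` fields may be NaN (they are then filled from
        the panel itself).
    genotypes
        individuals x variants dosage matrix with values in {0, 1, 2}; NaN
        marks missing calls.  Correlations are pairwise-complete.
    """

    MIN_CALL_RATE = 0.95

    def __init__(self, variants: Sequence[Variant], genotypes: np.ndarray):
        genotypes = np.asarray(genotypes, dtype=float)
        if genotypes.ndim != 2 or genotypes.shape[1] != len(variants):
            raise ValueError(
                f"genotypes shape {genotypes.shape} does not match "
                f"{len(variants)} variants"
            )
        valid = np.isnan(genotypes) | np.isin(genotypes, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be in {0, 1, 2} or NaN")
        self.genotypes = genotypes
        self._index = {v.id: k for k, v in enumerate(variants)}
        if len(self._index) != len(variants):
            raise ValueError("duplicate variant ids in panel")
        call_rate = 1.0 - np.isnan(genotypes).mean(axis=0)
        self.low_call_rate = frozenset(
            v.id for v, cr in zip(variants, call_rate) if cr < self.MIN_CALL_RATE
        )
        # fill missing eaf from the panel's own allele counts
        filled = []
        for k, v in enumerate(variants):
            if np.isnan(v.eaf):
                col = genotypes[:, k]
                freq = float(np.nanmean(col) / 2.0) if np.isfinite(col).any() else np.nan
                v = replace(v, eaf=freq)
            filled.append(v)
        self.variants = list(filled)

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.genotypes.shape[1]

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def variant(self, variant_id: str) -> Variant:
        return self.variants[self._index[variant_id]]

    def eaf(self, variant_id: str) -> float:
        return self.variant(variant_id).eaf

    def dosages(self, variant_id: str) -> np.ndarray:
        return self.genotypes[:, self._index[variant_id]]

    def r(self, i: str, j: str) -> float:
        """Signed Pearson correlation of dosages, pairwise-complete."""
        gi, gj = self.dosages(i), self.dosages(j)
        ok = ~np.isnan(gi) & ~np.isnan(gj)
        if ok.sum() < 2:
            raise UndefinedLdError(f"fewer than 2 shared calls for {i}, {j}")
        xi, xj = gi[ok], gj[ok]
        si, sj = xi.std(), xj.std()
        if si == 0.0 or sj == 0.0:
            raise UndefinedLdError(f"zero dosage variance for pair {i}, {j}")
        return float(np.corrcoef(xi, xj)[0, 1])

    def r2(self, i: str, j: str) -> float:
        return self.r(i, j) ** 2

    def corr_matrix(self, ids: Sequence[str]) -> np.ndarray:
        """Full signed correlation matrix for a subset of variants.

        Raises :class:`UndefinedLdError` if any requested variant has zero
        variance.  Uses complete rows when there is no missingness (fast
        path), otherwise falls back to pairwise computation.
        """
        cols = [self._index[i] for i in ids]
        sub = self.genotypes[:, cols]
        if not np.isnan(sub).any():
            sd = sub.std(axis=0)
            if np.any(sd == 0.0):
                bad = [ids[k] for k in np.where(sd == 0.0)[0]]
                raise UndefinedLdError(f"zero dosage variance for {bad}")
            return np.corrcoef(sub, rowvar=False).reshape(len(ids), len(ids))
        m = len(ids)
        out = np.eye(m)
        for a in range(m):
            for b in range(a + 1, m):
                out[a, b] = out[b, a] = self.r(ids[a], ids[b])
        return out


# ---------------------------------------------------------------------------
# Readers / writers (tab-separated text, gzip-transparent)
# ---------------------------------------------------------------------------


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _parse_float(text: str, line: int, col: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise SumstatsRowError(line, f"unparsable numeric in column {col}: {text!r}")


def read_sumstats(path, trait_kind: str = "gwas", strict: bool = True):
    """Read tab-separated summary statistics.

    Parameters
    ----------
    trait_kind
        ``"gwas"`` expects the base columns and yields :class:`AssocRecord`;
        ``"qtl"`` additionally expects PROBE/GENE/LAYER/PROBE_BP and yields
        :class:`QtlRecord`.
    strict
        When True (default) the first invalid row raises; when False invalid
        rows are collected and returned alongside the records.

    Returns
    -------
    records, or ``(records, diagnostics)`` when ``strict=False`` where
    diagnostics is a list of :class:`SumstatsRowError`.
    """
    if trait_kind not in ("gwas", "qtl"):
        raise ValueError("trait_kind must be 'gwas' or 'qtl'")
    required = QTL_COLUMNS if trait_kind == "qtl" else GWAS_COLUMNS
    records, problems = [], []
    with _open_text(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        missing = [c for c in required if c not in header]
        if missing:
            raise SumstatsFormatError(
                f"{path}: missing required column(s) {', '.join(missing)}"
            )
        idx = {c: header.index(c) for c in required}
        for lineno, raw in enumerate(fh, start=2):
            raw = raw.rstrip("\n")
            if not raw:
                continue
            fields = raw.split("\t")
            try:
                records.append(_parse_row(fields, idx, lineno, trait_kind))
            except SumstatsRowError as err:
                if strict:
                    raise
                problems.append(err)
            except ValueError as err:  # invariant violations from the dataclasses
                err = SumstatsRowError(lineno, str(err))
                if strict:
                    raise err from None
                problems.append(err)
    if strict:
        return records
    return records, problems


def _parse_row(fields, idx, lineno, trait_kind):
    def get(col):
        try:
            return fields[idx[col]]
        except IndexError:
            raise SumstatsRowError(lineno, f"row has no value for column {col}")

    variant = Variant(
        id=get("SNP"),
        chrom=get("CHR"),
        pos=int(_parse_float(get("BP"), lineno, "BP")),
        a1=get("A1").upper(),
        a2=get("A2").upper(),
        eaf=_parse_float(get("FREQ"), lineno, "FREQ"),
    )
    assoc = AssocRecord(
        variant=variant,
        beta=_parse_float(get("BETA"), lineno, "BETA"),
        se=_parse_float(get("SE"), lineno, "SE"),
        p=_parse_float(get("P"), lineno, "P"),
        n=int(_parse_float(get("N"), lineno, "N")),
    )
    if trait_kind == "gwas":
        return assoc
    return QtlRecord(
        assoc=assoc,
        probe_id=get("PROBE"),
        gene=get("GENE"),
        layer=get("LAYER"),
        probe_pos=int(_parse_float(get("PROBE_BP"), lineno, "PROBE_BP")),
    )


_FLOAT_FMT = "{:.17g}"  # round-trips IEEE doubles exactly


def write_sumstats(records: Iterable, path) -> None:
    """Write records in the tab-separated format :func:`read_sumstats` reads."""
    records = list(records)
    is_qtl = bool(records) and isinstance(records[0], QtlRecord)
    cols = QTL_COLUMNS if is_qtl else GWAS_COLUMNS
    with _open_text(path, "wt") as fh:
        fh.write("\t".join(cols) + "\n")
        for rec in records:
            assoc = rec.assoc if is_qtl else rec
            v = assoc.variant
            row = [
                v.id,
                v.chrom,
                str(v.pos),
                v.a1,
                v.a2,
                _FLOAT_FMT.format(v.eaf),
                _FLOAT_FMT.format(assoc.beta),
                _FLOAT_FMT.format(assoc.se),
                _FLOAT_FMT.format(assoc.p),
                str(assoc.n),
            ]
            if is_qtl:
                row += [rec.probe_id, rec.gene, rec.layer, str(rec.probe_pos)]
            fh.write("\t".join(row) + "\n")


def read_gene_sets(path) -> dict:
    """Read two-column (set_name, gene) TSV into {name: GeneSet}."""
    groups: dict = {}
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            raw = raw.rstrip("\n")
            if not raw or raw.startswith("#"):
                continue
            parts = raw.split("\t")
            if len(parts) < 2:
                raise SumstatsRowError(lineno, "expected two tab-separated columns")
            groups.setdefault(parts[0], set()).add(parts[1])
    return {name: GeneSet(name=name, genes=frozenset(g)) for name, g in groups.items()}


def read_term_annotations(path):
    """Term-to-gene annotation TSV: term_id, gene[, term_name, namespace]."""
    from .enrich import TermAnnotation  # local import to avoid a cycle

    rows: dict = {}
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            raw = raw.rstrip("\n")
            if not raw or raw.startswith("#"):
                continue
            parts = raw.split("\t")
            if len(parts) < 2:
                raise SumstatsRowError(lineno, "expected at least two columns")
            term = parts[0]
            name = parts[2] if len(parts) > 2 else term
            namespace = parts[3] if len(parts) > 3 else "BP"
            entry = rows.setdefault(term, (name, namespace, set()))
            entry[2].add(parts[1])
    return [
        TermAnnotation(term_id=t, term_name=n, namespace=ns, genes=frozenset(g))
        for t, (n, ns, g) in rows.items()
    ]


# --- LD panel I/O -----------------------------------------------------------


def write_panel(panel: LdPanel, dosage_path, varmap_path) -> None:
    """Write a panel as a dosage matrix plus a sidecar variant map."""
    with _open_text(varmap_path, "wt") as fh:
        fh.write("SNP\tCHR\tBP\tA1\tA2\n")
        for v in panel.variants:
            fh.write(f"{v.id}\t{v.chrom}\t{v.pos}\t{v.a1}\t{v.a2}\n")
    with _open_text(dosage_path, "wt") as fh:
        fh.write("\t".join(v.id for v in panel.variants) + "\n")
        for row in panel.genotypes:
            fh.write(
                "\t".join("NA" if np.isnan(x) else str(int(x)) for x in row) + "\n"
            )


def read_panel(dosage_path, varmap_path=None) -> LdPanel:
    """Read a panel from a dosage matrix + variant map, or from a VCF.

    A path ending in ``.vcf``/``.vcf.gz`` is parsed as VCF with GT fields
    (dosage = count of the effect allele a1 = ALT); otherwise a plain
    tab-separated dosage table with a header of variant ids and a sidecar
    variant map (SNP, CHR, BP, A1, A2) is expected.
    """
    p = str(dosage_path)
    if p.endswith(".vcf") or p.endswith(".vcf.gz"):
        return _read_panel_vcf(p)
    if varmap_path is None:
        raise ValueError("varmap_path is required for dosage-table panels")
    variants = []
    with _open_text(varmap_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        need = ["SNP", "CHR", "BP", "A1", "A2"]
        missing = [c for c in need if c not in header]
        if missing:
            raise SumstatsFormatError(
                f"{varmap_path}: missing column(s) {', '.join(missing)}"
            )
        idx = {c: header.index(c) for c in need}
        for raw in fh:
            raw = raw.rstrip("\n")
            if not raw:
                continue
            f = raw.split("\t")
            variants.append(
                Variant(
                    id=f[idx["SNP"]],
                    chrom=f[idx["CHR"]],
                    pos=int(f[idx["BP"]]),
                    a1=f[idx["A1"]].upper(),
                    a2=f[idx["A2"]].upper(),
                    eaf=float("nan"),
                )
            )
    with _open_text(dosage_path) as fh:
        ids = fh.readline().rstrip("\n").split("\t")
        if ids != [v.id for v in variants]:
            raise SumstatsFormatError("dosage header does not match variant map order")
        rows = []
        for raw in fh:
            raw = raw.rstrip("\n")
            if not raw:
                continue
            rows.append(
                [np.nan if x in ("NA", ".") else float(x) for x in raw.split("\t")]
            )
    return LdPanel(variants, np.asarray(rows, dtype=float))


def _read_panel_vcf(path: str) -> LdPanel:
    try:
        from cyvcf2 import VCF
    except ImportError as err:  # pragma: no cover - cyvcf2 is an optional reader
        raise ImportError("reading VCF panels requires cyvcf2") from err
    variants, columns = [], []
    for rec in VCF(path):
        if len(rec.ALT) != 1:
            continue  # biallelic SNPs only
        try:
            variants.append(
                Variant(
                    id=rec.ID or f"{rec.CHROM}:{rec.POS}",
                    chrom=str(rec.CHROM),
                    pos=rec.POS,
                    a1=rec.ALT[0].upper(),
                    a2=rec.REF.upper(),
                    eaf=float("nan"),
                )
            )
        except ValueError:
            continue  # indels / non-ACGT
        gt = np.asarray(rec.genotype.array(), dtype=float)[:, :2]
        gt[gt < 0] = np.nan
        columns.append(gt.sum(axis=1))
    return LdPanel(variants, np.column_stack(columns))
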