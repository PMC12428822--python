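"""End-to-end workflow: QC -> SMR/HEIDI per layer -> cross-omics integration
-> colocalization of integrated genes -> enrichment, from a single manifest.

The pipeline is a pure function of (manifest, input files): given the same
inputs and seed it writes byte-identical outputs.  Stages run in order and
any failure aborts with the stage name and offending context; per-stage
survivor counts are written to ``funnel.tsv`` and a machine-readable run log
records versions, the full config echo, collected warnings and stage
timings.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from . import coloc as coloc_mod
from . import enrich as enrich_mod
from . import integrate as integrate_mod
from .qc import QcConfig, run_qc, harmonize
from .smr import HeidiConfig, SmrResult, smr_analysis
from .sumstats import (
    GeneSet,
    read_gene_sets,
    read_panel,
    read_sumstats,
    read_term_annotations,
)

logger = logging.getLogger(__name__)

__all__ = ["RunManifest", "PipelineError", "run_pipeline"]

LAYERS = ("mQTL", "eQTL", "pQTL")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass
class RunManifest:
    """Everything one run needs: input paths, configuration, output dir."""

    mqtl: Optional[str]
    eqtl: Optional[str]
    pqtl: Optional[str]
    gwas: Dict[str, str]  # phenotype -> path
    panel_dosage: str
    genes: str
    outdir: str
    panel_varmap: Optional[str] = None
    annotations: Optional[str] = None
    background: Optional[str] = None
    focus_gene: Optional[str] = None
    seed: int = 0
    qc: QcConfig = field(default_factory=QcConfig)
    heidi: HeidiConfig = field(default_factory=HeidiConfig)
    priors: coloc_mod.ColocPriors = field(default_factory=coloc_mod.ColocPriors)
    abf: coloc_mod.AbfParams = field(default_factory=coloc_mod.AbfParams)
    windows_kb: Dict[str, int] = field(
        default_factory=lambda: dict(coloc_mod.LAYER_WINDOW_KB)
    )
    coloc_all_genes: bool = False
    strict_heidi: bool = False

    def __post_init__(self):
        if not self.gwas:
            raise ValueError("manifest needs at least one phenotype GWAS")

    @classmethod
    def from_yaml(cls, path) -> "RunManifest":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key, typ in (
            ("qc", QcConfig),
            ("heidi", HeidiConfig),
            ("priors", coloc_mod.ColocPriors),
            ("abf", coloc_mod.AbfParams),
        ):
            if key in raw and isinstance(raw[key], dict):
                fixed = {
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in raw[key].items()
                }
                raw[key] = typ(**fixed)
        return cls(**raw)

    def echo(self) -> dict:
        out = dataclasses.asdict(self)
        return json.loads(json.dumps(out, default=str))


def _read_genes(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype={"GENE": str, "CHR": str, "BP": int})
    missing = {"GENE", "CHR", "BP"} - set(df.columns)
    if missing:
        raise PipelineError("load", f"gene table missing columns {sorted(missing)}")
    return list(df.itertuples(index=False))


def _stage(timings, name):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            return self

        def __exit__(self, exc_type, exc, tb):
            timings[name] = round(time.perf_counter() - self.t0, 4)
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(name, str(exc)) from exc
            return False

    return _Timer()


def run_pipeline(manifest: RunManifest) -> dict:
    """Execute the whole workflow and write the output tables.

    Writes ``table1.tsv`` (per-phenotype summary), ``smr_full.tsv`` (one row
    per probe x phenotype), ``coloc.tsv`` (PP.H0..PP.H4 per integrated gene
    x layer), ``forest.tsv`` (per-gene OR summaries with 95% CI),
    ``enrich.tsv``, ``upset.tsv`` (for >= 2 phenotypes), ``funnel.tsv`` and
    ``run_log.json``.  Returns the in-memory results keyed by table name.

    Colocalization is restricted to the cross-omics integrated genes by
    default (``coloc_all_genes`` lifts that), using the most significant
    probe per gene x layer.
    """
    outdir = Path(manifest.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict = {}
    caught: list = []

    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")
        results = _run_stages(manifest, timings)
        caught = [str(w.message) for w in wrec]

    written = {}
    for name, df in results["tables"].items():
        path = outdir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        written[name] = str(path)
    import scipy

    log = {
        "versions": {
            "omicsmr": _version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
        },
        "manifest": manifest.echo(),
        "timings_s": timings,
        "warnings": caught,
        "outputs": written,
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    results["run_log"] = log
    return results


def _version() -> str:
    from importlib.metadata import PackageNotFoundError, version

    try:
        return version("omicsmr")
    except PackageNotFoundError:
        return "unknown"


def _run_stages(manifest: RunManifest, timings: dict) -> dict:
    with _stage(timings, "load"):
        layer_paths = {
            "mQTL": manifest.mqtl, "eQTL": manifest.eqtl, "pQTL": manifest.pqtl
        }
        qtl = {
            layer: read_sumstats(path, "qtl")
            for layer, path in layer_paths.items()
            if path is not None
        }
        present_layers = tuple(qtl)
        gwas = {
            phen: read_sumstats(path, "gwas")
            for phen, path in manifest.gwas.items()
        }
        panel = read_panel(manifest.panel_dosage, manifest.panel_varmap)
        genes = _read_genes(manifest.genes)
        annotations = (
            read_term_annotations(manifest.annotations)
            if manifest.annotations
            else None
        )

    gene_pos = {g.GENE: (g.CHR, g.BP) for g in genes}
    by_probe: Dict[str, dict] = {layer: {} for layer in present_layers}
    for layer in present_layers:
        for rec in qtl[layer]:
            by_probe[layer].setdefault((rec.gene, rec.probe_id), []).append(rec)

    smr_rows: list = []
    funnel_rows: list = []
    summaries: list = []
    coloc_rows: list = []
    forest_rows: list = []
    enrich_rows: list = []
    phenotype_sets: Dict[str, set] = {}

    for phen, outcome in gwas.items():
        outcome_by_id = {r.variant.id: r for r in outcome}
        layer_sets: Dict[str, set] = {}
        probe_counts: Dict[str, int] = {}
        phen_results: list = []
        cis_pool: dict = {}

        with _stage(timings, f"qc+smr:{phen}"):
            for layer in present_layers:
                for (gene, probe_id), records in sorted(by_probe[layer].items()):
                    if gene not in gene_pos:
                        raise PipelineError(
                            "qc", f"gene {gene} absent from the gene table"
                        )
                    chrom, pos = gene_pos[gene]
                    pairs, funnel = run_qc(
                        records, outcome, panel, pos, layer,
                        manifest.qc, gene_chrom=chrom,
                    )
                    for stage, n_in, n_out in funnel.stages:
                        funnel_rows.append(
                            {
                                "phenotype": phen, "layer": layer, "gene": gene,
                                "probe": probe_id, "stage": stage,
                                "n_in": n_in, "n_out": n_out,
                            }
                        )
                    if not pairs:
                        continue
                    # HEIDI pool: the harmonized cis set, including variants
                    # that clumping removed from the instrument list
                    pool = []
                    for rec in records:
                        out_rec = outcome_by_id.get(rec.variant.id)
                        if out_rec is None:
                            continue
                        hp = harmonize(
                            rec, out_rec, manifest.qc.palindromic_eaf_band
                        )
                        if not hp.dropped:
                            pool.append(hp)
                    cis_pool[(phen, layer, gene, probe_id)] = pool
                    res = smr_analysis(
                        pairs, panel, manifest.heidi,
                        cis_pairs=pool, phenotype=phen,
                    )
                    phen_results.append(res)
                    smr_rows.append(_smr_row(res))

        with _stage(timings, f"integrate:{phen}"):
            for layer in present_layers:
                n_probes, gene_set = integrate_mod.significant_set(
                    phen_results, layer, manifest.strict_heidi
                )
                layer_sets[layer] = gene_set
                probe_counts[layer] = n_probes
            integrated = integrate_mod.integrate_genes(layer_sets)
            phenotype_sets[phen] = integrated
            for gene in sorted(layer_sets.get("mQTL", set())):
                try:
                    s = integrate_mod.summarize_gene_or(phen_results, gene, "mQTL")
                except ValueError:
                    continue
                forest_rows.append(
                    {
                        "phenotype": phen, "gene": gene, "layer": "mQTL",
                        "n_probes": s.n_probes, "or": round(s.summary_or, 3),
                        "summary": s.summary_label, "ci_low": "", "ci_high": "",
                    }
                )
            for layer in [l for l in ("eQTL", "pQTL") if l in present_layers]:
                for res in phen_results:
                    if res.layer != layer or res.gene not in layer_sets[layer]:
                        continue
                    if not (res.p_smr < integrate_mod.P_SMR_MAX
                            and res.heidi_pass()):
                        continue
                    lo = np.exp(res.b_smr - 1.96 * res.se_smr)
                    hi = np.exp(res.b_smr + 1.96 * res.se_smr)
                    forest_rows.append(
                        {
                            "phenotype": phen, "gene": res.gene, "layer": layer,
                            "n_probes": 1, "or": round(res.or_smr, 3),
                            "summary": "Mean", "ci_low": round(float(lo), 3),
                            "ci_high": round(float(hi), 3),
                        }
                    )

        with _stage(timings, f"coloc:{phen}"):
            targets = (
                sorted({r.gene for r in phen_results})
                if manifest.coloc_all_genes
                else sorted(integrated)
            )
            strong: set = set()
            for gene in targets:
                for layer in present_layers:
                    best = _best_probe(phen_results, gene, layer)
                    if best is None:
                        continue
                    pool = cis_pool.get((phen, layer, gene, best.probe_id))
                    if not pool:
                        continue
                    qtl_recs = [p.exposure for p in pool]
                    gwas_recs = [p.outcome for p in pool]
                    probe_pos = qtl_recs[0].probe_pos
                    try:
                        res = coloc_mod.coloc_locus(
                            qtl_recs, gwas_recs, probe_pos, layer,
                            manifest.priors, manifest.abf,
                            window_kb=manifest.windows_kb.get(layer),
                            gene=gene, phenotype=phen,
                        )
                    except ValueError as err:
                        raise PipelineError("coloc", f"{gene}/{layer}: {err}")
                    coloc_rows.append(res.as_dict())
                    if res.strong_colocalization:
                        strong.add(gene)
            summaries.append(
                integrate_mod.PhenotypeSummary(
                    phenotype=phen,
                    n_cpg_sites=probe_counts.get("mQTL", 0),
                    n_genes_mqtl=len(layer_sets.get("mQTL", set())),
                    n_genes_eqtl=len(layer_sets.get("eQTL", set())),
                    n_genes_pqtl=len(layer_sets.get("pQTL", set())),
                    integrated_genes=frozenset(integrated),
                    strong_coloc_genes=frozenset(strong & integrated),
                )
            )

        with _stage(timings, f"enrich:{phen}"):
            if annotations is not None and integrated:
                universe = set().union(*(t.genes for t in annotations))
                if manifest.background:
                    bg_sets = read_gene_sets(manifest.background)
                    bg_genes = set().union(*(g.genes for g in bg_sets.values()))
                else:
                    bg_genes = universe & {g.GENE for g in genes} | integrated
                background = GeneSet("background", frozenset(bg_genes))
                rows = enrich_mod.hypergeom_enrich(
                    GeneSet(phen, frozenset(integrated)), annotations, background
                )
                for row in rows:
                    enrich_rows.append(
                        {
                            "phenotype": phen,
                            "term": row.term.term_id,
                            "name": row.term.term_name,
                            "namespace": row.term.namespace,
                            "k": row.k, "K": row.K, "n": row.n, "N": row.N,
                            "p": row.p, "p_adj": row.p_adj,
                            "significant": row.significant,
                            "genes": ",".join(sorted(row.genes_hit)),
                        }
                    )

    tables = {
        "table1": integrate_mod.phenotype_summary_table(summaries),
        "smr_full": pd.DataFrame(
            smr_rows,
            columns=[
                "phenotype", "layer", "gene", "probe", "top_snp", "b_smr",
                "se_smr", "p_smr", "or_smr", "p_heidi", "n_heidi_snps",
            ],
        ),
        "coloc": pd.DataFrame(
            coloc_rows,
            columns=[
                "phenotype", "gene", "layer", "PP.H0", "PP.H1", "PP.H2",
                "PP.H3", "PP.H4", "n_snps", "window_kb", "strong_coloc",
                "low_coverage",
            ],
        ),
        "forest": pd.DataFrame(
            forest_rows,
            columns=[
                "phenotype", "gene", "layer", "n_probes", "or", "summary",
                "ci_low", "ci_high",
            ],
        ),
        "enrich": pd.DataFrame(
            enrich_rows,
            columns=[
                "phenotype", "term", "name", "namespace", "k", "K", "n", "N",
                "p", "p_adj", "significant", "genes",
            ],
        ),
        "funnel": pd.DataFrame(
            funnel_rows,
            columns=[
                "phenotype", "layer", "gene", "probe", "stage", "n_in", "n_out",
            ],
        ),
    }
    if len(phenotype_sets) >= 2:
        tables["upset"] = integrate_mod.overlap_matrix(phenotype_sets)
    return {
        "tables": tables,
        "summaries": summaries,
        "phenotype_sets": phenotype_sets,
    }


def _smr_row(res: SmrResult) -> dict:
    return {
        "phenotype": res.phenotype,
        "layer": res.layer,
        "gene": res.gene,
        "probe": res.probe_id,
        "top_snp": res.top_snp,
        "b_smr": res.b_smr,
        "se_smr": res.se_smr,
        "p_smr": res.p_smr,
        "or_smr": res.or_smr,
        "p_heidi": res.p_heidi if res.p_heidi is not None else "NA",
        "n_heidi_snps": res.n_heidi_snps,
    }


def _best_probe(results, gene: str, layer: str) -> Optional[SmrResult]:
    rows = [r for r in results if r.gene == gene and r.layer == layer]
    if not rows:
        return None
    return min(rows, key=lambda r: (r.p_smr, r.probe_id))
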