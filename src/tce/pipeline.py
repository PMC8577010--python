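"""End-to-end orchestration: simulate or load inputs, then filter ->
residualize -> correlate (permutation FDR) -> eQTL -> ASE -> GWAS ->
integrate -> GSEA, writing one TSV per stage plus a config echo and run log.

Reruns with an identical config (including seed) produce byte-identical
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import ase as ase_mod
from . import assoc, correlate, integrate, io_tables, preprocess
from . import gsea as gsea_mod
from .sim import SimConfig, simulate_population, toy_gene_sets

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class RunConfig:
    """Everything one pipeline run needs: inputs (files or a simulate block),
    stage thresholds, the master seed, and the output directory."""

    out_dir: str
    seed: int
    simulate: SimConfig | None = None
    expression: str | None = None
    genotypes: str | None = None
    genotype_dialect: str = "vcf"
    snp_map: str | None = None
    samples: str | None = None
    allele_counts: str | None = None
    annotation: str | None = None
    gene_sets: str | None = None

    tpm_min: float = 0.01
    sample_frac: float = 0.90
    log_offset: float = 1.0
    n_perm: int = 10_000
    cor_fdr: float = 0.01
    fdr_floor: float = 1e-5
    n_pcs: int = 5
    cis_window: int = assoc.CIS_WINDOW
    eqtl_fdr: float = 0.05
    gwas_p: float = 1e-3
    gwas_alpha: float = 0.05
    ase_min_depth: int = 10
    ase_site_fdr: float = 0.05
    ase_gene_min_n: int = 2
    gsea_n_perm: int = 1000
    gsea_fdr: float = 0.25

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim_block = raw.pop("simulate", None)
        cfg = cls(**raw)
        if sim_block is not None:
            cfg.simulate = SimConfig(**sim_block)
        return cfg

    def validate(self) -> None:
        if self.seed is None:
            raise PipelineError("config validation: seed is mandatory")
        if self.simulate is None:
            required = {"expression": self.expression, "samples": self.samples,
                        "genotypes": self.genotypes, "annotation": self.annotation}
            for name, p in required.items():
                if p is None:
                    raise PipelineError(
                        f"config validation: {name} path required when not simulating")
                if not Path(p).exists():
                    raise PipelineError(
                        f"config validation: {name} path does not exist: {p}")

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def _load_inputs(cfg: RunConfig):
    if cfg.simulate is not None:
        sim = simulate_population(cfg.simulate)
        sets = toy_gene_sets(sim.truth, sim.expression.gene_ids,
                             seed=cfg.simulate.seed)
        return (sim.genotypes, sim.expression, sim.samples, sim.allele_counts,
                sim.annotation, sets)
    gt = io_tables.read_genotypes(cfg.genotypes, dialect=cfg.genotype_dialect,
                                  snp_map=cfg.snp_map)
    expr = io_tables.read_expression(cfg.expression)
    samples = io_tables.read_samples(cfg.samples)
    counts = (io_tables.read_allele_counts(cfg.allele_counts)
              if cfg.allele_counts else None)
    ann = io_tables.read_annotation(cfg.annotation)
    sets = gsea_mod.read_gmt(cfg.gene_sets) if cfg.gene_sets else None
    return gt, expr, samples, counts, ann, sets


def run_pipeline(cfg: RunConfig) -> Path:
    """Run every stage and write the result directory.  Returns its path."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    def stage(name):
        def wrap(fn, *args, **kw):
            try:
                return fn(*args, **kw)
            except Exception as e:  # noqa: BLE001 - re-raised with stage name
                raise PipelineError(f"stage {name!r} failed: {e}") from e
        return wrap

    gt, expr, samples, counts, ann, gene_sets = stage("load")(_load_inputs, cfg)
    shared, dropped = io_tables.align_samples(
        list(expr.sample_ids), list(gt.sample_ids), list(samples.sample_ids))
    log(f"samples: {len(shared)} shared ({dropped} dropped from expression)")

    expr = io_tables.ExpressionMatrix(expr.values[shared])
    gt = io_tables.GenotypeMatrix(gt.dosages[shared], gt.snps)
    samples = io_tables.SampleTable(samples.data.loc[shared])

    # --- preprocess ------------------------------------------------------
    kept = stage("filter")(preprocess.filter_expressed, expr,
                           cfg.tpm_min, cfg.sample_frac)
    log(f"filter: kept {kept.shape[0]} of {expr.shape[0]} genes "
        f"(TPM > {cfg.tpm_min} in > {cfg.sample_frac:.0%} of samples)")
    log2e = preprocess.log2_transform(kept, cfg.log_offset)
    design = stage("design")(preprocess.build_design, samples)
    expr_resid = preprocess.residualize_matrix(log2e, design)
    pheno_resid, _ = preprocess.residualize(samples.phenotype, design)

    # --- correlation + permutation FDR -----------------------------------
    cor = stage("correlate")(correlate.correlate_all, expr_resid, pheno_resid)
    cor["fdr_perm"] = stage("permutation_fdr")(
        correlate.permutation_fdr, cor["p"], expr_resid, pheno_resid,
        n_perm=cfg.n_perm, seed=cfg.seed, floor=cfg.fdr_floor)
    cor["significant"] = cor["fdr_perm"] <= cfg.cor_fdr
    sig_genes = cor.index[cor["significant"].fillna(False)]
    log(f"correlation: {len(sig_genes)} genes at permutation FDR <= "
        f"{cfg.cor_fdr} ({cfg.n_perm} permutations, floor {cfg.fdr_floor:g})")

    # --- eQTL (design + genotype PCs) ------------------------------------
    pcs = stage("genotype_pcs")(assoc.genotype_pcs, gt, cfg.n_pcs)
    design_g = stage("design")(preprocess.build_design, samples,
                               extra=pcs.scores)
    eqtl = stage("eqtl")(assoc.eqtl_scan, log2e, gt, design_g, ann,
                         window=cfg.cis_window)
    sig_eqtl = eqtl[eqtl["fdr"] < cfg.eqtl_fdr]
    cis_genes = set(sig_eqtl.loc[sig_eqtl["type"] == "cis", "gene_id"])
    trans_genes = set(sig_eqtl.loc[sig_eqtl["type"] == "trans", "gene_id"])
    log(f"eqtl: {len(cis_genes)} cis / {len(trans_genes)} trans genes at "
        f"BH FDR < {cfg.eqtl_fdr} (window {cfg.cis_window} bp, "
        f"{cfg.n_pcs} genotype PCs)")

    # --- ASE --------------------------------------------------------------
    if counts is not None and len(counts.counts):
        ase_genes_df = stage("ase")(
            ase_mod.summarize_ase, counts, gt, ann,
            min_depth=cfg.ase_min_depth, p0=0.5, site_fdr=cfg.ase_site_fdr)
        ase_set = set(ase_genes_df.loc[
            ase_genes_df["ase_n"] >= cfg.ase_gene_min_n, "gene_id"])
    else:
        ase_genes_df = pd.DataFrame(
            columns=["gene_id", "snp_id", "het_n", "ase_n", "ratio"])
        ase_set = set()
    log(f"ase: {len(ase_set)} genes with >= {cfg.ase_gene_min_n} imbalanced "
        f"heterozygotes (site BH FDR <= {cfg.ase_site_fdr}, "
        f"min depth {cfg.ase_min_depth})")

    # --- GWAS --------------------------------------------------------------
    gwas = stage("gwas")(assoc.gwas_scan, samples.phenotype, gt, design_g)
    gw_threshold = assoc.bonferroni_threshold(cfg.gwas_alpha, len(gt.snp_ids))
    n_hits = int((gwas["p"] <= cfg.gwas_p).sum())
    log(f"gwas: {n_hits} SNPs at p <= {cfg.gwas_p:g}; genome-wide threshold "
        f"{cfg.gwas_alpha}/{len(gt.snp_ids)} = {gw_threshold:.2E}")

    # --- integration -------------------------------------------------------
    overlaps = integrate.overlap_sets(set(sig_genes), cis_genes, ase_set,
                                      trans_genes)
    triples = stage("integrate")(
        integrate.triple_candidates, cor, eqtl, gwas,
        cor_fdr=cfg.cor_fdr, eqtl_fdr=cfg.eqtl_fdr, gwas_p=cfg.gwas_p)
    log("overlaps: " + ", ".join(f"{k}={v}" for k, v in overlaps.counts.items()))
    log(f"integrate: {len(triples)} SNP-gene-trait triples "
        f"(cor FDR <= {cfg.cor_fdr}, eQTL FDR < {cfg.eqtl_fdr}, "
        f"GWAS p <= {cfg.gwas_p:g})")

    lead = None
    gw_sig = gwas[gwas["p"] <= gw_threshold]
    if len(gw_sig):
        lead_snp = gw_sig["p"].idxmin()
        near = integrate.nearest_correlated_gene(
            gwas.loc[lead_snp, "chrom"], int(gwas.loc[lead_snp, "pos"]),
            ann, cor.loc[sig_genes])
        lead = {"snp_id": lead_snp, "p": float(gwas.loc[lead_snp, "p"]),
                "nearest_correlated_gene": near}
        log(f"gwas lead: {lead_snp} (p={lead['p']:.2E}); nearest correlated "
            f"gene: {near['gene_id'] if near else 'none'}")

    # --- GSEA --------------------------------------------------------------
    gsea_df = pd.DataFrame(
        columns=["set_name", "es", "nes", "p_perm", "fdr", "leading_edge",
                 "significant"])
    if gene_sets and len(gene_sets) >= 2:
        ranked = gsea_mod.RankedList.from_correlations(cor)
        gsea_df = stage("gsea")(gsea_mod.nes_fdr, ranked, gene_sets,
                                n_perm=cfg.gsea_n_perm, seed=cfg.seed,
                                fdr_threshold=cfg.gsea_fdr)
        log(f"gsea: {int(gsea_df['significant'].sum())} of {len(gsea_df)} "
            f"sets at FDR < {cfg.gsea_fdr}")

    # --- outputs -----------------------------------------------------------
    cor_out = cor.reset_index()[
        ["gene_id", "r", "p", "fdr_perm", "significant"]]
    gwas_out = gwas.reset_index(names="snp_id")[
        ["snp_id", "chrom", "pos", "beta", "r_assoc", "p"]]
    gwas_out = gwas_out[gwas_out["p"].notna()]
    io_tables.write_result_tables(
        {
            "correlation": cor_out,
            "eqtl_cis": sig_eqtl[sig_eqtl["type"] == "cis"].reset_index(drop=True),
            "eqtl_trans": sig_eqtl[sig_eqtl["type"] == "trans"].reset_index(drop=True),
            "gwas": gwas_out,
            "ase_genes": ase_genes_df,
            "overlaps": overlaps.to_frame(),
            "triples": triples,
            "gsea": gsea_df.drop(columns=["leading_edge"]),
        },
        out,
    )
    summary = {
        "n_samples": len(shared),
        "n_genes_tested": int(cor["p"].notna().sum()),
        "n_correlated": int(len(sig_genes)),
        "overlap_counts": overlaps.counts,
        "n_gwas_hits": n_hits,
        "genomewide_threshold": gw_threshold,
        "n_triples": int(len(triples)),
        "lead": lead,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (out / "config.json").write_text(json.dumps(cfg.echo(), indent=2, sort_keys=True))
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return out
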