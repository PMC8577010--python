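"""Synthetic genotype / expression / phenotype / allele-count generator with
planted, recorded effects.

The generator emulates the study design the pipeline targets: ~189 crossbred
pigs with sex, slaughter batch, boar and age (210 +/- 6 days) as nuisance
covariates, an intramuscular-fat-like phenotype (mean 3.35, SD ~1.16), a
SNP-chip-like genotype panel in Hardy-Weinberg proportions, TPM expression
for a few thousand genes, and per-site allele read counts at heterozygotes.

Planted effects, all recorded in a :class:`TruthTable`:

* trait-correlated genes -- after covariate adjustment, gene residual
  correlates with the phenotype residual at a drawn rho (sign random);
* cis-eQTL genes -- log2 expression shifted linearly by the dosage of a SNP
  within 50 kb of the gene body;
* trans-eQTL genes -- same, with the SNP on another chromosome;
* phenotype QTLs -- dosage effects jointly explaining a ``qtl_h2`` fraction
  of the residual phenotype variance;
* ASE genes -- allele counts at an exonic tag SNP drawn binomially with a
  reference fraction of ``ase_imbalance`` in heterozygotes (0.5 elsewhere);
* one *triple* SNP-gene-trait configuration -- when correlated, cis and QTL
  effects are all requested, the first correlated gene is also the first cis
  gene and its cis SNP doubles as the first QTL, so the integration stage
  has a known positive.

Genotypes are drawn independently per SNP (no linkage disequilibrium).
Identical configs (including seed) give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_tables import (
    AlleleCountTable,
    ExpressionMatrix,
    FeatureAnnotation,
    GenotypeMatrix,
    SampleTable,
)

__all__ = ["SimConfig", "TruthTable", "SimResult", "simulate_population",
           "toy_gene_sets", "write_simulation"]

GENE_LENGTH = 5_000          # bp
GENE_SPACING = 200_000       # bp between gene starts on a chromosome
CIS_SNP_MAX_OFFSET = 50_000  # bp from the gene body for planted cis SNPs


class ConfigurationError(ValueError):
    """Raised when a SimConfig is internally inconsistent."""


@dataclass
class SimConfig:
    """Simulation parameters.  Defaults mirror the target study design."""

    n_samples: int = 189
    n_genes: int = 2000
    n_snps: int = 2000
    n_chromosomes: int = 18
    maf_range: tuple[float, float] = (0.05, 0.5)
    frac_correlated_genes: float = 0.02
    rho_range: tuple[float, float] = (0.20, 0.37)
    n_cis_genes: int = 20
    n_trans_genes: int = 10
    cis_beta: float = 1.0
    n_qtl: int = 3
    qtl_h2: float = 0.2
    ase_depth: float = 30.0
    ase_imbalance: float = 0.8
    noise_sd: float = 0.5
    n_ase_genes: int = 10
    n_ase_null_genes: int = 20
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_samples", "n_genes", "n_snps", "n_chromosomes"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        for name in ("frac_correlated_genes", "qtl_h2"):
            if not 0 <= getattr(self, name) <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if not 0 < self.ase_imbalance < 1:
            raise ConfigurationError("ase_imbalance must lie in (0, 1)")
        n_corr = self.n_correlated
        blocks = (n_corr + max(0, self.n_cis_genes - self._triple)
                  + self.n_trans_genes + self.n_ase_genes + self.n_ase_null_genes)
        if blocks > self.n_genes:
            raise ConfigurationError(
                f"planted gene blocks ({blocks}) exceed n_genes ({self.n_genes})"
            )
        n_special_snps = (self.n_cis_genes + self.n_trans_genes
                          + self.n_ase_genes + self.n_ase_null_genes
                          + max(0, self.n_qtl - self._triple))
        if n_special_snps > self.n_snps:
            raise ConfigurationError(
                f"designated SNPs ({n_special_snps}) exceed n_snps ({self.n_snps})"
            )

    @property
    def n_correlated(self) -> int:
        return int(round(self.frac_correlated_genes * self.n_genes))

    @property
    def _triple(self) -> int:
        """1 when a SNP-gene-trait triple is planted, else 0."""
        return int(self.n_correlated >= 1 and self.n_cis_genes >= 1
                   and self.n_qtl >= 1)


@dataclass
class TruthTable:
    """Record of every planted effect plus the covariate coefficients used."""

    effects: pd.DataFrame  # kind, gene_id, snp_id, value
    pheno_covariate_coefs: pd.Series
    expr_covariate_coefs: pd.DataFrame

    def of_kind(self, kind: str) -> pd.DataFrame:
        return self.effects[self.effects["kind"] == kind]


@dataclass
class SimResult:
    genotypes: GenotypeMatrix
    expression: ExpressionMatrix
    samples: SampleTable
    allele_counts: AlleleCountTable
    annotation: FeatureAnnotation
    truth: TruthTable

    def __iter__(self):
        return iter((self.genotypes, self.expression, self.samples,
                     self.allele_counts, self.annotation, self.truth))


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def simulate_population(config: SimConfig) -> SimResult:
    """Generate one synthetic population under ``config``.

    See the module docstring for the planted-effect layout.  All randomness
    flows from ``config.seed`` through a single generator in a fixed order,
    so identical configs give bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, g, m = config.n_samples, config.n_genes, config.n_snps
    nchrom = config.n_chromosomes

    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    gene_ids = [f"GENE{i + 1:05d}" for i in range(g)]
    snp_ids = [f"SNP{i + 1:05d}" for i in range(m)]

    # --- gene annotation: round-robin over chromosomes -------------------
    chrom = np.array([str(i % nchrom + 1) for i in range(g)])
    slot = np.arange(g) // nchrom
    start = 1_000_000 + slot * GENE_SPACING
    end = start + GENE_LENGTH - 1
    annotation = FeatureAnnotation(pd.DataFrame(
        {"chrom": chrom, "start": start, "end": end, "strand": "+"},
        index=pd.Index(gene_ids, name="gene_id"),
    ))
    chrom_len = int(start.max() + 1_000_000)

    # --- planted gene blocks --------------------------------------------
    n_corr = config.n_correlated
    triple = config._triple
    corr_idx = list(range(n_corr))
    cursor = n_corr
    cis_idx = ([0] if triple else []) + list(
        range(cursor, cursor + config.n_cis_genes - triple))
    cursor += config.n_cis_genes - triple
    trans_idx = list(range(cursor, cursor + config.n_trans_genes))
    cursor += config.n_trans_genes
    ase_idx = list(range(cursor, cursor + config.n_ase_genes))
    cursor += config.n_ase_genes
    ase_null_idx = list(range(cursor, cursor + config.n_ase_null_genes))

    # --- SNP placement ---------------------------------------------------
    snp_chrom = np.empty(m, dtype=object)
    snp_pos = np.empty(m, dtype=np.int64)
    snp_cursor = 0

    def _place(chrom_label: str, pos: int) -> int:
        nonlocal snp_cursor
        i = snp_cursor
        snp_chrom[i] = chrom_label
        snp_pos[i] = max(1, pos)
        snp_cursor += 1
        return i

    cis_snp_of: dict[int, int] = {}
    for gi in cis_idx:
        offset = int(rng.integers(-CIS_SNP_MAX_OFFSET, CIS_SNP_MAX_OFFSET + 1))
        cis_snp_of[gi] = _place(chrom[gi], int(start[gi]) + offset)
    trans_snp_of: dict[int, int] = {}
    for gi in trans_idx:
        other = str((int(chrom[gi]) % nchrom) + 1)  # next chromosome
        trans_snp_of[gi] = _place(other, int(rng.integers(1, chrom_len)))
    tag_snp_of: dict[int, int] = {}
    for gi in ase_idx + ase_null_idx:
        pos = int(rng.integers(start[gi], end[gi] + 1))
        tag_snp_of[gi] = _place(chrom[gi], pos)
    qtl_snps: list[int] = []
    if triple:
        qtl_snps.append(cis_snp_of[0])
    for _ in range(config.n_qtl - len(qtl_snps)):
        qtl_snps.append(_place(str(int(rng.integers(1, nchrom + 1))),
                               int(rng.integers(1, chrom_len))))
    while snp_cursor < m:
        _place(str(int(rng.integers(1, nchrom + 1))),
               int(rng.integers(1, chrom_len)))

    # --- genotypes: independent HWE draws at drawn MAFs ------------------
    maf = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    dosages = rng.binomial(2, maf[:, None], size=(m, n)).astype(float)
    ref = np.full(m, "A")
    alt = np.full(m, "G")
    genotypes = GenotypeMatrix(
        pd.DataFrame(dosages, index=pd.Index(snp_ids, name="snp_id"),
                     columns=sample_ids),
        pd.DataFrame({"chrom": snp_chrom, "pos": snp_pos, "ref": ref,
                      "alt": alt, "maf": maf},
                     index=pd.Index(snp_ids, name="snp_id")),
    )

    # --- covariates ------------------------------------------------------
    sex = rng.choice(["F", "M"], size=n)
    batch = rng.choice([f"B{i}" for i in range(1, 5)], size=n)
    boar = rng.choice([f"D{i}" for i in range(1, 9)], size=n)
    age = rng.integers(204, 217, size=n).astype(float)  # 210 +/- 6 days

    cov_levels = (["sex[M]"] + [f"batch[B{i}]" for i in range(2, 5)]
                  + [f"boar[D{i}]" for i in range(2, 9)] + ["age"])
    pheno_coef = pd.Series(
        np.concatenate([
            rng.normal(0, 0.5, 1),            # sex
            rng.normal(0, 0.5, 3),            # batch
            rng.normal(0, 0.3, 7),            # boar
            [0.02],                           # age slope
        ]),
        index=cov_levels, name="coefficient",
    )
    cov_design = np.column_stack(
        [(sex == "M").astype(float)]
        + [(batch == f"B{i}").astype(float) for i in range(2, 5)]
        + [(boar == f"D{i}").astype(float) for i in range(2, 9)]
        + [age - age.mean()]
    )
    pheno_cov = cov_design @ pheno_coef.to_numpy()

    # --- phenotype: QTL effects + noise at the requested h2 --------------
    effects_rows: list[dict] = []
    env = rng.normal(0, 1, n)
    if config.n_qtl > 0 and config.qtl_h2 > 0:
        zg = np.column_stack([_standardize(dosages[s]) for s in qtl_snps])
        graw = zg.sum(axis=1)
        genetic = np.sqrt(config.qtl_h2) * _standardize(graw)
        resid = genetic + np.sqrt(1 - config.qtl_h2) * env
        for s in qtl_snps:
            effects_rows.append({"kind": "QTL", "gene_id": "",
                                 "snp_id": snp_ids[s],
                                 "value": config.qtl_h2 / len(qtl_snps)})
    else:
        resid = env
    phenotype = 3.35 + pheno_cov + resid
    resid_std = _standardize(resid)

    samples = SampleTable(pd.DataFrame(
        {"sex": sex, "batch": batch, "boar": boar, "age": age,
         "phenotype": phenotype},
        index=pd.Index(sample_ids, name="sample_id"),
    ))

    # --- expression ------------------------------------------------------
    baseline = rng.uniform(2.0, 8.0, g)
    expr_coef = pd.DataFrame(
        np.column_stack([
            rng.normal(0, 0.2, g),
            rng.normal(0, 0.2, (g, 3)),
            rng.normal(0, 0.1, (g, 7)),
            rng.normal(0, 0.005, g),
        ]),
        index=pd.Index(gene_ids, name="gene_id"), columns=cov_levels,
    )
    log2e = baseline[:, None] + expr_coef.to_numpy() @ cov_design.T
    gene_noise = rng.normal(0, 1, size=(g, n))

    rho_mag = rng.uniform(config.rho_range[0], config.rho_range[1], g)
    rho_sign = rng.choice([-1.0, 1.0], g)
    if triple:
        # the triple gene's correlation must reinforce, not cancel, its
        # cis-dosage channel (which is positively coupled to the phenotype
        # through the shared QTL), so its sign is fixed positive
        rho_sign[0] = 1.0
    signal = np.array(gene_noise)  # copied; correlated rows overwritten below
    for gi in corr_idx:
        rho = rho_mag[gi] * rho_sign[gi]
        signal[gi] = rho * resid_std + np.sqrt(1 - rho ** 2) * gene_noise[gi]
        effects_rows.append({"kind": "trait-correlation",
                             "gene_id": gene_ids[gi], "snp_id": "",
                             "value": rho})
    log2e += config.noise_sd * signal
    for gi, si in cis_snp_of.items():
        d = dosages[si]
        log2e[gi] += config.cis_beta * (d - d.mean())
        effects_rows.append({"kind": "cis-eQTL", "gene_id": gene_ids[gi],
                             "snp_id": snp_ids[si], "value": config.cis_beta})
    for gi, si in trans_snp_of.items():
        d = dosages[si]
        log2e[gi] += config.cis_beta * (d - d.mean())
        effects_rows.append({"kind": "trans-eQTL", "gene_id": gene_ids[gi],
                             "snp_id": snp_ids[si], "value": config.cis_beta})

    tpm = np.clip(np.exp2(log2e) - 1.0, 0.0, None)
    expression = ExpressionMatrix(pd.DataFrame(
        tpm, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids))

    # --- allele counts at heterozygous tag sites -------------------------
    count_rows: list[tuple] = []
    for gi, si in tag_snp_of.items():
        p_ref = config.ase_imbalance if gi in set(ase_idx) else 0.5
        het = np.where(dosages[si] == 1.0)[0]
        depth = rng.poisson(config.ase_depth, size=len(het))
        refs = rng.binomial(np.maximum(depth, 0), p_ref)
        for j, sj in enumerate(het):
            count_rows.append((snp_ids[si], sample_ids[sj],
                               int(refs[j]), int(depth[j] - refs[j])))
        if gi in set(ase_idx):
            effects_rows.append({"kind": "ASE", "gene_id": gene_ids[gi],
                                 "snp_id": snp_ids[si],
                                 "value": config.ase_imbalance})
    allele_counts = AlleleCountTable(pd.DataFrame(
        count_rows, columns=["snp_id", "sample_id", "ref_count", "alt_count"]))

    truth = TruthTable(
        effects=pd.DataFrame(effects_rows,
                             columns=["kind", "gene_id", "snp_id", "value"]),
        pheno_covariate_coefs=pheno_coef,
        expr_covariate_coefs=expr_coef,
    )
    return SimResult(genotypes, expression, samples, allele_counts,
                     annotation, truth)


def toy_gene_sets(
    truth: TruthTable,
    gene_ids,
    n_random: int = 8,
    set_size: int = 20,
    seed: int = 0,
) -> dict[str, set]:
    """Toy GMT-style gene sets: the planted positively / negatively
    correlated genes plus random sets, for exercising the enrichment stage."""
    rng = np.random.default_rng(seed)
    corr = truth.of_kind("trait-correlation")
    sets: dict[str, set] = {}
    pos = set(corr.loc[corr["value"] > 0, "gene_id"])
    neg = set(corr.loc[corr["value"] < 0, "gene_id"])
    if len(pos) >= 2:
        sets["planted_positive"] = pos
    if len(neg) >= 2:
        sets["planted_negative"] = neg
    gene_ids = list(gene_ids)
    for i in range(n_random):
        sets[f"random_{i + 1:02d}"] = set(
            rng.choice(gene_ids, size=min(set_size, len(gene_ids) - 1),
                       replace=False))
    return sets


def write_simulation(sim: SimResult, out_dir, gene_sets: dict | None = None):
    """Write a simulated dataset in the dialects the readers consume."""
    from pathlib import Path

    from . import io_tables
    from .gsea import write_gmt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io_tables.write_expression(sim.expression, out / "expression.tsv")
    io_tables.write_genotypes_vcf(sim.genotypes, out / "genotypes.vcf")
    io_tables.write_genotypes_tsv(sim.genotypes, out / "dosages.tsv",
                                  out / "snp_map.tsv")
    io_tables.write_samples(sim.samples, out / "samples.tsv")
    io_tables.write_allele_counts(sim.allele_counts, out / "allele_counts.tsv")
    io_tables.write_annotation(sim.annotation, out / "annotation.tsv")
    sim.truth.effects.to_csv(out / "truth.tsv", sep="\t", index=False)
    if gene_sets is None:
        gene_sets = toy_gene_sets(sim.truth, sim.expression.gene_ids)
    write_gmt(gene_sets, out / "gene_sets.gmt")
    return out
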