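"""Integration of correlation, eQTL, ASE and GWAS results.

Three complementary views are produced:

* set overlaps between trait-correlated genes and cis-eQTL / ASE /
  specific-trans-eQTL gene sets (Venn-style counts and membership lists);
* SNP-gene-trait *triple* candidates: markers simultaneously associated
  with the trait (GWAS), with a gene's expression (eQTL), for a gene whose
  expression correlates with the trait -- the same marker must carry both
  association signals;
* the nearest trait-correlated gene to a genome-wide-significant lead SNP,
  the fallback candidate when no eQTL links the locus to a gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_tables import FeatureAnnotation

__all__ = [
    "OverlapSummary",
    "overlap_sets",
    "triple_candidates",
    "nearest_correlated_gene",
]


@dataclass
class OverlapSummary:
    """Sorted membership lists of the pairwise and three-way intersections."""

    correlated_cis: list[str]
    correlated_ase: list[str]
    correlated_cis_ase: list[str]
    correlated_specific_trans: list[str]

    @property
    def counts(self) -> dict[str, int]:
        return {
            "correlated_cis": len(self.correlated_cis),
            "correlated_ase": len(self.correlated_ase),
            "correlated_cis_ase": len(self.correlated_cis_ase),
            "correlated_specific_trans": len(self.correlated_specific_trans),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"overlap": k, "n": len(v), "genes": ",".join(v)}
            for k, v in (
                ("correlated_cis", self.correlated_cis),
                ("correlated_ase", self.correlated_ase),
                ("correlated_cis_ase", self.correlated_cis_ase),
                ("correlated_specific_trans", self.correlated_specific_trans),
            )
        ]
        return pd.DataFrame(rows)


def overlap_sets(
    correlated, cis_genes, ase_genes, trans_genes
) -> OverlapSummary:
    """Intersect the trait-correlated gene set with cis-eQTL, ASE and trans
    gene sets.

    ``trans_genes`` may include genes that also have cis signals; the
    reported trans overlap is restricted to *specific* trans genes (trans
    without any cis signal).
    """
    correlated = set(correlated)
    cis = set(cis_genes)
    ase = set(ase_genes)
    specific_trans = set(trans_genes) - cis
    return OverlapSummary(
        correlated_cis=sorted(correlated & cis),
        correlated_ase=sorted(correlated & ase),
        correlated_cis_ase=sorted(correlated & cis & ase),
        correlated_specific_trans=sorted(correlated & specific_trans),
    )


def triple_candidates(
    cor: pd.DataFrame,
    eqtl: pd.DataFrame,
    gwas: pd.DataFrame,
    cor_fdr: float = 0.01,
    eqtl_fdr: float = 0.05,
    gwas_p: float = 1e-3,
) -> pd.DataFrame:
    """SNP-gene-trait triples passing all three significance filters.

    Inputs: ``cor`` indexed by gene_id with r, p, fdr_perm; ``eqtl`` long
    table with snp_id, gene_id, r_assoc, p, fdr, type; ``gwas`` indexed by
    snp_id with r_assoc, p.  The eQTL marker and the GWAS marker must be the
    identical SNP.  Output is ordered by gene id, then GWAS p.
    """
    for name, df in (("correlation", cor), ("eqtl", eqtl), ("gwas", gwas)):
        if df is None:
            raise ValueError(f"missing upstream table: {name}")
    sig_genes = cor[cor["fdr_perm"] <= cor_fdr]
    sig_eqtl = eqtl[(eqtl["fdr"] < eqtl_fdr) & eqtl["gene_id"].isin(sig_genes.index)]
    sig_gwas = gwas[gwas["p"] <= gwas_p]

    merged = sig_eqtl.merge(
        sig_gwas[["r_assoc", "p"]].rename(
            columns={"r_assoc": "gwas_r", "p": "gwas_p"}
        ),
        left_on="snp_id",
        right_index=True,
        how="inner",
    )
    merged = merged.merge(
        sig_genes[["r", "p", "fdr_perm"]].rename(
            columns={"r": "cor", "p": "cor_p", "fdr_perm": "cor_fdr"}
        ),
        left_on="gene_id",
        right_index=True,
        how="inner",
    )
    out = merged.rename(
        columns={"r_assoc": "eqtl_r", "p": "eqtl_p", "fdr": "eqtl_fdr"}
    )[
        ["snp_id", "gene_id", "cor", "cor_p", "cor_fdr",
         "eqtl_r", "eqtl_p", "eqtl_fdr", "type", "gwas_r", "gwas_p"]
    ].reset_index(drop=True)
    return out.sort_values(
        ["gene_id", "gwas_p", "snp_id"], kind="stable"
    ).reset_index(drop=True)


def nearest_correlated_gene(
    snp_chrom: str,
    snp_pos: int,
    annotation: FeatureAnnotation,
    correlated: pd.DataFrame,
    max_dist: float = 2e6,
) -> dict | None:
    """Nearest trait-correlated gene to a lead SNP, within ``max_dist`` bp.

    ``correlated`` is the significant slice of the correlation table (index
    gene_id, with fdr_perm for tie-breaking).  Distance is from the SNP to
    the gene interval [start, end] (0 inside).  Ties are broken by smaller
    correlation FDR, then lexicographic gene id.  Returns
    ``{gene_id, distance}`` or None.
    """
    genes = annotation.genes.loc[
        annotation.genes.index.intersection(correlated.index)
    ]
    genes = genes[genes["chrom"].astype(str) == str(snp_chrom)]
    if genes.empty:
        return None
    dist = np.maximum.reduce([
        genes["start"].to_numpy() - snp_pos,
        snp_pos - genes["end"].to_numpy(),
        np.zeros(len(genes), dtype=np.int64),
    ])
    cand = pd.DataFrame(
        {"distance": dist, "fdr": correlated.loc[genes.index, "fdr_perm"].to_numpy()},
        index=genes.index,
    )
    cand = cand[cand["distance"] <= max_dist]
    if cand.empty:
        return None
    cand = cand.sort_values(
        ["distance", "fdr"], kind="stable"
    )
    # final tie-break: lexicographic gene id
    best_d, best_f = cand.iloc[0][["distance", "fdr"]]
    ties = cand[(cand["distance"] == best_d) & (cand["fdr"] == best_f)]
    gene_id = sorted(ties.index)[0]
    return {"gene_id": gene_id, "distance": int(cand.loc[gene_id, "distance"])}
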