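"""Allele-specific expression: per-site binomial imbalance tests and per-gene
Het / ASE / ratio summaries.

At each heterozygous (dosage = 1) sample-site pair with sufficient read
depth, the reference-allele read fraction is tested against a null fraction
p0 (default 0.5) with an exact two-sided binomial test.  Within a site, the
per-sample p-values are Benjamini-Hochberg adjusted and samples at adjusted
p <= site_fdr are flagged as displaying ASE.  A gene is summarized by its
reporting site -- the site with the most testable heterozygotes (ties broken
by smaller median p) -- as Het (heterozygote count), ASE (flagged count) and
ratio = ASE / Het.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import bh_fdr
from .io_tables import AlleleCountTable, FeatureAnnotation, GenotypeMatrix

__all__ = [
    "ase_site_test",
    "site_calls",
    "summarize_gene_ase",
    "summarize_ase",
]

MIN_DEPTH = 10  # reads required to test a sample-site pair


@lru_cache(maxsize=100_000)
def _binom_p(ref: int, total: int, p0: float) -> float:
    return stats.binomtest(ref, total, p0).pvalue


def ase_site_test(
    ref_count: int, alt_count: int, p0: float = 0.5
) -> tuple[float, float]:
    """Exact two-sided binomial test of the reference-read fraction vs p0.

    Returns (ref_fraction, p).  Raises on zero total depth; depth filtering
    happens in :func:`site_calls`.
    """
    total = ref_count + alt_count
    if total <= 0:
        raise ValueError("no coverage: ref_count + alt_count must be > 0")
    if ref_count < 0 or alt_count < 0:
        raise ValueError("read counts must be non-negative")
    return ref_count / total, _binom_p(int(ref_count), int(total), p0)


def site_calls(
    counts: AlleleCountTable,
    gt: GenotypeMatrix,
    min_depth: int = MIN_DEPTH,
    p0: float = 0.5,
    site_fdr: float = 0.05,
) -> pd.DataFrame:
    """Per sample-site ASE calls restricted to heterozygotes.

    Only pairs where the genotype dosage is exactly 1 and total depth is at
    least ``min_depth`` are tested; other rows are dropped (low-depth
    heterozygotes are reported with ``tested = False``).  ``is_ase`` flags
    samples significant after BH adjustment across each site's samples.
    """
    df = counts.counts.copy()
    dos = gt.dosages
    known = df["snp_id"].isin(dos.index) & df["sample_id"].isin(dos.columns)
    df = df.loc[known]
    flat = dos.to_numpy(dtype=float)[
        dos.index.get_indexer(df["snp_id"]), dos.columns.get_indexer(df["sample_id"])
    ]
    df = df.loc[flat == 1.0].copy()  # heterozygotes only
    depth = df["ref_count"] + df["alt_count"]
    df["depth"] = depth
    df["tested"] = depth >= min_depth

    tested = df.loc[df["tested"]].copy()
    with np.errstate(invalid="ignore"):
        tested["ref_fraction"] = tested["ref_count"] / tested["depth"]
    tested["p"] = [
        _binom_p(int(r), int(d), p0)
        for r, d in zip(tested["ref_count"], tested["depth"])
    ]
    tested["p_adj"] = np.nan
    for _, idx in tested.groupby("snp_id").groups.items():
        tested.loc[idx, "p_adj"] = bh_fdr(tested.loc[idx, "p"].to_numpy())
    tested["is_ase"] = tested["p_adj"] <= site_fdr
    return tested.reset_index(drop=True)


def _sites_in_gene(gene: pd.Series, snps: pd.DataFrame) -> pd.Index:
    inside = (
        (snps["chrom"].astype(str) == str(gene["chrom"]))
        & (snps["pos"] >= int(gene["start"]))
        & (snps["pos"] <= int(gene["end"]))
    )
    return snps.index[inside]


def summarize_gene_ase(
    gene_id: str,
    gene: pd.Series,
    calls: pd.DataFrame,
    gt: GenotypeMatrix,
) -> dict | None:
    """Summarize one gene from its exonic sites' calls.

    Picks the reporting site with the largest number of testable
    heterozygotes (ties: smallest median p), and returns
    ``{gene_id, snp_id, het_n, ase_n, ratio}`` or None when no site has a
    testable heterozygote.
    """
    sites = _sites_in_gene(gene, gt.snps)
    sub = calls[calls["snp_id"].isin(sites)]
    if sub.empty:
        return None
    best_snp, best_key = None, None
    for snp_id, grp in sub.groupby("snp_id"):
        key = (-len(grp), float(np.median(grp["p"])), str(snp_id))
        if best_key is None or key < best_key:
            best_key, best_snp = key, snp_id
    grp = sub[sub["snp_id"] == best_snp]
    het_n = int(len(grp))
    ase_n = int(grp["is_ase"].sum())
    return {
        "gene_id": gene_id,
        "snp_id": best_snp,
        "het_n": het_n,
        "ase_n": ase_n,
        "ratio": ase_n / het_n,
    }


def summarize_ase(
    counts: AlleleCountTable,
    gt: GenotypeMatrix,
    annotation: FeatureAnnotation,
    min_depth: int = MIN_DEPTH,
    p0: float = 0.5,
    site_fdr: float = 0.05,
) -> pd.DataFrame:
    """Het / ASE / ratio summary for every gene with a testable site.

    Returns a DataFrame sorted by gene id with columns gene_id, snp_id,
    het_n, ase_n, ratio.  Genes without any testable heterozygote are
    excluded."""
    calls = site_calls(counts, gt, min_depth=min_depth, p0=p0, site_fdr=site_fdr)
    rows = []
    for gene_id, gene in annotation.genes.iterrows():
        row = summarize_gene_ase(gene_id, gene, calls, gt)
        if row is not None:
            rows.append(row)
    cols = ["gene_id", "snp_id", "het_n", "ase_n", "ratio"]
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values("gene_id", kind="stable").reset_index(drop=True)
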