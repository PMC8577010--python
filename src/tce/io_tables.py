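"""Tabular I/O for the pipeline: expression, genotypes, samples, allele counts,
feature annotations and result tables.

All containers are thin dataclasses around :class:`pandas.DataFrame` that
validate their schema on construction.  Readers reject malformed input with a
:class:`SchemaError` naming the offending row/column instead of silently
coercing.  Coordinates are 1-based inclusive throughout (VCF/GFF convention).
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "ExpressionMatrix",
    "GenotypeMatrix",
    "SampleTable",
    "AlleleCountTable",
    "FeatureAnnotation",
    "read_expression",
    "write_expression",
    "read_genotypes",
    "write_genotypes_vcf",
    "write_genotypes_tsv",
    "read_samples",
    "write_samples",
    "read_allele_counts",
    "write_allele_counts",
    "read_annotation",
    "write_annotation",
    "write_result_table",
    "write_result_tables",
    "read_result_table",
    "align_samples",
]


class SchemaError(ValueError):
    """Raised when an input table violates its declared schema."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()[:5]
        raise SchemaError(f"duplicate {what}: {dups}")


@dataclass
class ExpressionMatrix:
    """Gene x sample TPM matrix.  Index: gene ids; columns: sample ids."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        _check_unique(v.index, "gene ids")
        _check_unique(v.columns, "sample ids")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            bad = [c for c in v.columns if not np.issubdtype(v[c].dtype, np.number)]
            raise SchemaError(f"non-numeric expression column(s): {bad[:5]}")
        if not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise SchemaError(
                f"non-finite expression value at gene {v.index[i]!r}, sample {v.columns[j]!r}"
            )
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise SchemaError(
                f"negative expression value at gene {v.index[i]!r}, sample {v.columns[j]!r}"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class GenotypeMatrix:
    """SNP x sample dosage matrix (0/1/2 alt-allele count, NaN missing) with a
    SNP map (chrom, pos, ref, alt) sharing the same index."""

    dosages: pd.DataFrame
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.dosages.index, "snp ids")
        _check_unique(self.dosages.columns, "sample ids")
        if not self.dosages.index.equals(self.snps.index):
            raise SchemaError("dosage matrix and SNP map have different snp ids")
        missing_cols = {"chrom", "pos", "ref", "alt"} - set(self.snps.columns)
        if missing_cols:
            raise SchemaError(f"SNP map missing column(s): {sorted(missing_cols)}")
        if (self.snps["pos"] < 1).any():
            bad = self.snps.index[self.snps["pos"] < 1][0]
            raise SchemaError(f"SNP {bad!r} has position < 1 (coordinates are 1-based)")
        arr = self.dosages.to_numpy(dtype=float)
        obs = arr[~np.isnan(arr)]
        if not np.isin(obs, [0.0, 1.0, 2.0]).all():
            i, j = [
                (i, j)
                for i, j in np.argwhere(~np.isnan(arr))
                if arr[i, j] not in (0.0, 1.0, 2.0)
            ][0]
            raise SchemaError(
                f"dosage not in {{0,1,2,missing}} at SNP {self.dosages.index[i]!r}, "
                f"sample {self.dosages.columns[j]!r}"
            )

    @property
    def snp_ids(self) -> pd.Index:
        return self.dosages.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosages.columns


#: covariate columns every sample table must carry
SAMPLE_COLUMNS = ("sex", "batch", "boar", "age", "phenotype")


@dataclass
class SampleTable:
    """Per-sample covariates (sex, slaughter batch, boar, age in days) and the
    phenotype (IMF %).  Index: sample id."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "sample ids")
        missing = set(SAMPLE_COLUMNS) - set(self.data.columns)
        if missing:
            raise SchemaError(f"sample table missing column(s): {sorted(missing)}")
        pheno = self.data["phenotype"]
        present = pheno.notna()
        if not np.isfinite(pheno[present].to_numpy(dtype=float)).all():
            raise SchemaError("non-finite phenotype value")

    @property
    def sample_ids(self) -> pd.Index:
        return self.data.index

    @property
    def phenotype(self) -> pd.Series:
        return self.data["phenotype"].astype(float)


@dataclass
class AlleleCountTable:
    """Long-format per (SNP, sample) reference/alternate read counts."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"snp_id", "sample_id", "ref_count", "alt_count"} - set(
            self.counts.columns
        )
        if missing:
            raise SchemaError(f"allele count table missing column(s): {sorted(missing)}")
        for col in ("ref_count", "alt_count"):
            vals = self.counts[col]
            if not np.issubdtype(vals.dtype, np.integer):
                as_float = vals.to_numpy(dtype=float)
                if not np.isfinite(as_float).all() or (as_float % 1 != 0).any():
                    raise SchemaError(f"non-integer value in {col}")
                self.counts[col] = vals.astype(np.int64)
            if (self.counts[col] < 0).any():
                raise SchemaError(f"negative value in {col}")
        dup = self.counts.duplicated(subset=["snp_id", "sample_id"])
        if dup.any():
            row = self.counts[dup].iloc[0]
            raise SchemaError(
                f"duplicate allele-count entry for ({row['snp_id']}, {row['sample_id']})"
            )


@dataclass
class FeatureAnnotation:
    """Gene coordinates: chrom, start, end (1-based inclusive), optional strand.
    Index: gene id."""

    genes: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.genes.index, "gene ids")
        missing = {"chrom", "start", "end"} - set(self.genes.columns)
        if missing:
            raise SchemaError(f"annotation missing column(s): {sorted(missing)}")
        bad = self.genes["start"] > self.genes["end"]
        if bad.any():
            raise SchemaError(f"start > end for gene {self.genes.index[bad][0]!r}")
        if (self.genes["start"] < 1).any():
            raise SchemaError("annotation coordinates are 1-based; start must be >= 1")

    @property
    def gene_ids(self) -> pd.Index:
        return self.genes.index


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_expression(path: str | os.PathLike) -> ExpressionMatrix:
    """Read a TSV expression matrix: first column gene id, header = sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            raise SchemaError(
                f"non-numeric expression value(s) in sample column {col!r}"
                + (f" at gene {bad[0]!r}" if len(bad) else "")
            )
    return ExpressionMatrix(df.astype(float))


def write_expression(expr: ExpressionMatrix, path: str | os.PathLike) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


_GT_CODE = {"0/0": 0.0, "0|0": 0.0, "0/1": 1.0, "1/0": 1.0, "0|1": 1.0, "1|0": 1.0,
            "1/1": 2.0, "1|1": 2.0, "./.": np.nan, ".|.": np.nan, ".": np.nan}


def read_genotypes(
    path: str | os.PathLike,
    dialect: str = "vcf",
    snp_map: str | os.PathLike | None = None,
) -> GenotypeMatrix:
    """Read genotypes from a VCF (``dialect='vcf'``) or from a TSV dosage matrix
    plus a SNP map TSV with columns snp_id, chrom, pos, ref, alt
    (``dialect='tsv'``).

    VCF GT fields are recoded 0/0 -> 0, 0/1 -> 1, 1/1 -> 2, ./. -> missing.
    Multiallelic records are rejected.
    """
    if dialect == "vcf":
        return _read_vcf(path)
    if dialect == "tsv":
        if snp_map is None:
            raise SchemaError("tsv dialect requires a snp_map path")
        dos = pd.read_csv(path, sep="\t", index_col=0).astype(float)
        smap = pd.read_csv(snp_map, sep="\t", index_col=0)
        missing = dos.index.difference(smap.index)
        if len(missing):
            raise SchemaError(f"SNP map has no entry for {missing[0]!r}")
        smap = smap.loc[dos.index, ["chrom", "pos", "ref", "alt"]]
        smap["chrom"] = smap["chrom"].astype(str)
        return GenotypeMatrix(dos, smap)
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def _read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, rows, meta = [], [], []
    for v in vcf:
        if len(v.ALT) != 1:
            raise SchemaError(
                f"multiallelic record at {v.CHROM}:{v.POS} is unsupported"
            )
        sid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        # cyvcf2 gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        codes = np.asarray(v.gt_types, dtype=float)
        dos = np.where(codes == 0, 0.0,
              np.where(codes == 1, 1.0,
              np.where(codes == 3, 2.0, np.nan)))
        ids.append(sid)
        rows.append(dos)
        meta.append((str(v.CHROM), int(v.POS), v.REF, v.ALT[0]))
    dosages = pd.DataFrame(rows, index=pd.Index(ids, name="snp_id"), columns=samples)
    snps = pd.DataFrame(meta, index=dosages.index, columns=["chrom", "pos", "ref", "alt"])
    return GenotypeMatrix(dosages, snps)


_VCF_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_genotypes_vcf(gt: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a minimal VCF 4.2 with GT-only genotype fields."""
    order = np.lexsort(
        (gt.snps["pos"].to_numpy(), gt.snps["chrom"].astype(str).to_numpy())
    )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(gt.snps["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gt.sample_ids)
            + "\n"
        )
        dos = gt.dosages.to_numpy(dtype=float)
        for i in order:
            row = gt.snps.iloc[i]
            calls = "\t".join(
                _VCF_GT.get(d, "./.") if not np.isnan(d) else "./." for d in dos[i]
            )
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{gt.snp_ids[i]}\t"
                f"{row['ref']}\t{row['alt']}\t.\tPASS\t.\tGT\t{calls}\n"
            )


def write_genotypes_tsv(
    gt: GenotypeMatrix,
    dosage_path: str | os.PathLike,
    map_path: str | os.PathLike,
) -> None:
    out = gt.dosages.copy()
    out.to_csv(dosage_path, sep="\t", index_label="snp_id", float_format="%g")
    gt.snps.to_csv(map_path, sep="\t", index_label="snp_id")


def read_samples(path: str | os.PathLike) -> SampleTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={"sex": str, "batch": str, "boar": str})
    return SampleTable(df)


def write_samples(samples: SampleTable, path: str | os.PathLike) -> None:
    samples.data.to_csv(path, sep="\t", index_label="sample_id")


def read_allele_counts(path: str | os.PathLike) -> AlleleCountTable:
    df = pd.read_csv(path, sep="\t")
    return AlleleCountTable(df)


def write_allele_counts(counts: AlleleCountTable, path: str | os.PathLike) -> None:
    counts.counts.to_csv(path, sep="\t", index=False)


def read_annotation(path: str | os.PathLike) -> FeatureAnnotation:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return FeatureAnnotation(df)


def write_annotation(ann: FeatureAnnotation, path: str | os.PathLike) -> None:
    ann.genes.to_csv(path, sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

#: column-name based float formats for result serialization; p-values and FDRs
#: use scientific notation with 3 significant digits
_SCI_COLS = {"p", "fdr", "p_perm", "fdr_perm", "cor_p", "cor_fdr", "eqtl_p",
             "eqtl_fdr", "gwas_p", "p_threshold"}
_F2_COLS = {"ratio"}


def _format_cell(col: str, value) -> str:
    if pd.isna(value):
        return "NA"
    if col in _SCI_COLS:
        return f"{value:.2E}"
    if col in _F2_COLS:
        return f"{value:.2f}"
    if isinstance(value, (float, np.floating)):
        return f"{value:.4g}"
    if isinstance(value, (bool, np.bool_)):
        return str(bool(value))
    return str(value)


def write_result_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Serialize a result table as TSV with a deterministic column order and
    fixed float formats (scientific, 3 significant digits for p/FDR columns).

    Re-serializing a read-back table is byte-identical."""
    with open(path, "w") as fh:
        fh.write("\t".join(map(str, df.columns)) + "\n")
        for _, row in df.iterrows():
            fh.write("\t".join(_format_cell(c, row[c]) for c in df.columns) + "\n")


def read_result_table(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])


def write_result_tables(
    results: Mapping[str, pd.DataFrame], out_dir: str | os.PathLike
) -> dict[str, Path]:
    """Write each named result table as ``<out_dir>/<name>.tsv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in results.items():
        p = out_dir / f"{name}.tsv"
        write_result_table(df, p)
        paths[name] = p
    return paths


def align_samples(*id_sets: Sequence[str]) -> tuple[list[str], int]:
    """Intersect sample id collections, preserving the order of the first.

    Returns the shared ids and the number of ids dropped from the first set;
    the drop count is also logged."""
    if not id_sets:
        return [], 0
    first = list(id_sets[0])
    shared = set(first)
    for ids in id_sets[1:]:
        shared &= set(ids)
    kept = [s for s in first if s in shared]
    dropped = len(first) - len(kept)
    if dropped:
        logger.info("sample alignment dropped %d of %d samples", dropped, len(first))
    return kept, dropped
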