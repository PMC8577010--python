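"""Linear-model association: GWAS (SNP -> phenotype) and eQTL (SNP -> gene).

One shared OLS kernel serves both scans.  For each SNP the model regresses
the response on additive dosage (0/1/2) plus the fixed-model design columns;
the dosage slope is tested with a t-test.  The kernel uses the
Frisch-Waugh-Lovell decomposition: response and dosages are residualized on
the design once, after which every SNP reduces to a simple regression -- the
resulting slope, SE, t and p are exactly those of the full multiple
regression.  Alongside the slope, the signed model correlation

    r_assoc = sign(t) * sqrt(t^2 / (t^2 + df))

is reported, the statistic printed by MatrixEQTL-style tools.

eQTL runs add the top genotype principal components (and age) to the design,
classify each SNP-gene pair as cis (within a 1 Mb window of the gene body)
or trans, and adjust p-values with Benjamini-Hochberg within each scope.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_tables import FeatureAnnotation, GenotypeMatrix
from .preprocess import DesignMatrix

__all__ = [
    "GenotypePCs",
    "genotype_pcs",
    "linear_assoc",
    "association_scan",
    "classify_cis_trans",
    "bonferroni_threshold",
    "bh_fdr",
    "eqtl_scan",
    "gwas_scan",
]

CIS_WINDOW = 1_000_000  # bp, symmetric around the gene body


class GenotypePCs:
    """Top-k principal component scores of the standardized dosage matrix."""

    def __init__(self, scores: pd.DataFrame, explained_variance: np.ndarray):
        self.scores = scores
        self.explained_variance = explained_variance

    @property
    def sample_ids(self) -> pd.Index:
        return self.scores.index


def _imputed_dosages(gt: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """SNP x sample dosages with per-SNP mean imputation of missing calls.

    Returns (matrix, polymorphic_mask)."""
    D = gt.dosages.to_numpy(dtype=float).copy()
    means = np.nanmean(D, axis=1)
    idx = np.where(np.isnan(D))
    D[idx] = means[idx[0]]
    poly = D.std(axis=1) > 0
    return D, poly


def genotype_pcs(gt: GenotypeMatrix, k: int = 5) -> GenotypePCs:
    """PCA of the column-standardized dosage matrix (samples x SNPs).

    Missing dosages are mean-imputed per SNP and monomorphic SNPs dropped
    before standardization.  Scores are U * S from the SVD of the centered,
    unit-variance matrix; component signs are fixed so the largest-magnitude
    loading of each component is positive.
    """
    D, poly = _imputed_dosages(gt)
    X = D[poly].T  # samples x snps
    n, m = X.shape
    if k >= min(n, m):
        raise ValueError(f"k={k} must be < min(n_samples, n_snps)={min(n, m)}")
    X = (X - X.mean(axis=0)) / X.std(axis=0)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each right vector positive
    for j in range(k):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    scores = pd.DataFrame(
        U[:, :k] * S[:k],
        index=gt.sample_ids,
        columns=[f"PC{i + 1}" for i in range(k)],
    )
    return GenotypePCs(scores, explained_variance=(S[:k] ** 2) / (n - 1))


def _fwl_scan(Y: np.ndarray, G: np.ndarray, X: np.ndarray):
    """Vectorized per-SNP OLS of each row of Y on each row of G plus design X.

    Y: targets x samples, G: snps x samples, X: samples x p.
    Returns beta, se, t, p, r_assoc arrays of shape (snps, targets) and df.
    """
    n, p = X.shape
    Q = np.linalg.solve(X.T @ X, X.T)          # p x n
    Yr = Y - (Y @ Q.T) @ X.T                   # residualize rows on design
    Gr = G - (G @ Q.T) @ X.T
    gg = np.einsum("ij,ij->i", Gr, Gr)         # per-SNP residual sum of squares
    yy = np.einsum("ij,ij->i", Yr, Yr)
    num = Gr @ Yr.T                            # snps x targets
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = num / gg[:, None]
        rss = yy[None, :] - beta * num
        df = n - p - 1
        rss = np.clip(rss, 0.0, None)
        se = np.sqrt(rss / df / gg[:, None])
        t = beta / se
    p_val = 2.0 * stats.t.sf(np.abs(t), df)
    with np.errstate(invalid="ignore"):
        r_assoc = np.sign(t) * np.sqrt(t * t / (t * t + df))
    # exact fits (rss == 0) give infinite t
    p_val = np.where(np.isinf(t), 0.0, p_val)
    r_assoc = np.where(np.isinf(t), np.sign(t), r_assoc)
    return beta, se, t, p_val, r_assoc, df


def association_scan(
    Y: pd.DataFrame, gt: GenotypeMatrix, design: DesignMatrix
) -> dict[str, np.ndarray]:
    """Run the shared OLS kernel for every (SNP, target-row) pair.

    ``Y`` rows are targets (genes or a single phenotype row); columns must
    cover the design samples.  Monomorphic SNPs are flagged and excluded
    from the statistics (NaN)."""
    samples = design.sample_ids
    Ym = Y.loc[:, samples].to_numpy(dtype=float)
    D, poly = _imputed_dosages(
        GenotypeMatrix(gt.dosages.loc[:, samples], gt.snps)
    )
    X = design.matrix.to_numpy(dtype=float)
    beta = np.full((len(gt.snp_ids), Ym.shape[0]), np.nan)
    se = np.full_like(beta, np.nan)
    tstat = np.full_like(beta, np.nan)
    pval = np.full_like(beta, np.nan)
    r_assoc = np.full_like(beta, np.nan)
    if poly.any():
        b, s, t, p, r, df = _fwl_scan(Ym, D[poly], X)
        beta[poly], se[poly], tstat[poly], pval[poly], r_assoc[poly] = b, s, t, p, r
    else:
        df = X.shape[0] - X.shape[1] - 1
    return {
        "beta": beta, "se": se, "t": tstat, "p": pval, "r_assoc": r_assoc,
        "df": df, "monomorphic": ~poly,
    }


def linear_assoc(
    y: pd.Series, gt: GenotypeMatrix, design: DesignMatrix
) -> pd.DataFrame:
    """Per-SNP association of one response vector with additive dosage.

    Returns a DataFrame indexed by snp_id with beta, se, t, p, r_assoc and a
    ``monomorphic`` flag (such SNPs carry NaN statistics).
    """
    Y = pd.DataFrame([y.reindex(design.sample_ids)], index=["y"],
                     columns=design.sample_ids)
    res = association_scan(Y, gt, design)
    return pd.DataFrame(
        {
            "beta": res["beta"][:, 0],
            "se": res["se"][:, 0],
            "t": res["t"][:, 0],
            "p": res["p"][:, 0],
            "r_assoc": res["r_assoc"][:, 0],
            "monomorphic": res["monomorphic"],
        },
        index=gt.snp_ids,
    )


def classify_cis_trans(
    snp_chrom: str, snp_pos: int, gene: pd.Series, window: int = CIS_WINDOW
) -> str:
    """cis iff the SNP is on the gene's chromosome and within ``window`` bp of
    the gene body [start, end] (inclusive at the boundary); else trans."""
    if str(snp_chrom) != str(gene["chrom"]):
        return "trans"
    if gene["start"] <= snp_pos <= gene["end"]:
        return "cis"
    dist = min(abs(snp_pos - gene["start"]), abs(snp_pos - gene["end"]))
    return "cis" if dist <= window else "trans"


def bonferroni_threshold(alpha: float = 0.05, n_tests: int = 1) -> float:
    """Genome-wide significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _interval_distance(pos: np.ndarray, start: int, end: int) -> np.ndarray:
    """Distance from positions to the interval [start, end]; 0 inside."""
    return np.maximum.reduce([start - pos, pos - end, np.zeros_like(pos)])


def eqtl_scan(
    expr_log2: pd.DataFrame,
    gt: GenotypeMatrix,
    design: DesignMatrix,
    annotation: FeatureAnnotation,
    window: int = CIS_WINDOW,
) -> pd.DataFrame:
    """All-pairs SNP x gene association with cis/trans classification.

    ``expr_log2`` is the gene x sample log2 expression matrix (covariates are
    handled by the design, which should already include age and genotype
    PCs).  BH FDR is computed within the cis and trans scopes separately.
    Returns a long DataFrame: snp_id, gene_id, beta, r_assoc, p, fdr, type.
    """
    genes = [g for g in expr_log2.index if g in annotation.gene_ids]
    Y = expr_log2.loc[genes]
    res = association_scan(Y, gt, design)
    n_snps, n_genes = res["p"].shape

    ann = annotation.genes.loc[genes]
    snp_chrom = gt.snps["chrom"].astype(str).to_numpy()
    snp_pos = gt.snps["pos"].to_numpy()
    is_cis = np.zeros((n_snps, n_genes), dtype=bool)
    for j, g in enumerate(genes):
        row = ann.loc[g]
        same = snp_chrom == str(row["chrom"])
        d = _interval_distance(snp_pos[same], int(row["start"]), int(row["end"]))
        col = np.zeros(n_snps, dtype=bool)
        col[same] = d <= window
        is_cis[:, j] = col

    snp_idx, gene_idx = np.nonzero(~np.isnan(res["p"]))
    out = pd.DataFrame(
        {
            "snp_id": gt.snp_ids.to_numpy()[snp_idx],
            "gene_id": np.asarray(genes)[gene_idx],
            "beta": res["beta"][snp_idx, gene_idx],
            "r_assoc": res["r_assoc"][snp_idx, gene_idx],
            "p": res["p"][snp_idx, gene_idx],
            "type": np.where(is_cis[snp_idx, gene_idx], "cis", "trans"),
        }
    )
    out["fdr"] = np.nan
    for scope in ("cis", "trans"):
        m = out["type"] == scope
        if m.any():
            out.loc[m, "fdr"] = bh_fdr(out.loc[m, "p"].to_numpy())
    return out.sort_values(["gene_id", "p"], kind="stable").reset_index(drop=True)


def gwas_scan(
    phenotype: pd.Series,
    gt: GenotypeMatrix,
    design: DesignMatrix,
    standardize: bool = True,
    inverse_normal: bool = False,
) -> pd.DataFrame:
    """Per-SNP linear-regression GWAS of the phenotype.

    The phenotype is first residualized implicitly by the design inside the
    kernel; ``standardize`` additionally scales it to unit variance
    ("normalized" phenotype), and ``inverse_normal`` applies a rank-based
    inverse-normal transform instead.  Returns snp_id-indexed results with
    chrom/pos for Manhattan plotting.
    """
    y = phenotype.reindex(design.sample_ids).astype(float)
    if inverse_normal:
        ranks = y.rank()
        y = pd.Series(
            stats.norm.ppf((ranks - 0.5) / y.notna().sum()), index=y.index
        )
    elif standardize:
        y = (y - y.mean()) / y.std()
    res = linear_assoc(y, gt, design)
    res.insert(0, "pos", gt.snps["pos"])
    res.insert(0, "chrom", gt.snps["chrom"])
    return res
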