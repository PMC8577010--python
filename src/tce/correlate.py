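"""Trait-gene Pearson correlation on residuals with permutation-based FDR.

After covariate residualization, each gene's residual expression is
correlated with the residual phenotype.  Significance is assessed by a
trait-permutation null: the phenotype residual vector is jointly permuted
across samples (preserving the gene-gene correlation structure) and the full
set of gene p-values is recomputed per permutation.  The FDR at an observed
p-value t is the pooled-null estimator

    FDR(t) = mean_b #{perm p <= t} / #{obs p <= t}

made monotone (step-up) and clipped to [floor, 1].  The floor defaults to
1e-5, the most extreme FDR resolvable with 10,000 permutations as used in
the study design this pipeline follows.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import ResidualMatrix

__all__ = [
    "UndefinedCorrelationError",
    "pearson",
    "correlate_all",
    "permutation_fdr",
]


class UndefinedCorrelationError(ValueError):
    """Raised when a correlation is requested on a zero-variance vector."""


def _r_to_p(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p for a Pearson r at sample size n via the t transform
    t = r * sqrt((n-2) / (1-r^2)) against Student t with n-2 df."""
    r = np.clip(np.asarray(r, dtype=float), -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return np.where(np.abs(r) >= 1.0, 0.0, p)


def pearson(x, y) -> tuple[float, float]:
    """Product-moment Pearson correlation with a two-sided t-test p-value.

    Requires equal-length vectors of n >= 3 with non-zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("need n >= 3 for a correlation test")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt((xc * xc).sum())
    sy = np.sqrt((yc * yc).sum())
    if sx == 0.0 or sy == 0.0:
        raise UndefinedCorrelationError("zero variance in input vector")
    r = float((xc * yc).sum() / (sx * sy))
    r = max(-1.0, min(1.0, r))
    return r, float(_r_to_p(np.array([r]), n)[0])


def _standardize_rows(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center and scale rows to unit L2 norm; returns (Z, nonzero_mask)."""
    A = A - A.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(A, axis=1)
    ok = norms > 0
    Z = np.zeros_like(A)
    Z[ok] = A[ok] / norms[ok, None]
    return Z, ok


def correlate_all(
    expr_resid: ResidualMatrix | pd.DataFrame, pheno_resid: pd.Series
) -> pd.DataFrame:
    """Pearson r and p for every gene against the residual phenotype.

    Returns a DataFrame indexed by gene id (sorted) with columns ``r`` and
    ``p``.  Genes with zero residual variance get NaN r/p and a True
    ``zero_variance`` flag; they are excluded from downstream FDR.
    """
    R = expr_resid.residuals if isinstance(expr_resid, ResidualMatrix) else expr_resid
    y = pheno_resid.reindex(R.columns).to_numpy(dtype=float)
    if np.isnan(y).any():
        raise ValueError("phenotype residual missing for some samples")
    A = R.to_numpy(dtype=float)
    n = A.shape[1]
    Z, ok = _standardize_rows(A)
    yc = y - y.mean()
    ny = np.linalg.norm(yc)
    if ny == 0:
        raise UndefinedCorrelationError("zero variance in phenotype residual")
    r = Z @ (yc / ny)
    p = _r_to_p(r, n)
    out = pd.DataFrame(
        {"r": np.where(ok, r, np.nan), "p": np.where(ok, p, np.nan),
         "zero_variance": ~ok},
        index=R.index,
    )
    out.index.name = "gene_id"
    return out.sort_index()


def permutation_fdr(
    obs_p: pd.Series,
    expr_resid: ResidualMatrix | pd.DataFrame,
    pheno_resid: pd.Series,
    n_perm: int = 10_000,
    seed: int | None = None,
    floor: float = 1e-5,
) -> pd.Series:
    """Permutation FDR for the observed correlation p-values.

    One joint permutation of the phenotype residual per round; all gene
    p-values are recomputed in a single matrix product.  See the module
    docstring for the estimator.  ``seed`` is mandatory.
    """
    if seed is None:
        raise ValueError("seed is mandatory for the permutation FDR")
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is very low; FDR estimates will be noisy",
                      stacklevel=2)
    R = expr_resid.residuals if isinstance(expr_resid, ResidualMatrix) else expr_resid
    obs = obs_p.dropna()
    R = R.loc[obs.index]
    y = pheno_resid.reindex(R.columns).to_numpy(dtype=float)
    A = R.to_numpy(dtype=float)
    n = A.shape[1]
    Z, ok = _standardize_rows(A)
    if not ok.all():
        raise ValueError("zero-variance genes must be excluded before FDR")
    rng = np.random.default_rng(seed)
    perms = np.empty((n, n_perm))
    yc = y - y.mean()
    yn = yc / np.linalg.norm(yc)
    for b in range(n_perm):
        perms[:, b] = rng.permutation(yn)
    r_null = Z @ perms                       # genes x n_perm
    p_null = _r_to_p(r_null, n).ravel()
    p_null.sort()

    t = obs.to_numpy(dtype=float)
    order = np.argsort(t, kind="stable")
    t_sorted = t[order]
    n_obs_le = np.searchsorted(t_sorted, t_sorted, side="right")
    mean_null_le = np.searchsorted(p_null, t_sorted, side="right") / n_perm
    raw = mean_null_le / n_obs_le
    # step-up: enforce FDR non-decreasing in t
    stepped = np.minimum.accumulate(raw[::-1])[::-1]
    fdr_sorted = np.clip(stepped, floor, 1.0)
    fdr = np.empty_like(fdr_sorted)
    fdr[order] = fdr_sorted
    out = pd.Series(fdr, index=obs.index, name="fdr_perm")
    return out.reindex(obs_p.index)
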