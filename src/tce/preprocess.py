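"""Expression filtering, log2 transformation and covariate residualization.

Both the phenotype and every gene's log2 expression are adjusted with the
same fixed linear model

    Y = G + Ba + Bo + A + e

with sex (G), slaughter batch (Ba) and boar (Bo) as one-hot fixed effects and
age in days (A) as a numeric covariate; downstream statistics operate on the
residual e.  Extra numeric covariates (e.g. genotype principal components)
can be appended to the design.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .io_tables import ExpressionMatrix, SampleTable

logger = logging.getLogger(__name__)

__all__ = [
    "DesignMatrix",
    "ResidualMatrix",
    "RankDeficientDesignError",
    "filter_expressed",
    "log2_transform",
    "build_design",
    "residualize",
    "residualize_matrix",
]


class RankDeficientDesignError(ValueError):
    """Raised when one-hot encoding produces linearly dependent columns."""


@dataclass
class DesignMatrix:
    """Sample x covariate design: intercept, one-hot factors (first level
    dropped), numeric covariates.  Guaranteed full column rank."""

    matrix: pd.DataFrame

    @property
    def sample_ids(self) -> pd.Index:
        return self.matrix.index

    @property
    def n_params(self) -> int:
        return self.matrix.shape[1]

    def projector(self) -> np.ndarray:
        """Return pinv-style solve operator Q such that fitted = X @ (Q @ y)."""
        X = self.matrix.to_numpy(dtype=float)
        return np.linalg.solve(X.T @ X, X.T)


@dataclass
class ResidualMatrix:
    """Residuals of log2 expression (genes x samples) after OLS on the design,
    with the fitted coefficients kept for diagnostics."""

    residuals: pd.DataFrame
    coefficients: pd.DataFrame

    @property
    def gene_ids(self) -> pd.Index:
        return self.residuals.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.residuals.columns


def filter_expressed(
    expr: ExpressionMatrix, tpm_min: float = 0.01, sample_frac: float = 0.90
) -> ExpressionMatrix:
    """Keep genes whose TPM exceeds ``tpm_min`` (strictly) in strictly more
    than ``sample_frac`` of samples.

    Both inequalities are strict: a gene expressed in exactly 90% of samples
    is dropped under the default threshold.
    """
    v = expr.values
    frac = (v.to_numpy() > tpm_min).mean(axis=1)
    keep = frac > sample_frac
    if not keep.any():
        warnings.warn("expression filter removed every gene", stacklevel=2)
    logger.info("expression filter kept %d of %d genes", int(keep.sum()), len(keep))
    return ExpressionMatrix(v.loc[keep])


def log2_transform(expr: ExpressionMatrix, offset: float = 1.0) -> pd.DataFrame:
    """Return log2(TPM + offset) as a gene x sample DataFrame."""
    v = expr.values.to_numpy()
    if (v + offset <= 0).any():
        raise ValueError("log2 transform undefined: value + offset <= 0")
    return pd.DataFrame(
        np.log2(v + offset), index=expr.values.index, columns=expr.values.columns
    )


def build_design(
    samples: SampleTable,
    factors: tuple[str, ...] = ("sex", "batch", "boar"),
    numeric: tuple[str, ...] = ("age",),
    extra: pd.DataFrame | None = None,
) -> DesignMatrix:
    """Construct the fixed-model design matrix from a sample table.

    One-hot encodes each factor dropping its first level, adds an intercept
    and the numeric covariates, and optionally appends extra numeric columns
    (e.g. genotype PCs) aligned on sample id.  Samples with any missing
    covariate are dropped listwise (logged).  Raises
    :class:`RankDeficientDesignError` naming aliased columns if the result is
    rank deficient.
    """
    df = samples.data
    needed = list(factors) + list(numeric)
    complete = df[needed].notna().all(axis=1)
    if (~complete).any():
        logger.info("dropping %d samples with missing covariates", int((~complete).sum()))
    df = df.loc[complete]

    cols = {"intercept": pd.Series(1.0, index=df.index)}
    for f in factors:
        fac = df[f].astype(str)
        counts = fac.value_counts()
        small = counts[counts < 3]
        if len(small):
            warnings.warn(
                f"factor {f!r} has level(s) with < 3 samples: {sorted(small.index)[:5]}",
                stacklevel=2,
            )
        levels = sorted(fac.unique())
        for lev in levels[1:]:  # drop first level
            cols[f"{f}[{lev}]"] = (fac == lev).astype(float)
    for c in numeric:
        cols[c] = df[c].astype(float)
    X = pd.DataFrame(cols, index=df.index)
    if extra is not None:
        missing = X.index.difference(extra.index)
        if len(missing):
            raise ValueError(f"extra covariates missing sample(s): {list(missing[:5])}")
        X = pd.concat([X, extra.loc[X.index].astype(float)], axis=1)

    _check_full_rank(X)
    return DesignMatrix(X)


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    _, R, piv = linalg.qr(arr, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(arr.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        aliased = [X.columns[piv[i]] for i in range(rank, X.shape[1])]
        raise RankDeficientDesignError(
            f"design matrix is rank deficient; aliased column(s): {aliased}"
        )


def residualize(
    y: pd.Series | np.ndarray, design: DesignMatrix
) -> tuple[pd.Series, pd.Series]:
    """OLS-residualize a vector on the design.

    Returns ``(residuals, coefficients)``.  ``y`` must align with the design's
    samples (a Series is reindexed; a bare array must match in length).
    """
    X = design.matrix.to_numpy(dtype=float)
    if isinstance(y, pd.Series):
        y = y.reindex(design.sample_ids)
    yv = np.asarray(y, dtype=float)
    if yv.shape[0] != X.shape[0]:
        raise ValueError("y length does not match design rows")
    if not np.isfinite(yv).all():
        raise ValueError("y contains non-finite values")
    coef, *_ = np.linalg.lstsq(X, yv, rcond=None)
    resid = yv - X @ coef
    return (
        pd.Series(resid, index=design.sample_ids, name="residual"),
        pd.Series(coef, index=design.matrix.columns, name="coefficient"),
    )


def residualize_matrix(Y: pd.DataFrame, design: DesignMatrix) -> ResidualMatrix:
    """Residualize every row of a gene x sample matrix on the design at once."""
    Ym = Y.loc[:, design.sample_ids].to_numpy(dtype=float)
    X = design.matrix.to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(X, Ym.T, rcond=None)
    resid = Ym - (X @ coef).T
    return ResidualMatrix(
        residuals=pd.DataFrame(resid, index=Y.index, columns=design.sample_ids),
        coefficients=pd.DataFrame(coef.T, index=Y.index, columns=design.matrix.columns),
    )
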