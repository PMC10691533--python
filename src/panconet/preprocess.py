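"""Expression preprocessing: low-expression filtering, log2 transform, and
linear covariate adjustment.

Genes with missing or zero values in more than 75% of samples are removed,
values are log2(x + offset) transformed, and each gene is replaced by the
residuals of an ordinary-least-squares fit on intercept + covariates (age,
sex, race by default) so that downstream correlations are not driven by
demographic confounders.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger("panconet")


def filter_genes(raw: pd.DataFrame, max_bad_fraction: float = 0.75) -> pd.DataFrame:
    """Drop genes whose fraction of missing-or-zero entries exceeds the cutoff.

    A gene is retained when (n_missing + n_zero) / n_samples <= max_bad_fraction
    (removal uses the strict ``>`` comparison); input order is preserved.
    """
    bad = (raw.isna() | (raw == 0)).sum(axis=1) / raw.shape[1]
    kept = raw.loc[bad <= max_bad_fraction]
    n_removed = raw.shape[0] - kept.shape[0]
    if n_removed:
        logger.info("filter_genes: removed %d of %d genes (> %.0f%% missing/zero)",
                    n_removed, raw.shape[0], 100 * max_bad_fraction)
    if kept.empty:
        raise ValueError("no genes pass filter")
    return kept


def log2_transform(matrix: pd.DataFrame, offset: float = 1.0) -> pd.DataFrame:
    """log2(x + offset); requires nonnegative input."""
    if (matrix < 0).any().any():
        raise ValueError("log2_transform requires nonnegative values")
    return np.log2(matrix + offset)


def _design_matrix(covariates: pd.DataFrame) -> pd.DataFrame:
    """Intercept + numeric columns + indicator contrasts for categoricals.

    Constant (or otherwise degenerate) columns are dropped with a warning so
    the design stays full rank.
    """
    parts = [pd.Series(1.0, index=covariates.index, name="(intercept)")]
    for col in covariates.columns:
        s = covariates[col]
        if pd.api.types.is_numeric_dtype(s):
            parts.append(s.astype(float))
        else:
            dummies = pd.get_dummies(s.astype(str), prefix=col, drop_first=True)
            parts.extend(dummies[c].astype(float) for c in dummies.columns)
    X = pd.concat(parts, axis=1)
    # drop columns that are constant (beyond the intercept) or duplicated
    keep = ["(intercept)"]
    for col in X.columns[1:]:
        v = X[col].dropna()
        if v.nunique() <= 1:
            logger.warning("adjust_covariates: dropping constant covariate "
                           "column %r", col)
            continue
        keep.append(col)
    X = X[keep]
    # rank check on complete rows
    complete = X.dropna()
    if len(complete):
        rank = np.linalg.matrix_rank(complete.to_numpy())
        while rank < X.shape[1]:
            dropped = X.columns[-1]
            logger.warning("adjust_covariates: dropping rank-deficient "
                           "covariate column %r", dropped)
            X = X.iloc[:, :-1]
            rank = np.linalg.matrix_rank(X.dropna().to_numpy())
    return X


def adjust_covariates(matrix: pd.DataFrame,
                      covariates: pd.DataFrame) -> pd.DataFrame:
    """Replace every gene row by OLS residuals on intercept + covariates.

    Covariate rows must align with the matrix's samples. Missing expression
    entries are handled per gene by complete-case fitting; their residuals
    stay missing. Residual rows are orthogonal to every design column.
    """
    missing = matrix.columns.difference(covariates.index)
    if len(missing):
        raise ValueError(f"covariates missing for sample {missing[0]!r}")
    X = _design_matrix(covariates.loc[matrix.columns])
    Xv = X.to_numpy(dtype=float)
    Y = matrix.to_numpy(dtype=float)

    resid = np.full_like(Y, np.nan)
    obs_ok = ~np.isnan(Y)
    cov_ok = ~np.isnan(Xv).any(axis=1)
    full_rows = obs_ok.all(axis=1)

    if full_rows.any() and cov_ok.all():
        # vectorized fit for fully observed genes
        Q, _ = np.linalg.qr(Xv)
        Yf = Y[full_rows]
        resid[full_rows] = Yf - (Yf @ Q) @ Q.T
    for i in np.flatnonzero(~full_rows if cov_ok.all() else
                            np.ones(Y.shape[0], bool)):
        mask = obs_ok[i] & cov_ok
        if mask.sum() <= Xv.shape[1]:
            logger.warning("adjust_covariates: gene %r has too few observed "
                           "samples; centered only", matrix.index[i])
            resid[i, mask] = Y[i, mask] - np.nanmean(Y[i, mask])
            continue
        Xi = Xv[mask]
        beta, *_ = np.linalg.lstsq(Xi, Y[i, mask], rcond=None)
        resid[i, mask] = Y[i, mask] - Xi @ beta
    return pd.DataFrame(resid, index=matrix.index, columns=matrix.columns)


def preprocess(raw: pd.DataFrame, covariates: pd.DataFrame | None = None, *,
               max_bad_fraction: float = 0.75, apply_log2: bool = True,
               log2_offset: float = 1.0) -> pd.DataFrame:
    """Filter, optionally log2-transform, and covariate-adjust a raw matrix."""
    m = filter_genes(raw, max_bad_fraction)
    if apply_log2:
        m = log2_transform(m, log2_offset)
    if covariates is not None and len(covariates.columns):
        m = adjust_covariates(m, covariates)
    else:
        m = m.sub(m.mean(axis=1), axis=0)
    return m
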