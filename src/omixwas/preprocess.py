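"""Omic preprocessing: rank-based inverse normal transform, principal
component and surrogate-value scores, chi-squared outlier removal, and
covariate residualization.

The pipeline order is fixed: normalize -> score (PCs + surrogate values) ->
chi-squared outlier filter (union over the two score sets) -> recompute
scores on the retained samples -> residualize on covariates + surrogate
values.  Surrogate values are the top singular directions of the
covariate-residualized matrix — a deterministic two-step variant of
surrogate variable analysis that serves the same two purposes here:
outlier detection and adjustment for unobserved factors.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def inverse_normal_transform(values, offset: float = 0.5) -> np.ndarray:
    """Rank-based inverse normal transform.

    Maps value with (average, tie-aware) rank r among n to
    ``Phi^-1((r - offset) / (n - 2*offset + 1))``; the default offset 0.5
    gives ``Phi^-1((r - 0.5)/n)``.  Blom's variant uses offset 3/8.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-d vector with n >= 2")
    if np.ptp(x) == 0:
        raise ValueError("constant vector cannot be inverse-normalized")
    ranks = stats.rankdata(x, method="average")
    n = x.size
    return stats.norm.ppf((ranks - offset) / (n - 2.0 * offset + 1.0))


def _center(X: np.ndarray) -> np.ndarray:
    return X - X.mean(axis=0)


def _unit_variance_scores(U: np.ndarray, s: np.ndarray, k: int) -> np.ndarray:
    scores = U[:, :k] * s[:k]
    sd = scores.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance score column (degenerate matrix)")
    return scores / sd


def compute_pc_scores(matrix: pd.DataFrame, k: int) -> pd.DataFrame:
    """Top-k principal component scores of the column-centered matrix,
    scaled to unit variance per column."""
    n = matrix.shape[0]
    if k >= n:
        raise ValueError(f"k ({k}) must be < n_samples ({n})")
    X = _center(matrix.to_numpy(dtype=float))
    if not np.any(X.std(axis=0) > 0):
        raise ValueError("zero-variance matrix: identical samples")
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = _unit_variance_scores(U, s, k)
    return pd.DataFrame(scores, index=matrix.index,
                        columns=[f"PC{j + 1}" for j in range(k)])


def _design(covariates: pd.DataFrame) -> np.ndarray:
    D = np.column_stack([np.ones(covariates.shape[0]),
                         covariates.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(D) < D.shape[1]:
        names = _collinear_columns(covariates)
        raise ValueError(f"rank-deficient covariate design; collinear "
                         f"columns: {names}")
    return D


def _collinear_columns(covariates: pd.DataFrame) -> list[str]:
    D = np.ones((covariates.shape[0], 1))
    bad = []
    for name in covariates.columns:
        cand = np.column_stack([D, covariates[name].to_numpy(dtype=float)])
        if np.linalg.matrix_rank(cand) == cand.shape[1]:
            D = cand
        else:
            bad.append(name)
    return bad


def estimate_surrogate_values(matrix: pd.DataFrame,
                              covariates: pd.DataFrame,
                              k: int) -> pd.DataFrame:
    """Surrogate values: regress each feature on the covariates, then take
    the top-k left singular directions of the residual matrix (unit
    variance per column)."""
    n = matrix.shape[0]
    if k >= n:
        raise ValueError(f"k ({k}) must be < n_samples ({n})")
    D = _design(covariates.loc[matrix.index])
    Y = matrix.to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(D, Y, rcond=None)
    R = Y - D @ coef
    if float(np.abs(R).max()) < 1e-10:
        raise ValueError("covariates explain all variance; residual matrix "
                         "is (numerically) zero")
    U, s, _ = np.linalg.svd(_center(R), full_matrices=False)
    scores = _unit_variance_scores(U, s, k)
    return pd.DataFrame(scores, index=matrix.index,
                        columns=[f"SV{j + 1}" for j in range(k)])


def chisq_outlier_filter(score_table: pd.DataFrame,
                         alpha: float = 0.001) -> pd.Index:
    """Samples whose squared score norm is not an outlier.

    With k standardized score columns, d = sum_j s_j^2 is chi-squared with
    k degrees of freedom under multivariate normality; samples with upper
    tail probability below ``alpha`` are removed.  Returns retained ids.
    """
    S = score_table.to_numpy(dtype=float)
    d = np.sum(S * S, axis=1)
    p = stats.chi2.sf(d, df=S.shape[1])
    return score_table.index[p >= alpha]


def residualize(matrix: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """OLS residuals of every feature on the design (plus intercept).

    Residuals are orthogonal to every design column by construction; rank
    deficiency raises an error naming the collinear columns.
    """
    D = _design(design.loc[matrix.index])
    Y = matrix.to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(D, Y, rcond=None)
    return pd.DataFrame(Y - D @ coef, index=matrix.index,
                        columns=matrix.columns)


def preprocess_layer(matrix: pd.DataFrame, covariates: pd.DataFrame,
                     n_pcs: int = 10, n_surrogates: int = 10,
                     outlier_alpha: float = 0.001,
                     int_offset: float = 0.5,
                     recompute_after_filter: bool = True,
                     ) -> tuple[pd.DataFrame, pd.Index, dict]:
    """Full preprocessing for one omic layer.

    Inverse-normalize each feature, compute PC and surrogate-value scores,
    remove samples failing the chi-squared outlier test on either score set
    (union), optionally recompute scores on the retained samples, then
    residualize on covariates + surrogate values.

    Returns ``(residuals, retained_sample_ids, run_log)``.
    """
    norm = matrix.apply(lambda col: inverse_normal_transform(col, int_offset),
                        axis=0)
    covs = covariates.loc[norm.index]
    pcs = compute_pc_scores(norm, n_pcs)
    svs = estimate_surrogate_values(norm, covs, n_surrogates)
    keep_pc = chisq_outlier_filter(pcs, outlier_alpha)
    keep_sv = chisq_outlier_filter(svs, outlier_alpha)
    retained = norm.index[norm.index.isin(keep_pc) & norm.index.isin(keep_sv)]
    log = {
        "n_input_samples": int(matrix.shape[0]),
        "n_features": int(matrix.shape[1]),
        "n_removed_pc": int(matrix.shape[0] - len(keep_pc)),
        "n_removed_sv": int(matrix.shape[0] - len(keep_sv)),
        "n_removed_union": int(matrix.shape[0] - len(retained)),
        "n_retained": int(len(retained)),
        "order": ["normalize", "scores", "outlier_filter",
                  "rescore" if recompute_after_filter else "reuse_scores",
                  "residualize"],
    }
    norm = norm.loc[retained]
    covs = covs.loc[retained]
    if recompute_after_filter:
        svs = estimate_surrogate_values(norm, covs, n_surrogates)
    else:
        svs = svs.loc[retained]
    design = pd.concat([covs, svs], axis=1)
    residuals = residualize(norm, design)
    return residuals, retained, log
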