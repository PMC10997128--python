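"""Composite undernutrition index from anthropometric z-scores.

Stunting, underweight and wasting are measured by the height-for-age (HAZ),
weight-for-age (WAZ) and weight-for-height (WHZ) z-scores.  Because the three
indicators are substantially correlated, a single composite index is formed
as the first principal component of their correlation matrix: the PC1
loadings weight each z-score and the per-child weighted sum is dichotomised
at a cutoff (default -2, the conventional undernutrition threshold) into
nourished / undernourished.

The cutoff is applied to the raw PC1-weighted sum by default, whose standard
deviation is sqrt(lambda1) rather than 1; ``standardize=True`` rescales the
composite to unit variance first for the statistically conventional variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CompositeIndexResult",
    "correlation_matrix",
    "principal_components",
    "composite_scores",
    "classify_undernutrition",
    "build_composite_index",
]

ZSCORE_COLUMNS = ("haz", "waz", "whz")


@dataclass
class CompositeIndexResult:
    corr: np.ndarray
    eigenvalues: np.ndarray
    loadings: np.ndarray            # columns: unit-norm eigenvectors
    proportion_explained: np.ndarray
    composite_scores: pd.Series
    undernutrition: pd.Series
    cutoff: float = -2.0
    standardized: bool = False
    n_used: int = 0
    n_dropped: int = 0

    def report(self) -> dict:
        """Eigenstructure summary in plain types (for JSON/text rendering)."""
        return {
            "eigenvalues": self.eigenvalues.tolist(),
            "proportion_explained": self.proportion_explained.tolist(),
            "cumulative_proportion": np.cumsum(self.proportion_explained).tolist(),
            "loadings": self.loadings.tolist(),
            "correlation": self.corr.tolist(),
            "cutoff": self.cutoff,
            "standardized": self.standardized,
            "n_used": self.n_used,
            "n_dropped": self.n_dropped,
            "undernutrition_prevalence": float(self.undernutrition.mean()),
        }


def correlation_matrix(records: pd.DataFrame, weights=None) -> np.ndarray:
    """(Weighted) Pearson correlation matrix of the three z-score columns.

    Requires at least 3 complete rows; raises on non-finite or constant
    columns.  With weights, means/covariances are weighted averages.
    """
    x = records.loc[:, list(ZSCORE_COLUMNS)].to_numpy(dtype=float)
    if x.shape[0] < 3:
        raise ValueError("need at least 3 complete rows")
    if not np.isfinite(x).all():
        raise ValueError("z-scores must be finite")
    if weights is None:
        w = np.ones(x.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be nonnegative, not all zero")
    w = w / w.sum()
    mean = w @ x
    xc = x - mean
    cov = (xc * w[:, None]).T @ xc
    sd = np.sqrt(np.diag(cov))
    if np.any(sd == 0):
        raise ValueError("a z-score column is constant; correlation undefined")
    corr = cov / np.outer(sd, sd)
    np.fill_diagonal(corr, 1.0)
    return 0.5 * (corr + corr.T)


def principal_components(corr: np.ndarray):
    """Eigen-decomposition of a correlation matrix, PCA convention.

    Returns ``(eigenvalues, loadings, proportion_explained)`` with
    eigenvalues in descending order and each loading column sign-flipped so
    its largest-magnitude entry is positive (for PC1 of a positively
    correlated triplet this makes all three loadings positive).
    """
    corr = np.asarray(corr, dtype=float)
    if corr.shape[0] != corr.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    if eigvals[-1] < -1e-10:
        raise ValueError("correlation matrix is not positive semi-definite")
    for j in range(eigvecs.shape[1]):
        k = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[k, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    proportion = eigvals / eigvals.sum()
    return eigvals, eigvecs, proportion


def composite_scores(records: pd.DataFrame, loadings_pc1) -> pd.Series:
    """Per-child composite score ``l1*HAZ + l2*WAZ + l3*WHZ``.

    ``loadings_pc1`` must be approximately unit-norm (within 1e-2, so that
    printed 3-dp loadings such as (0.521, 0.600, 0.608) pass).  Rows with any
    missing z-score are excluded (complete-case) and reported via the index
    of the returned series.
    """
    load = np.asarray(loadings_pc1, dtype=float)
    if abs(np.linalg.norm(load) - 1.0) > 1e-2:
        raise ValueError("PC1 loadings must be (approximately) unit norm")
    sub = records.loc[:, list(ZSCORE_COLUMNS)]
    complete = sub.notna().all(axis=1)
    if (~complete).any():
        warnings.warn(
            f"dropping {(~complete).sum()} rows with missing z-scores "
            "(complete-case)",
            UserWarning,
        )
    x = sub.loc[complete].to_numpy(dtype=float)
    return pd.Series(x @ load, index=sub.index[complete], name="composite")


def classify_undernutrition(scores, cutoff: float = -2.0) -> pd.Series:
    """Dichotomise composite scores: 1 (undernourished) iff score < cutoff.

    The inequality is strict: a score exactly at the cutoff is nourished.
    """
    s = pd.Series(scores)
    if not np.isfinite(s.to_numpy(dtype=float)).all():
        raise ValueError("scores must be finite")
    return (s < cutoff).astype(int).rename("undernutrition")


def build_composite_index(
    records: pd.DataFrame,
    cutoff: float = -2.0,
    standardize: bool = False,
    weights=None,
    min_pc1_proportion: float = 0.5,
) -> CompositeIndexResult:
    """Full pipeline: correlation -> PCA -> composite score -> dichotomy.

    A warning (not an error) is raised when PC1 explains less than
    ``min_pc1_proportion`` of the total variance, since a single composite
    is then a questionable summary of the three indicators.
    """
    sub = records.loc[:, list(ZSCORE_COLUMNS)]
    complete = sub.notna().all(axis=1)
    used = records.loc[complete]
    w = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)[complete.to_numpy()]
    corr = correlation_matrix(used, weights=w)
    eigvals, loadings, proportion = principal_components(corr)
    if proportion[0] < min_pc1_proportion:
        warnings.warn(
            f"PC1 explains only {proportion[0]:.1%} of total variance; "
            "a single composite index may be inadequate",
            UserWarning,
        )
    scores = composite_scores(used, loadings[:, 0])
    if standardize:
        scores = scores / np.sqrt(eigvals[0])
    undernutrition = classify_undernutrition(scores, cutoff=cutoff)
    return CompositeIndexResult(
        corr=corr,
        eigenvalues=eigvals,
        loadings=loadings,
        proportion_explained=proportion,
        composite_scores=scores,
        undernutrition=undernutrition,
        cutoff=cutoff,
        standardized=standardize,
        n_used=int(complete.sum()),
        n_dropped=int((~complete).sum()),
    )
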