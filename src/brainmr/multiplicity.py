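"""Multiple-testing control across correlated imaging outcomes.

Imaging panels measure many strongly correlated phenotypes; a raw
Bonferroni correction over all of them is too severe.  The effective number
of independent tests is estimated as the number of principal components
explaining a stated share (default 95%) of the outcome-matrix variance, and
the family-wise threshold is alpha divided by that count.  Benjamini-
Hochberg FDR adjustment is also provided here and reused by the
transcriptomics stages.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "MultiplicityDecision",
    "effective_tests_pca",
    "effective_tests_from_correlation",
    "bonferroni_threshold",
    "bh_fdr",
]


@dataclass
class MultiplicityDecision:
    n_eff: int
    variance_threshold: float = 0.95
    alpha: float = 0.05

    @property
    def threshold(self) -> float:
        return bonferroni_threshold(self.alpha, self.n_eff)


def effective_tests_from_correlation(corr: np.ndarray, variance_threshold: float = 0.95) -> int:
    """Smallest k whose top-k eigenvalue share of ``corr`` reaches the threshold."""
    if not 0 < variance_threshold <= 1:
        raise ValueError("variance_threshold must lie in (0, 1]")
    corr = np.asarray(corr, float)
    eig = np.linalg.eigvalsh(corr)[::-1]
    eig = np.clip(eig, 0.0, None)  # numerical negatives from near-singular blocks
    share = np.cumsum(eig) / eig.sum()
    return int(np.searchsorted(share, variance_threshold - 1e-12) + 1)


def effective_tests_pca(
    matrix: pd.DataFrame | np.ndarray, variance_threshold: float = 0.95
) -> int:
    """Effective number of tests for an individuals x measures matrix.

    Columns are centered and scaled to unit variance (PCA on the correlation
    matrix — measures mix volumes and thicknesses, so scales differ);
    missing entries are mean-imputed per column; zero-variance columns are
    dropped with a warning.
    """
    x = np.asarray(matrix, float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least 2 individuals (rows)")
    if x.shape[1] < 1:
        raise ValueError("need at least 1 measure (column)")
    if np.isnan(x).any():
        col_mean = np.nanmean(x, axis=0)
        x = np.where(np.isnan(x), col_mean, x)
    sd = x.std(axis=0, ddof=1)
    if (sd == 0).any():
        logger.warning("dropping %d zero-variance measures before PCA", int((sd == 0).sum()))
        x = x[:, sd > 0]
        if x.shape[1] == 0:
            raise ValueError("all measures have zero variance")
    corr = np.corrcoef(x, rowvar=False)
    corr = np.atleast_2d(corr)
    return effective_tests_from_correlation(corr, variance_threshold)


def bonferroni_threshold(alpha: float, n_eff: int) -> float:
    """Family-wise significance threshold alpha / N_eff."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if n_eff < 1:
        raise ValueError("n_eff must be a positive integer")
    return alpha / n_eff


def bh_fdr(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, order-preserving."""
    p = np.asarray(p, float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]
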