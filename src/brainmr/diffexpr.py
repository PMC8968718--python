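"""Region-versus-rest differential expression on log2 intensities.

Probes are collapsed to genes (max-mean probe by default), expression may
be z-score normalized per gene for presentation, and each gene is tested
with a Welch two-sample t-test of the target region's samples against all
other samples.  logFC is the difference of group mean log2 values (target
minus rest), q-values are Benjamini-Hochberg, and the region's
overexpressed gene set is the strict filter ``q < 0.05 and logFC > 2``.

The Welch test is used rather than a moderated (empirical-Bayes) test: it
is assumption-light at atlas-scale sample counts per region; a moderated
variant is a natural extension point.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .multiplicity import bh_fdr
from .simulate import ExpressionMatrix

__all__ = [
    "collapse_probes",
    "zscore_normalize",
    "differential_expression",
    "filter_overexpressed",
]


def collapse_probes(expr: ExpressionMatrix, rule: str = "max_mean") -> pd.DataFrame:
    """Collapse probes x samples to a gene x sample matrix.

    ``max_mean`` keeps, per gene, the probe with the highest mean intensity
    across samples; ``mean`` averages a gene's probes per sample.
    """
    if rule not in ("max_mean", "mean"):
        raise ValueError(f"unknown collapse rule {rule!r}")
    genes = expr.probe_to_gene.loc[expr.values.index]
    if rule == "mean":
        return expr.values.groupby(genes).mean().sort_index()
    means = expr.values.mean(axis=1)
    best = means.groupby(genes).idxmax()
    out = expr.values.loc[best.values]
    out.index = best.index
    return out.sort_index()


def zscore_normalize(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene z-score normalization (divisor n-1).

    Returns the normalized matrix and the list of zero-variance genes,
    which are left at 0 rather than producing NaNs.
    """
    mean = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    flagged = sd.index[sd == 0].tolist()
    safe_sd = sd.replace(0, 1.0)
    out = matrix.sub(mean, axis=0).div(safe_sd, axis=0)
    out.loc[flagged] = 0.0
    return out, flagged


def differential_expression(
    matrix: pd.DataFrame,
    sample_to_region: pd.Series,
    target: str,
) -> pd.DataFrame:
    """Welch t-test of the target region against all other samples, per gene.

    Returns a frame with ``gene, logFC, t, p, q, direction`` where
    ``logFC = mean(target) - mean(rest)`` on log2 values and q is BH-FDR
    across genes.
    """
    regions = sample_to_region.loc[matrix.columns]
    in_target = (regions == target).to_numpy()
    if in_target.sum() < 2 or (~in_target).sum() < 2:
        raise ValueError(
            f"need >=2 samples in {target!r} and >=2 elsewhere "
            f"(got {int(in_target.sum())} and {int((~in_target).sum())})"
        )
    a = matrix.to_numpy(float)[:, in_target]
    b = matrix.to_numpy(float)[:, ~in_target]
    t, p = sps.ttest_ind(a, b, axis=1, equal_var=False)
    # degenerate rows (both groups constant and equal) give nan -> null outcome
    t = np.where(np.isnan(t), 0.0, t)
    p = np.clip(np.where(np.isnan(p), 1.0, p), np.finfo(float).tiny, 1.0)
    logfc = a.mean(axis=1) - b.mean(axis=1)
    out = pd.DataFrame(
        {
            "gene": matrix.index,
            "logFC": logfc,
            "t": t,
            "p": p,
            "q": bh_fdr(p),
            "direction": np.sign(logfc).astype(int),
        }
    )
    return out.reset_index(drop=True)


def filter_overexpressed(
    results: pd.DataFrame, q_max: float = 0.05, logfc_min: float = 2.0
) -> list[str]:
    """Genes with ``q < q_max`` and ``logFC > logfc_min`` (both strict).

    Only the positive direction is filtered; underexpression is reported by
    the caller as an observation, not removed here.
    """
    if results.empty:
        return []
    keep = (results["q"] < q_max) & (results["logFC"] > logfc_min)
    return sorted(results.loc[keep, "gene"])
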