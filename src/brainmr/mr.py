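"""Two-sample inverse-variance-weighted MR with correlated instruments.

For J instruments with exposure associations ``gamma`` and outcome
associations ``Gamma`` (SEs ``se_y``) whose pairwise LD correlations are
``rho``, the causal effect of the exposure on the outcome is estimated by
generalized least squares::

    Omega_jk = se_y[j] * se_y[k] * rho[j, k]
    beta_hat = (gamma' Omega^-1 gamma)^-1  gamma' Omega^-1 Gamma
    se(beta_hat) = (gamma' Omega^-1 gamma)^(-1/2)

With ``rho`` the identity this collapses to the textbook IVW estimator
``sum(gamma_j Gamma_j / se_y_j^2) / sum(gamma_j^2 / se_y_j^2)``.  First-order
weights are used: exposure-side uncertainty ``se_x`` is carried in the data
model but not propagated (the standard no-measurement-error convention).
Estimates divided by their standard errors are reported as z scores, with a
positive z meaning genetically predicted biomarker levels positively
associated with the outcome measure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .instruments import HarmonizationError, InstrumentSet, SummaryStats, harmonize

logger = logging.getLogger(__name__)

__all__ = ["MRInput", "MRResult", "ivw_correlated", "two_tailed_p", "run_panel"]

#: condition-number ceiling beyond which Omega gets one ridge bump
_COND_MAX = 1e10
_RIDGE = 1e-8


@dataclass
class MRInput:
    """Aligned per-instrument associations plus LD for one exposure/outcome pair."""

    gamma: np.ndarray
    se_x: np.ndarray
    Gamma: np.ndarray
    se_y: np.ndarray
    rho: np.ndarray

    def __post_init__(self) -> None:
        self.gamma = np.atleast_1d(np.asarray(self.gamma, float))
        self.se_x = np.atleast_1d(np.asarray(self.se_x, float))
        self.Gamma = np.atleast_1d(np.asarray(self.Gamma, float))
        self.se_y = np.atleast_1d(np.asarray(self.se_y, float))
        self.rho = np.atleast_2d(np.asarray(self.rho, float))
        j = len(self.gamma)
        if j < 1:
            raise ValueError("at least one instrument is required")
        for name, v in (("se_x", self.se_x), ("Gamma", self.Gamma), ("se_y", self.se_y)):
            if len(v) != j:
                raise ValueError(f"length mismatch: {name} has {len(v)} entries, gamma has {j}")
        if self.rho.shape != (j, j):
            raise ValueError(f"rho shape {self.rho.shape} does not match {j} instruments")
        if (self.se_y <= 0).any():
            raise ValueError("se_y must be strictly positive")

    @property
    def n_instruments(self) -> int:
        return len(self.gamma)


@dataclass
class MRResult:
    beta: float
    se: float
    z: float
    p: float
    n_instruments: int
    method: str = "ivw_correlated"


def two_tailed_p(z: float) -> float:
    """Two-tailed normal p-value, computed on the survival-function side.

    Using ``2 * Phi_bar(|z|)`` rather than ``2 * (1 - Phi(|z|))`` preserves
    precision at large ``|z|`` (no underflow to zero for ``|z| <= 8``).
    """
    if not math.isfinite(z):
        raise ValueError(f"z must be finite, got {z!r}")
    return min(1.0, 2.0 * float(sps.norm.sf(abs(z))))


def ivw_correlated(inp: MRInput) -> MRResult:
    """Correlated-instrument IVW causal-effect estimate via GLS."""
    omega = np.outer(inp.se_y, inp.se_y) * inp.rho
    if np.linalg.cond(omega) > _COND_MAX:
        omega = omega + _RIDGE * float(np.mean(np.diag(omega))) * np.eye(len(omega))
        if np.linalg.cond(omega) > _COND_MAX:
            raise ValueError(
                "LD-weighted covariance is numerically singular; "
                "prune instruments at a stricter r2 ceiling"
            )
    w_gamma = np.linalg.solve(omega, inp.gamma)
    precision = float(inp.gamma @ w_gamma)
    if precision <= 0:
        raise ValueError("non-positive GLS precision; check inputs")
    beta = float(w_gamma @ inp.Gamma) / precision
    se = precision**-0.5
    z = beta / se
    return MRResult(beta=beta, se=se, z=z, p=two_tailed_p(z), n_instruments=inp.n_instruments)


def run_panel(
    instruments: InstrumentSet,
    outcomes: dict[str, SummaryStats],
    metadata: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """IVW MR of one exposure against a panel of outcome measures.

    Returns one row per measure: ``measure_id, beta, se, z, p,
    n_instruments`` joined with ``metadata`` (indexed or keyed by
    ``measure_id``) when provided.  Measures sharing no variant with the
    instrument set are skipped with a warning.
    """
    rows = []
    for measure_id, stats in outcomes.items():
        try:
            pairs = harmonize(instruments.stats, stats)
        except HarmonizationError:
            logger.warning("measure %s shares no variants with instruments; skipped", measure_id)
            continue
        ld = instruments.ld.submatrix(pairs["variant_id"].tolist())
        res = ivw_correlated(
            MRInput(
                gamma=pairs["gamma"].to_numpy(),
                se_x=pairs["se_x"].to_numpy(),
                Gamma=pairs["Gamma"].to_numpy(),
                se_y=pairs["se_y"].to_numpy(),
                rho=ld.r,
            )
        )
        rows.append(
            {
                "measure_id": measure_id,
                "beta": res.beta,
                "se": res.se,
                "z": res.z,
                "p": res.p,
                "n_instruments": res.n_instruments,
            }
        )
    panel = pd.DataFrame(rows, columns=["measure_id", "beta", "se", "z", "p", "n_instruments"])
    if metadata is not None and len(panel):
        meta = metadata.reset_index() if metadata.index.name == "measure_id" else metadata
        panel = panel.merge(meta, on="measure_id", how="left")
    return panel
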