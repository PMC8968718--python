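"""Calibration and recovery experiments for the correlated-IVW estimator.

Each simulated dataset is a full two-sample draw: fresh biomarker noise on
the exposure panel (giving a fresh exposure GWAS), a fresh outcome-sample
genotype panel from the same LD structure, and fresh outcome noise.  Only
the exposure panel itself — which doubles as the LD reference — is fixed
across replicates, mirroring a design in which the reference population is
one fixed dataset.  Under the null the IVW z should then be standard
normal; with a planted effect the mean estimate should recover it up to
weak-instrument attenuation (kept negligible by the default sample sizes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seeds import substream
from .mr import MRInput, ivw_correlated
from .simulate import (
    _marginal_regressions,
    empirical_ld,
    simulate_reference_panel,
)

__all__ = ["ReplicateStudy", "type_i_error", "recovery"]

#: study conditions: 5 instruments in one moderately correlated block,
#: per-allele effect 0.3, unit-variance biomarker/outcome noise
_BLOCKS = [(5, 0.5)]
_N_VARIANTS = 5
_EFFECT = 0.3


@dataclass
class ReplicateStudy:
    """Fixed exposure panel / LD reference for replicate MR simulations."""

    dosages_x: np.ndarray
    rho: np.ndarray
    effects: np.ndarray
    seed: int
    n_outcome: int

    @classmethod
    def build(cls, seed: int, n_exposure: int = 5000, n_outcome: int = 2000) -> "ReplicateStudy":
        panel_x = simulate_reference_panel(n_exposure, _N_VARIANTS, _BLOCKS, seed=seed)
        return cls(
            dosages_x=panel_x.dosages.astype(float),
            rho=empirical_ld(panel_x).r,
            effects=np.full(_N_VARIANTS, _EFFECT),
            seed=seed,
            n_outcome=n_outcome,
        )

    def estimates(self, true_beta: float, n_replicates: int) -> np.ndarray:
        """(beta, se, z, p) per simulated dataset; shape (n_replicates, 4)."""
        rng = substream(self.seed, "replicate_datasets")
        out = np.empty((n_replicates, 4))
        for r in range(n_replicates):
            # fresh exposure GWAS on the fixed panel
            yx = self.dosages_x @ self.effects + rng.standard_normal(len(self.dosages_x))
            gamma, se_x, _ = _marginal_regressions(self.dosages_x, yx)
            # fresh outcome sample with the same LD structure
            panel_y = simulate_reference_panel(
                self.n_outcome, _N_VARIANTS, _BLOCKS,
                seed=int(rng.integers(2**31 - 1)),
            )
            score = panel_y.dosages @ self.effects
            yy = true_beta * score + rng.standard_normal(self.n_outcome)
            Gamma, se_y, _ = _marginal_regressions(panel_y.dosages, yy)
            res = ivw_correlated(MRInput(gamma, se_x, Gamma, se_y, self.rho))
            out[r] = (res.beta, res.se, res.z, res.p)
        return out


def type_i_error(
    n_replicates: int = 2000, alpha: float = 0.05, seed: int = 0,
    n_exposure: int = 5000, n_outcome: int = 2000,
) -> float:
    """Empirical type-I error of correlated IVW under the all-null panel."""
    study = ReplicateStudy.build(seed, n_exposure, n_outcome)
    est = study.estimates(0.0, n_replicates)
    return float((est[:, 3] < alpha).mean())


def recovery(
    true_beta: float = 0.2, n_replicates: int = 500, seed: int = 0,
    n_exposure: int = 5000, n_outcome: int = 2000,
) -> dict[str, float]:
    """Mean estimate and Monte-Carlo SE when a causal effect is planted."""
    study = ReplicateStudy.build(seed, n_exposure, n_outcome)
    est = study.estimates(true_beta, n_replicates)
    return {
        "true_beta": true_beta,
        "mean_beta": float(est[:, 0].mean()),
        "mc_se": float(est[:, 0].std(ddof=1) / np.sqrt(n_replicates)),
        "n_replicates": n_replicates,
    }
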