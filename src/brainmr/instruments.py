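"""Instrument selection and harmonization for two-sample MR.

Genetic instruments for a molecular exposure are taken from a cis region
around the coding gene (variants with known regulatory effects on the
biomarker), thinned so that no retained pair exceeds an r-squared ceiling
(default 0.6 — moderately correlated instruments are allowed because the
estimator models their correlation), and aligned so that exposure and
outcome effects refer to the same allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SUMMARY_COLUMNS",
    "SummaryStats",
    "LDMatrix",
    "InstrumentSet",
    "HarmonizationError",
    "select_cis_variants",
    "prune_by_ld",
    "harmonize",
]

#: canonical column order of a per-variant summary-statistics table
SUMMARY_COLUMNS = ["variant_id", "chrom", "pos", "effect_allele", "other_allele", "beta", "se", "p"]

_PALINDROMIC = ({"A", "T"}, {"C", "G"})


class HarmonizationError(ValueError):
    """No shared variants between exposure and outcome statistics."""


@dataclass
class SummaryStats:
    """GWAS summary statistics for one trait.

    ``table`` holds one row per variant with columns :data:`SUMMARY_COLUMNS`.
    Betas are per-allele effects of ``effect_allele``.
    """

    trait: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in SUMMARY_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"summary table missing columns {missing}")
        self.table = self.table[SUMMARY_COLUMNS].reset_index(drop=True)
        if len(self.table):
            if self.table["variant_id"].duplicated().any():
                dup = self.table.loc[self.table["variant_id"].duplicated(), "variant_id"].iloc[0]
                raise ValueError(f"duplicate variant id {dup!r} in {self.trait}")
            if (self.table["se"] <= 0).any():
                raise ValueError("standard errors must be strictly positive")
            p = self.table["p"].to_numpy(float)
            if ((p <= 0) | (p > 1)).any():
                raise ValueError("p-values must lie in (0, 1]")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def variant_ids(self) -> list[str]:
        return self.table["variant_id"].tolist()


@dataclass
class LDMatrix:
    """Signed variant correlation matrix (r, not r-squared)."""

    variant_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        j = len(self.variant_ids)
        if self.r.shape != (j, j):
            raise ValueError(f"LD matrix shape {self.r.shape} does not match {j} variants")
        if not np.allclose(self.r, self.r.T, atol=1e-10):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-10):
            raise ValueError("LD matrix diagonal must be exactly 1")
        if j and np.linalg.eigvalsh(self.r).min() < -1e-8:
            raise ValueError("LD matrix is not positive semidefinite (tolerance 1e-8)")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def submatrix(self, ids: list[str]) -> "LDMatrix":
        try:
            idx = [self._index[v] for v in ids]
        except KeyError as exc:
            raise KeyError(f"variant {exc.args[0]!r} not present in LD matrix") from None
        return LDMatrix(list(ids), self.r[np.ix_(idx, idx)])


@dataclass
class InstrumentSet:
    """Pruned instruments with their exposure effects and LD submatrix."""

    stats: SummaryStats
    ld: LDMatrix
    r2_max: float = 0.6

    def __post_init__(self) -> None:
        if self.stats.variant_ids != self.ld.variant_ids:
            raise ValueError("instrument statistics and LD submatrix are not aligned")
        off = self.ld.r[~np.eye(len(self.ld.variant_ids), dtype=bool)]
        if off.size and (off**2).max() >= self.r2_max:
            raise ValueError(f"instrument pair exceeds r2 < {self.r2_max}")

    def __len__(self) -> int:
        return len(self.stats)

    @property
    def variant_ids(self) -> list[str]:
        return self.stats.variant_ids

    @property
    def gamma(self) -> np.ndarray:
        """Variant–exposure associations."""
        return self.stats.table["beta"].to_numpy(float)

    @property
    def se_x(self) -> np.ndarray:
        return self.stats.table["se"].to_numpy(float)


def select_cis_variants(
    stats: SummaryStats,
    chrom: str,
    start: int,
    end: int,
    flank: int = 0,
    conditional: set[str] | None = None,
) -> SummaryStats:
    """Restrict summary statistics to a cis gene region.

    Retains variants on ``chrom`` with 1-based position in the closed
    interval ``[start - flank, end + flank]``.  ``conditional`` optionally
    intersects with an externally supplied list of conditionally associated
    variants (these sets come from the literature per biomarker; they are
    inputs, not re-derived here).  An empty result is returned with a
    warning, not raised.
    """
    if start > end:
        raise ValueError("region start must not exceed end")
    t = stats.table
    keep = (
        (t["chrom"].astype(str) == str(chrom))
        & (t["pos"] >= start - flank)
        & (t["pos"] <= end + flank)
    )
    if conditional is not None:
        keep &= t["variant_id"].isin(conditional)
    out = t.loc[keep]
    if out.empty:
        logger.warning(
            "cis selection for %s on %s:[%d,%d]+-%d returned no variants",
            stats.trait, chrom, start, end, flank,
        )
    return SummaryStats(stats.trait, out)


def prune_by_ld(candidates: SummaryStats, ld: LDMatrix, r2_max: float = 0.6) -> InstrumentSet:
    """Greedy LD pruning at ``r2 < r2_max``.

    Candidates are ranked by ascending exposure p-value (ties broken by
    variant id, making the ordering total and the output invariant to input
    order); each candidate is accepted iff its squared correlation with
    every already-accepted variant stays below the ceiling.
    """
    if not 0 < r2_max <= 1:
        raise ValueError("r2_max must lie in (0, 1]")
    for v in candidates.variant_ids:
        if v not in ld._index:
            raise KeyError(f"candidate variant {v!r} missing from LD matrix")
    ranked = candidates.table.sort_values(["p", "variant_id"], kind="mergesort")
    accepted: list[str] = []
    for v in ranked["variant_id"]:
        r_with_kept = np.array([ld.r[ld._index[v], ld._index[a]] for a in accepted])
        if (r_with_kept**2 < r2_max).all():
            accepted.append(v)
    sub = candidates.table.set_index("variant_id").loc[accepted].reset_index()
    return InstrumentSet(SummaryStats(candidates.trait, sub), ld.submatrix(accepted), r2_max)


def harmonize(
    exposure: SummaryStats,
    outcome: SummaryStats,
    drop_palindromic: bool = False,
) -> pd.DataFrame:
    """Align outcome effects to the exposure's effect alleles.

    Returns a frame with columns ``variant_id, gamma, se_x, Gamma, se_y`` in
    the exposure's variant order.  Variants whose alleles are swapped
    between the two sources get their outcome beta sign flipped; variants
    with irreconcilable allele sets are dropped with a logged reason.
    """
    exp = exposure.table.set_index("variant_id")
    out = outcome.table.set_index("variant_id")
    shared = [v for v in exposure.variant_ids if v in out.index]
    if not shared:
        raise HarmonizationError(
            f"no shared variants between {exposure.trait!r} and {outcome.trait!r}"
        )
    rows = []
    for v in shared:
        e, o = exp.loc[v], out.loc[v]
        alleles = {e["effect_allele"], e["other_allele"]}
        if drop_palindromic and alleles in _PALINDROMIC:
            logger.info("dropping palindromic variant %s", v)
            continue
        if (o["effect_allele"], o["other_allele"]) == (e["effect_allele"], e["other_allele"]):
            gamma_y = float(o["beta"])
        elif (o["effect_allele"], o["other_allele"]) == (e["other_allele"], e["effect_allele"]):
            gamma_y = -float(o["beta"])
        else:
            logger.warning(
                "dropping %s: alleles %s/%s vs %s/%s do not match",
                v, e["effect_allele"], e["other_allele"], o["effect_allele"], o["other_allele"],
            )
            continue
        rows.append(
            {
                "variant_id": v,
                "gamma": float(e["beta"]),
                "se_x": float(e["se"]),
                "Gamma": gamma_y,
                "se_y": float(o["se"]),
            }
        )
    if not rows:
        raise HarmonizationError(
            f"all shared variants between {exposure.trait!r} and {outcome.trait!r} were dropped"
        )
    return pd.DataFrame(rows, columns=["variant_id", "gamma", "se_x", "Gamma", "se_y"])
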