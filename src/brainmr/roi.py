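"""Aggregate per-measure MR results into named brain regions of interest.

A tabular stand-in for voxel-space ROI identification: measures are grouped
by (atlas, region, hemisphere), each ROI is represented by its extreme-|z|
measure, and ROIs are flagged significant when the representative p falls
below the multiplicity-corrected threshold.
"""

from __future__ import annotations

import pandas as pd

from .mr import two_tailed_p

__all__ = ["map_measures_to_rois", "ROI_COLUMNS"]

ROI_COLUMNS = [
    "atlas",
    "region",
    "hemisphere",
    "measure_id",
    "z",
    "p",
    "n_measures",
    "measure_ids",
    "significant",
]


def map_measures_to_rois(
    panel: pd.DataFrame,
    lookup: pd.DataFrame,
    threshold: float,
    aggregate: str = "extreme",
) -> pd.DataFrame:
    """Group panel results into ROIs and flag significant ones.

    ``panel`` needs columns ``measure_id, z, p``; ``lookup`` maps
    ``measure_id`` to ``atlas, region, hemisphere``.  ``aggregate`` is
    ``"extreme"`` (representative = max-|z| measure, the reporting style of
    one z per named region) or ``"mean"`` (representative z = mean of
    member z scores, p recomputed from the normal tail).  Output is sorted
    by ascending p.
    """
    if aggregate not in ("extreme", "mean"):
        raise ValueError(f"unknown aggregation rule {aggregate!r}")
    if panel.empty:
        return pd.DataFrame(columns=ROI_COLUMNS)
    missing = set(panel["measure_id"]) - set(lookup["measure_id"])
    if missing:
        raise KeyError(f"measures missing from ROI lookup: {sorted(missing)[:5]}")
    merged = panel.drop(columns=["atlas", "region", "hemisphere"], errors="ignore").merge(
        lookup[["measure_id", "atlas", "region", "hemisphere"]], on="measure_id"
    )
    rows = []
    for (atlas, region, hemi), grp in merged.groupby(["atlas", "region", "hemisphere"]):
        best = grp.loc[grp["z"].abs().idxmax()]
        if aggregate == "extreme":
            z, p, rep = float(best["z"]), float(best["p"]), best["measure_id"]
        else:
            z = float(grp["z"].mean())
            p, rep = two_tailed_p(z), best["measure_id"]
        rows.append(
            {
                "atlas": atlas,
                "region": region,
                "hemisphere": hemi,
                "measure_id": rep,
                "z": z,
                "p": p,
                "n_measures": len(grp),
                "measure_ids": ";".join(sorted(grp["measure_id"])),
                "significant": bool(p < threshold),
            }
        )
    out = pd.DataFrame(rows, columns=ROI_COLUMNS)
    return out.sort_values(["p", "region"], kind="mergesort").reset_index(drop=True)
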