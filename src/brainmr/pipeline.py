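"""End-to-end orchestration: simulate -> instruments -> MR -> multiplicity
-> ROI -> differential expression -> enrichment -> connectivity.

The pipeline runs entirely on synthetic data with planted ground truth and
writes every stage's inputs/outputs as plain text, a manifest with content
hashes, and a machine-readable summary.  Re-running with the same config
reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexpr, enrichment, io, netenrich, roi
from .instruments import prune_by_ld, select_cis_variants
from .mr import run_panel
from .multiplicity import MultiplicityDecision, effective_tests_pca
from .simulate import (
    GroundTruth,
    empirical_ld,
    measure_metadata,
    simulate_annotations,
    simulate_exposure_gwas,
    simulate_expression,
    simulate_network,
    simulate_outcome_panel,
    simulate_reference_panel,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "demo_config", "run_pipeline"]

_REGIONS = [
    "MTG", "SFG", "FuG", "ITG", "precuneus",
    "putamen", "operculum", "occipital_pole", "pericallosal", "vermis_I_IV",
]


@dataclass
class PipelineConfig:
    """All sizes, densities, planted effects and thresholds for one run."""

    seed: int = 1
    # genotypes / GWAS
    n_exposure_individuals: int = 2000
    n_outcome_individuals: int = 5000
    n_variants: int = 12
    ld_blocks: list[tuple[int, float]] = field(
        default_factory=lambda: [(4, 0.5), (4, 0.5), (4, 0.3)]
    )
    maf_range: tuple[float, float] = (0.15, 0.45)
    exposure_effects: dict[str, float] = field(
        default_factory=lambda: {"var0000": 0.35, "var0004": 0.3, "var0008": 0.3}
    )
    exposure_noise_sd: float = 1.0
    # outcome panel
    n_measures: int = 120
    region_labels: list[str] = field(default_factory=lambda: list(_REGIONS))
    planted_region: str = "MTG"
    planted_hemisphere: str = "right"
    planted_measure_effect: float = 0.3
    measure_blocks: list[tuple[int, float]] = field(
        default_factory=lambda: [(10, 0.5)] * 12
    )
    # expression
    samples_per_region: int = 10
    n_genes: int = 1000
    probes_per_gene: int = 2
    n_planted_genes: int = 40
    planted_shift: float = 3.0
    expression_noise_sd: float = 0.5
    # annotations
    ontologies: list[str] = field(
        default_factory=lambda: ["disease", "biological_process", "phenotype"]
    )
    n_terms: int = 50
    term_size_range: tuple[int, int] = (10, 60)
    n_enriched_terms: int = 3
    enriched_fraction: float = 0.8
    # network
    background_density: float = 0.01
    module_size: int = 20
    module_density: float = 0.3
    # thresholds
    r2_max: float = 0.6
    variance_threshold: float = 0.95
    alpha: float = 0.05
    q_max: float = 0.05
    logfc_min: float = 2.0

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.r2_max <= 1:
            raise ValueError("r2_max must lie in (0, 1]")
        if not 0 < self.variance_threshold <= 1:
            raise ValueError("variance_threshold must lie in (0, 1]")
        if not 0 < self.q_max < 1:
            raise ValueError("q_max must lie in (0, 1)")
        if self.logfc_min < 0:
            raise ValueError("logfc_min must be non-negative")
        if self.module_density <= self.background_density:
            raise ValueError("module density must exceed background density")
        if self.planted_region not in self.region_labels:
            raise ValueError("planted region must be one of the region labels")
        if self.n_planted_genes > self.n_genes:
            raise ValueError("cannot plant more genes than exist")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("ld_blocks", "measure_blocks"):
            if key in raw:
                raw[key] = [tuple(b) for b in raw[key]]
        for key in ("maf_range", "term_size_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        def listify(x):
            if isinstance(x, (list, tuple)):
                return [listify(v) for v in x]
            return x

        d = {k: listify(v) for k, v in dataclasses.asdict(self).items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def demo_config(seed: int = 1) -> PipelineConfig:
    """The bundled demo: every planted structure at its default condition."""
    return PipelineConfig(seed=seed)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage, write artifacts under ``out_dir``, return the summary."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    manifest: list[dict] = []

    def record(stage: str, paths: list[Path]) -> None:
        manifest.append(
            {"stage": stage, "seed": seed,
             "outputs": {p.name: _sha256(p) for p in sorted(paths)}}
        )

    # -- simulate ----------------------------------------------------------
    panel_x = simulate_reference_panel(
        config.n_exposure_individuals, config.n_variants, config.ld_blocks,
        config.maf_range, seed=seed,
    )
    panel_y = simulate_reference_panel(
        config.n_outcome_individuals, config.n_variants, config.ld_blocks,
        config.maf_range, seed=seed + 1,
    )
    exposure = simulate_exposure_gwas(
        panel_x, config.exposure_effects, config.exposure_noise_sd, seed=seed
    )
    ld = empirical_ld(panel_x)

    meta = measure_metadata(config.n_measures, config.region_labels)
    planted_ids = meta.loc[
        (meta["region"] == config.planted_region)
        & (meta["hemisphere"] == config.planted_hemisphere),
        "measure_id",
    ].tolist()
    causal_map = {m: config.planted_measure_effect for m in planted_ids}
    outcome_stats, outcome_matrix, meta = simulate_outcome_panel(
        panel_y, config.exposure_effects, causal_map,
        config.n_measures, config.measure_blocks, config.region_labels, seed=seed,
    )

    genes = [f"g{i:04d}" for i in range(config.n_genes)]
    planted_genes = genes[: config.n_planted_genes]
    expr = simulate_expression(
        config.region_labels, config.samples_per_region, config.n_genes,
        config.probes_per_gene, {g: config.planted_shift for g in planted_genes},
        target_region=config.planted_region, noise_sd=config.expression_noise_sd,
        seed=seed,
    )

    tables = {}
    enriched: dict[str, dict[str, float]] = {}
    for i, ont in enumerate(config.ontologies):
        ids = {f"{ont}:t{j:04d}": config.enriched_fraction
               for j in range(config.n_enriched_terms)}
        tables[ont] = simulate_annotations(
            genes, config.n_terms, config.term_size_range, ids, planted_genes,
            seed=seed + i, ontology=ont,
        )
        enriched[ont] = ids

    module_genes = planted_genes[: config.module_size]
    network = simulate_network(
        genes, config.background_density, module_genes, config.module_density,
        seed=seed,
    )

    truth = GroundTruth(
        causal_measures=causal_map,
        overexpressed_genes={g: config.planted_shift for g in planted_genes},
        enriched_terms=enriched,
        module_genes=module_genes,
        seeds={"master": seed},
    )

    io.write_summary_stats(exposure, out / "exposure.tsv")
    io.write_ld(ld, out / "ld.tsv")
    io.write_matrix(outcome_matrix, out / "outcome_matrix.tsv")
    meta.to_csv(out / "measures.tsv", sep="\t", index=False)
    io.write_expression(expr, out / "expression")
    for ont, table in tables.items():
        io.write_gmt(table, out / f"{ont}.gmt")
    io.write_edge_list(network, out / "network.tsv")
    io.write_ground_truth(truth, out / "ground_truth.json")
    record("simulate", list(out.glob("*.tsv")) + list(out.glob("*.gmt"))
           + [out / "ground_truth.json"])
    logger.info("simulate: %d variants, %d measures, %d genes",
                config.n_variants, config.n_measures, config.n_genes)

    # -- instruments -------------------------------------------------------
    pos = panel_x.variants["pos"]
    cis = select_cis_variants(exposure, "1", int(pos.min()), int(pos.max()))
    instruments = prune_by_ld(cis, ld, config.r2_max)
    instruments.stats.table.to_csv(out / "instruments.tsv", sep="\t", index=False)
    record("instruments", [out / "instruments.tsv"])
    logger.info("instruments: %d candidates -> %d kept at r2 < %s",
                len(cis), len(instruments), config.r2_max)

    # -- mr panel ----------------------------------------------------------
    panel_results = run_panel(instruments, outcome_stats, meta)
    panel_results.to_csv(out / "mr_panel.tsv", sep="\t", index=False, float_format="%.10g")
    record("mr", [out / "mr_panel.tsv"])

    # -- multiplicity ------------------------------------------------------
    n_eff = effective_tests_pca(outcome_matrix, config.variance_threshold)
    decision = MultiplicityDecision(n_eff, config.variance_threshold, config.alpha)
    (out / "multiplicity.json").write_text(json.dumps(
        {"n_eff": decision.n_eff, "alpha": decision.alpha,
         "variance_threshold": decision.variance_threshold,
         "threshold": decision.threshold}, indent=2))
    record("multiplicity", [out / "multiplicity.json"])
    logger.info("multiplicity: N_eff=%d, threshold=%.3g", n_eff, decision.threshold)

    # -- roi ---------------------------------------------------------------
    rois = roi.map_measures_to_rois(panel_results, meta, decision.threshold)
    rois.to_csv(out / "rois.tsv", sep="\t", index=False, float_format="%.10g")
    record("roi", [out / "rois.tsv"])

    # -- differential expression ------------------------------------------
    by_gene = diffexpr.collapse_probes(expr)
    de = diffexpr.differential_expression(by_gene, expr.sample_to_region,
                                          config.planted_region)
    de_genes = diffexpr.filter_overexpressed(de, config.q_max, config.logfc_min)
    de.to_csv(out / "de.tsv", sep="\t", index=False, float_format="%.10g")
    (out / "de_genes.txt").write_text("\n".join(de_genes) + "\n")
    record("de", [out / "de.tsv", out / "de_genes.txt"])
    logger.info("de: %d genes pass q < %s and logFC > %s",
                len(de_genes), config.q_max, config.logfc_min)

    # -- enrichment --------------------------------------------------------
    enrich_summary = {}
    for ont, table in tables.items():
        results = enrichment.hypergeom_enrich(de_genes, table, genes)
        top = enrichment.top_terms(results)
        pd.DataFrame([dataclasses.asdict(r) for r in top]).to_csv(
            out / f"enrich_{ont}.tsv", sep="\t", index=False, float_format="%.6g")
        enrich_summary[ont] = {
            "significant_terms": sorted(r.term_id for r in results if r.q < config.q_max),
            "min_q": min(r.q for r in results),
        }
    record("enrich", sorted(out.glob("enrich_*.tsv")))

    # -- connectivity ------------------------------------------------------
    conn = netenrich.connectivity_pvalue(network, de_genes, method="binomial")
    conn_perm = netenrich.connectivity_pvalue(
        network, de_genes, method="permutation", n_perm=10_000, seed=seed)
    (out / "connectivity.json").write_text(json.dumps(
        {m.method: dataclasses.asdict(m) for m in (conn, conn_perm)}, indent=2))
    record("net", [out / "connectivity.json"])

    # -- summary -----------------------------------------------------------
    significant = panel_results.loc[panel_results["p"] < decision.threshold]
    summary = {
        "seed": seed,
        "n_instruments": len(instruments),
        "n_measures_tested": int(len(panel_results)),
        "n_eff": decision.n_eff,
        "threshold": decision.threshold,
        "n_significant_measures": int(len(significant)),
        "significant_measures": sorted(significant["measure_id"]),
        "planted_measures": sorted(planted_ids),
        "planted_measures_significant": sorted(
            set(planted_ids) & set(significant["measure_id"])),
        "significant_rois": rois.loc[rois["significant"],
                                     ["atlas", "region", "hemisphere"]]
                               .agg("/".join, axis=1).tolist(),
        "n_overexpressed_genes": len(de_genes),
        "planted_gene_recall": len(set(de_genes) & set(planted_genes))
                               / len(planted_genes),
        "enrichment": enrich_summary,
        "connectivity": {
            "n_nodes": conn.n_nodes, "e_obs": conn.e_obs, "e_exp": conn.e_exp,
            "mean_degree": conn.mean_degree,
            "p_binomial": conn.p, "p_permutation": conn_perm.p,
        },
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return summary
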