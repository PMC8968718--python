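"""Synthetic study generator with planted ground truth.

Every input the pipeline consumes can be generated here with known truth:
a reference genotype panel with block LD instrumenting a biomarker, a panel
of correlated imaging measures a small subset of which carries a planted
causal effect, a regional log2 expression matrix with one region
overexpressing a planted gene module, GMT-style annotation tables in which
designated terms are enriched for that module, and a sparse background
interaction network containing a denser planted subnetwork.

Design notes
------------
* Dosages are sums of two latent-Gaussian haplotypes thresholded at the
  allele frequency.  Thresholding deflates correlation, so the latent
  within-block correlation is calibrated by tetrachoric inversion to hit
  the requested *dosage* correlation.  Downstream stages consume the
  empirical (not target) LD.
* Summary statistics are produced by per-variant simple regression on
  simulated individuals rather than drawn directly, so SEs, LD and effect
  correlations are mutually consistent — this is what makes the correlated
  IVW estimator correctly calibrated on these data.
* All randomness flows from one master seed through named substreams
  (:mod:`brainmr._seeds`), so each stage can be regenerated independently.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import brentq

import networkx as nx

from ._seeds import substream
from .instruments import SUMMARY_COLUMNS, LDMatrix, SummaryStats

__all__ = [
    "GenotypePanel",
    "GroundTruth",
    "ExpressionMatrix",
    "AnnotationTable",
    "Term",
    "simulate_reference_panel",
    "simulate_exposure_gwas",
    "simulate_outcome_panel",
    "simulate_expression",
    "simulate_annotations",
    "simulate_network",
    "measure_metadata",
    "empirical_ld",
]

_MODALITY_ATLAS = {"GMV": "harvard_oxford", "CT": "destrieux"}
_HEMISPHERES = ("left", "right")


# ---------------------------------------------------------------------------
# containers


@dataclass
class GenotypePanel:
    """Individuals x variants dosage panel with variant annotations."""

    individual_ids: list[str]
    variants: pd.DataFrame  # variant_id, chrom, pos, effect_allele, other_allele, maf
    dosages: np.ndarray  # (n_individuals, n_variants), values in {0, 1, 2}

    def __post_init__(self) -> None:
        d = np.asarray(self.dosages)
        if d.min() < 0 or d.max() > 2:
            raise ValueError("dosages must lie in [0, 2]")
        af = d.mean(axis=0) / 2
        if ((af <= 0) | (af >= 1)).any():
            raise ValueError("every variant must be polymorphic (allele frequency in (0,1))")
        if self.variants["variant_id"].duplicated().any():
            raise ValueError("variant ids must be unique")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def variant_ids(self) -> list[str]:
        return self.variants["variant_id"].tolist()


@dataclass
class ExpressionMatrix:
    """Probes x samples log2 intensities with probe->gene and sample->region maps."""

    values: pd.DataFrame
    probe_to_gene: pd.Series
    sample_to_region: pd.Series

    def __post_init__(self) -> None:
        if set(self.values.index) - set(self.probe_to_gene.index):
            raise ValueError("every probe must map to a gene")
        if set(self.values.columns) - set(self.sample_to_region.index):
            raise ValueError("every sample must map to a region")

    @property
    def genes(self) -> list[str]:
        return sorted(self.probe_to_gene.unique())


@dataclass
class Term:
    term_id: str
    name: str
    genes: list[str]


@dataclass
class AnnotationTable:
    ontology: str
    terms: list[Term]

    def __post_init__(self) -> None:
        ids = [t.term_id for t in self.terms]
        if len(set(ids)) != len(ids):
            raise ValueError("term ids must be unique")


@dataclass
class GroundTruth:
    """Everything that was planted, plus the seeds that reproduce it."""

    causal_measures: dict[str, float] = field(default_factory=dict)
    overexpressed_genes: dict[str, float] = field(default_factory=dict)
    enriched_terms: dict[str, dict[str, float]] = field(default_factory=dict)  # ontology -> term -> fraction
    module_genes: list[str] = field(default_factory=list)
    seeds: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# genotypes and GWAS


def _latent_correlation(target: float, maf: float) -> float:
    """Latent-Gaussian correlation yielding ``target`` correlation after thresholding.

    Inverts the tetrachoric relation phi(r_latent) -> binary correlation at
    a common threshold Phi^-1(maf).  Summing two independent haplotypes
    leaves the correlation unchanged, so calibrating the haplotype Bernoulli
    correlation calibrates the dosage correlation.
    """
    if target <= 0:
        return 0.0
    t = sps.norm.ppf(maf)
    denom = maf * (1 - maf)

    def binary_corr(r: float) -> float:
        p11 = sps.multivariate_normal.cdf([t, t], mean=[0.0, 0.0], cov=[[1.0, r], [r, 1.0]])
        return (p11 - maf * maf) / denom

    hi = 0.9995
    if binary_corr(hi) < target:
        raise ValueError(f"correlation target {target} infeasible at maf {maf:.3f}")
    return brentq(lambda r: binary_corr(r) - target, 0.0, hi, xtol=1e-4)


def simulate_reference_panel(
    n_individuals: int,
    n_variants: int,
    block_structure: list[tuple[int, float]],
    maf_range: tuple[float, float] = (0.1, 0.5),
    seed: int = 0,
    chrom: str = "1",
) -> GenotypePanel:
    """Generate a dosage panel with block-structured LD.

    ``block_structure`` is a list of ``(block_size, target_r)`` pairs whose
    sizes must sum to ``n_variants``; within-block dosage correlations
    approximate ``target_r`` (latent-Gaussian thresholding with tetrachoric
    calibration), across-block correlations are ~0.
    """
    if n_individuals < 50:
        raise ValueError("n_individuals must be >= 50")
    sizes = [s for s, _ in block_structure]
    if sum(sizes) != n_variants:
        raise ValueError(f"block sizes sum to {sum(sizes)}, expected {n_variants}")
    for _, r in block_structure:
        if not 0 <= r <= 0.95:
            raise ValueError(f"correlation target {r} outside [0, 0.95]")
    lo, hi = maf_range
    if not 0 < lo <= hi < 0.5 + 1e-12:
        raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")

    rng = substream(seed, "reference_panel")
    # variants in one LD block share a MAF, so the tetrachoric calibration
    # holds for every within-block pair, not just on average
    mafs = np.concatenate(
        [np.full(size, rng.uniform(lo, hi)) for size, _ in block_structure]
    )
    cols = []
    start = 0
    for size, target in block_structure:
        block_maf = float(mafs[start])
        r_lat = _latent_correlation(target, block_maf) if size > 1 else 0.0
        for attempt in range(10):
            haps = []
            for _ in range(2):  # two independent haplotypes per individual
                shared = rng.standard_normal((n_individuals, 1))
                noise = rng.standard_normal((n_individuals, size))
                z = np.sqrt(r_lat) * shared + np.sqrt(1 - r_lat) * noise
                thresh = sps.norm.ppf(mafs[start : start + size])
                haps.append((z < thresh).astype(np.int8))
            block = haps[0] + haps[1]
            if (block.std(axis=0) > 0).all():
                break
        else:
            raise ValueError("could not generate polymorphic variants; widen maf_range")
        cols.append(block)
        start += size
    dosages = np.hstack(cols)

    # alleles are a fixed property of the variant (index), not of the sample
    # draw, so two panels over the same variant ids always harmonize
    alleles = np.array([["A", "G"], ["C", "T"], ["G", "A"], ["T", "C"]])
    pick = np.arange(n_variants) % len(alleles)
    variants = pd.DataFrame(
        {
            "variant_id": [f"var{i:04d}" for i in range(n_variants)],
            "chrom": chrom,
            "pos": np.arange(1, n_variants + 1) * 1000,
            "effect_allele": alleles[pick, 0],
            "other_allele": alleles[pick, 1],
            "maf": mafs,
        }
    )
    ids = [f"ind{i:05d}" for i in range(n_individuals)]
    return GenotypePanel(ids, variants, dosages)


def empirical_ld(panel: GenotypePanel) -> LDMatrix:
    """Signed empirical dosage correlation matrix of a panel."""
    r = np.corrcoef(panel.dosages, rowvar=False)
    r = np.atleast_2d(r)
    np.fill_diagonal(r, 1.0)
    r = (r + r.T) / 2
    return LDMatrix(panel.variant_ids, r)


def _marginal_regressions(dosages: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, ...]:
    """Per-variant simple regression (with intercept) of ``y`` on each dosage column.

    ``y`` may be (n,) or (n, m); returns beta, se, p each shaped (J,) or (J, m).
    """
    n = dosages.shape[0]
    if n < 3:
        raise ValueError("need at least 3 individuals for per-variant regression")
    gc = dosages - dosages.mean(axis=0)
    yc = np.atleast_2d(np.asarray(y, float).T).T - np.asarray(y, float).mean(axis=0)
    ssg = (gc**2).sum(axis=0)  # (J,)
    beta = (gc.T @ yc) / ssg[:, None]  # (J, m)
    ssy = (yc**2).sum(axis=0)  # (m,)
    rss = np.clip(ssy[None, :] - beta**2 * ssg[:, None], 1e-300, None)
    se = np.sqrt(rss / (n - 2) / ssg[:, None])
    p = 2 * sps.t.sf(np.abs(beta / se), df=n - 2)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    if np.asarray(y).ndim == 1:
        return beta[:, 0], se[:, 0], p[:, 0]
    return beta, se, p


def _stats_frame(panel: GenotypePanel, beta, se, p, trait: str) -> SummaryStats:
    t = panel.variants[["variant_id", "chrom", "pos", "effect_allele", "other_allele"]].copy()
    t["beta"], t["se"], t["p"] = beta, se, p
    return SummaryStats(trait, t[SUMMARY_COLUMNS])


def simulate_exposure_gwas(
    panel: GenotypePanel,
    causal_effects: dict[str, float],
    noise_sd: float = 1.0,
    seed: int = 0,
    trait: str = "biomarker",
) -> SummaryStats:
    """Simulate a continuous biomarker and its per-variant GWAS.

    The biomarker is a linear combination of causal dosages plus Gaussian
    noise; each variant is then tested by simple regression, so the
    resulting betas/SEs are mutually consistent with the panel's LD.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    unknown = set(causal_effects) - set(panel.variant_ids)
    if unknown:
        raise KeyError(f"causal variants not in panel: {sorted(unknown)}")
    rng = substream(seed, "exposure_gwas")
    a = np.array([causal_effects.get(v, 0.0) for v in panel.variant_ids])
    y = panel.dosages @ a + rng.normal(0.0, noise_sd, panel.n_individuals)
    beta, se, p = _marginal_regressions(panel.dosages, y)
    return _stats_frame(panel, beta, se, p, trait)


def measure_metadata(n_measures: int, region_labels: list[str] | None = None) -> pd.DataFrame:
    """Deterministic measure_id -> (modality, atlas, region, hemisphere) table.

    Regions cycle fastest, then hemisphere, so each (region, hemisphere)
    pair collects every ``2 * len(region_labels)``-th measure; modality is
    GMV for the first half of measures and CT for the second, with the
    atlas implied by the modality.  Exposed as a pure function so planted
    causal effects can be addressed to one named ROI before simulating.
    """
    if n_measures < 1:
        raise ValueError("n_measures must be >= 1")
    if region_labels is None:
        region_labels = [f"region{i:02d}" for i in range(max(1, n_measures // 12))]
    rows = []
    for i in range(n_measures):
        modality = "GMV" if i < n_measures / 2 else "CT"
        rows.append(
            {
                "measure_id": f"m{i:04d}",
                "modality": modality,
                "atlas": _MODALITY_ATLAS[modality],
                "region": region_labels[i % len(region_labels)],
                "hemisphere": _HEMISPHERES[(i // len(region_labels)) % 2],
            }
        )
    return pd.DataFrame(rows)


def simulate_outcome_panel(
    panel: GenotypePanel,
    exposure_effects: dict[str, float],
    causal_map: dict[str, float],
    n_measures: int,
    measure_blocks: list[tuple[int, float]] | None = None,
    region_labels: list[str] | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[dict[str, SummaryStats], pd.DataFrame, pd.DataFrame]:
    """Simulate an imaging-outcome panel at the individual level.

    Each measure is ``true_effect * genetically_predicted_exposure`` plus
    noise that is correlated across measures in equicorrelated blocks
    (``measure_blocks`` is a list of ``(size, rho)``).  Returns per-measure
    summary statistics from per-variant regressions, the individuals x
    measures outcome matrix (input to the PCA multiplicity step), and the
    measure metadata.
    """
    meta = measure_metadata(n_measures, region_labels)
    ids = meta["measure_id"].tolist()
    unknown = set(causal_map) - set(ids)
    if unknown:
        raise KeyError(f"causal effects on unknown measures: {sorted(unknown)}")
    if measure_blocks is None:
        measure_blocks = [(n_measures, 0.0)]
    if sum(s for s, _ in measure_blocks) != n_measures:
        raise ValueError("measure block sizes must sum to n_measures")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")

    rng = substream(seed, "outcome_panel")
    a = np.array([exposure_effects.get(v, 0.0) for v in panel.variant_ids])
    score = panel.dosages @ a  # genetically predicted exposure in this sample
    n = panel.n_individuals

    noise_cols = []
    for size, rho in measure_blocks:
        if not 0 <= rho <= 1:
            raise ValueError("measure correlation must lie in [0, 1]")
        shared = rng.standard_normal((n, 1))
        idio = rng.standard_normal((n, size))
        noise_cols.append(np.sqrt(rho) * shared + np.sqrt(1 - rho) * idio)
    noise = np.hstack(noise_cols) * noise_sd

    effects = np.array([causal_map.get(m, 0.0) for m in ids])
    outcomes = score[:, None] * effects[None, :] + noise

    beta, se, p = _marginal_regressions(panel.dosages, outcomes)
    stats = {
        m: _stats_frame(panel, beta[:, j], se[:, j], p[:, j], trait=m)
        for j, m in enumerate(ids)
    }
    matrix = pd.DataFrame(outcomes, index=panel.individual_ids, columns=ids)
    return stats, matrix, meta


# ---------------------------------------------------------------------------
# expression, annotations, network


def simulate_expression(
    regions: list[str],
    samples_per_region: int,
    n_genes: int,
    probes_per_gene: int = 1,
    overexpressed: dict[str, float] | None = None,
    target_region: str | None = None,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> ExpressionMatrix:
    """Simulate a probes x samples log2 intensity matrix.

    Gene baselines are uniform on [5, 10] log2 units with small probe
    offsets; planted genes get their stated log2 shift added in the target
    region's samples only.  Probes map many-to-one to genes.
    """
    overexpressed = overexpressed or {}
    if not regions:
        raise ValueError("at least one region is required")
    if probes_per_gene < 1 or n_genes < 1 or samples_per_region < 1:
        raise ValueError("counts must be positive")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if overexpressed and target_region is None:
        raise ValueError("a target region must be designated for planted shifts")
    if target_region is not None and target_region not in regions:
        raise ValueError(f"target region {target_region!r} not in regions")
    genes = [f"g{i:04d}" for i in range(n_genes)]
    unknown = set(overexpressed) - set(genes)
    if unknown:
        raise KeyError(f"shift specified for unknown genes: {sorted(unknown)}")

    rng = substream(seed, "expression")
    baseline = rng.uniform(5.0, 10.0, n_genes)
    shift = np.array([overexpressed.get(g, 0.0) for g in genes])

    probes, probe_gene = [], []
    for g in genes:
        for k in range(probes_per_gene):
            probes.append(f"{g}_p{k}")
            probe_gene.append(g)
    probe_offset = rng.normal(0.0, 0.25, len(probes))

    samples, sample_region = [], []
    for r in regions:
        for j in range(samples_per_region):
            samples.append(f"{r}_s{j:02d}")
            sample_region.append(r)
    in_target = np.array([r == target_region for r in sample_region])

    gene_idx = np.repeat(np.arange(n_genes), probes_per_gene)
    mean = baseline[gene_idx][:, None] + probe_offset[:, None]
    mean = mean + shift[gene_idx][:, None] * in_target[None, :]
    values = mean + rng.normal(0.0, noise_sd, (len(probes), len(samples)))

    return ExpressionMatrix(
        values=pd.DataFrame(values, index=probes, columns=samples),
        probe_to_gene=pd.Series(probe_gene, index=probes, name="gene"),
        sample_to_region=pd.Series(sample_region, index=samples, name="region"),
    )


def simulate_annotations(
    gene_universe: list[str],
    n_terms: int,
    term_size_range: tuple[int, int],
    enriched_terms: dict[str, float] | None = None,
    planted_set: list[str] | None = None,
    seed: int = 0,
    ontology: str = "ontology",
) -> AnnotationTable:
    """Simulate a GMT-style annotation table.

    Terms draw members uniformly from the universe, except the designated
    enriched terms, which draw the stated fraction of their members from
    ``planted_set`` (capped at its size).  Term ids are ``{ontology}:t0000``
    onward, so enriched term ids can be named in advance.
    """
    enriched_terms = enriched_terms or {}
    if not gene_universe:
        raise ValueError("gene universe must be non-empty")
    lo, hi = term_size_range
    if not 1 <= lo <= hi:
        raise ValueError("invalid term size range")
    if hi > len(gene_universe):
        raise ValueError("term size exceeds gene universe")
    for t, f in enriched_terms.items():
        if not 0 < f <= 1:
            raise ValueError(f"planted fraction for {t} must lie in (0, 1]")
    if enriched_terms and not planted_set:
        raise ValueError("enriched terms require a designated planted gene set")
    planted = [g for g in (planted_set or []) if g in set(gene_universe)]

    rng = substream(seed, f"annotations:{ontology}")
    universe = np.array(gene_universe)
    terms = []
    for i in range(n_terms):
        tid = f"{ontology}:t{i:04d}"
        size = int(rng.integers(lo, hi + 1))
        frac = enriched_terms.get(tid)
        if frac is not None:
            n_from = min(int(round(frac * size)), len(planted))
            members = list(rng.choice(planted, n_from, replace=False))
            rest_pool = np.array(sorted(set(gene_universe) - set(members)))
            members += list(rng.choice(rest_pool, size - n_from, replace=False))
        else:
            members = list(rng.choice(universe, size, replace=False))
        terms.append(Term(tid, f"{ontology} term {i}", sorted(members)))
    unknown = set(enriched_terms) - {t.term_id for t in terms}
    if unknown:
        raise KeyError(f"enriched term ids never generated: {sorted(unknown)}")
    return AnnotationTable(ontology, terms)


def simulate_network(
    gene_universe: list[str],
    background_density: float,
    planted_module: list[str] | None = None,
    module_density: float | None = None,
    seed: int = 0,
) -> nx.Graph:
    """Erdos-Renyi background with a denser planted module.

    Every unordered gene pair carries an edge with probability
    ``background_density``, except pairs internal to ``planted_module``,
    which are rewired to ``module_density``.  Simple undirected graph, no
    self-loops.
    """
    planted_module = planted_module or []
    if not 0 < background_density < 1:
        raise ValueError("background density must lie in (0, 1)")
    if planted_module:
        if module_density is None or not 0 < module_density <= 1:
            raise ValueError("module density must lie in (0, 1]")
        if module_density <= background_density:
            raise ValueError("module density must exceed background density")
        unknown = set(planted_module) - set(gene_universe)
        if unknown:
            raise KeyError(f"module genes not in universe: {sorted(unknown)}")

    rng = substream(seed, "network")
    nodes = list(gene_universe)
    n = len(nodes)
    iu, ju = np.triu_indices(n, k=1)
    prob = np.full(iu.shape, background_density)
    if planted_module:
        in_mod = np.isin(nodes, planted_module)
        both = in_mod[iu] & in_mod[ju]
        prob[both] = module_density
    present = rng.random(iu.shape) < prob
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(
        (nodes[i], nodes[j]) for i, j in zip(iu[present], ju[present])
    )
    return g
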