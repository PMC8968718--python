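# Methods

## The estimator

`brainmr.mr.ivw_correlated` implements fixed-effect inverse-variance-weighted
MR for correlated instruments as generalized least squares. With J
instruments, exposure associations γ ∈ ℝᴶ, outcome associations Γ ∈ ℝᴶ with
standard errors σ_Y, and signed LD correlations ρ:

    Ω = diag(σ_Y) ρ diag(σ_Y)
    β̂ = (γᵀΩ⁻¹γ)⁻¹ γᵀΩ⁻¹Γ
    se(β̂) = (γᵀΩ⁻¹γ)^(-1/2)

Assumptions and conventions:

- **First-order weights.** Exposure-side uncertainty σ_X is carried in the
  data model but not propagated (the standard no-measurement-error
  convention). With strong cis instruments the resulting attenuation is
  second-order; the recovery experiment below quantifies it empirically.
- **Fixed effects, no over-dispersion correction.** z = β̂/se and
  p = 2·Φ̄(|z|), computed on the survival-function side so p does not
  underflow for |z| ≤ 8.
- **Conditioning.** If cond(Ω) > 1e10 a single ridge of 1e-8·mean(diag Ω) is
  added; if the matrix is still numerically singular the estimator refuses
  and advises stricter pruning. In practice r² < 0.6 pruning keeps Ω
  comfortably invertible; the ridge only engages for degenerate synthetic
  draws (e.g. duplicated variants), where it collapses duplicates onto the
  single-instrument ratio.
- With ρ = I the estimator reduces exactly to
  Σ(γ_jΓ_j/σ_Yj²) / Σ(γ_j²/σ_Yj²); tests assert this reduction and
  equivalence with an independent Cholesky-whitening GLS route to 1e-10.

## Instruments

Cis selection keeps variants inside a 1-based closed interval (gene region ±
flank); externally supplied conditional-association lists are intersected
rather than re-derived, since such sets are curated per biomarker from the
literature. Pruning is greedy clumping: candidates ranked by ascending
exposure p (ties by variant id, making the rule total and order-invariant),
accepted when r² with all kept variants stays below the ceiling (default
0.6 — the estimator tolerates moderate correlation because ρ enters Ω).
Harmonization flips the outcome beta when effect/other alleles are swapped,
drops irreconcilable allele sets with a logged reason, and can optionally
drop palindromic variants (off by default; the synthetic data never
generates strand ambiguity).

## Multiplicity

`effective_tests_pca` standardizes each measure (PCA on the correlation
matrix, since volumes and thicknesses live on different scales), takes
eigenvalues of the correlation matrix, and returns the smallest k whose
cumulative eigenvalue share reaches the variance threshold (default 0.95).
The family-wise threshold is α/N_eff. Missing entries are mean-imputed per
column; zero-variance columns are dropped with a warning. BH-FDR is the
standard step-up adjustment (statsmodels) and is reused verbatim by the DE
and enrichment stages.

## ROI aggregation

Voxel-space ROI identification is replaced by a tabular stand-in: measures
group by (atlas, region, hemisphere); the representative statistic is the
extreme-|z| member (matching the convention of reporting a single z per
named region), with a mean-z mode behind a flag (its p recomputed from the
normal tail). The significant flag is exactly p < threshold.

## Differential expression

Probes collapse to genes by the max-mean-intensity probe (averaging
available as an alternative). Per gene, a Welch two-sample t-test compares
the target region's samples to all non-target samples on log2 intensities;
logFC is the difference of group means, i.e. log2 fold change ("rest of
brain" excludes the target region). The overexpressed set is the strict
filter q < 0.05 and logFC > 2 (log2 scale, the microarray convention),
positive direction only. Welch was chosen over a moderated empirical-Bayes
test because it is assumption-light at tens of samples per region; a
moderated variant is a natural extension. Donor-level blocking and
hemispheric asymmetry are not modeled.

## Enrichment

For each term, with universe size N (genes measured on the platform, not
the genome), term size K, query size n and overlap k, p is the one-sided
upper hypergeometric tail P(X ≥ k). The odds ratio comes from the 2×2
table with Haldane–Anscombe 0.5 correction only when a zero cell exists;
CI = exp(log OR ± 1.96·SE) with SE = √(Σ 1/cell); z = log OR / SE (the
Wald construction — reported OR/CI/z conventions vary across tools, and
this is the assumed definition). BH runs within each ontology separately;
`top_terms` orders by (q, p, term id), a total order.

## Network connectivity

The null is uniform edge density: D = |E|/C(|V|,2), E_exp = C(k,2)·D, and
the binomial tail P(Bin(C(k,2), D) ≥ E_obs). The permutation alternative
draws uniform k-node sets and uses the add-one estimator
(1 + hits)/(1 + n_perm), which can never return 0 and has resolution
1/(n_perm+1). Degree-corrected nulls used by curated interaction databases
are deliberately not reproduced; on Erdős–Rényi backgrounds (degree
homogeneous) the binomial and permutation routes agree within Monte-Carlo
error, and tests assert this. Query genes absent from the background are
dropped by default (with a log line) or counted as isolated nodes behind a
flag; edge confidences are ignored for counting but can pre-filter edges.

## Synthetic data

The generator produces every pipeline input with planted, recorded truth.

- **Genotypes.** Dosages are sums of two latent-Gaussian haplotypes
  thresholded at Φ⁻¹(MAF). Thresholding deflates correlation, so the latent
  within-block correlation is calibrated by inverting the tetrachoric
  relation (Brent root-finding on the bivariate-normal orthant probability);
  variants within a block share a MAF so the calibration holds for every
  pair. Targets above 0.95 are rejected as infeasible. Downstream stages
  consume the empirical (not target) LD.
- **Summary statistics** are per-variant simple regressions on simulated
  individuals, never drawn directly — this makes betas, SEs and their
  cross-variant correlations mutually consistent with the LD, which is what
  makes the correlated IVW estimator correctly calibrated on these data
  (empirical type-I ≈ 0.05 by construction, verified by test).
- **Outcome panel.** Each measure is (true effect × genetic exposure score)
  plus noise equicorrelated in blocks; metadata assigns modality
  (GMV/CT), atlas, region and hemisphere deterministically, so planted
  effects can be addressed to one named ROI. Block correlation of 1 is
  allowed (identical measures), which pins the effective-test count to the
  block count exactly.
- **Expression.** Gene baselines uniform on [5, 10] log2 units, small probe
  offsets, planted genes shifted in the target region only.
- **Annotations.** Terms sample uniformly from the universe except
  designated enriched terms, which draw a stated fraction from the planted
  set (capped at its size).
- **Network.** Independent Bernoulli edges at the background density, with
  planted-module-internal pairs rewired to the module density.
- **Determinism.** All draws flow from one master seed through named
  substreams (crc32 of the stream name into a `SeedSequence`), so each
  stage regenerates independently and identical configs are byte-identical.

What the generator does **not** emulate: realistic human LD maps or
population structure, MRI phenotype derivation, microarray normalization
artifacts, donor effects, degree-heterogeneous interaction networks.
Passing tests therefore demonstrate correctness of the statistical
machinery under its stated assumptions, not robustness to those real-data
complications.

## Study conditions and problem sizes

Calibration experiments: 5 instruments in one r = 0.5 block, per-allele
effect 0.3, exposure sample n = 5000 (keeps weak-instrument attenuation of
the no-measurement-error weights well below Monte-Carlo resolution),
outcome sample n = 2000; 2000 replicate datasets for type-I error, 500 for
recovery of a planted effect of 0.2. Each replicate redraws the exposure
GWAS noise, the outcome genotype panel and the outcome noise; only the
exposure panel (which doubles as the LD reference) is fixed, mirroring a
fixed reference population.

Demo pipeline: exposure/outcome samples of 2000/5000 individuals, 12
variants in blocks (4, r=0.5), (4, r=0.5), (4, r=0.3), MAF ∈ [0.15, 0.45];
120 measures (10 regions × 2 hemispheres × 6 measures), noise blocks of 10
at ρ = 0.5, 6 planted measures at effect 0.3 in MTG/right; 1000 genes × 2
probes, 10 samples per region, 40 planted genes at +3 log2 in the MTG,
noise SD 0.5; three ontologies of 50 terms (sizes 10–60), 3 enriched terms
each at fraction 0.8; background network density 0.01 with a 20-gene module
at 0.3. These sizes keep the full chain at a few seconds while leaving
every planted signal comfortably detectable at its stage's threshold.

## Known limitations

- Exposure-side SEs are never propagated; very weak instruments would bias
  β̂ toward zero without warning beyond the documented convention.
- The effective-tests rule is the PCA-count estimator only; spectral
  alternatives (Nyholt/Li–Ji) are documented as alternatives, not built.
- ROI grouping by shared labels is a stand-in for spatial overlap logic.
- The connectivity null ignores degree heterogeneity; on scale-free
  backgrounds the binomial p is anticonservative for hub-rich query sets.
- Enrichment assumes a flat term list: no ontology DAG propagation or
  term-term redundancy reduction.
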