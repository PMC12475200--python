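# Methods

This note records the models, defaults, and numerical choices behind
`ecostate`, and what the synthetic benchmarks do and do not demonstrate.

## Generative model

A bulk sample is modeled as a linear mixture of cell-type expression
profiles in RNA-mass space. Cell fractions `c_t` live on a simplex; the
fraction of RNA a type contributes is

    e_t = r_t · c_t / Σ_u r_u · c_u

where `r_t` is relative RNA content per cell (1 for all types except LP,
default 16.67). Each sample's expression is `Σ_t e_t · b_t ⊙ p_{t,s(t)}`
with `b_t` the base profile and `p_{t,s}` the multiplicative program of the
sample's planted state `s(t)`, optionally perturbed by i.i.d. multiplicative
lognormal noise and TPM-normalized per column. Because TPM deconvolution
operates in RNA-mass space, its LP estimate is inflated relative to the LP
cell fraction by `e/c = r / (1 + (r − 1)c)` — about 13.9× at 1–2% LP when
r = 16.67. The genotype anchor estimates exactly this realized inflation;
its planted value is recorded as `SyntheticTruth.inflation_factor`.

States are sample-dominant: each sample carries one planted state per cell
type, matching the dominant-state abstraction used downstream (33%
abundance, 15% margin). Sample-level ecotypes pin one state per cell type
wherever the type has at least as many states as ecotypes; a configurable
share of samples (default 15%) draws states independently and is planted
"unassigned".

### Generator defaults and why

- **14 cell types, 35 states** (B:4; CD4T, CD8T, MonoMac, Tfh, LP:3;
  eight others:2) — the lineage panel and the observed 2–4 states per type
  in immune-rich lymphoma tissue; six multi-state types give each of the
  three ecotypes six exclusive member states, enough for the ≥4-states-per-
  ecotype rule to have headroom.
- **LP cell fraction ∈ (0.005, 0.02)**, matching the ~1% malignant content
  characteristic of this disease; `rna_content[LP] = 16.67`.
- **Marker genes**: 20 per type at ≥8-fold over every other type — strong,
  well-conditioned signatures (condition number ≈ 2).
- **State programs**: ~18–26 genes per state (scaled to the gene budget) at
  3-fold change, on genes ~2× elevated in the owner type, with baselines
  lognormal around 10 expression units. This places the planted states in
  the regime the method targets: subtle relative to marker separation,
  recoverable at lognormal σ = 0.2 but not trivially so, and visible to
  dispersion-based gene selection (coefficient of variation of log2(x+1)
  penalizes genes whose mean dwarfs their spread, so state genes are kept
  near the background expression scale).
- **Clonal VAFs**: mean VAF = LP cell fraction / 2 per sample
  (heterozygous clonal mutations), relative noise `vaf_noise_sd`;
  plasma compartment with duplex support and deep coverage by default so
  planted variants survive the specificity filters, plus low-support
  artifact rows so the filters are exercised.
- **Repertoires**: clonotype frequencies follow a one-parameter power law;
  the exponent is found by bisection against the realized count entropy
  (monotone in the exponent), hitting targets within ±0.05 nats at
  repertoire size ≥ 500. A small per-sample jitter (sd 0.02 nats) avoids
  degenerate ties in rank tests.
- **Survival**: exponential times with hazard
  `baseline · exp(log_hr · LPE3 abundance)`, independent exponential
  censoring calibrated to the requested censor rate, LP-IPS and management
  stratum drawn independently.

### What the generator does not emulate

Sequencing-level artifacts (UMIs, read depth, mapping), platform batch
effects between signature and mixture, correlated gene-gene noise,
continuous state gradients within a sample, doublets/segmentation errors in
single-nucleus data, and real spatial morphology. Passing benchmarks
therefore demonstrate the correctness and self-consistency of the
algorithms under the stated generative assumptions, not field performance
on clinical cohorts.

## Numerical and procedural choices

- **ν-SVR deconvolution**: linear kernel, C = 1, ν grid {0.25, 0.5, 0.75},
  best in-sample RMSE kept; signature z-scored globally, mixture z-scored
  per sample over shared genes (case-insensitive symbol match, first
  occurrence wins on duplicates); negative coefficients clipped, simplex
  renormalized. Estimates are invariant to TPM column rescaling.
- **Anchor regression** is through the origin (the expected 1:1 relation
  between 2×median VAF and true LP fraction has no intercept), regressing
  2×median(VAF) on the LP estimate; scale factor = 1/slope. The correction
  sets LP to estimate/scale and rescales only the other types to fill the
  row: this keeps the corrected LP exactly at the anchored value, so a
  second anchoring yields slope 1 (idempotence). Dividing LP and
  renormalizing the whole row instead would re-inflate LP by the row
  deficit (~20% at these LP levels).
- **GEP imputation**: stage 1 solves per-gene NNLS of expression on the
  fraction matrix (exact on noiseless linear mixtures); a gene is imputed
  for a type when the fit explains the gene (R² ≥ 0.2) and the type
  expresses it (positive coefficient). Stage 2 scales the group estimate by
  `1 + w · relative residual`, `w` = the type's share of total fraction
  among expressing types; constant genes keep their group estimate. Types
  with < 50 imputed genes are excluded. Zero-abundance types are excluded
  rather than making the rank check fail; genuinely collinear fractions
  raise an error advising more samples.
- **NMF**: multiplicative updates, Frobenius objective, random
  non-negative initialization per restart; scan fits capped at 500
  iterations (tol 1e-6), final fit best-of-restarts at 2000. Input is
  log2(x+1), per-gene standardized (frozen means/stds reused verbatim in
  recovery), posneg-stacked.
- **Rank selection**: per candidate rank, the consensus matrix of argmax-H
  co-clustering across restarts is summarized by (a) the cophenetic
  coefficient and (b) per-cluster reproducibility — cutting the consensus
  dendrogram at that rank must realize that many clusters, each with ≥ 2
  samples and median within-cluster co-clustering ≥ the same 0.95
  threshold. The selected rank is the largest meeting all three. The
  reproducibility requirement exists because the cophenetic coefficient
  saturates once clusters are well separated (between-cluster
  dissimilarities dominate the correlation), so by itself it cannot detect
  that a higher rank merely inherits a stable coarser clustering; the
  median (not mean) within-cluster consensus is robust to a few stray
  samples from unresolvably rare states. If no rank qualifies, rank 2 is
  returned flagged low-confidence; a curve that passes everywhere is
  flagged degenerate.
- **AFI**: share of a state's top-50 basis loadings that sit in the
  negative posneg block; states above 0.5 are dropped and the coefficient
  matrix renormalized. Dropping never reorders surviving samples'
  abundances.
- **Ecotypes**: gating keeps a Jaccard entry only when the upper-tail
  hypergeometric co-occurrence p-value is < α = 0.01 (enrichment, never
  depletion); average linkage on 1 − J; states with no significant
  co-occurrence at all are excluded before clustering (they cannot belong
  to an ecotype); candidate cuts must give every cluster ≥ 4 states;
  silhouette (on states, precomputed 1 − J distance) picks the cut, ties
  preferring fewer ecotypes. Sample assignment requires significance
  (BH Q < 0.25 on the Welch test of member vs non-member abundances);
  non-finite test statistics (e.g., perfectly flat samples) map to p = 1,
  i.e., unassigned.
- **Spatial**: dominant state per (spot, type) set to 1, multiplied by the
  parent type fraction, divided by the type's 99th-percentile spot value
  under the linear-interpolation quantile convention, capped at 1. Rook
  adjacency is the default neighbor rule on integer grids, the 6-neighbor
  Visium array rule and k-nearest-neighbor weights are available. Moran's I
  uses the textbook double-sum with mean-centered values; the permutation
  p-value is upper-tail with the +1 correction. Constant fields raise
  (autocorrelation undefined).
- **Threshold optimization** maximizes the two-group log-rank chi-square
  over an abundance grid (10th–90th percentile, 41 points), each side
  keeping ≥ 10% of samples, ties taking the lower threshold; an optional
  permutation p re-optimizes over shuffled abundances to correct the
  optimism of the chosen cutpoint. The inner statistic is a vectorized
  log-rank identical to the lifelines value (asserted in tests) but ~100×
  faster, which makes the permutation correction affordable.
- **Cox**: lifelines partial likelihood (Breslow ties), stratified by
  management type, adjusted for LP-IPS; a guard requires ≥ 5 events per
  parameter. ROC AUC uses midranks (= Mann-Whitney U / n₁n₀); the
  relapse-by-horizon label excludes samples censored before the horizon,
  and the with/without-ecotype comparison scores in-sample linear
  predictors of unpenalized logistic fits.
- **Rank-sum comparisons** are exact when both groups have ≤ 20 tie-free
  observations, tie-corrected normal otherwise. Entropy defaults to nats
  (comparisons are base-invariant); a bits option exists.

## Problem sizes

The test suite and `scripts/acceptance.py` run cohorts of 40 (noiseless
deconvolution), 60–80 (state/ecotype discovery at σ = 0.2), 50 (validation
recovery) and 200 (outcomes) samples on a 1200-gene panel, with rank scans
over 2–6 and 20 restarts, 12–20 seed replicates for stochastic rates, 200
simulation runs for Cox coverage, and 100–400-spot grids for spatial
checks. These sizes were chosen so the statistical properties asserted
(selection rates, ARIs, coverage, KS uniformity) are measured with
meaningful replication while the whole suite completes in about a minute on
one CPU; the algorithms themselves have no dependence on these sizes.

## Known limitations

- The AFI formula, the single-cell recovery statistic (Pearson correlation
  of a cell's log profile with each state's positive basis), and the
  two-stage imputation are documented in-house constructions for steps
  whose published descriptions name only intent, not arithmetic; they are
  exact on noiseless constructions and validated on synthetic data, but
  they are not reconstructions of any external tool's internals.
- Dominant-state binarization discards within-sample state mixtures; the
  Welch assignment test treats state abundances as exchangeable
  observations, which is approximate when types contribute different state
  counts.
- The optimized log-rank threshold's naive p-value is optimistic by
  construction; use the permutation-adjusted value for inference.
- Batch or cross-platform normalization between signature and mixture is
  deliberately out of scope (a config hook exists); the synthetic data are
  single-platform.
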