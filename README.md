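# ecostate

Cell-state ecotype analysis for nodular lymphocyte-predominant Hodgkin
lymphoma (NLPHL) and similar immune-rich tumors, built as a tested, reusable
pipeline with a synthetic-data generator that plants every structure the
analysis assumes.

NLPHL is a rare B-cell malignancy in which the malignant lymphocyte-
predominant (LP) cells make up only ~1% of the tissue; nearly everything a
bulk RNA-seq sample measures is microenvironment. `ecostate` implements the
full analytical chain used to characterize such tumors:

1. **Digital deconvolution** — a marker-gene signature matrix over 14 cell
   types (13 immune/stromal lineages + LP) is fitted to each bulk TPM
   profile by linear-kernel ν-support-vector regression (ν ∈ {0.25, 0.5,
   0.75}, best RMSE kept), giving per-sample cell-type fractions on a
   simplex. A two-tier composition (immune-subset fractions × coarse immune
   fraction) and pooling of fine types into the 14 lineages are provided.
2. **Genotype-anchored LP rescaling** — for a heterozygous clonal somatic
   mutation, tumor fraction ≈ 2×VAF. After variant filtering (≥4 supporting
   reads; VAF > 3% in tumor or > 0.1% with duplex support in plasma), a
   through-origin regression of 2×median(VAF) on the estimated LP fraction
   yields a slope whose inverse is the factor by which expression-based
   deconvolution overestimates LP abundance (LP cells carry far more RNA
   per cell). LP fractions are divided by this scale factor, the other
   types absorbing the difference symmetrically.
3. **Cell-state discovery** — cell type-specific expression is imputed from
   bulk (two-stage non-negative least squares with residual-share
   re-apportioning), reduced to its most dispersed genes, log-transformed,
   gene-standardized, split into stacked positive/negative parts (posneg),
   and factored by consensus NMF. The number of states per cell type is
   chosen by consensus stability at threshold 0.95 (cophenetic coefficient
   plus per-cluster reproducibility) over candidate ranks 2–20; states
   dominated by negative-part features are removed by the adaptive
   false-positive index (AFI) filter.
4. **Ecotype discovery** — each sample receives a dominant state per cell
   type (abundance ≥ 33%, margin ≥ 15%); state co-occurrence across samples
   is measured by the Jaccard index, gated by an upper-tail hypergeometric
   test (α = 0.01), clustered hierarchically (≥ 4 states per cluster,
   silhouette-maximizing number of clusters), and samples are assigned to
   their top ecotype when a Welch t-test of member versus non-member state
   abundances survives BH correction (Q < 0.25).
5. **Recovery** — frozen state/ecotype models are mapped onto validation
   cohorts (NNLS against the frozen basis), single-nucleus data
   (permutation z-scores combined by Stouffer's method, z > 1.65), and
   spatial transcriptomics (per-spot dominant states scaled by parent
   fractions and the 99th percentile, ecotype = mean of member states,
   aggregation tested by Moran's I with permutation p-values).
6. **Repertoire & outcomes** — Shannon entropy of TCR/BCR clonotype tables
   with rank-sum group comparisons; freedom-from-progression association by
   Kaplan-Meier/log-rank with an optimized (and permutation-corrected)
   abundance threshold, stratified Cox regression adjusted for the LP-IPS
   score, and ROC AUC for relapse-by-horizon prediction.

All of it runs end to end on synthetic cohorts from `ecostate.simulate`,
which plants known cell fractions (LP at 0.5–2% with ~16.7× RNA content),
2–4 transcriptional states per cell type, three sample-level ecotypes,
clonal VAFs, spatial ecotype regions, entropy-controlled repertoires, and
ecotype-dependent hazards — so every stage can be scored against ground
truth.

## Worked example

```python
from ecostate import simulate, deconvolution as dc, states

panel = simulate.generate_reference_panel(1200, simulate.default_cell_type_spec(), seed=7)
eco_map = simulate.default_ecotype_state_map(panel, 3)
expr, truth = simulate.generate_bulk_cohort(panel, 40, 3, eco_map, noise_model=None, seed=1)

sig = dc.build_signature_matrix(panel.base_profiles)
res = dc.SupportVectorDeconvolution(expr, sig).fit()
print(res.summary())

gt = dc.filter_variants(simulate.generate_genotype_table(truth, vaf_noise_sd=0.0, seed=3))
scaled, fit = dc.genotype_anchor_scale(res.fractions, gt)
print(f"anchor slope = {fit.slope:.4f}, scale factor = {fit.scale_factor:.2f}")
print(f"LP fraction before/after: {res.fractions['LP'].mean():.4f} -> {scaled['LP'].mean():.4f}")
print(f"planted LP cell fraction: {truth.cell_fractions['LP'].mean():.4f}")
```

prints

```
nu-SVR deconvolution
  samples: 40   cell types: 14
  shared signature genes: 140
  median fit RMSE (z-scale): 0.0002
  mean fractions:
               B  0.0653
       ...
              LP  0.1792
anchor slope = 0.0743, scale factor = 13.46
LP fraction before/after: 0.1792 -> 0.0133
planted LP cell fraction: 0.0132
```

The raw deconvolution reports ~18% LP because LP cells contribute ~13.9×
more RNA per cell than the average cell in these mixtures; the genotype
anchor recovers that inflation (13.46 vs the planted 13.86) and corrects the
LP estimate to the true ~1.3% cell fraction. Continuing,

```python
gep = simulate.generate_celltype_gep(panel, truth, "Tfh", noise_sigma=0.2, seed=11)
st = states.CellStateNMF(gep, "Tfh", ranks=range(2, 7), n_restarts=20,
                         n_top_genes=150, scan_max_iter=200).fit(seed=0)
print(st.summary())
```

```
cell states: Tfh
  selected rank: 3
  surviving states: S01, S02, S03
  dropped by AFI: none
  cophenetic by rank: 2:0.988, 3:1.000, 4:0.997, 5:0.996, 6:0.985
```

recovering the three planted follicular-helper T-cell states.

A command-line interface mirrors the modules
(`ecostate simulate|deconvolve|discover-states|discover-ecotypes|recover|spatial|repertoire|outcomes`);
see `ecostate --help`.

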