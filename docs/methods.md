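# Methods

This note documents the modelling assumptions, numerical choices and
parameter defaults of the `iscn` package, and what the synthetic-cohort
tests do and do not establish about real data.

## Similarity-network construction

**Inputs.** Per-region vectors of modulated GMV voxel values, either
extracted from a NIfTI GMV map + integer atlas on the same voxel grid
(voxel-exact alignment is required; resampling is preprocessing and out of
scope) or read from the cohort archive (long-format TSV of
`subject, region, voxel_value` triples plus a JSON sidecar freezing the
region order — streamable, language-neutral, bit-exact on round trip).
Zero-GMV voxels inside a parcel are kept by default (`drop_zeros` flag
available): the distribution of a parcel includes its empty voxels unless
the user's mask convention says otherwise.

**KDE.** Gaussian kernel, 512 evaluation points, bandwidth by Silverman's
robust rule `h = 0.9 · min(sd, IQR/1.34) · n^(-1/5)`, density renormalized
to unit trapezoid integral on its grid. 512 points is deliberately
conservative: halving or doubling it changes KLS values only in the fourth
decimal for typical parcel sizes.

**Grid convention.** Divergences require a common support. Each region
*pair* gets its own grid: 512 equally spaced points spanning the pooled
[min, max] of the two samples, padded by 3 pooled-sample bandwidths per
side so kernel tails are not clipped. A pair-pooled grid preserves
resolution for low-variance regions, which a single global grid would
starve; a `global_grid` mode exists for sensitivity analysis.

**Divergence.** Symmetric KLD in the Jeffreys form
`Σ (p−q)(ln p − ln q) w` with trapezoid weights, computed on ε-floored
(ε = 1e-10) and renormalized densities. Flooring keeps the sum finite where
one density underflows; every term is nonnegative, so KLD ≥ 0 and
KLS = exp(−KLD) ∈ (0,1] with KLS = 1 iff the densities coincide. The edge
between identical distributions is exactly 1; the diagonal is fixed at 0 and
excluded from thresholding (self-similarity carries no information).

**Numerics.** Kernel evaluations run in float32 with float64 accumulation
(relative error ~1e-7, orders of magnitude below the KDE's statistical
error; ~2x faster). Voxel samples are sorted before summation, making the
network bit-exactly invariant to voxel ordering, and the KLD term uses
`ln p − ln q` rather than `ln(p/q)` so the divergence is bitwise symmetric
in its arguments. A 246-region subject builds in well under 30 s on one
core (~2 s for 60 regions × 200 voxels).

## Topology

**Thresholding.** The K% strongest off-diagonal edges are retained and
binarized; the edge count is `round(K/100 · R(R−1)/2)` with
round-half-away-from-zero, and ties are broken by ascending (i, j) index so
every subject has exactly the same edge count at a given K. Because the
retained set is a prefix of the sorted edge list, edge sets nest as K
grows — connectedness at the lower bound therefore holds over the whole
range, and global efficiency is non-decreasing in K.

**Metrics.** Global efficiency is the mean of 1/d over ordered node pairs
(unreachable pairs contribute 0); the clustering coefficient is the mean
nodal triangle ratio (degree < 2 contributes 0); characteristic path length
averages over reachable pairs. Small-worldness
σ = (C/C_rand)/(L/L_rand) uses 20 Maslov–Sneppen degree-preserving rewired
surrogates with 10·|E| swap attempts each (numba kernel, seeded); 20
surrogates bound the runtime while keeping the surrogate-mean noise near
1%. Modularity is the best Q over 10 seeded Leiden restarts
(`leidenalg`, run to convergence). Assortativity is the Pearson correlation
of endpoint degrees over edges and is NaN (undefined) on degree-regular
graphs such as complete graphs. Degree is left raw, betweenness is
normalized by (R−1)(R−2)/2, eigenvector centrality is the principal
adjacency eigenvector scaled to max 1 — fixed conventions so group
statistics are scale-consistent.

**Range selection.** K_min is the smallest scanned density (step 1) at
which every subject's network is one connected component; K_max is the
largest density of the contiguous run from K_min over which every subject's
σ exceeds 1.1 (σ decays toward 1 with density). Scanning is capped at
K = 60% by default. On the synthetic cohorts the selected range typically
starts near K = 11 and reaches the cap: KLS networks built from 1-D
Gaussian mean spacings are proximity graphs, whose clustering stays far
above degree-matched surrogates even when dense. Real morphometric
networks lose small-worldness sooner; the config accepts an explicit
`density_range` (e.g. 12–39, step 1) to reproduce a fixed-range analysis.

**AUC.** Each metric is integrated over the retained densities by the
trapezoid rule with unit (step) spacing, un-normalized, using the identical
threshold set for every subject. Metrics that are non-finite for any
subject at any threshold (e.g. σ = ∞ when all surrogates of a very sparse
graph are triangle-free) are dropped from the harmonized feature set.

## ComBat harmonization

Parametric empirical-Bayes ComBat: per-feature standardization on the full
design (site indicators + protected covariates), normal prior on additive
site effects γ, inverse-gamma on multiplicative effects δ², priors
moments-matched across features, iterative conditional estimation to
tolerance 1e-4, then adjustment `(z − γ*)/δ*` with the intercept, covariate
effects and pooled scale restored. Diagnosis is preserved by default
(drop it from `preserve` to change that). Topology and edge features are
harmonized as separate matrices; subgroup analyses re-harmonize within the
subgroup's sites. Constant features pass through with a warning; sites
need ≥ 2 subjects; confounded designs are rejected.

The implementation agrees with Bioconductor `sva::ComBat` to ~2e-7 on a
frozen fixture (tests/data). Note a structural property verified in the
tests: on *null* data the adjustment does not vanish — it equals the
EB-shrunk sampling noise of the per-site estimates, ~1/√(n_site) of the
feature SD — so "output ≈ input" holds only for large sites (~4% deviation
at 500 subjects/site, ~13% at 20/site). This is inherent to ComBat, not an
implementation artifact.

## Group inference

**GLM.** Per feature, OLS of `feature ~ group + covariates` (age, gender by
default; any extra phenotype column such as TIV can be added). Cohen's d is
the group contrast divided by the residual SD, matching the GLM framing.
Bonferroni families: 5 for global metrics, R per centrality type for nodal
metrics (the 3R alternative is available by passing `family`). Constant
features yield NaN statistics, never a spurious p.

**NBS.** Edge-wise t statistics for the group contrast with covariates;
suprathreshold edges taken separately for positive and negative t beyond
the two-tailed p < 0.001 critical value; connected components found by
breadth-first search; group labels permuted (covariates stay attached to
subjects — the classic scheme; the permutation count defaults to 10 000)
with the identity as the first permutation, so corrected p ≥ 1/n_perm and
the observed statistic equals the identity-permutation statistic by
construction. Component "size" is the edge count; increased and decreased
components are tested against their own direction's max-size null because
the two directions are reported separately. With a p < 0.001 edge
threshold the discrete null makes the procedure conservative: on null
cohorts the realized familywise error sits well below the nominal 5%
(verified by simulation), which is the standard behaviour of max-statistic
permutation tests on sparse discrete statistics.

**Yeo summaries.** For a significant component, the connection weight
between systems A and B is the component's A–B edge count divided by the
maximum possible count in the parcellation (n_A·n_B between systems,
n_A(n_A−1)/2 within), plus per-system weight sums.

**Clinical association.** Partial Pearson correlation by residualizing
feature and score on the covariates, two-tailed p on n − k − 2 dof,
Bonferroni over the feature family (topology and connectivity treated as
separate families).

## Classification

Linear SVM, C = 1, no hyperparameter search; stratified k-fold
(default 10) with shuffling seeded; features standardized with
training-fold statistics only (no leakage). Accuracy/sensitivity/
specificity are pooled over test folds, AUC comes from pooled
decision-function scores, and the 95% CI is mean ± 1.96·SE of fold
accuracies. Region contributions aggregate the mean |w| across folds: in
topology mode a region's score is the mean over its three centrality AUC
features (global metrics map to no region); in connectivity mode the mean
over its R−1 incident edges; ties rank by ascending region label.

## Synthetic cohorts

Voxels of subject i, region r are drawn
`N(base_mean_r + site_shift + age_slope·(age−40) + gender_offset·male
+ group terms, (base_sd_r · site_scale)²)`. Defaults, chosen once as
plausible for modulated GMV: region means spread over [0.35, 0.85]
(seed-shuffled so region index and mean rank are not confounded), SD 0.08,
site shifts ±0.02, site SD scale ±10%, age slope −0.002/yr, male offset
+0.01, 3 sites, 60 regions × 200 voxels, 120 subjects (< 1 min end-to-end).
Gaussian voxels were chosen because the Gaussian symmetric KLD has the
closed form `(μ₁−μ₂)²/σ²` (equal variances), giving analytic oracles for
the network builder. Edge effects move one region's patient mean toward or
away from its partner's by a stated fraction; HAMD-17 is a linear function
of the *realized* KLS of a designated edge (z-scored) plus noise, scaled to
center 30, SD 6, rounded and clipped to the clinical inclusion range
[18, 52], so the target partial correlation `coef/√(coef²+noise²)` is known
exactly up to the (small) clipping attenuation.

What the generator does **not** emulate: spatial autocorrelation of MRI,
non-Gaussian GMV distributions (bimodality at tissue boundaries), realistic
atlas geometry, scanner-specific voxel covariance, or site-by-age
interactions. Passing recovery tests therefore establish that the
pipeline's statistics behave correctly under their stated models — not that
effect sizes or accuracies transfer to real consortium data.

## Known limitations

- Modularity maximization is NP-hard; Leiden multi-start matches exhaustive
  search on essentially all tiny graphs (verified on hundreds of ≤ 8-node
  graphs) but rare degenerate landscapes can defeat any restart budget.
- The σ criterion depends on the surrogate ensemble; with 20 surrogates the
  threshold-range upper bound can move by ±1 density step between seed
  streams. The acceptance check therefore re-verifies the selected range
  with fresh seeds rather than reusing the selection's.
- ComBat here is the parametric variant only (no non-parametric or GAM
  modes, no longitudinal design).
- NBS permutes labels only; a Freedman–Lane residual-permutation flag is
  exposed in the API surface but the classic scheme is the default and the
  one validated by simulation.
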