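# Methods

## Pipeline overview

The analysis runs in a fixed order, mirroring how a multi-cohort bulk
expression study is processed:

1. **Expression preprocessing** — low-expression filter → GC-aware quantile
   normalization → log2(CPM + 0.25) → PCA outlier removal → duplicate and
   small-batch removal → empirical-Bayes batch correction (ComBat) →
   removal of subtypes with fewer than 10 tumors. All of this operates
   within each cancer type, as each type is its own dataset.
2. **Methylation deconvolution** — epithelial / fibroblast / immune
   fractions per sample by robust partial correlations.
3. **Panel selection** — immunomodulators (cancer germline antigens,
   immunoinhibitors, MHC genes) are dropped if lowly expressed in any
   subtype, or strongly and significantly correlated with the immune
   fraction in any cancer type.
4. **Relative effects** — per cancer type, each retained variable
   (panel-gene expression, nonsilent mutation burden, CD4/CD8 T-cell
   levels) is summarized per subtype as a probability on [0, 1].
5. **MHC clustering** — the subtype × MHC-gene probability matrix is
   consensus-clustered; clusters are labeled MHC-low / MHC-intermediate /
   MHC-high by ascending mean probability.
6. **Mutation summary and pan-cancer correlation summary.**

## Relative effects: estimator and reference choice

The relative effect `p_i = P(Z < X_i) + ½ P(Z = X_i)` is estimated with
midranks; ties contribute half counts throughout.

Two references are implemented and the choice matters:

* **Normal-tissue reference (default).** `p_i` is estimated from pairwise
  comparisons between subtype *i* and the normal-adjacent group of the same
  cancer type. The anchor is then interpretable — 0.5 means "exchangeable
  with normal tissue" — and, crucially, a subtype's probability does not
  depend on which *other* subtypes its cancer type happens to contain, so
  rows from different cancer types are mutually comparable. This is what a
  cross-type clustering substrate needs.
* **Pooled reference (option).** `p_i = (mean pooled midrank − 0.5)/N` per
  cancer type. This variant satisfies an exact conservation identity (the
  group-size-weighted mean per variable is 0.5 to machine precision, which
  the tests assert at 1e-9) and is the natural companion of the ANOVA-type
  statistic. Its drawback as a clustering substrate is compositional: in a
  cancer type dominated by MHC-low subtypes, a merely average subtype ranks
  near the top of the pool and its probability saturates upward. In
  development this visibly merged the intermediate and high classes on
  planted data, which is why it is not the default for the subtype matrix.
  The unweighted (equal group weight) pooled estimator is also available.

The ANOVA-type statistic `T = Σ_v Σ_i n_i (p̂_vi − 0.5)²` uses the pooled
weighted effects. Its permutation null (group labels shuffled jointly
across variables, `p = (1 + #{T* ≥ T}) / (n_perm + 1)`) makes the test
exactly calibrated regardless of the omitted variance normalization of the
classical studentized form; the acceptance suite verifies a 2–8% rejection
rate at α = 0.05 over 200 null datasets.

Band calls discretize probabilities at 0.4 / 0.6: ≤ 0.4 "lower", ≥ 0.6
"higher", otherwise "not changed".

## Deconvolution

Robust partial correlations: each bulk beta profile is regressed on the
reference profiles by Huber M-estimation (tuning constant 1.345, IRLS to
1e-6 or 50 iterations, no intercept — betas and references share the [0,1]
scale and mixtures are affine-free). Negative coefficients are truncated to
zero and the vector renormalized to the simplex; renormalization applies
even when the raw coefficients sum above 1. `huber_c = inf` reduces the fit
to ordinary least squares followed by the same truncation (asserted to
1e-6 on clean data). CD4/CD8 T-cell levels use the same fit against an
extended reference and return the two T-cell columns without
renormalization after extraction.

## Preprocessing details

* **Low-expression rule:** CPM ≥ 1 in ≥ 20% of samples (both thresholds
  configurable).
* **GC adjustment:** genes are stratified into 10 GC-quantile bins; within
  each sample every stratum is full-quantile mapped (midrank plotting
  positions, linear interpolation) onto the sample's overall count
  distribution; a second, between-sample full quantile normalization maps
  every column onto the mean sorted distribution. With tie-free data the
  sorted columns agree exactly afterwards; tied values share their
  interpolated midrank value.
* **PCA outliers:** one pass; samples are projected on the first two
  principal components of the gene-centred matrix and dropped when farther
  than 3× the root-mean-square distance from the projection centroid.
* **Batch hygiene:** duplicate sample ids keep the first occurrence;
  batches with ≤ 4 samples are removed.
* **ComBat:** parametric priors only (normal on the per-batch location,
  inverse-gamma on the scale, moment-matched, iterative conditional update
  to 1e-4). Genes with zero within-batch variance have their scale estimate
  floored at 1e-8 with a warning. After back-transformation each gene is
  re-centred to its original overall mean: empirical-Bayes shrinkage
  otherwise leaves a small location residual, and batch correction is only
  defined up to overall location. A cross-check test compares the output
  against the scanpy port of the same scheme (agreement to ~4e-3 after
  centering).
* **Subtype-size filter:** tumor subtypes with < 10 samples (within their
  cancer type) are dropped; normals always pass because they are the
  reference group downstream.

## Panel selection

Spearman correlations use midranks with two-sided p-values from the
t-approximation; Benjamini-Hochberg FDR is computed within each cancer type
across the panel genes (filter) or across variable pairs (summary) — the
FDR family is recorded in the run log. The removal rule defaults to
positive-only correlation (`rho ≥ 0.4` and `q ≤ 0.05`), with an absolute
mode available; a gene flagged in any cancer type is removed globally. The
pan-cancer summary adds sign(rho) per cancer type for every strong &
significant pair and sums over types, yielding integers bounded by ± the
number of types.

## Clustering

Algorithms: Ward/Euclidean hierarchical clustering (cut at K), k-means with
25 restarts (seeded), PAM (greedy BUILD then SWAP on Euclidean distances).
The validity battery is a fixed, documented set of 12 indices — average
silhouette width, Calinski-Harabasz, Davies-Bouldin (lower is better),
Dunn, connectivity with 10 nearest neighbours (lower), C-index (lower),
within-cluster sum of squares (lower), between/within variance ratio, gap
statistic with 20 uniform-reference k-means draws, PBM, Xie-Beni (lower)
and the separation gap (mean between-cluster minus mean within-cluster
distance). Undefined scores (e.g. singleton clusters) receive the worst
rank. K is chosen by mean rank over all algorithm × index series, ties
toward smaller K. Consensus: PAM and hierarchical labels are aligned to
k-means by maximum-agreement Hungarian matching, followed by majority vote;
three-way disagreements go to the cluster whose unanimous-member centroid
is nearest. Labeling ties (equal means) are broken by cluster size, larger
= lower.

## Synthetic cohort generator

The generator emulates the joint structure the analysis relies on:

* **Counts:** negative-binomial (gamma-Poisson) with a single shared
  dispersion (default 0.1, i.e. ~0.46 log2 units of biological noise),
  per-sample library sizes log-normal (ln-mean 14.5 ≈ 2M reads, ln-sd 0.3),
  per-gene baselines with a weakly expressed background slice so the
  low-expression filter has work to do.
* **Panel:** 105 CAGs, 25 immunoinhibitors, 32 MHC genes by default,
  embedded in a 400-gene background. The background must dwarf the panel:
  CPM normalization couples every gene to the library total, so an
  unrealistically panel-heavy library damps planted immune correlations
  and induces spurious negative ones (observable by shrinking the
  background in tests).
* **Immune structure:** per-sample (epithelial, fibroblast, immune)
  fractions from Dirichlet(2, 1, 1) — mean immune fraction 0.25 with a wide
  spread, as bulk tumors show; a configurable fraction of panel genes
  (default 0.3) gains `immune_beta × immune fraction` log2 units (default
  β = 2). CD4/CD8 truth levels are 0.6/0.4 × immune fraction plus N(0,
  0.02) noise.
* **MHC archetypes:** each subtype is low / intermediate / high with log2
  shifts −1.5 / −0.25 / +1.5 applied to MHC genes in tumor samples only.
  The shift sizes are calibration choices: large enough that an archetype
  is detectable at 20–30 samples per subtype over ~0.46 log2 noise, small
  enough that single-gene bands remain probabilistic.
* **Study layout:** `table1_composition()` reproduces the 13-type /
  55-subtype layout with its published MHC-low membership (27 subtypes).
  The 8-member MHC-high set is not enumerated in the source study; the
  generator's stand-in picks hypermutated / viral / immunogenic subtypes
  (COAD-CMS1, STAD-MSI, STAD-EBV, UCEC-POLE, UCEC-MSI, HNSC-CIMP,
  LIHC-iCluster-3, ESCA-EAC), consistent with the elevated mutation burden
  reported for the high class.
* **Batches:** assigned within cancer type; shifts are drawn per gene ×
  batch (N(0, batch_sd)). A batch shift constant across genes would cancel
  exactly under CPM normalization, leaving nothing for ComBat to correct,
  so the per-gene form is the meaningful plate-effect model.
* **Methylation:** reference profiles are cell-type-discriminating CpGs
  (betas 0.1/0.9 in non-constant patterns); bulk betas are the convex
  mixture plus clipped Gaussian noise (default sd 0.05).
* **Mutations:** per sample × gene Bernoulli (default 0.002) with
  archetype multipliers (low 1×, intermediate 2×, high 5×), nonsilent MAF
  classes only, tumors only.

What the generator does **not** emulate: probe-level array artifacts,
copy-number and mutational signatures, per-gene heterogeneity of archetype
shifts, correlated gene modules beyond the immune factor, and FFPE/platform
effects. Passing tests therefore demonstrate correctness of the machinery
and recoverability of planted structure, not performance on real tumors.

## Problem sizes and numerical choices

The default planted-layout run uses 20 tumors per subtype (1,100 tumors +
130 normals, 562 genes, 500 CpGs) — large enough that the planted three
class structure is recovered exactly and reproducibly across seeds, small
enough to run in seconds. The end-to-end recovery test uses 20 replicate
seeds at 30 samples per subtype on a 5-type, 15-subtype layout (five
subtypes per class — below ~4 rows per class the K-selection problem
itself becomes ill-posed); the type-I calibration
test uses 200 null datasets with 199 permutations each. Convergence
tolerances: IRLS 1e-6; ComBat EB updates 1e-4; conservation identity
asserted at 1e-9; permutation-tie comparisons use a 1e-12 epsilon. A single
master seed spawns per-stage seeds (numpy SeedSequence), so skipping a
stage does not perturb the others.

## Known limitations

* The normal-reference relative effect saturates for large shifts (3+
  noise SDs give probabilities near 0 or 1), so distances between strongly
  shifted subtypes compress; ordering, not magnitude, is the reliable
  signal there.
* With ~10 normals per type the pairwise estimator's sampling SD is ~0.1;
  band calls for single variables at that depth are noisy, which is why
  clustering pools across all MHC genes.
* The validity battery has 12 indices, not the 14 of the software package
  the study used (whose exact list is not published); the aggregation
  scheme (mean rank, ties toward smaller K) is a documented concretization.
* Deconvolution quality is bounded by the reference panel; the package
  treats the reference as an input and does not ship a real CpG panel.
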