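# Methods

This note documents the models and procedures implemented in `regiontx`,
the parameters that matter, what the synthetic-data generator does and
does not emulate, and the numerical and design choices that were genuinely
open.

## Voxel-based group analysis

**Model.** Each subject contributes one volumetric phenotype map. The
per-voxel model is ordinary least squares on the design
[intercept, group, covariates], and the reported statistic is the t of the
group coefficient ("patient > control"; the opposite contrast is the
negation). Assumptions are the usual GLM ones — independent subjects,
homoscedastic Gaussian voxel noise — and the permutation inference below
does not rely on the Gaussian part.

**Smoothing.** Volumes are smoothed before fitting with a separable
Gaussian kernel, σ = FWHM / (2√(2 ln 2)) / voxel size; the default FWHM is
3 mm at 1 mm voxels. At mask edges the smoothed volume is divided by the
smoothed mask, so edge voxels are not diluted by out-of-mask zeros. FWHM 0
is the identity.

**TFCE.** The t-map is enhanced with threshold-free cluster enhancement,
TFCE(v) = Σ_h e_h(v)^E h^H dh, where e_h(v) is the size of the connected
component containing v at threshold h. Defaults E = 0.5, H = 2,
26-connectivity, and dh = max|t|/100: these are the standard defaults of
the TFCE literature (the method's originating toolboxes do not vary them),
and the step rule makes the discrete sum scale as λ^(H+1) when the map is
scaled by λ. Positive and negative parts are enhanced separately and
recombined with their signs, so the enhancement is an odd function of the
input. Thresholds are midpoints (k + ½)dh; an isolated unit-height voxel
then integrates to ∫₀¹ h² dh = 1/3 up to O(dh²). Per-voxel values at the
default step carry an O(dh/|t|) discretisation error relative to the
continuum integral, which is material only for voxels whose |t| is a few
steps — comparisons against the integral (or against a finer-step sum)
are therefore made at matched step size.

**Permutation FWE.** Covariates stay in the model, so permutation uses the
Freedman–Lane scheme: the reduced model [intercept, covariates] is fitted
once, its residuals are row-permuted and re-added to the reduced fit, and
the full-model group t is recomputed. The null statistic is the maximum
|TFCE| over the mask; p_fwe(v) = (1 + #{perm max ≥ |TFCE_obs(v)|}) /
(n_perm + 1), giving an estimator floor of 1/(n_perm+1). The default
permutation count is 5000; the scaled-down study configuration uses 200,
which bounds attainable p at 1/201 ≈ 0.005 and is sufficient for a 0.05
FWE threshold.

**Parcellation.** Regional phenotype = mean statistic over the in-mask
voxels of each atlas label; label 0 is background; a region with no
in-mask voxels is flagged and set missing rather than silently imputed.

## Spatial nulls

Regional brain maps are spatially smooth, so testing a spatially smooth
covariate (gene expression) against a naive permutation null overstates
significance. The surrogate generator randomises the phenotype while
preserving its empirical variogram: permute the values; smooth with a
Gaussian distance kernel on region-centroid distances, over a bandwidth
grid of 10%…90% of the maximum centroid distance; then form
√α·(smoothed) + √β·(white noise), with (α, β) the non-negative
least-squares fit of the empirical variogram on [smoothed-variogram, 1].
The white-noise term supplies the nugget — at typical parcellation
resolution the nearest centroids are several units apart and the map
already decorrelates partially at that lag, which a smoothed permutation
alone cannot reproduce (without it the variogram fit stalls around r ≈
0.5; with it, ≥ 0.99 on spatially structured maps). The bandwidth with
the smallest variogram residual is kept per surrogate, the mean is reset
to the original mean, and the per-surrogate fit (Pearson r between
empirical and realised surrogate variograms) is recorded. Variograms use
equal-count distance bins (default 10) so every bin is estimated from the
same number of pairs. Distances are Euclidean between centroids — the
only geometry available at regional level.

## PLS gene ranking

Expression columns and the phenotype are z-scored (sample SD, ddof = 1);
zero-variance genes are dropped with a logged count and stay excluded
from every downstream universe. The fit is NIPALS partial least squares
with a univariate response: per component, w = X'y/‖X'y‖ (so the
component-1 weight vector is exactly the normalised vector of
gene–phenotype covariances — an identity the tests exploit), score
t = Xw, followed by rank-one deflation of X and y. Explained response
variance per component is q_k²‖t_k‖²/‖y‖², which sums to the cumulative
R² because scores are orthogonal. Both response- and predictor-side
variance fractions are reported, since "variance explained" is ambiguous
in the field's usage. The default fit reports K = 10 components; the
ranking uses component 1.

**Alignment.** The NIPALS weight sign is arbitrary, so component weights
are flipped whenever the component scores correlate negatively with the
phenotype. After alignment a large positive weight means expression rises
with the phenotype — the convention under which the top/bottom-gene
validation regression must come out positive/negative. (With this fit the
component-1 score–phenotype correlation is non-negative by construction,
so the flip only ever fires for deflated components or externally supplied
models.)

**Z statistic.** The PLS is refitted against every surrogate phenotype;
gene g's statistic is Z_g = w̃_g(observed) / SD(w̃_g over surrogates).
This calibrates each gene against how strongly its (spatially smooth)
expression pattern aligns with *any* map of the phenotype's spatial
character, not just the observed one. Genes with zero null SD are
excluded and logged. Ties in Z are broken by gene symbol for determinism.
A region-resampling bootstrap SD is provided as an alternative
denominator but is not the default — the spatial-null SD is the operative
definition of the ranking.

**Validation.** The top-5 and bottom-5 ranked genes are regressed
(expression on phenotype, per gene); slopes and r are reported. On
planted data all top slopes are positive and all bottom slopes negative.

## Preranked GSEA

Classic weighted running-sum enrichment: hits increment by
|Z|^p / Σ|Z|^p (default p = 1), misses decrement by 1/(N − |S|), ES is the
signed maximum deviation, and the leading edge is the hit genes up to the
extremum (from it, for negative ES). The permutation unit is gene labels
(a same-size set drawn uniformly from the universe), the only null
available for a preranked list; the null ES for all permutations of a set
size is computed in a vectorised pass using the fact that the running-sum
extremum can only occur at a hit position or immediately before one.
NES = ES / mean(|null ES| of the same sign); p is the same-sign null tail
with add-one correction; FDR q is the standard NES-based pooled-null
ratio of tail fractions, clipped to [0, 1]. Size filters default to
[10, 500], the conventions of the packages practitioners use; for
deliberately small collections (the synthetic pSI marker panels of ~5–8
genes) the pipeline lowers the minimum to 3 — the filter is a stability
convention, not part of the statistic. Redundancy pruning is greedy by
significance with a gene-overlap Jaccard threshold (default 0.7): GO
semantic similarity would require an ontology dependency, and gene
overlap is the operative quantity for enrichment redundancy; this is a
documented divergence from ontology-based "simplify" procedures.

## Cell-type specificity (SI/pSI)

Per RNA-seq series, FPKM is averaged per cell type (endothelial, neuron,
oligodendrocyte, astrocyte, microglia, OPC — fixed order). For target
type A, genes are ranked by (FPKM_A + ε)/(FPKM_B + ε) against each other
type B (rank 1 = most A-enriched, average ranks on ties; ε = 1 FPKM
guards zeros and keeps low-expression ratios conservative). SI_A is the
mean of the five ranks; a gene expressed only in A has SI_A = 1; under
exchangeability the mean SI is (G+1)/2 and each comparison's ranks sum to
G(G+1)/2 exactly.

pSI is a permutation p-value with a gene-pooled null: each permutation
shuffles the sample→cell-type assignment, recomputes type means and SI;
null SIs are pooled across genes and permutations, and
pSI(g, A) = (1 + #{null SI_A ≤ SI_A(g)}) / (pool + 1). Pooling across
genes is what makes the 0.001 set-defining threshold reachable from ~100
permutations of a 2,000-gene table (2×10⁵ pooled draws) instead of 10⁵
per-gene permutations. The permutation unit was a genuinely open choice:
shuffling gene labels within each type column looks natural but pairs the
numerator and denominator of a fold change from different genes, so the
shared per-gene baseline no longer cancels and the null acquires the
wrong cross-comparison dependence — measured as systematically
non-uniform null pSI. Sample-label permutation preserves each gene's
baseline structure, makes the observed table a genuine null draw under no
specificity (null pSI uniform by construction), and is the standard
expression-analysis null; it is the default whenever sample-level data
are available, with the column shuffle retained only as a fallback for
mean-only input. Genes with pSI below the threshold (default 0.001) form
one gene set per cell type and series.

## Synthetic data: what it emulates, and what it does not

The generator produces every pipeline input with planted ground truth,
fully determined by integer seeds:

- **Atlas** — Voronoi regions around random seed voxels: contiguous,
  disjoint, covering; default 83 regions, the size of the volumetric
  Desikan–Killiany parcellation. The mask is the full grid.
- **Cohort** — unit-variance Gaussian voxel noise (the simplest model
  satisfying the GLM's assumptions); patients add the effect size d
  inside the chosen regions, so the planted voxel-wise Cohen's d equals d
  (default scaled-down study: d = 1.5, 20 per group, 16³ grid). Age ~
  U(45, 75) years, sex ~ Bernoulli(0.5); covariate slopes default to 0
  but are configurable, and the covariates are always in the model so the
  Freedman–Lane machinery is exercised regardless.
- **Expression** — coupled gene g is ρ_g·z(phenotype) + √(1−ρ_g²)·z(noise),
  with all noise fields sharing an exponential spatial covariance
  exp(−d/range) on centroids (default range 5 grid units ⇒ neighbouring
  regions correlate ≈ 0.4, a moderate, AHBA-like smoothness). This gives
  the surrogate stage real autocorrelation to preserve and the ranking
  stage real spatial confounding to overcome: with a whole-map smooth
  gradient as phenotype the uncoupled-but-smooth genes confound strongly
  (sensitivity drops to ~0.67), whereas with the pipeline's own focal
  TFCE phenotype the calibrated ranking recovers essentially all planted
  genes — the study conditions use the latter, which is what the real
  analysis does.
- **Cell-type FPKM** — log-normal baselines shared across types (so
  between-type folds are driven by sampling noise), three independently
  seeded series, 5 samples per type. Planted markers: 5 per type,
  multiplied by fold 10 in their own type, baselines drawn from the upper
  expression range (mean log-FPKM 2 vs 1). The small, well-expressed
  panel is deliberate: K markers per type compete for the top K fold
  ranks, so the weakest planted marker has SI ≈ K, and the ε pseudo-count
  dampens the fold of weakly expressed genes; detection at pSI < 0.001 is
  mathematically restricted to genes ranking in the extreme few of every
  comparison. Canonical marker panels — small sets of robustly expressed
  genes — are exactly that regime.
- **Gene sets** — one planted-positive and one planted-negative set from
  the coupled genes plus uniform random decoys (sizes uniform in
  [10, 50]).

Not emulated: susceptibility physics or units, registration/segmentation
error, site or donor effects, AHBA probe/donor structure, gene–gene
coexpression modules beyond shared spatial autocorrelation, and
sequencing-depth artefacts in FPKM. Passing tests therefore demonstrate
the statistical machinery — calibration, recovery, determinism — under a
clean generative model, not robustness to the real data's artefacts.

## Pipeline and reproducibility

`run_all` executes the stages with per-stage seeds derived from one
top-level seed by a counter-based rule (`SeedSequence([seed, stage_index])`,
reduced below 2³¹), so the whole run is reproducible to the byte and
stages can be regenerated independently (the numbered `analysis/` scripts
rely on this to stay self-contained). Identifiers (region ids, gene
symbols) travel in every table; joins are by key, never by position. Any
stage failure is re-raised tagged with the stage name.

The scaled-down study configuration (16³ grid, 83→20 regions depending on
stage, 40 subjects, 2,000 genes, 200 surrogates, 200 FWE permutations,
1,000 GSEA permutations, 100 pSI permutations) is chosen so the complete
suite and the acceptance script run on a single CPU in minutes while
every statistic remains in its calibrated regime; the full-size defaults
(83 regions, 1,000 surrogates, 5,000 FWE permutations) are the package
defaults on the individual functions.

## Known limitations

- TFCE is computed by threshold stepping (100 steps); per-voxel values
  for near-zero |t| carry the discretisation error described above.
  Inference is unaffected (the max statistic and suprathreshold sets are
  dominated by well-resolved voxels).
- The surrogate model matches first/second moments and the variogram, not
  higher-order spatial structure.
- The GSEA FDR is the field-standard pooled-NES estimator; it can return
  q = 0 when the observed NES exceeds every pooled null draw, and is not
  monotone in NES by construction.
- The pSI fallback for mean-only tables uses the column-shuffle null and
  inherits its bias; supply sample-level tables where possible.
- Jaccard pruning is a proxy for ontology-aware term simplification.
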