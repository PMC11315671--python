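# Methods

This note documents the models implemented in `invasig`, the parameter
choices that matter, what the synthetic-data generators do and do not
emulate, and the numerical conventions used throughout. It states no
empirical result that the test suite and `scripts/acceptance.py` do not
themselves compute.

## Single-cell quality control

Three filters run per sample, in a fixed order. The boundary
conventions are taken literally from the filtering rules they encode:

| filter | rule | boundary |
|---|---|---|
| low quality | total UMIs ≤ 1000 **or** mitochondrial fraction > 5% removed | 1000 removed, exactly 5% kept |
| gene–UMI envelope | keep cells inside the 1 − α prediction band | inclusive on both bounds |
| doublets | doublet score > 0.5 removed | exactly 0.5 kept |

The gene–UMI envelope fits log₁₀(genes detected + 1) on
log₁₀(UMIs + 1) by ordinary least squares and evaluates the classical
two-sided prediction interval at confidence 1 − α, with α = 1 / (number
of droplets in the sample), computed per sample. A Huber-weighted fit
is available behind the `robust` flag; OLS is the default because its
interval has a closed form and is exactly reproducible. The `+1` inside
the logs guards zero counts; the log–log scale is where the relation is
close to linear in real data. A zero-variance fit returns infinite
bounds with a warning flag rather than failing.

Two caveats are worth recording. First, whether the original analysis
used robust or ordinary regression, and whether its "tolerance" band is
a prediction or confidence band, is not specified anywhere we could
pin down; the prediction band is the only reading under which single
displaced barcodes are removable at all. Second, re-running QC on
already-filtered data refits the envelope on the survivors; on clean
data the second pass removes nothing (tested), but idempotence is a
property of the data regime, not an algebraic identity.

## Differential expression

Counts are normalized to `ln(1 + 10⁴ · c / total)` per cell. Per gene,
the two groups are compared with a two-sided Wilcoxon rank-sum test
(`scipy`'s `mannwhitneyu`, `method="auto"`: exact null for small
tie-free groups, tie- and continuity-corrected normal approximation
otherwise). Genes constant across both groups carry no evidence and are
assigned p = 1. The fold change is

    logFC = log2((mean_A + 1) / (mean_B + 1))

on the CP10K scale (pseudocount 1), so the gates logFC ≥ 0.5 (inclusive)
and BH-adjusted p < 0.001 (strict) match the published selection rule.
The BH family is all genes tested in the comparison. The base and
pseudocount of the fold change are recorded in the result's provenance
because reproduced gene counts shift under any defensible alternative.

## Signature construction

Over-representation of a query gene list in a gene set is the
hypergeometric upper tail P(X ≥ k) for a universe of N genes, K set
members and a query of n — identical to one-sided Fisher's exact on the
2×2 table (tested to 1e-10). This replaces a web-service enrichment
tool with a deterministic, offline equivalent sufficient for the
set-intersection use of GO terms.

The correlated-cluster step computes the gene × gene Pearson
correlation over patients, clusters on distance **1 − |r|** with average
linkage, cuts the dendrogram at height 1 − r_min, and returns the
largest cluster (ties: higher mean intra-cluster |r|, then
lexicographically first gene). Absolute correlation is used so the
distance lives in [0, 1] and a cut at r_min = 0 sits above every
possible merge; strongly anti-correlated genes are treated as
co-regulated. Linkage, threshold, and the selection rule are exposed as
parameters because no published values exist for them; the default
r_min = 0.5 selects tight modules (pairwise r ≳ 0.5) without demanding
near-duplication. Candidate genes absent from the cohort are dropped
with a warning — mirroring how unmatched symbols are handled in
practice — and a singleton "cluster" is flagged rather than returned
silently.

## Cohort survival analysis

Preprocessing is a fixed five-step chain:

1. entries with detection p > 0.05 are set missing (skipped when no
   detection matrix is supplied);
2. genes missing in > 70% of patients are removed;
3. remaining missing entries are imputed with seeded uniform draws
   between the gene's observed minimum and its 15th percentile — the
   most literal "random numbers coming from the 15th percentile"; a
   constant-percentile variant is available by flag;
4. quantile normalization across patients (each patient's sorted values
   replaced by the across-patient mean order statistics; ties take the
   mean of their candidate values);
5. genes with SD < 0.5 are removed.

The SD filter acts on quantile-normalized values *before* z-scoring:
after z-scoring every SD is 1, so a post-z filter would be vacuous —
the ordering ambiguity is resolved in the only way that gives the
filter content. z-scores use population SD (ddof 0). The activity
score is the per-patient mean of z-scores over the signature genes that
survived preprocessing, with the surviving list reported.

Stratification sorts patients by score (ties broken by patient id) and
assigns the first ⌈n/2⌉ to the low group — the extra patient in odd
cohorts goes to "low", which is deterministic and conservative against
inflating the high-risk group. Survival comparisons are standard:
Kaplan–Meier product-limit curves with at-risk tables, the two-group
log-rank χ² (1 df), and a univariate Cox proportional-hazards fit on
I(high) with Efron tie handling and Wald 95% CI (via `lifelines`).
Degenerate fits (e.g. one event) are flagged `converged=False` rather
than raised; the multi-cohort screen records per-cohort failures
without aborting.

HPV filtering is a row filter on the `hpv_status` covariate applied
before everything else. Whether quantile normalization and imputation
belong in every cohort's preprocessing or only in microarray cohorts is
not specifiable in general; the same chain runs by default with flags
to disable individual steps.

## Imaging

**Segmentation.** Nuclei: Otsu threshold, connected components, and a
watershed on the distance transform to split touching nuclei. The
cytosolic compartment is a 3-px dilation annulus per nucleus, clipped
against neighboring cells; cells whose annulus falls below 10 px are
discarded as mis-segmented. This is a synthetic-scene-grade
segmentation, not a replacement for a dedicated cell segmenter on real
microscopy.

**Positional classes.** `single`: the cell's pixels are disjoint from
the organoid mask; `core`: centroid inside the mask eroded by 3 median
cell diameters (the "inner layer, excluding the outer 3 layers" rule);
`strand`: the rest. When no mask is provided it is derived as the
largest connected cell-occupied component.

**Orientation and coherency.** Gaussian-derivative gradients at scale
σ_g = 1 px; tensor components ⟨Ix²⟩, ⟨IxIy⟩, ⟨Iy²⟩ smoothed at σ_w =
4 px; gradient-dominant angle φ = ½·atan2(2Jxy, Jxx − Jyy); fiber
orientation θ = 90° − φ wrapped into (−90°, 90°], counter-clockwise
from the image x-axis (fibers are bright ridges, perpendicular to the
dominant gradient). Coherency C = (λ₁ − λ₂)/(λ₁ + λ₂), set to 0 where
the tensor trace is below 1e-12; C is invariant to affine intensity
rescaling. The scales are defaults, exposed as parameters — the
plugin-based original does not publish its scales.

**Border alignment.** The border normal is the gradient of the
smoothed distance transform of the structure mask. For pixels within
100 µm of the border, the deviation between fiber orientation and the
normal is folded into [0°, 90°]; pixels within 20° of the normal count
as perpendicular fibers, and their mean coherency is reported in 10-µm
bins, with a bin flagged aligned above the 0.2 non-random cutoff. How
the original plugin combines coherency and perpendicularity into its
0–1 alignment value is unpublished; per-bin mean coherency of
perpendicular fibers is one defensible reading, and the tolerance and
bin width are parameters.

**Region sampling.** Square regions (62,500 µm², i.e. 250 µm × 250 µm)
are placed uniformly at random, fully inside the requested zone mask,
by a seeded RNG; each region reports the mean ratio of the cells whose
centroid it contains. Random placement is a choice — manual placement
is not reproducible.

## Synthetic-data generators

The generators define the study conditions for every recovery test;
their defaults are fixed once and shared by the test suite and the
acceptance script.

**Single-cell counts.** Gene relative abundances are log-normal
(σ = 2), spanning several decades as real transcriptomes do;
mitochondrial genes (2% of genes) jointly take ~2.5% of reads.
Counts are negative binomial with mean μ = depth · p_gene and variance
μ + 0.1·μ² per cell. Per-cell depth is log-normal (mean 5000, natural-
log σ = 0.35) truncated at ±2σ: the deep depth tails are precisely what
the planted low-quality class models, so healthy cells stay within a
bounded range. Each cell additionally carries a bounded
transcriptome-diversity exponent τ ~ U(0.92, 1.08) applied to the
log-abundances — cells genuinely differ in how many genes they express
at a given depth, and this bounded cell-to-cell spread dominates the
residual of the genes~UMIs regression, so the 1 − α envelope does not
clip healthy cells. DE genes are planted (fold 2^logFC in the invasive
group) only on genes expressed at ≥ ~2 counts per 10k: an effect on a
silent gene is not an observable condition at the logFC ≥ 0.5 gate.
Planted low-quality cells are created by binomial thinning to ≤ 1000
UMIs or by adding mitochondrial reads past 5%; doublet scores are
Beta(8,2) truncated above 0.5 for doublets and Beta(2,8) truncated
below for singlets — only the 0.5 threshold matters downstream. The
generator does **not** emulate ambient RNA, batch effects, or real
doublet expression profiles (scores are planted, not computed).

**Cohorts.** A latent per-patient factor drives the signature genes
with unit loading and noise SD 1/3, putting their pairwise correlation
near 0.9 — the regime a "strongly cross-correlated cluster"
represents. The planted activity score (mean z over signature genes on
the clean matrix) defines high/low at the median; survival is
exponential with hazard multiplied by the configured HR in the high
group, censoring is independent uniform with its upper bound solved so
the expected censored fraction matches the configured rate. Missing
entries and detection failures are planted preferentially on
low-expression entries (detection-limit regime) — the setting in which
low-value imputation is approximately unbiased; uniformly random
missingness would contradict the imputation model the pipeline
implements. Recovered hazard ratios are mildly attenuated relative to
the planted value because stratification happens on the noisy,
preprocessed score rather than the planted one; the acceptance script
reports the median over a 30-seed ensemble.

**Scenes.** Nuclei are disks (r = 4 px) with 3-px cytosol rings; the
core is a disk (r = 100 px), strands are capsules touching it, single
cells sit in a detached annulus; geometry is schematic because the test
targets are intensities and angles, not morphology. The marker channel
paints nucleus = ratio × cytosol per positional class; the collagen
channel blends a sinusoidal stripe texture at the configured angle with
smoothed isotropic noise inside the aligned band and pure isotropic
texture elsewhere. Core cells are placed within 55% of the core radius
so the positional ground truth is unambiguous under the 3-layer
erosion rule.

## Problem sizes and determinism

All randomness flows from `numpy.random.default_rng(seed)`; every
stage is reproducible bit-for-bit from its seed, and the full pipeline
serializes to byte-identical JSON across runs (tested). The default
problem sizes — 600–1000 cells, 2000 genes, cohorts of 1000 patients,
30–100-seed ensembles for survival recovery, 256²–512² px images —
were chosen so the whole test suite and the acceptance script each run
in about a minute while keeping Monte-Carlo error well inside the
asserted tolerances.

## Known limitations

- The gene–UMI envelope's exact-recovery behavior is a property of the
  generator's bounded residual regime; on real data the envelope will
  (by design) trim ~α·n cells per sample.
- Reproduced DE gene counts on real data depend on the platform's test
  and logFC conventions, which are not published; ours are recorded in
  output provenance but cannot be guaranteed to match.
- The imaging module quantifies 2-D scenes only and approximates
  DAB/optical-density analyses by the same grayscale ratio machinery.
- Loaders accept user-supplied cohort tables only; no external
  downloads are performed or reproduced.
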