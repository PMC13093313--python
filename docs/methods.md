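# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical conventions, and the design choices behind `thermomem`. It
states no empirical result that the test-suite or
`scripts/acceptance.py` does not itself compute.

## Preprocessing

Counts are filtered on counts-per-million: a gene is kept when
CPM = count / library-size × 10⁶ is ≥ `min_cpm` (default 1) in at least
`min_samples` (default 4) samples. The published filtering rule's wording
("< 1 CPM in at least four individuals ... removed") is ambiguous between a
keep- and a remove-rule; the keep-rule is used because it is the
conventional reading and the thresholds are configurable either way.

Size factors are median-of-ratios: for genes expressed in every sample,
factor_s = median_g (count_gs / geometric-mean_g). Normalization is
`log2(count / factor + 1)`. This is a deliberate stand-in for a
regularized variance-stabilizing transform: it preserves the intent
(log-scale values with library-size removed) without re-implementing
dispersion-trend fitting, and exact numerical parity with such transforms
is a non-goal.

Low-variance genes (sample variance < 0.05, n−1 denominator) are removed on
the normalized scale. Sample outliers are detected once by standardized
connectivity k_s = Σ_{t≠s} (1 + cor(s,t))/2; samples with z < −2.5 are
dropped. The cutoff is applied one-sided on the low tail (an outlier sample
is one that fails to correlate with the rest; high connectivity is not a
defect), a sign the published "< 2.5" leaves implicit.

## Differential expression

Per-gene NB GLMs with log link and offset log(size factor). Dispersion is a
per-gene method of moments computed within design cells: for each cell c
with ≥ 2 replicates, α_c = (s²_c − μ̄_c)/μ̄²_c on normalized counts, pooled
across cells weighted by degrees of freedom and floored at 10⁻⁸. Computing
the MoM per cell (rather than pooling variances over a global mean) keeps
real between-condition fold-changes out of the dispersion estimate. There
is no empirical-Bayes shrinkage — this is an explicit simplification, so
DEG counts are not expected to match shrinkage-based pipelines gene for
gene; the acceptance-level claims are therefore about calibration (type-I
in [0.03, 0.07] at nominal 5%) and power on planted effects, not about
reproducing specific DEG totals.

Model comparisons are likelihood-ratio tests between nested models with the
dispersion held fixed (full model's estimate), χ² with df = parameter
difference, statistic clamped at 0. Default reduced models: the temperature
test drops temperature from priming + temperature; the priming test drops
priming; the interaction test drops the interaction from the full factorial.
Wald contrasts use z = cᵀβ̂ / se(cᵀβ̂) with log2FC = cᵀβ̂ / ln 2.
Benjamini–Hochberg correction excludes non-converged genes from m (they are
flagged, not silently dropped); significance is called at adjusted p < 0.01.

## Signed networks

Gene–gene adjacency a_ij = ((1 + cor_ij)/2)^β with β = 6 (Pearson by
default; gene–gene Spearman available). Topological overlap
TOM_ij = (ℓ_ij + a_ij)/(min(k_i,k_j) + 1 − a_ij) with
ℓ_ij = Σ_{u≠i,j} a_iu a_uj. Modules come from average-linkage clustering of
1 − TOM with a *static* cut at a configurable quantile of the merge heights
(default 0.70), clusters below 50 genes assigned to background (label 0),
and iterative merging of modules whose eigengenes correlate above 0.75
(dissimilarity < 0.25). The static percentile cut replaces the adaptive
branch-cutting heuristic of the reference implementations: on data with a
clear module/background split the merge-height distribution has a long flat
plateau between within-module merges and background agglomeration, and any
cut on that plateau gives the same modules (the default sits mid-plateau);
the quantile is exposed because clean fixtures without background need a
higher cut. Module eigengenes are first principal components of the
standardized member genes, scaled to unit variance and oriented so the mean
member kME is positive.

Gene significance is |cor(gene, trait)|; module–trait association uses
Spearman ρ with the t approximation (exact enumeration for n ≤ 9).
Intramodular weighted degree is the within-module adjacency row sum.

## Module preservation

For a module discovered in one family and evaluated in the other, seven
statistics are computed from the standardized test-side expression X, the
test-side summary profile h (first PC sample scores, sign-aligned to
positive mean node contribution), node contributions NC_i = cor(X_i, h),
and the frozen discovery-side references (correlations, NC, intramodular
degree):

| statistic    | definition |
|--------------|------------|
| avg_weight   | mean off-diagonal test adjacency in the module |
| coherence    | share of module variance explained by h |
| avg_contrib  | mean_i sign(NC_i^disc) · NC_i^test |
| cor_contrib  | cor(NC^disc, NC^test) |
| avg_cor      | mean over pairs of cor^test · sign(cor^disc) |
| cor_cor      | cor of the two correlation lower-triangles |
| cor_degree   | cor of intramodular weighted degrees |

The permutation null re-draws, without replacement, gene sets of the
module's size from **all** test-dataset genes (members included — the
simplest exchangeable null; exclusion is flag-switchable) and injects them
into the module positions in random order; discovery-side references never
change. All alternatives are one-sided "greater" (preservation predicts
large values), with p = (1 + #{null ≥ observed})/(N + 1), so p is never 0
and is exactly uniform under the null. A module is called preserved when
every requested statistic has p < α (default 10⁻⁴ at N = 10,000 — note the
attainable floor is 1/(N+1), so α must be chosen consistently with N; the
pipeline default is α = 0.01 at N = 1,000). Small p is evidence *of*
preservation for that statistic; a module is reported not-preserved with
the list of failing statistics. Genes missing from the test matrix ("NI")
are reported separately and excluded from the comparison; more than 50%
missing is an error.

## Candidates, enrichment, phenotypes

Candidates are module genes in the DEG set **and** above the within-module
`gs_quantile` (default 0.90) of gene significance **and** above the
`degree_quantile` (default 0.90) of intramodular degree, ties at the
boundary included. Neighbourhoods: the ⌈fraction·(n−1)⌉ genes most
correlated with a candidate (signed, descending, lexicographic tie-break),
edges binarized at the `edge_quantile` (default 0.90) of positive
correlations. "Top decile" is the default operational definition; a top-k
variant is reachable by setting the fraction.

KOG-style enrichment: delta rank = mean rank of the score among class
members minus the mean rank among non-members (mid-ranks, ranks over the
whole scored universe), two-sided Mann–Whitney U — exact null distribution
(own dynamic program) on tie-free universes of ≤ 25 genes, normal
approximation with tie correction otherwise; BH across classes. Unannotated
genes form an implicit, untested background. The same rank engine accepts
kME-or-zero score vectors for module-wise enrichment. GO-style enrichment is
a two-sided Fisher exact test per term with the conditional odds ratio
(infinite ratios reported as `inf`), BH across terms, significance at
corrected p < 0.01. Note the exact conservation law for this delta-rank
definition is Σ_c n_c (N − n_c) Δ_c = 0 over a partition (not Σ n_c Δ_c).

Survival uses the product-limit estimator (censored-at-t individuals count
as at risk at t); LT50 is the first event time with S ≤ 0.5 on the step
function (no interpolation — this matches tank-level "time until mortality
reached 50%" bookkeeping), reported as not-reached when S never crosses.
Group comparisons use the Fleming–Harrington G^ρ family with weights
Ŝ_pooled(t⁻)^ρ: ρ = 0 (log-rank) when the two KM curves do not strictly
cross, ρ = 1 (Wilcoxon-type) when they do. Mixed-effects proportional-
hazards modelling with random tank effects is out of scope; tank can be
handled by comparing replicates directly with the same G^ρ machinery.
Respiration rates are standardized with Ys = (Ws/We)^b · Ye, b = 0.75,
Ws = 1 g.

## Synthetic-data generator

The generator emulates the study design: 2 families × 2 priming × 2
temperature × `samples_per_cell` samples (default 6 → 96 samples), duplicate
tanks per cell, lognormal fresh weights (median 0.19 g, log-sd 0.3).
Defaults: 4,000 genes, four modules of 300/250/150/100 genes, NB size 20
(α = 0.05), baseline log2 means uniform on (5, 9), truncated-lognormal
library sizes on (0.7, 1.4).

Latent module eigengenes are E = (a·T + b·P + ε)/√(a² + b² + 1) with
T, P coded −1/+1. Default effects (a, b): (2, 3), (−2, 0), (0, 0),
(1.5, −2) — the first module responds to both temperature and priming (the
memory-carrying module), the others are up-, non- and cross-responding. Two
deliberate identifiability choices:

- the effect vectors are chosen so no two eigengenes are *positively*
  correlated — in a signed network, negatively correlated modules cannot
  bridge, which keeps the planted partition recoverable at these sample
  sizes;
- the noise components ε are drawn orthogonal in-sample to the design
  codings and to each other within each family, so the planted eigengene
  correlation structure is realized exactly instead of up to O(n^(−1/2))
  fluctuations (at n = 24 per family, a chance |cor| ≈ 0.3 between two
  "independent" eigengenes would otherwise merge their modules in a
  non-negligible fraction of realizations). All observable quantities
  remain stochastic through gene-level and counting noise.

A member gene with loading λ contributes s·(λE + √(1−λ²)z) log2 units
(s = 2.0); loadings are drawn U-shaped (Beta(0.4, 0.4) scaled to
(0.65, 0.9)) so each module has core and peripheral members — the
degree/contribution heterogeneity that real modules show and that the
profile-concordance preservation statistics need in order to carry signal.
Background genes are not pure noise: each loads weakly (0.3–0.6) on one
global expression axis, preserved across families, with intrinsic log2 sd
0.6. This pervasive low-level co-expression matters for the permutation
null — random gene sets drawn from a transcriptome with *no* shared
background structure are unrealistically incoherent, which makes the null
distributions of the concordance statistics degenerate around zero.

Ten designated hub candidates in the memory module get λ = 0.99 plus a
gene-level priming log2 shift of 1.0 in the coherent family, beyond the
module's shared response — the definition of a memory candidate is a gene
whose priming signal exceeds its module's, and this keeps its gene
significance identifiable above the module's own ceiling. They are the
ground truth for candidate triangulation. Means are corrected by
E[2^noise] so the marginal expectation stays at the baseline; counts are
NB(mean × library size, size).

The non-preserved module keeps its structure in family B; in family A each
of its genes is re-assigned with probability ½ to a random *other* module's
eigengene with random sign and re-drawn loading, and with probability ½ to
a private noise factor. A plain independent re-draw of loading magnitudes
would *not* break correlation structure (genes would still co-load on the
same factor); the reassignment mechanism reproduces the empirically
observed pattern of a dissolved module whose genes split across other
modules with opposite eigengene signs, while half decouple entirely. A
configurable fraction of background genes (default 10%) receives a
temperature log2 fold-change of 0.75 — these form a genuine diffuse
heat-response cluster, which realistically contaminates the detected
version of the memory module with genes whose co-expression *is* preserved;
planted-structure evaluation therefore tests preservation on the planted
gene sets, while detection quality is scored separately by the adjusted
Rand index over planted module genes.

What the generator does *not* emulate: GC/length biases and other
library-composition effects, batch structure, gene–gene regulatory
directionality, isoform-level signal, and real annotation structure.
Passing the planted-recovery suite therefore demonstrates that the chain's
inference machinery is correct and calibrated under its own model class,
not that any particular biological dataset would yield the same module
counts or candidate lists.

## Validation summary (computed by tests / acceptance script)

- Planted recovery at the default design: module-detection ARI ≥ 0.9 over
  planted module genes; all seven permutation p ≤ 0.01 for every preserved
  planted module (N = 1,000); cor_cor or coherence p > 0.05 for the
  scrambled module; hub-candidate sensitivity ≥ 0.8.
- Null calibration: for modules drawn uniformly from an unstructured
  background (200 modules × 500 permutations), each statistic's p-value
  ECDF lies inside the 95% Kolmogorov band around uniform.
- Type-I: NB-GLM LRT (two-group Poisson null, 1,000 genes, 20/group) and
  G^ρ (random splits, 500 reps) within [0.03, 0.07] at nominal 5%.
- Kernel oracles: TOM vs triple loop (10⁻¹²), eigengene vs SVD (10⁻¹⁰),
  MWU/Fisher vs exact enumeration, BH vs hand computation, KM/log-rank vs
  hand tables and lifelines, NB GLM vs Poisson oracle at α → 0 (10⁻⁴).

## Known limitations

- The log2 stand-in transform under-stabilizes very-low-count genes
  relative to a fitted variance-stabilizing transform; the variance filter
  downstream removes most of the affected genes.
- Per-gene MoM dispersion is noisy at small replicate counts; with strong
  planted effects the LRT loses some power relative to shrinkage-based
  estimators (calibration is unaffected).
- The static percentile tree cut assumes a module/background height
  plateau; on data that are all module (no background) the default cut
  falls inside module formation and must be raised.
- cor_cor and the profile-concordance statistics carry little information
  for small, homogeneous modules (nothing to be concordant about); verdicts
  for modules below ~100 genes lean on the density-style statistics.
- Permutation p-values are floored at 1/(N+1): preservation calls at
  α = 10⁻⁴ require N ≥ 10,000 permutations.
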