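# Methods

This note documents the models, conventions and numerical choices behind
`maizecore`, stage by stage, and what the synthetic data do and do not
establish about real germplasm panels.

## Statistical conventions

One convention is applied globally: sample standard deviation (n−1
denominator) everywhere, including z-scores, CV and the F-test; kurtosis is
reported as excess kurtosis (normal = 0) with the bias-corrected estimators;
missing trait values are excluded pairwise in raw summaries and mean-imputed
only where a complete matrix is required (PCA, distances). CV% is
100·sd/|mean| and is flagged as undefined, not silently zeroed, when a trait
mean is zero.

## Trait diversity index

The Shannon–Weaver index of a quantitative trait is computed over ten
frequency classes: class 1 below mean − 2sd, classes 2–9 in half-sd steps,
class 10 at or above mean + 2sd. This is the scheme conventional in
germplasm diversity studies; since diversity-index values depend on the
binning and the convention is rarely stated in publications, the class
edges are a parameter (`edges`) and published index values are not treated
as reference points. H′ is bounded by ln 10 ≈ 2.303.

## Distances and clustering

Mahalanobis distances use the sample covariance of the standardized trait
matrix; a singular covariance falls back to the Moore–Penrose pseudo-inverse,
or to (S + λI)⁻¹ when a ridge λ > 0 is requested.

Agglomeration is a generalized Lance–Williams engine:
d(k, i∪j) = αᵢ d(k,i) + αⱼ d(k,j) + β d(i,j) + γ|d(k,i) − d(k,j)|, covering
single (½,½,0,−½), complete (½,½,0,+½), median (½,½,−¼,0), centroid
(nᵢ/(nᵢ+nⱼ), nⱼ/(nᵢ+nⱼ), −nᵢnⱼ/(nᵢ+nⱼ)², 0), group average (UPGMA),
weighted average (WPGMA, ½,½,0,0), flexible ((1−β)/2, (1−β)/2, β, 0) with
β = −0.25 by default (the classical recommendation; configurable), and Ward
((nᵢ+nₖ)/N, (nⱼ+nₖ)/N, −nₖ/N, 0). The geometric methods — centroid, median,
Ward — are applied to **squared** distances with reported heights
square-rooted back, the only space in which their parameter sets are exact
(and the convention scipy uses, which the tests exploit as an independent
cross-check for the seven linkages scipy implements; the flexible method has
no scipy counterpart and is checked against a naive recompute oracle).
Nearest-pair ties break on the smallest (i, j) index pair, making merge
order deterministic. Centroid and median linkage can produce height
inversions; these are recorded, not corrected.

The mapping from the traditional Chinese-literature method names to standard
linkages used here: shortest distance → single, longest distance → complete,
intermediate distance → median, class averaging → group average, variable
class averaging → weighted average, sum-of-squares of deviations → Ward.
The naming in that literature is not fully standardized, so the mapping is a
documented package choice.

Neighbor joining is Saitou–Nei with the Q-matrix criterion via scikit-bio,
negative branch lengths clamped to zero, newick output. On additive
distances NJ recovers the generating tree exactly; this is the oracle the
tests use.

## Phenotypic core sampling

The stepwise procedure is realized as: z-standardize, build the distance
matrix, agglomerate, cut the dendrogram into k = round(ratio·n) clusters
(round = half away from zero), keep one representative per cluster. This
uses all four strategy factors and yields exact core sizes. Deviation
allocation keeps the member with the largest sum of squared deviations from
its cluster centroid in standardized trait space — the retained-variance
maximizing choice, which is why deviation cores typically show VR above
100% — with ties broken by smallest accession id. Random allocation draws
uniformly under the strategy seed. Cluster trees are cached per
(distance, linkage) across ratios.

## Core evaluation

MD% and VD% count traits whose core-vs-full Welch t-test, respectively
two-sided variance-ratio F-test, is significant at α (default 0.05), as a
percentage of the m traits; they therefore live on the lattice {100·j/m}.
The core is compared against the full panel as if independent, the
convention of this evaluation literature, and no multiple-testing correction
is applied because the statistics are defined on the raw per-trait tests.
CR% and VR% average the per-trait range and CV ratios; traits whose full
range or CV is zero (or whose CV is undefined) are excluded with the count
adjusted and a warning. The verdict thresholds MD < 20% and CR > 80% are
configurable. Ranking is fully deterministic: passing verdict, then
ascending MD, then descending CR, VR, VD, with the stable sort preserving
input order on exact ties.

## SNP statistics

Calls are coded 0/1/2 (ref-hom / het / alt-hom) with −1 for missing.
MAF uses allele counts (a heterozygote contributes one alternate allele)
over non-missing calls; the filter keeps loci with MAF strictly above the
threshold and missing rate strictly below it (defaults 0.01 and 0.01), and
is idempotent. Per-locus He = 1 − p² − q² ≤ 0.5 and Shannon's
I = −(p ln p + q ln q) ≤ ln 2 follow the per-biallelic-locus
allele-frequency convention; panel values are unweighted locus means
(whether to weight by locus or accession is a genuine choice; unweighted
locus means are used throughout). GSC is the identity-by-state allele
sharing proportion, per co-called locus 1 − |xₐ − x_b|/2. Genotype PCA
mean-imputes per locus and decomposes the centered call matrix.

Evanno ΔK consumes a (K, replicate, logL) table from external model-based
clustering software — the Bayesian clustering itself is out of scope — and
computes ΔK = |L(K+1) − 2L(K) + L(K−1)| / sd(L(K)) over replicate means for
interior K, requiring at least three replicates and three contiguous K
values; a zero replicate SD yields an infinite ΔK with a warning rather
than an error.

## Genotypic core

The modified Rogers distance for biallelic loci reduces to
d(a,b) = sqrt(mean over co-called loci of (xₐ − x_b)²) with x = call/2,
bounded in [0,1] with 1 attained by opposite homozygotes everywhere. The
selector maximizes the mean entry-to-nearest-entry distance: greedy
construction from the most distant pair (each candidate evaluated in O(k)
using maintained nearest-entry caches), then steepest-ascent single-swap
search until no improving swap or `max_iters` (default 1000) swaps. This is
a deterministic single-objective surrogate for the stochastic
multi-objective engines used interactively in core-collection software;
"diversity captured" is operationalized as allele coverage — the share of
(locus, allele) pairs observed in the panel that remain observed in the
core — since that phrase has no single established definition.

Integration is a set union: final = phenotypic ∪ genotypic core, with the
complement as the reserve set.

## Tolerance classification

Indicators are scored with the min–max membership function (the standard
form in the crop stress-tolerance literature), reversed for lower-is-better
indicators; constant indicators are dropped. The comprehensive value is
D = Σⱼ wⱼUⱼ with weights either equal or (default) PCA contribution rates:
per-indicator squared loadings weighted by each component's eigenvalue
share, summed over all components and normalized — interpreting "weighted"
via the variance structure of the indicator set. Classification clusters
the 1-D D values (not the raw membership matrix, for interpretability) with
Ward linkage into five groups labelled I–V by descending group mean D; the
tolerant set is groups I–III. Whether indicators should be expressed
relative to an unstressed control is a data-preparation question left to
the caller.

## Synthetic data: what it emulates and what it does not

The generators reproduce the statistical structure the analysis assumes, at
defaults chosen to mirror a real cold-region maize panel characterization:

* **Phenotypes**: Gaussian copula; each column affinely rescaled so sample
  mean/SD equal the targets exactly (so CV checks are deterministic rather
  than merely unbiased). Default traits are the 19 published
  (mean, SD) pairs, e.g. plot yield (1547, 875.683) kg and growth period
  (148.47, 6.571) days. No skewness is injected although real trait
  distributions are mildly skewed: every downstream statistic used here
  depends only on moments and correlations. The real panel's trait
  correlation matrix is not public, so the default correlation is identity
  and a user matrix can be supplied (PSD-checked, with the offending
  eigenvalue named on rejection).
* **Genotypes**: Balding–Nichols with a single F for all subpopulations.
  Defaults n = 588 accessions, K = 6 subpopulations, Fst = 0.1, ancestral
  MAF ~ U(0.1, 0.5), residual heterozygosity 0.03, per-call missingness
  0.005, 2000 loci over 10 chromosomes. These defaults give panel
  Ho ≈ 0.03 and He ≈ 0.39–0.40 after filtering, matching the reported
  inbred-panel profile; the locus count is scaled down from the
  7439-marker panel as the package's default problem size. No linkage
  disequilibrium, pedigree structure, or genotype × environment interaction
  is modelled, so tests demonstrate algorithmic correctness and statistical
  recovery under the stated model, not robustness to LD or kinship
  confounding.
* **Germination indicators**: five latent plateaus at (0.90, 0.75, 0.55,
  0.35, 0.15) across six indicators with Gaussian noise (sd 0.02), group
  sizes by largest-remainder apportionment of the proportions
  (default 4/14/47/64/43 of 172, the empirical five-group split of a
  germinated core panel). Plateau gaps of at least 5 noise-SD make label
  recovery a well-posed check of the membership → D → Ward chain.
* **L(K) tables**: replicate means piecewise-linear in K with the only
  slope change at the true K (2000 → 200 log-likelihood units per K step,
  replicate noise sd 20), a constructed optimum for the ΔK estimator.

## Degenerate inputs and tie-breaks

Constant traits: dropped (with warning) by z-standardization and
membership scoring, flagged in summaries, excluded from CR/VR. Singleton
clusters: their sole member is the representative. All-missing loci:
dropped and counted. Pairs with no co-called locus: NaN GSC with warning;
an error for modified Rogers (where downstream optimization needs a
complete matrix). All randomness flows through explicit integer seeds;
repeated runs are bit-identical, and pipeline outputs embed their seeds in
the run manifest.

## Known limitations

Strategy-grid composition (which linkages and ratios enter) is caller
supplied; the package does not prescribe one. The E-NE maximizer is a local
optimizer — it provably dominates large random-subset baselines in tests but
carries no global-optimality guarantee. Panel-level diversity values from
other software may differ by their locus-weighting and missing-data
conventions. The evaluation t/F tests treat overlapping samples as
independent, inheriting the conservatism/liberality of that convention.
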