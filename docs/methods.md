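# Methods

This note documents the models, estimators and design choices behind the
pipeline: what each stage computes, what the synthetic-data generators do and
do not emulate, and where the numerics have edges worth knowing about.

## The analysis in one paragraph

The pipeline characterises heterogeneity in a stem-cell-derived epicardial
culture from a gene-by-sample count matrix: cells failing plate-based QC
rules are removed; counts are library-size corrected (CPM), gene-filtered,
log-transformed and batch-corrected; cells are embedded by a seeded t-SNE
sweep and clustered with partitioning around medoids (PAM); the two main
clusters are compared by a negative-binomial Wald test; significant genes
feed a hypergeometric gene-set over-representation with a directional
z-score.  In parallel, bulk transcription-factor expression across
developmental stages drives directed network inference: mutual-information
association with CLR background correction (undirected, mirrored into both
directions) is intersected with per-target tree-ensemble importances
(directed), surviving edges are ranked by the product of the two scores, and
seed subnetworks around chosen TFs are summarised by their outgoing-edge
fraction — the operational "master regulator" signal.

## Quality control

Five rules, applied in one fixed order with removal attributed to the FIRST
violated rule: ERCC fraction > 0.97, fraction of reads in genes < 0.80,
detected-gene fraction < 0.02, total reads < 500,000, detected genes < 7000.
Those absolute defaults assume a real transcriptome; the simulator carries
thresholds scaled to its own size (reads: 5x gene count; genes: a quarter of
the gene count) so that planted violations and healthy cells are cleanly
separable at desk scale.  Note that an ERCC-dominated well arithmetically
also fails the in-gene-fraction rule whenever total reads equal the column
sum (E/T > 0.97 forces G/T < 0.03); first-rule attribution keeps the report
unambiguous.  Spike-in rows are excluded from CPM (numerator and
denominator) and from detected-gene counts throughout: spike-ins calibrate
wells, they are not biology.

Gene filters: discard genes below 1 CPM in every sample, and genes whose
(CPM + 1) fold range across samples is below 2.  The pseudo-count avoids
dividing by zero for all-zero samples.

The variance-stabilising transform is a shifted log2, log2(CPM + 1) — a
deliberate closed-form stand-in for regularised-log normalisation.  It is
monotone in the input, so every rank-based downstream quantity (equal-
frequency MI, embeddings driven by relative distances, PAM on those
distances) is unaffected by the substitution; absolute low-count variances
are stabilised less aggressively than the regularised log would.

Batch correction is the parametric empirical-Bayes location/scale
adjustment: per gene, standardise against the batch-size-weighted grand mean
and pooled residual variance; estimate per-batch additive and multiplicative
effects; shrink them across genes (normal prior on locations, inverse-gamma
on scales, method-of-moments hyperparameters, estimates iterated to
convergence); remove; restore the grand mean and pooled scale.  Tests verify
agreement with an independent reference implementation to ~1e-3.  Two edges:
(1) shrinkage means a per-gene shift is removed *exactly* only in the
no-shrinkage limit — shifts large relative to within-batch noise, many genes
informing the prior; with comparable shift and noise scales, the posterior
deliberately leaves the sampling-noise share of the observed batch
difference in place.  (2) Genes with zero pooled within-batch variance pass
through unchanged (no standardisation is defined for them).

## Embedding and clustering

PCA is the SVD of the centred (optionally scaled) sample-by-gene matrix;
variance fractions are reported over all components so they sum to 1, which
is what "how many components absorb 90% of the variance" needs.  On the
default simulation the leading component absorbs ~2% of variance and ~185
components absorb 90% — high-dimensional, weakly structured data of the
same character as the real system (which shows ~2.5% and 195).

The t-SNE sweep runs every (perplexity, seed) combination (defaults:
perplexity 30, 5 seeds, 2000 iterations, exact gradient at theta = 0; a
positive theta switches to Barnes-Hut with that angle) and returns the run
with the lowest final Kullback-Leibler divergence, ties to the earlier
seed.  Inputs are first reduced to their 50 leading principal components,
the convention of the standard t-SNE tools; perplexity must stay below
(n_samples - 1)/3.

PAM is the classic BUILD + SWAP k-medoids: greedy seeding, then repeated
best single (medoid, non-medoid) exchanges until no exchange lowers the
total dissimilarity.  That stopping rule is a *local* optimum: on ~10% of
small unstructured random instances a strictly better medoid set exists two
swaps away, and the reference R implementation returns the identical local
optimum on such instances (verified on fixed examples).  On clustered data
— its intended regime — PAM reliably reaches the exhaustive-search optimum,
which the tests assert.  The default k is 2 (the two-population structure
the default simulation guarantees); k = 3 with the smallest cluster set
aside is the configuration for data with a detectable mitotic subset.

## Differential expression and enrichment

A transparent negative-binomial Wald test: median-of-ratios size factors
(with a positive-counts fallback when dropout leaves no gene fully
observed), per-gene method-of-moments dispersion floored at 1e-8, Wald
statistic on the log fold change with a delta-method variance
(1/mu + alpha)/n per group, and a t reference with n_A + n_B - 2 degrees of
freedom — the moment dispersion makes the normal reference anticonservative
at n = 20 per group, and the t reference restores ~5% type-I error
(measured 0.05-0.06 on null permutations).  Genes below a base-mean floor
(default 0.5) are excluded before testing and before the Benjamini-Hochberg
adjustment.  No dispersion or fold-change shrinkage is applied; the engine
trades the power refinements of the large packages for full
specifiability, and a test cross-checks that its gene ranking agrees with
the reference shrinkage-based NB implementation (Spearman rho > 0.8).
Significance defaults to adjusted p < 0.01.

Over-representation is the hypergeometric upper tail on (background, term
within background, hit list, overlap), BH-adjusted across terms, retained
at FDR < 0.05.  The directional z-score for a term with a genes up in
population A and b up in population B is (a - b)/sqrt(a + b), zero at
(0, 0); it is antisymmetric under swapping the populations.

## Network inference

Mutual information uses the plug-in estimator on equal-frequency bins
(default ceil(sqrt(n_samples)) bins), with ties broken by stable ordering —
this makes MI, and therefore the whole CLR score, invariant to any strictly
monotone transform of each gene.  Constant genes get MI 0 with a warning.
CLR: z_i(j) = max(0, (MI_ij - mean_i)/sd_i) over gene i's off-diagonal MI
background, combined as sqrt(z_i^2 + z_j^2); a zero-spread background
contributes z = 0.

Tree importances: per target, a random forest of regression trees fit on
all other regulators (default 1000 trees, sqrt(p) candidate features per
split, fully grown), importance = the regulator's normalised share of total
variance reduction.  Regulators are sorted internally and each target draws
its seed from (master seed, target name), so gene order cannot change
results.  The recovery benchmarks run 200 trees per target: at 59
regulators the importance ranking is stable well below the 1000-tree
default (benchmark AUPR ratio 3.8 vs 3.9 at 1000 trees, identical
directionality), at a fifth of the cost.

Combination: CLR edges are mirrored into both directions with identical
score; a directed edge survives iff its CLR score AND its tree importance
are strictly positive; survivors are ranked by the score product, ties
broken lexicographically by (source, target).  Seed subnetworks retain each
seed's top-N (default 100) incident edges by rank (an absolute
combined-score threshold is also available); the outgoing fraction among a
seed's retained edges — optionally its top-k strongest — is the
directionality statistic.

A structural property worth stating plainly: because CLR is symmetric and
fully-grown forest importances are strictly positive in practice, both
directions of every surviving pair co-survive the intersection.  A seed's
outgoing fraction can therefore differ from exactly 0.5 only where the
top-N truncation (or a score threshold) actually bites.  With 60 TFs a seed
has at most 118 incident directed edges, so at top-N = 100 the statistic is
nearly pinned to 0.5; among the 50 strongest edges the truncation is sharp
and the planted hub shows 56-62% outgoing against the sink's 46-50%.  In
systems with many hundreds of TFs the top-100 cut is severe and the
fraction becomes informative at that depth too.

## The synthetic generators

Single-cell: per-gene base expression is log-normal (background
log-mean log 10, log-sd 1.6 — a skewed, realistic expression distribution;
program genes log 60, log-sd 0.5 so programs sit in the detectable range).
Two populations (defaults 146 and 62 cells) each express a 250-gene marker
program 8-fold higher than the other population; a 24-cell mitotic subset
additionally overexpresses a 30-gene proliferation program 6-fold on top of
a randomly inherited parent program.  Cells carry log-normal library-size
variation (log-sd 0.4), two culture batches differ by a 0.4 natural-log
additive offset on all gene means, counts are Poisson around a log-normal
noise layer (log-sd 0.3, giving overdispersion), ERCC spike-ins are
Dirichlet-proportioned rows at ~5% of reads scaling with depth, and dropout
zeros are Bernoulli at rate 0.3 *independent of expression level* — a
deliberate simplification.  Planted QC violators cycle through three
classes (spike-in-swamped wells, low-depth cells, few-gene cells), each
violating its class's rule while passing the ones ordered before it.

What passing tests show — and don't: uniform dropout at high expression is
*harsher* than real Smart-seq2 dropout (which concentrates at low
expression), so distances carry a large isotropic noise floor; the marker
programs are sized so the population split clears that floor the way the
real populations separate on t-SNE (leading-PC variance fraction ~2%,
matching the real scale).  The mitotic subset is detectable by its DE/
enrichment signature but is *not* guaranteed to form its own embedding
island at these noise conditions — its cells sit with their parent
populations — so the default clustering is k = 2.  No UMI structure,
isoforms, or gene-level parameter matching to the real accessions is
attempted.

Bulk/GRN: a linear-Gaussian structural model evaluated in topological order
over a randomly generated DAG of 60 TFs.  The hub sits at the top of a
cascade — its 20 targets are the immediately-downstream ranks, so its
influence propagates through the Poisson(1.5)-out-degree background edges
to most of the network (the master-regulator structure).  A terminal sink
TF (in-degree >= 3, out-degree 0) is planted as the directional foil.  Edge
weights are uniform in magnitude on (0.4, 1.0) with random sign (chosen so
chain variance neither explodes nor dies); root TFs carry stage-specific
intercepts (sd 2.0) over 4 stages, 24 samples assigned round-robin; every
TF adds Gaussian noise (sd 0.3).  In the noise-free limit every non-root is
an exact affine function of its parents, which the tests exploit.

NB fixture generator: gamma-Poisson (negative binomial) two-group counts
with planted fold changes, used by the DE calibration and power analyses.

## Problem sizes and runtimes

Benchmarks run at: QC fixture 60 cells; clustering recovery 150 cells x
2000 genes, 5 embedding seeds (~30 s); DE calibration 200 genes x 40
samples, 5 permutation draws, power 50 planted genes (~15 s); network
recovery 60 TFs x 24 samples, 5 simulation seeds, 200 trees per target
(~45 s).  The full synthetic demo (`epinet all`) completes in about a
minute on one CPU.

## Reproducibility

Every stochastic component takes an explicit seed; per-target tree seeds
derive from (master seed, target name) via a stable hash.  Identical
configs and seeds reproduce byte-identical TSV outputs; provenance sidecars
(JSON: version, config hash, seed, timestamp) accompany each stage's
primary output without touching the data files.
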