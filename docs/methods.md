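# Methods

This note documents the models behind each stage, the defaults and why
they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions that matter for reproducing
results. Nothing here states an empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Quality control and normalization

A cell passes QC iff `total_reads >= min_reads` (default 10,000) **and**
`mito_ratio <= max_mito` (default 0.2). Both comparisons are strict on
the failing side: a cell with exactly 10,000 reads or a ratio of exactly
0.2 is retained. The filter is idempotent by construction.

Expression statistics use counts-per-10,000 per cell, log1p-transformed.
The per-cell scheme is not prescribed by the workflow this package
follows, so the most common droplet convention was adopted; size-factor
normalization (total / median total) is used instead wherever a count
model needs an offset (dynamic-gene testing, profile clustering).

Variable genes: per-gene dispersion = log(variance/mean) of normalized
counts, z-scored within 20 equal-frequency mean bins (fewer bins for
tiny matrices, so a 2-gene toy still ranks by dispersion), ranked
descending with lexicographic gene-id tie-breaks. Default n = 1,500.

## Embedding and clustering

Scaled (per-gene z-scored, clipped at ±10) log-normalized HVG expression
is reduced with exact-SVD PCA (default 25 components). The 2-D embedding
is pluggable: UMAP (n_neighbors = 50, min_dist = 0.1, fixed seed) by
default, or the first two PCs (`method="pca"`) when byte-level
determinism matters more than manifold structure — the test suite and
the acceptance pipeline use the PCA backend for that reason.

Clustering builds a k-nearest-neighbor graph (k = 15, a conventional
default; the source workflow clusters on 2-D coordinates without
stating k) and optimizes modularity with the Leiden algorithm
(RBConfiguration partition, seeded) at resolution presets 0.05 (coarse,
cell types) and 0.5 (fine, pseudo-bulk clusters). Leiden was chosen over
classic Louvain because the available Louvain implementation is not
seed-parameterized; the contract — modularity communities on the
embedding's kNN graph — is unchanged. Labels are relabelled 0..k−1 by
decreasing cluster size.

Cluster annotation computes, per (cluster, marker), the mean
log-normalized expression and detection fraction (the dot-plot
statistics); each cluster is assigned the cell type whose markers have
the highest mean across-cluster-standardized expression.

## Pseudotime

The backbone is deliberately simple and transparent rather than a port
of DDRTree's alternating optimization: k-means centroids (n ≈ cells/15,
capped at 30) in the PCA space, a Euclidean minimum spanning tree over
centroids, and orthogonal projection of every cell onto its nearest tree
edge. Pseudotime is the geodesic distance from a provisional root (an
end of the tree diameter) to the projected point, min-max normalized so
the output range is exactly [0, 1]. Branch states label the tree
segments between degree-≥3 nodes. What downstream stages consume — a
tree, two components, a normalized ordering — is exactly what this
provides.

Orientation: among the two ends, the root is chosen so the mean
expression of caller-supplied origin markers over the lowest-pseudotime
decile is minimal (the biological rule: the origin markers are lowest at
the leaf base). If both ends score equal within tolerance the
orientation is refused (`AmbiguousOrientationError`) rather than
guessed. Reversal maps p → 1 − p exactly.

## Dynamic-gene test

Genes with mean size-factor-normalized expression > 0.1 are tested.
Model: negative-binomial GLM of raw counts with log size-factor offset;
full model = intercept + natural cubic spline of pseudotime (df = 3,
boundary knots at the data range, interior knots at quantiles); null =
intercept. The dispersion is estimated per gene by moments from a
Poisson fit of the full model and held fixed in both NB fits, so the
likelihood-ratio statistic is chi-squared with df = 3 under the null
(the fixed-dispersion LRT convention of the bulk RNA-seq testing
literature). BH correction runs across successfully tested genes;
per-gene fit failures are flagged and excluded. The suite verifies
calibration (null false-positive fraction at q < 0.05 stays ≤ 0.07) and
power (2-fold monotone effects at 500 cells detected with ≥ 0.8 power).

"Dynamic" defaults to q < 0.01; the threshold is exposed because the
upstream workflow reports a DEG count without printing its cutoff.

Profile clusters: significant genes are summarized as binned means over
100 equal-width pseudotime bins (empty bins linearly interpolated),
z-scored, Ward-clustered on Euclidean distance, and cut into k = 6
clusters relabelled G1..G6 by the pseudotime of each cluster's mean
profile peak. Binned means were chosen over smoothers because they are
deterministic and oracle-checkable.

## Pseudo-bulk and coexpression

Each fine cluster becomes one sample: summed counts, RPM normalization
(rows sum to 1e6 before the log), log2(RPM + 1), and the mean member
pseudotime. Gene dispersion (variance/mean) for the top-75% filter is
computed on the pseudo-bulk samples — the object actually being
analyzed; a switch could compute it on cells instead.

The network is unsigned, a_ij = |Pearson r|^β. β = "auto" picks the
smallest β ∈ 1..20 whose connectivity distribution fits a power law with
R² ≥ 0.8 (negative slope), falling back to the conventional β = 6 with a
warning — on a handful of pseudo-bulk samples the scale-free fit rarely
succeeds, and the fallback is the expected path. TOM uses the standard
unsigned formula (see README); the implementation is matrix-product
based and is tested to 1e−10 against a triple-loop oracle. Modules come
from average-linkage clustering of 1 − TOM (default 6 modules — a
reporting convenience, not a tuned quantity). "Coexpression
connections" are pairs with TOM at or above the 0.95 quantile of
off-diagonal values; the quantile is exposed because the upstream
workflow never states an absolute threshold. With ~22 samples,
correlation p-values are deliberately not used.

## Linear-ODE network inference

Model: expression x(t) ≈ W z(t) with dz/dt = diag(b) z, hence
z(t) = exp(b t) columnwise, observed at the per-cell pseudotimes
(required to lie in [0, 1]). Per run: b ∈ R^z is initialized uniformly
in [−10, 2] and refined by 100 iterations of single-coordinate random
replacement, keeping a candidate iff the least-squares residual of
x ≈ W exp(b t) (W refit each time) improves. The regulatory matrix is
A = W diag(b) W⁺ (Moore–Penrose); the reported A is the elementwise
mean over 50 runs (defaults z = 4, n_runs = 50). Averaging is justified
empirically in the suite: across repetitions, 50-run averages have
far lower variance than single runs. Non-finite runs are discarded and
logged; the effective run count is reported.

Consensus cutoffs (0.1 exploratory, 0.5 condensed) apply to |mean A|;
absolute values are used because a signed threshold would silently drop
repressor edges. Hub ranking uses undirected degree over unique
partners, ties broken by summed |weight| then id.

TF-family enrichment: expected_f = |high| × n_f / N, so expected counts
sum to |high| per cell type by construction; the observed
(in-family, out-of-family) split is tested with a 1-df chi-squared,
with a Fisher-exact fallback when an expected cell is zero.
"Highly expressed" TF lists are caller-provided.

## Regulome integration

Coordinates: BED inputs are 0-based half-open; GFF3 (1-based closed) is
converted on read; the TSS of a minus-strand gene is its interval end − 1.
Coverage is a bedGraph step function, normalized to counts per million
of the track total for metagene profiles.

Metagene: TSS ± 1,500 bp in 100-bp bins (30 bins), minus-strand genes
reversed so bins run 5′→3′, genes averaged within groups; windows
exceeding chromosome bounds are skipped and logged.

Motif scanning: log2-odds against the PWM background, both strands
(minus strand via the reverse-complement matrix, offsets reported on the
forward coordinates), default threshold 80% of the maximum achievable
score. Degenerate consensus positions (the nn in AGAAnnTTCT) get uniform
columns; non-ACGT bases score zero (background odds). Enrichment is a
one-sided Fisher exact test on sequences-with-hit counts, foreground vs
background, BH-corrected across motifs.

Footprints: per-base coverage over ± w (default 100 bp) around each
motif span, minus-strand hits reversed, averaged over sites. Promoter
sequences are stored in genomic forward orientation, so hit offsets map
to genomic coordinates by simple addition — a deliberate simplification
that trades a small amount of biological realism for coordinate-algebra
transparency. The footprint window is a separate parameter from the
±1 kb promoter window used for network membership, because the source
analyses use different widths in the two roles (500 bp vs 1 kb).

Network rules: `chip_direct` = TF peak overlapping [TSS − 1 kb,
TSS + 1 kb); `PPI` = promoters joined by a chain of ≤ max_chain = 2
loops, where "consecutive" loops are formalized as anchors overlapping
by ≥ 1 bp (the chain walk enters one anchor of a loop and exits the
other; anchor-to-anchor hops between loops are free); `PDI` = TF peak
overlapping a dACR on a loop anchor whose partner anchor overlaps the
gene's promoter window; `predicted` = imported consensus edges. Every
edge stores the peak/dACR/loop ids that created it, and
`validate_provenance` re-checks each rule from the stored evidence.
All overlap predicates use ≥ 1 bp, since no overlap fraction is
prescribed anywhere upstream.

## Synthetic data: what it emulates, and what it does not

`simulate_grn` draws a signed TF×TF matrix: off-diagonal entries nonzero
independently with the requested density, magnitudes uniform in
[0.5, 1.5] (bounded away from zero so "edge" is well-defined), random
signs; diagonal entries are strictly negative self-degradation terms at
0.2× the interaction scale (`decay_scale`). The slow-decay choice
encodes the assumption that TF turnover is slow relative to regulatory
drive over the developmental window, so the observable dynamics are
dominated by the interactions being inferred. This matters for
identifiability: a rank-z latent fit can only learn the part of A
visible in the subspace the single trajectory excites, and when uniform
decay dominates, that subspace carries little edge information
regardless of inference quality.

`simulate_cells` integrates dz/dt = A_true·z from a fixed positive
initial state (trajectory shapes preserved by a global positive shift,
not clipping), adds template-driven target genes (logistic increasing /
decreasing, Gaussian transient, flat), two cell types by additive marker
offsets on disjoint panels (M-like majority, BS-like minority), a
mitochondrial block carrying ~5% of healthy reads, and planted
low-quality cells violating either QC threshold. Counts are
gamma-multinomial: gamma-perturbed propensities (dispersion 0.2,
a typical single-cell biological CV) distributed by a multinomial over
an exact log-normal library size (mean 44,805 reads — the depth reported
for the real experiment; the full depth distribution is not reported, so
the log-normal spread σ = 0.3 is a choice, not a calibration). Totals
therefore equal library sizes exactly. A `dynamics="logistic"` switch
replaces the ODE drive with nonlinear templates to probe robustness.

`simulate_genome_tracks` lays out non-overlapping genes with random
strands on one toy chromosome; MNase-hypersensitive peaks over
promoters; motif consensus instances planted at recorded offsets and
strands in half the promoters; coverage elevated 10× inside peaks and
multiplied by (1 − footprint_depth) inside planted motifs; and disjoint
single-loop PPI pairs, PDI configurations (TF peak on a dACR looped to
a promoter), decoy dACRs and direct promoter ChIP peaks, all recorded
as truth so the network construction can be scored by set equality.

What the generator does **not** emulate: ambient RNA, doublets, batch
effects, zero-inflation beyond NB, branching fates, genuine sequence
composition biases, overlapping regulatory elements, or loops longer
than the planted configurations. Passing tests therefore demonstrate
correctness of the algorithms under the stated statistical model, not
robustness to every artifact of real droplet data.

## Problem sizes and determinism

The suite and the acceptance script run deliberately scaled-down but
structurally faithful problems — 500-cell QC/pseudotime checks, 1,000
null genes for calibration, 20 TFs × 300 cells × 50 runs × 5 seeds for
network recovery, a 30-gene toy chromosome — sizes at which every
quantity is recomputable from scratch in seconds on one CPU. All
randomness flows from explicit seeds through `numpy.random.default_rng`
(per-run child seeds via `SeedSequence.spawn`), file writers use fixed
float formats, and the pipeline manifest records SHA-256 digests, so two
runs with the same config are byte-identical; the deterministic PCA
embedding backend is used wherever that guarantee is asserted.

## Known limitations

- The pseudotime backbone handles a single main path well; multi-branch
  topologies get branch labels but no fate analysis.
- The ODE inference's AUROC ceiling is structural (single trajectory,
  rank-4 latent space), not statistical: more cells do not help once the
  excited subspace is saturated, and count-level noise at realistic
  dispersion lowers recovery substantially — which is why the recovery
  surface is the latent expression, and why run averaging is essential.
- With ~22 pseudo-bulk samples, the scale-free criterion for β rarely
  holds; the β = 6 fallback is the expected path, and module structure
  on so few samples is indicative rather than robust.
- The chi-squared enrichment uses the 1-df observed-vs-expected form;
  for very small families the Fisher fallback changes the null model
  slightly (conditioning on margins).
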