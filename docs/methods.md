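# Methods

`screg` implements a single-cell chromatin accessibility (scATAC-seq)
analysis workflow for datasets that mix ATAC-only and joint ATAC+RNA
(multiome) nuclei: quality control, iterative latent semantic indexing
(LSI), split-and-pool consensus peak calling, Pearson-residual marker
statistics, anchor-net RNA imputation, distance-penalized covariance
linking of regulatory regions to genes (cCREs), and a sequence-based
convolutional enhancer classifier with per-nucleotide attribution.  This
note records the models, the parameters that matter, and the places where
the design was genuinely open.

Coordinates are 0-based half-open (BED) throughout; intervals sharing only
a boundary base do not overlap.  Both ends of every fragment are treated
as independent Tn5 insertion events.

## Quality control

**TSS enrichment.**  For every nucleus the insertion density inside a
50-bp window centred on the nearest transcription start site is divided by
the density in the outermost 100 bp of the ±1,000-bp flanks.  The
per-sample score is the depth-weighted mean over nuclei; samples scoring
below 5 are flagged for discard.  When the flank density is zero the score
is capped at 100.  The per-nucleus *TSS fraction* used for filtering is
the fraction of fragments with an end within ±1 kb of a TSS.

**Filtering.**  A nucleus passes when it is not a doublet, has more than
5,000 and fewer than 100,000 fragments, and more than 20% TSS fragments;
multiome nuclei additionally need more than 1,000 RNA UMIs and at least
10% unspliced UMIs (boundary inclusive).  The filter is monotone: improving
any one metric can never flip a pass into a fail.

**Doublets.**  Artificial doublets — summed counts of random nucleus
pairs, numbering 20% of the real nuclei — are co-embedded with the data by
TF-IDF + LSI on the 5-kb bin matrix; each nucleus's doublet score is the
fraction of artificial profiles among its k = 10 nearest neighbours.
Because the thresholding rule of the original detector is not fully
specified, the call threshold is calibrated so the called fraction equals
a user-set expected rate (default 5%).  Homotypic doublets (two parents
from the same cluster, with an independent depth draw) are close to
undetectable by construction; the detector's practical ceiling on data
with many clusters is therefore well below AUROC 1.

**Sex inference** uses only the Y-chromosome fragment fraction (male when
strictly above 0.05%); a TSS-fraction-based disambiguation step is
deliberately not implemented because no rule for it is available.

## Latent semantic indexing

TF-IDF weights are `(count_ij / depth_i) * log(1 + n / df_j)`; the
`log(1 + ·)` dialect gives ubiquitous features a small non-zero weight.
Forty components are computed by randomized truncated SVD (seeded).  Two
filters then run in order of component index:

- a component whose scores have |Spearman correlation| > 0.7 with log
  depth is dropped (it encodes sequencing depth, not biology);
- from the second component on, a two-sample Kolmogorov–Smirnov test
  compares the raw score distribution with the previous retained
  component; if p > 0.05 the spectrum is judged to have hit its noise
  floor and this and all later components are dropped.

The KS comparison uses *raw* (uncentred, unscaled) scores: the signal that
distinguishes informative components is precisely their scale and shape,
and standardizing first makes every pair look alike.  Both thresholds
(0.7; 0.05) are exposed as arguments.  The KS test is a stand-in — the
statistical test behind the successive-component rule in the original
pipeline is unnamed — and it is conservative: a long, smoothly decaying
spectrum will be truncated once adjacent components become statistically
indistinguishable at the sample size at hand.

**Iterative LSI.**  Round 1 embeds the 20,000 top-coverage autosomal
features and preclusters the nuclei (kNN + Louvain).  Round 2 re-selects
the 20,000 features with the highest across-precluster variance of
Pearson residuals and re-embeds.  Sex-chromosome features are never
selected in round 1.

**Batch correction** equalizes per-component batch means within soft
clusters: responsibilities from a seeded soft k-means (k = 8 by default)
weight a per-cluster shift of every batch centroid onto the cluster
centroid, iterated five times.  When batch distributions are identical the
shift is exactly zero.  An external corrector can be plugged in through
the `corrector` callable; the published batch-correction algorithm itself
is out of scope.

## Peaks

**Preclustering** uses 20-kb genomic bins as temporary features: the top
20% of autosomal bins by coverage, excluding bins detected in more than
60% of nuclei (on deeply covered miniature genomes this ceiling can
exclude everything; it is then ignored with a warning), then TF-IDF + LSI
+ kNN (k = 25) + Louvain.

**Split-and-pool calling.**  Each precluster's nuclei are randomly halved
into two pseudobulk replicates, capped at 25 million fragments by uniform
downsampling.  The caller mirrors the printed fixed-parameter settings at
desk scale: every insertion event is placed at `position − 100` and
extended 200 bp; the per-base pileup is tested against a single global
Poisson rate λ = total extended coverage / genome size; per-base upper-tail
p-values are Benjamini–Hochberg adjusted over all genome bases (computed
exactly on the pileup-level histogram) and bases with q < 0.05 are merged
into peaks across gaps of up to 30 bp.  Local-λ refinement as in full
peak callers is intentionally absent.  Summits are the leftmost pileup
argmax.

Replicate-1 peaks are fixed at 400 bp around their summit (extension
first, then the overlap test) and kept only when they overlap any
replicate-2 peak by at least one base.  Pooled cluster peaks are grouped
into connected components of pairwise overlap; each group becomes one
consensus peak of exactly 400 bp centred on the floor-midpoint of the
group's merged span.  Consensus peaks overlapping the blacklist are
removed, and peaks that would extend past a chromosome edge are discarded
rather than truncated, so every emitted peak is exactly 400 bp.

**Annotation:** a peak is a promoter peak when its centre lies within
2 kb of a TSS, else distal; the genic label follows the precedence
exon > intron > intergenic on any overlap.

## Clusters and markers

Nuclei are clustered by Louvain modularity on a symmetrized Euclidean
kNN graph (an edge joins two nuclei when either is among the other's k
nearest).  Enrichment of cluster-aggregated counts is the analytic
Pearson residual under a negative binomial null with dispersion fixed at
θ = 100:

    Z_cg = (X_cg − μ̂_cg) / sqrt(μ̂_cg − μ̂_cg² / θ),   μ̂_cg = c_tot(c) · g_frac(g)

where `c_tot` is the cluster's fragment total and `g_frac` the feature's
overall fragment fraction.  The variance term is implemented with the
minus sign as printed; entries where μ̂ ≥ θ make that variance
non-positive and are set to 0, and all residuals are clamped to |Z| ≤ 30.
A `variance_form="plus"` switch provides the conventional negative
binomial variance μ̂ + μ̂²/θ.  Marker peaks are the top 2,000 features per
cluster by Z (ties break to the earlier coordinate); the cluster
dendrogram uses the 20,000 most variable residual features with
correlation distance and average linkage (both unstated upstream and
configurable here).

## RNA imputation and trinarization

Multiome expression profiles are scaled to 5,000 UMIs.  Every nucleus is
joined to its 10 nearest multiome nuclei in the shared embedding; weights
are inverse distance (ε = 1e-12 guard) normalized to sum to 1, and the
imputed profile is the weighted mean of the scaled neighbour profiles.
Multiome nuclei keep exactly their own scaled profile, so imputation is
idempotent on them.  The inverse-distance kernel is a package choice —
only the normalization is specified upstream.

Trinarization — the posterior probability that a cluster truly expresses
a gene — uses a Beta posterior: with f of n nuclei expressing
(count > 0), the expressing fraction has a Beta(f + 1.5, n − f + 2)
posterior, and the score is P(fraction > f0) with f0 = 0.2.  The exact
prior constants of the originally cited procedure are not restated in the
source; these defaults reproduce the cited family's saturating behaviour
and are fully configurable.

## Co-accessibility and cCREs

Region–region and region–gene covariance is estimated in 500-kb windows
with 250-kb overlap by a graphical lasso with a per-entry penalty that
grows exponentially with genomic distance, `penalty_ij = λ exp(d_ij/d0)`.
The solver is a block coordinate descent over columns with an
elementwise-penalized lasso inner loop (verified against scikit-learn's
GraphicalLasso at uniform penalty).  The co-accessibility score of a pair
is the regularized covariance rescaled to a correlation.  Accessibility
enters as depth-normalized log1p counts; expression vectors for cCREs are
5,000-UMI-scaled log1p values placed at their gene's TSS.

**Choosing d0 and λ.**  Both are selected jointly by held-out likelihood:
for 100 random 500-kb windows, the penalized estimate is fitted on a
random half of the nuclei and scored by the Gaussian log-likelihood of
the held-out half; the (d0, λ) grid point with the best mean held-out fit
wins.  A d0 too small over-penalizes genuine short-range links, one too
large lets long-range noise overfit, so the criterion has an interior
optimum at the distance scale where links actually live.  (A penalized
in-sample objective degenerates to preferring the sparsest model, and a
sparsity-targeted λ calibration is retained as a helper but is not used
for selection.)

**Window consistency.**  Pairs estimated in two overlapping windows are
kept only when both estimates agree in sign and differ by less than
2-fold in magnitude (scores then averaged); otherwise the pair is
discarded.  This quantifies the idea of discarding "inconsistent"
double-sampled pairs.

**Cutoff.**  Connected components of the thresholded link graph (over the
fixed node set, so the count is non-decreasing in the threshold) are
counted over a log-spaced threshold grid.  In a two-regime link set the
curve rises steeply while noise edges fall away, plateaus across the
score gap, then rises again as true links break; the cutoff is the start
of the longest flat stretch after at least half of the total rise.

**Gene activity** is the accessibility matrix times the non-negative
region→TSS link-score matrix, normalized by size factors from a global
OLS fit of log1p(total activity) on log(depth) (geometric-mean centred),
then smoothed by averaging each nucleus with its 25 nearest embedding
neighbours.  Per-sample size-factor fits would also be defensible; the
global fit is the simpler default.

In fixtures with cluster structure, genes linked to one region also
correlate with every co-accessible region of the same cluster; cCRE
evaluation therefore uses recall at a fixed false-positive rate rather
than top-k precision.

## Enhancer sequence model

Training examples are 401-bp one-hot windows (centre − 200 … centre +
200, inclusive) around consensus peaks whose top supercluster CPM exceeds
the second-highest by log2 fold change > 1; the class is the argmax
supercluster.  Peaks whose window leaves the chromosome are skipped and
counted.

The classifier follows the printed stack: four convolutional layers of
256, 60, 60, 120 filters with kernels 7, 3, 5, 3, each followed by batch
normalization, ReLU and max pooling; two dense layers of 256 units with
batch normalization, ReLU and dropout 0.4; softmax head; label-smoothed
(0.1) cross-entropy; Adam at learning rate 0.01; 26 epochs; batch 256.
Pooling sizes/strides and 'same' padding are unstated upstream and are
configuration here (default 2/2 per layer, which keeps the flattened
dimension positive for 401-bp input).  All layers are implemented
directly in numpy (im2col convolutions, hand-written backward passes,
float32 parameters); gradients are verified against finite differences in
the test suite.

`desk_spec()` is the reduced configuration used for single-CPU
experiments: filters (64, 32, 32, 64), one dense layer of 64, poolings
(2, 2, 5, 10), learning rate 0.005, batch 64, ≤ 16 epochs.  The large
terminal poolings make the flattened representation nearly translation
invariant, which matters far more than capacity when the training set is
a few thousand examples; with the printed 2/2 poolings and a flatten into
wide dense layers, small training sets are memorized positionally and
validation AUC stalls.

**Attribution** is expected gradients: for each of n_background
mononucleotide-preserving shuffles of the input, the gradient of the
class logit is averaged along the straight path from the shuffle to the
input (midpoint rule) and multiplied by (input − shuffle); backgrounds
are averaged.  For this piecewise-linear network the completeness
identity Σ(attributions) = logit(x) − mean logit(backgrounds) holds up to
path discretization; 32 steps give ≈ 2–4% relative error and 128 steps
< 1%.  The per-position attribution is projected onto all four bases
(background-corrected) as the hypothetical score; the actual track is the
hypothetical score masked to the observed base.  Shuffles preserve
mononucleotide (not dinucleotide) composition.

**Saturation mutagenesis** re-scores every single-base substitution
(batched forward passes); reference-base deltas are exactly zero by
definition.

**Seqlets.**  15-bp windows whose summed |attribution| exceeds the mean +
2 s.d. of a per-track position-shuffled null are extracted greedily
without overlap and extended by 5-bp flanks.  Clustering is greedy: the
highest-scoring unassigned seqlet seeds a cluster, and a candidate joins
when the normalized cross-correlation of the high-signal 9-column cores
of their hypothetical scores reaches 0.8 in either orientation within ±4
columns of alignment.  Comparing cores instead of the full 25-column
matrices keeps background flanks from diluting the correlation.  Clusters
below 30 seqlets (test fixtures use a lower floor) are dropped; members'
actual-score matrices are averaged core-aligned into a contribution
weight matrix.  This is a deliberate simplification of the published
seqlet-clustering tool; its fidelity target is planted-motif recovery,
not parity.

## Differential accessibility and trends

Per (sample, class) fragment pools are run through the same peak caller
to give accessible-region counts.  Differential regions use one-sided
(greater) Fisher exact tests on (in-region, out-of-region) count pairs
with BH correction; zero-margin tables give p = 1.  The age trend is
ordinary least squares of region count on age (post-conception weeks) with
t = coefficient / s.e. and two-sided p from the t distribution — the
"generalized linear model" is realized as Gaussian-identity OLS, matching
the printed t/d.f. reporting.  Bonferroni thresholds are α/m (0.05 over
135 × 11 tests gives 3.37e-5).

## Synthetic data: what it does and does not emulate

The generator draws i.i.d. genomes at a target GC fraction, carves
non-overlapping 400-bp enhancer regions on a jittered grid, and plants
per-class consensus motifs (1–3 copies per region, each exact or with one
mismatch).  Fragments are simulated per nucleus with log-normal depth
(σ = 0.45 around the requested mean), a 50% in-region signal fraction
directed at the nucleus's own cluster regions, multiplicative log-normal
per-batch jitter (σ = 0.3) on region weights, and uniform background
elsewhere; doublets are unions of two parents' draws under an independent
depth draw.  Multiome RNA gives linked genes Poisson rates increasing
linearly in their region's per-nucleus accessibility, with gene TSS
placed within ±100 kb of the linked region; row totals are log-normal
around 4,000 UMIs with a Beta(5, 15) unspliced fraction.

Defaults reflect the intended regime (depth in the hundreds-to-thousands,
3–5 clusters, 10% doublets where doublets are tested, 30–40% multiome
nuclei), scaled to genomes of a few hundred kilobases so the full
pipeline runs in minutes on one CPU; the methods' parameters (400-bp
peaks, θ = 100, k = 10 anchors, 20% spike-in, 401-bp windows) are never
scaled.  Not emulated: fragment-length periodicity, chromatin contact
structure, sequencing error, per-cell GC effects.  Passing tests
demonstrate algorithmic correctness against planted truth at these
scales, not performance on real tissue atlases.

## Known limitations

- The simplified Poisson peak caller has no local background model; on
  real data it would over-call in high-signal domains relative to MACS2.
- The successive-KS component filter is conservative on smooth spectra.
- The doublet detector's score saturates at the homotypic ceiling.
- The windowed graphical lasso is O(p³)-ish per window in pure Python;
  windows with many hundreds of peaks (dense real data) would need a
  compiled solver.
- Seqlet discovery is greedy; it reports dominant motifs reliably but
  makes no attempt at the published tool's full decomposition.
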