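# Methods

This note documents the model behind `forkswitch`, the numerical and
design choices made where the procedure was genuinely open, the synthetic
benchmark conditions, and the limitations of both.

## The correlation score and the greedy search

A bicluster is a pair (gene set *G*, sample subset *S*) scored by the mean
absolute pairwise Pearson correlation of the genes in *G* computed across
the samples in *S* only. The absolute value is essential: the target
structure is a *switch*, two gene groups with positive correlation within
each group and negative correlation between them, and |r| treats both
orientations as signal. The score is bounded in [0, 1], invariant to gene
and sample order, and invariant to affine rescaling of individual genes.

`find_seed` performs a pure greedy walk over m-sample subsets: start from
a uniformly random subset, propose replacing one uniformly chosen member
with one uniformly chosen outsider, accept only on a strict score
increase. There is no temperature or annealing; exploration comes from
independent restarts. Consequences that the tests rely on:

* the score trajectory is non-decreasing by construction;
* a run is a pure function of the data, gene set, m and its RNG seed;
* on small instances (≤ 12 samples) the best of 20 restarts attains the
  exhaustively enumerated global optimum.

Defaults: m = 10 samples, 1000 iterations per run. Small sample seeds keep
the search sharp — with m = 10 a pure-noise gene pair still shows
E|r| ≈ 0.27, so absolute score values are informative only relative to
that baseline, and scores of runs with different m are not comparable.
Zero-variance genes over a candidate subset are dropped from that
evaluation (logged once per run); an explicit `correlation_score` call on
such a gene raises instead, because a user-supplied gene set with a
constant gene is an input error, not a sampling accident.

Per-run RNG seeds in an ensemble are `base_seed + run_index`, recorded on
each run, so any single run can be reproduced in isolation.

## Ensemble consolidation

Runs are compared through correlation vectors (below): the distance
between two runs is 1 − |r| of their CVs, so a run that found the same
switch with flipped orientation is distance ~0. Average-linkage
hierarchical clustering is cut at the k in 2..k_max (default 10) with the
highest mean silhouette width; if even the best silhouette is below 0.25
the ensemble is declared a single bicluster. The silhouette gate value is
a package default — conventional for "no real cluster structure" — and is
configurable. Each cluster is represented by its highest-scoring run.

After consolidation the representative's gene set is refined: genes in the
bottom decile of mean |r| to the rest of the set over the seed samples are
dropped (configurable fraction, default 0.1), then the set is split into
its two anticorrelated groups by the sign of each gene's loading on the
leading eigenvector of the gene–gene correlation matrix over the seed
samples. If every gene is mutually positively correlated the split is
degenerate; the bicluster is reported with a single group and a warning.

## Correlation-vector extension and the two-pass pipeline

The correlation vector extends a bicluster to all genes: CV(g) is the
Pearson correlation of gene g with the reference profile — the per-sample
mean expression of a coherent core of *representative genes* — over the
context samples. Representative genes are chosen inside the larger split
group by average-linkage clustering of 1 − r distances: the largest
cluster whose internal mean pairwise r reaches the coherence threshold
(default 0.7), pruned of members whose own mean correlation to the cluster
falls below half the threshold, with a minimum size of 4 genes or 5% of
the group. When nothing qualifies the whole larger group serves as
reference (warning); with a few hundred coherent genes in the group the
mean profile is a good factor estimate even then.

Context samples for the CV are the top-ranked max(2m, 10% of the cohort)
samples after `sample_sort`, not the m seed samples alone: correlations
over 10 samples are too noisy to rank 20 000 genes, and the top-ranked
context stays inside the bicluster's regime while multiplying the sample
size.

`sample_sort` ranks the whole cohort by greedy accretion: repeatedly
append the outside sample whose inclusion maximizes the score of the
bicluster genes over the augmented set. Seed members rank first, ordered
by leave-one-out score contribution; accretion ties break by input sample
order. Two engineering choices keep this O(N²)-evaluation procedure
tractable at cohort scale, both documented parameters:

* the sort uses at most `max_sort_genes` (default 80) genes — the most
  coherent ones over the seed samples — since ranking quality saturates
  well below the full gene set while cost grows quadratically;
* scores along the accretion are maintained with incremental sufficient
  statistics (per-gene sums and the gene-pair product matrix), so each
  step is one vectorized pass over the remaining candidates; callers that
  need only the head of the ranking can truncate accretion after
  `n_accrete` steps, with the tail ordered by last augmented score.

The discovery pipeline runs the extension twice. Pass 1 ranks samples with
the core (refined seed) gene set just far enough to select the CV context,
computes the CV, and extends the gene groups to every gene with
|CV| ≥ `cv_gene_threshold` (default 0.6), split by CV sign. Pass 2 re-runs
the full ranking and CV with those extended groups, which now carry the
switch's full signal. The final reported gene groups are the CV-extended
groups: the switch's dominant genes are deliberately not limited to the
seed set, since high-|CV| genes beyond the seed belong to the same
regulatory pattern. A candidate whose extension finds no genes beyond the
threshold on one side is flagged spurious, keeps its core groups, and
sorts after genuine switches in the result list; genuine results are
ordered by extended gene count (largest coregulation structure first).

## PC1, forkscale and fork membership

PC1 summarizes the switch geometry per sample: take the n_top_genes
(default 500) genes with the largest |CV|, balanced between CV signs when
possible; z-score them over all samples; fit the first principal component
(by SVD, deterministic) on the top `top_fraction` (default 0.3) ranked
samples; project every sample. Two normalizations fix the two free
choices:

* *sign*: samples whose representative-gene mean expression is above the
  cohort median must project positively, so the upper fork is always the
  one expressing the reference profile;
* *origin*: the cohort median projection is subtracted, anchoring the
  non-switch bulk at PC1 ≈ 0 even when the fit set is dominated by one
  fork. Without this, an asymmetric fit set shifts the background off
  zero and a small forkscale threshold mislabels hundreds of background
  samples.

The forkscale divides non-negative PC1 values by the maximum and negative
values by |minimum|, mapping the fork tips to exactly +1 and −1. A sample
joins the upper fork when forkscale ≥ 0.04 and the lower fork when
≤ −0.04 (boundaries inclusive). The 0.04 default is deliberately
permissive: with tips normalized to ±1 and the background anchored at 0,
it corresponds to a few background standard deviations in typical
geometries. The threshold applies to the forkscale of all samples — the
switch position of every cohort member is reported, not only the
top-ranked ones.

## Switch topology

Fork sample sets are compared across biclusters with UpSet semantics
(exclusive intersection counts, which sum to the union of all fork
samples) and pairwise Jaccard indices. Cross-bicluster fork pairs with
Jaccard ≥ `merge_jaccard` (default 0.5, inclusive) are merged into shared
states by union-find; biclusters linked through a shared state are
classified multistate, the rest bistate. The 0.5 default quantifies "near
complete overlap" conservatively and is configurable; classification is
symmetric in bicluster order by construction.

## Enrichment and single-sample scoring

CV tails (top/bottom `tail_size` genes, ties broken lexicographically by
gene id) are tested against annotation sets with the exact hypergeometric
upper tail P[X ≥ k] and fold enrichment (k/n)/(K/N); the universe defaults
to all genes in the matrix. Benjamini–Hochberg correction is applied per
batch (one CV × one collection). Pathway CV profiles report members ranked
by CV and the dominance (mean member CV); pathways mapping fewer than 3
genes are skipped.

The single-sample switch score z-scores every gene across samples and
takes delta = mean z over the UF tail genes − mean z over the LF tail
genes. The null resamples `n_perm` random disjoint gene-set pairs of the
same sizes; the permutation p uses the add-one rule (exceedances+1)/(n_perm+1),
so p is never zero and is calibrated for null samples. Assignment: UF if
delta > 0 and p ≤ 0.05, LF if delta < 0 and p ≤ 0.05, else unassigned.
This score is self-contained and exactly testable; it reproduces the
contract of established single-sample gene-set scoring (rank samples on a
signature with a significance volcano) without external machinery.

## Synthetic benchmark conditions

The generator plants switch modules in i.i.d. Normal(0, σ²) background:
each module sample carries a latent factor f — |Normal(0,1)| for UF
samples, −|Normal(0,1)| for LF, zero elsewhere — and each module gene
gains +a·f (positive group) or −a·f (negative group). Half-normal
magnitudes put the strongest samples at the fork tips, reproducing the
tipped-fork PC1 geometry of real switches. Two same-group genes then
correlate at a²/(a²+σ²) across module samples (the shared term a·f against
independent noise), an analytic oracle the tests check empirically.

The reference design is 2000 genes × 500 samples, one module with 100+100
anticorrelated genes and 60+60 fork samples, effect a = 2, noise σ = 1
(within-group r → 0.8), with gene and sample positions scattered
uniformly. The benchmark pipeline configuration is unbiased discovery:
two random 500-gene seed sets, two greedy restarts each, 1000 iterations,
m = 10. Topology benchmarks use two-module designs (1200 × 300, 60-gene
groups, 40-sample forks) that either share their LF sample set (tripolar,
multistate) or are fully disjoint (two bistate switches), searched from
each module's own gene set as an explicit seed — the defined-gene-set mode
of the pipeline. These sizes keep the full benchmark suite within minutes
on a single CPU while leaving the per-module signal identical to the
reference design.

What the generator does *not* emulate: platform-specific noise,
batch/array effects, probe structure, correlated background blocks
(available behind a flag but off by default), or the partially overlapping
annotation structure of real gene-set catalogues. Passing benchmarks
therefore demonstrate the machinery — search, extension, geometry,
topology, statistics — under a faithful abstraction of the switch
structure, not robustness to every artifact of real cohorts.

## Numerical details and edge cases

* Variances below 1e-12 count as zero; such genes are dropped from search
  scoring, get CV = 0 (logged), and are excluded from splits.
* Eigenvector and SVD signs are canonicalized (largest-magnitude loading
  positive; fork sign convention above), so outputs are bit-reproducible.
* All-zero PC1 is a degenerate-geometry error; one-sided PC1 (a cohort
  with only one fork populated) warns and reports the populated side.
* Accretion and tail ties break by input sample order; CV-tail ties break
  by gene id.
* In the shared-LF multistate regime the CV extension deliberately admits
  genes of a sibling module that are genuinely correlated through the
  shared fork; the merged topology then reports the shared state. The
  per-module gene identity is preserved in the core gene sets.

## Known limitations

* The greedy search with random seed gene sets needs the planted module to
  occupy a non-negligible fraction of the seed set (~10% in the reference
  design). Much rarer modules require anchor or explicit (hypothesis)
  seed gene sets, which is how the method is used in practice.
* Run scores are weakly informative about which restart found signal when
  m is small; consolidation relies on CV clustering plus the post-hoc
  spurious-candidate flag rather than on score alone.
* `sample_sort` truncation and the sort-gene cap trade exactness of the
  full accretion definition for cohort-scale tractability; both are
  parameters, and the exact procedure is recovered by setting
  `max_sort_genes=None` and `n_accrete=None`.
* The pipeline assumes log-scale, normalized input and performs no
  preprocessing, probe collapsing or batch correction.
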