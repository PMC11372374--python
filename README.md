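# forkswitch

Discovery and analysis of large **anticorrelated gene-expression switches**
in bulk transcriptome datasets.

Heterogeneous tumor cohorts (and other large expression datasets) contain
subsets of samples in which hundreds of genes are tightly coregulated — and
typically split into two gene groups with strong positive correlation
inside each group and negative correlation between them. Such a *bicluster*
behaves like a toggle switch: each sample expresses one gene group or the
other. `forkswitch` finds these biclusters by stochastic greedy search,
extends them to the whole transcriptome and cohort, quantifies each
sample's switch position, classifies multi-bicluster topologies (bistate
vs. multistate switches), and annotates the switch gene sets with pathway
enrichment and single-sample scores. It is aimed at computational
biologists studying large-scale coregulation — for example of metabolic
and mitochondrial programs across cancer subtypes.

## The method

**Correlation score.** For a gene set *G* and sample subset *S*, the score
is the mean absolute pairwise Pearson correlation

&nbsp;&nbsp;&nbsp;&nbsp;score(G, S) = mean over gene pairs (g, h) of | r(x_g, x_h) | across S,

which lies in [0, 1]. Using |r| means a perfectly anticorrelated gene pair
counts as much as a perfectly correlated one — exactly the structure of an
expression switch.

**Greedy search.** `find_seed` starts from a random *m*-sample subset and
repeatedly proposes swapping one member for one outside sample, accepting
only strict score increases. Independent restarts from several ~1000-gene
seed sets (random, explicit, or the genes most correlated with an anchor
gene) form an ensemble; average-linkage clustering of the runs'
correlation vectors with the silhouette criterion consolidates the
ensemble into distinct biclusters.

**Extension.** Each bicluster is extended to the whole transcriptome with
the *correlation vector* (CV): every gene's Pearson correlation with the
mean profile of a coherent core of representative bicluster genes. All
samples are ranked by greedy accretion of the correlation score
(`sample_sort`), and projected on the first principal component of the
high-|CV| genes (PC1). Plotted against the rank index, PC1 traces the
characteristic bifurcating *fork*; normalizing PC1 so the fork tips sit at
+1/−1 gives each sample a **forkscale**, and a threshold of 0.04 assigns
samples to the upper fork (UF), lower fork (LF) or neither.

**Topology.** Fork sample sets are compared across biclusters with UpSet
exclusive-intersection counts; fork pairs with Jaccard ≥ 0.5 are merged
into shared states. Biclusters linked by a shared state form a
*multistate* switch (e.g. a common LF with two distinct UFs — a tripolar
pattern); unlinked biclusters are independent *bistate* switches.

**Annotation.** Gene sets (GMT, e.g. mitochondrial inventories or KEGG
pathways) are tested for fold enrichment FE = (k/n)/(K/N) in the CV tails
with exact hypergeometric upper-tail p-values and Benjamini–Hochberg
correction. Pathway CV profiles summarize which fork expresses a pathway
more highly (mean member CV, the *dominance*). A single-sample switch
score — the difference of mean z-scored expression between the UF and LF
tail gene sets, with a gene-resampling permutation null — places external
samples (e.g. cell lines) on a discovered switch.

**Synthetic data.** `forkswitch.simulate` plants switch modules in
Gaussian noise: module samples carry a half-normal latent factor f
(positive for UF, negative for LF), and each module gene gains ±a·f. Two
same-group genes then correlate at a²/(a²+σ²) across module samples,
giving an analytic oracle for testing; shared-LF designs reproduce the
multistate geometry.

## Worked example

Plant one switch (2000 genes × 500 samples, 100+100 anticorrelated genes,
60 UF + 60 LF samples, effect 2, noise 1) and rediscover it from random
seed gene sets:

```python
from forkswitch import (reference_design, generate_planted_data,
                        discover_biclusters, score_recovery)
from forkswitch.pipeline import reference_pipeline_config

design = reference_design(rng_seed=1)          # 2000 genes x 500 samples
matrix, truth = generate_planted_data(design)  # one planted 100+100 / 60+60 switch
results, topology = discover_biclusters(matrix, reference_pipeline_config(rng_seed=1))
top = results[0]
print(f"biclusters found: {len(results)}")
print(f"{top.bicluster.bicluster_id}: search score={top.core.score:.3f}, "
      f"extended genes={len(top.bicluster.gene_set)} "
      f"(UF {len(top.bicluster.group_pos)} / LF {len(top.bicluster.group_neg)})")
uf, lf = top.ranking.fork_sets()
print(f"fork samples: UF={len(uf)}, LF={len(lf)}")
for k, v in score_recovery(truth, top.bicluster, top.ranking).items():
    print(f"{k}: {v:.3f}")
```

Output:

```
biclusters found: 1
B1: search score=0.291, extended genes=200 (UF 100 / LF 100)
fork samples: UF=57, LF=54
sample_jaccard: 0.864
gene_precision: 1.000
gene_recall: 1.000
gene_f1: 1.000
fork_balanced_accuracy: 0.931
```

The search score 0.291 is the mean |r| of the 500-gene random seed set
over the 10 found seed samples (most of that set is background, so the
score sits well below 1 even when the switch is found). The CV extension
recovers exactly the 100+100 planted genes (gene F1 = 1.0), the 111 fork
samples capture most of the 120 planted switch samples with little
background contamination (Jaccard 0.864), and labeled samples land on the
correct side of the switch (balanced accuracy 0.931 over UF/LF/NONE).

## Command line

```bash
forkswitch simulate --config design.yaml --out expr.tsv --truth truth.json
forkswitch run --config run.yaml          # search -> extend -> forks -> enrich
forkswitch search --expr expr.tsv --seed-mode random --m 10 --iters 1000 \
    --runs 2 --rng 1 --out run_dir/
forkswitch enrich --cv run_dir/cv_B1.tsv --gmt sets.gmt --expr expr.tsv \
    --tail 1000 --out enrichment.tsv
forkswitch score --expr lines.tsv --uf uf.txt --lf lf.txt --perm 1000 \
    --rng 7 --out scores.tsv
```

All stage outputs are plain TSV/JSON; `manifest.json` records the
configuration hash and a checksum of every artifact, and re-running the
same configuration reproduces identical checksums.

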