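"""Synthetic expression matrices with planted anticorrelated switch modules.

The generator emulates the structure a switch-discovery pipeline must
recover: a background of independent Gaussian noise, plus one or more
planted modules.  Each module has two disjoint fork sample sets (UF, LF)
and two disjoint gene groups (positive, negative).  A latent factor f is
drawn per fork sample — half-normal magnitude, positive sign for UF
samples and negative for LF, zero outside the module — and the expression
of a positive-group gene gains ``a * f(s)`` while a negative-group gene
gains ``-a * f(s)``.  The half-normal magnitudes put the strongest samples
at the fork tips, reproducing the tipped-fork PC1 geometry of real
switches.  Under this model the pairwise Pearson correlation of two
same-group genes across module samples converges to ``a^2 / (a^2 + sigma^2)``,
which serves as an analytic oracle.

Multistate topologies are planted by letting two modules share their LF
sample set (distinct UFs), yielding the tripolar pattern; independent
modules yield bistate switches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import ExpressionMatrix

logger = logging.getLogger("forkswitch")

__all__ = [
    "PlantedModule",
    "PlantedDesign",
    "PlantedTruth",
    "generate_planted_data",
    "expected_module_correlation",
    "score_recovery",
    "reference_design",
    "two_module_design",
]


@dataclass
class PlantedModule:
    """One planted switch: fork sample sets, gene groups and effect size."""

    uf_samples: list[str]
    lf_samples: list[str]
    pos_genes: list[str]
    neg_genes: list[str]
    effect: float = 2.0

    def __post_init__(self) -> None:
        if set(self.uf_samples) & set(self.lf_samples):
            raise ValueError("UF and LF sample sets must be disjoint")
        if set(self.pos_genes) & set(self.neg_genes):
            raise ValueError("positive and negative gene groups must be disjoint")
        if self.effect < 0:
            raise ValueError("effect size must be >= 0")

    @property
    def samples(self) -> list[str]:
        return self.uf_samples + self.lf_samples

    @property
    def genes(self) -> list[str]:
        return self.pos_genes + self.neg_genes


@dataclass
class PlantedDesign:
    """Full specification of a synthetic dataset."""

    n_genes: int
    n_samples: int
    modules: list[PlantedModule]
    noise_sd: float = 1.0
    rng_seed: int = 0
    gene_prefix: str = "G"
    sample_prefix: str = "S"

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise sd must be positive")
        taken: set[str] = set()
        for mod in self.modules:
            genes = set(mod.genes)
            if genes & taken:
                raise ValueError("planted gene groups overlap across modules")
            taken |= genes

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"{self.gene_prefix}{i + 1:0{width}d}" for i in range(self.n_genes)]

    def sample_ids(self) -> list[str]:
        width = len(str(self.n_samples))
        return [f"{self.sample_prefix}{j + 1:0{width}d}" for j in range(self.n_samples)]


@dataclass
class PlantedTruth:
    """The realized design plus the latent factor value of every sample."""

    design: PlantedDesign
    factors: list[np.ndarray]  # one per module, aligned with matrix sample order

    def module_samples(self, module: int = 0) -> set[str]:
        return set(self.design.modules[module].samples)

    def fork_label(self, module: int = 0) -> dict[str, str]:
        mod = self.design.modules[module]
        labels = {s: "NONE" for s in self.design.sample_ids()}
        labels.update({s: "UF" for s in mod.uf_samples})
        labels.update({s: "LF" for s in mod.lf_samples})
        return labels


def expected_module_correlation(a: float, sigma: float) -> float:
    """Asymptotic within-group pairwise correlation ``a^2 / (a^2 + sigma^2)``.

    Two same-group genes share the latent term ``a*f`` and have independent
    noise of variance ``sigma^2``, so across module samples their covariance
    is ``a^2 Var(f)`` against total variance ``a^2 Var(f) + sigma^2``; with
    unit-variance factors the ratio is ``a^2 / (a^2 + sigma^2)``.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return a * a / (a * a + sigma * sigma)


def generate_planted_data(design: PlantedDesign) -> tuple[ExpressionMatrix, PlantedTruth]:
    """Draw one expression matrix from a planted design, bit-reproducibly."""
    gene_ids = design.gene_ids()
    sample_ids = design.sample_ids()
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    sample_index = {s: j for j, s in enumerate(sample_ids)}

    rng = np.random.default_rng(design.rng_seed)
    values = rng.normal(0.0, design.noise_sd, size=(design.n_genes, design.n_samples))

    factors: list[np.ndarray] = []
    for mod in design.modules:
        f = np.zeros(design.n_samples)
        uf = [sample_index[s] for s in mod.uf_samples]
        lf = [sample_index[s] for s in mod.lf_samples]
        f[uf] = np.abs(rng.normal(0.0, 1.0, size=len(uf)))
        f[lf] = -np.abs(rng.normal(0.0, 1.0, size=len(lf)))
        pos = [gene_index[g] for g in mod.pos_genes]
        neg = [gene_index[g] for g in mod.neg_genes]
        values[pos, :] += mod.effect * f[None, :]
        values[neg, :] -= mod.effect * f[None, :]
        factors.append(f)

    matrix = ExpressionMatrix(gene_ids, sample_ids, values)
    return matrix, PlantedTruth(design=design, factors=factors)


# -- standard designs ------------------------------------------------------


def reference_design(
    rng_seed: int = 1,
    n_genes: int = 2000,
    n_samples: int = 500,
    genes_per_group: int = 100,
    samples_per_fork: int = 60,
    effect: float = 2.0,
    noise_sd: float = 1.0,
) -> PlantedDesign:
    """The reference single-module benchmark design.

    Defaults: 2000 genes x 500 samples, 100+100 anticorrelated planted
    genes, 60 UF + 60 LF fork samples, effect 2, noise sd 1.  Planted gene
    and sample positions are scattered uniformly under ``rng_seed`` so the
    module is not a contiguous block.
    """
    design = PlantedDesign(n_genes, n_samples, [], noise_sd, rng_seed)
    genes = design.gene_ids()
    samples = design.sample_ids()
    rng = np.random.default_rng(rng_seed + 10_000)
    gpick = rng.choice(n_genes, size=2 * genes_per_group, replace=False)
    spick = rng.choice(n_samples, size=2 * samples_per_fork, replace=False)
    module = PlantedModule(
        uf_samples=[samples[j] for j in spick[:samples_per_fork]],
        lf_samples=[samples[j] for j in spick[samples_per_fork:]],
        pos_genes=[genes[i] for i in gpick[:genes_per_group]],
        neg_genes=[genes[i] for i in gpick[genes_per_group:]],
        effect=effect,
    )
    design.modules = [module]
    return design


def two_module_design(
    shared_lf: bool,
    rng_seed: int = 1,
    n_genes: int = 1200,
    n_samples: int = 300,
    genes_per_group: int = 60,
    samples_per_fork: int = 40,
    effect: float = 2.0,
    noise_sd: float = 1.0,
) -> PlantedDesign:
    """Two planted modules, either sharing their LF sample set or independent.

    With ``shared_lf`` both modules use one common LF (tripolar, multistate
    topology); otherwise all four fork sample sets are disjoint (two
    independent bistate switches).
    """
    design = PlantedDesign(n_genes, n_samples, [], noise_sd, rng_seed)
    genes = design.gene_ids()
    samples = design.sample_ids()
    rng = np.random.default_rng(rng_seed + 20_000)
    gpick = rng.choice(n_genes, size=4 * genes_per_group, replace=False)
    n_fork_sets = 3 if shared_lf else 4
    spick = rng.choice(n_samples, size=n_fork_sets * samples_per_fork, replace=False)

    uf1 = [samples[j] for j in spick[:samples_per_fork]]
    uf2 = [samples[j] for j in spick[samples_per_fork : 2 * samples_per_fork]]
    lf1 = [samples[j] for j in spick[2 * samples_per_fork : 3 * samples_per_fork]]
    lf2 = lf1 if shared_lf else [samples[j] for j in spick[3 * samples_per_fork :]]

    g = [gpick[i * genes_per_group : (i + 1) * genes_per_group] for i in range(4)]
    design.modules = [
        PlantedModule(
            uf_samples=uf1, lf_samples=list(lf1),
            pos_genes=[genes[i] for i in g[0]], neg_genes=[genes[i] for i in g[1]],
            effect=effect,
        ),
        PlantedModule(
            uf_samples=uf2, lf_samples=list(lf2),
            pos_genes=[genes[i] for i in g[2]], neg_genes=[genes[i] for i in g[3]],
            effect=effect,
        ),
    ]
    return design


# -- recovery metrics ------------------------------------------------------


def _precision_recall_f1(found: set[str], truth: set[str]) -> tuple[float, float, float]:
    if not found or not truth:
        return 0.0, 0.0, 0.0
    tp = len(found & truth)
    prec = tp / len(found)
    rec = tp / len(truth)
    f1 = 2 * prec * rec / (prec + rec) if (prec + rec) else 0.0
    return prec, rec, f1


def score_recovery(
    truth: PlantedTruth,
    bicluster,
    ranking,
    module: int = 0,
) -> dict[str, float]:
    """Compare a recovered bicluster + ranking against a planted module.

    Returns sample-set Jaccard (planted module samples vs. found seed plus
    fork samples), gene-group precision/recall/F1 under the best
    group-to-group matching, and fork balanced accuracy (macro-average
    recall over the UF / LF / NONE classes, background samples counting as
    NONE).
    """
    design = truth.design
    mod = design.modules[module]
    universe_s = set(design.sample_ids())
    universe_g = set(design.gene_ids())
    if not set(ranking.sample_ids) == universe_s:
        raise ValueError("ranking sample universe does not match the design")
    if not set(bicluster.gene_set) <= universe_g:
        raise ValueError("bicluster gene universe does not match the design")

    uf_found, lf_found = (
        ranking.fork_sets() if ranking.fork_labels is not None else (set(), set())
    )
    found_samples = set(bicluster.sample_seed) | uf_found | lf_found
    planted_samples = set(mod.samples)
    union = found_samples | planted_samples
    jac = len(found_samples & planted_samples) / len(union) if union else 0.0

    # best matching of found groups to planted groups
    fpos, fneg = set(bicluster.group_pos), set(bicluster.group_neg)
    tpos, tneg = set(mod.pos_genes), set(mod.neg_genes)
    straight = [_precision_recall_f1(fpos, tpos), _precision_recall_f1(fneg, tneg)]
    crossed = [_precision_recall_f1(fpos, tneg), _precision_recall_f1(fneg, tpos)]
    pick = straight if np.mean([x[2] for x in straight]) >= np.mean(
        [x[2] for x in crossed]
    ) else crossed
    precision = float(np.mean([x[0] for x in pick]))
    recall = float(np.mean([x[1] for x in pick]))
    f1 = float(np.mean([x[2] for x in pick]))

    balanced = float("nan")
    if ranking.fork_labels is not None:
        true_labels = truth.fork_label(module)
        pred = dict(zip(ranking.sample_ids, ranking.fork_labels))
        # the found fork orientation may be flipped relative to the planted one
        accs = []
        for flip in (False, True):
            recalls = []
            for cls in ("UF", "LF", "NONE"):
                members = [s for s in design.sample_ids() if true_labels[s] == cls]
                if not members:
                    continue
                want = cls
                if flip and cls in ("UF", "LF"):
                    want = "LF" if cls == "UF" else "UF"
                hit = sum(1 for s in members if pred[s] == want)
                recalls.append(hit / len(members))
            accs.append(float(np.mean(recalls)))
        balanced = max(accs)

    return {
        "sample_jaccard": float(jac),
        "gene_precision": precision,
        "gene_recall": recall,
        "gene_f1": f1,
        "fork_balanced_accuracy": balanced,
    }
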