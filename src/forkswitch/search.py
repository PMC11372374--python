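"""Stochastic greedy bicluster discovery.

The engine searches for a subset of samples over which a chosen gene set is
maximally coregulated.  Coregulation is measured by the *correlation score*:
the mean absolute pairwise Pearson correlation over all unordered gene
pairs, computed across the candidate samples only.  Because the score uses
absolute correlations, a high-scoring bicluster typically decomposes into
two gene groups with strong positive correlation inside each group and
negative correlation between them — an expression switch.

The search itself is a pure greedy walk over m-sample subsets: each
iteration proposes swapping one seed sample for one outside sample and
accepts the move only on a strict score increase.  Exploration comes from
independent restarts (``run_ensemble``); distinct biclusters in an ensemble
are consolidated with average-linkage clustering of the runs' correlation
vectors plus the silhouette criterion (``cluster_runs_silhouette``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .io import ExpressionMatrix

if TYPE_CHECKING:  # pragma: no cover
    from .extension import CorrelationVector

logger = logging.getLogger("forkswitch")

_EPS = 1e-12

__all__ = [
    "SeedSpec",
    "BiclusterRun",
    "Bicluster",
    "DegenerateScoreError",
    "build_seed_geneset",
    "correlation_score",
    "find_seed",
    "run_ensemble",
    "refine_gene_set",
    "split_gene_groups",
    "cluster_runs_silhouette",
]


class DegenerateScoreError(ValueError):
    """The correlation score is undefined (zero-variance gene or too few genes)."""


@dataclass
class SeedSpec:
    """How to build a starting gene set for the search.

    mode
        ``"explicit"`` (use ``genes`` intersected with the matrix),
        ``"random"`` (uniform sample of ``size`` genes without replacement)
        or ``"anchor_correlated"`` (the ``size`` genes most correlated with
        ``anchor`` across all samples, anchor included).
    """

    mode: str
    genes: list[str] | None = None
    size: int | None = None
    anchor: str | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("explicit", "random", "anchor_correlated"):
            raise ValueError(f"unknown seed mode {self.mode!r}")
        if self.mode == "explicit" and not self.genes:
            raise ValueError("explicit seed mode requires a gene list")
        if self.mode in ("random", "anchor_correlated"):
            if self.size is None or self.size < 1:
                raise ValueError(f"seed mode {self.mode!r} requires a positive size")
        if self.mode == "anchor_correlated" and not self.anchor:
            raise ValueError("anchor_correlated seed mode requires an anchor gene")


@dataclass
class BiclusterRun:
    """One greedy search run: its seed samples, score trajectory and final score."""

    run_id: str
    rng_seed: int
    gene_set: list[str]
    sample_seed: list[str]
    trajectory: list[float]
    score: float


@dataclass
class Bicluster:
    """A sample seed plus a gene set split into two anticorrelated groups."""

    bicluster_id: str
    sample_seed: list[str]
    gene_set: list[str]
    group_pos: list[str]
    group_neg: list[str]
    score: float

    def __post_init__(self) -> None:
        pos, neg = set(self.group_pos), set(self.group_neg)
        if pos & neg:
            raise ValueError("gene groups must be disjoint")
        if pos | neg != set(self.gene_set):
            raise ValueError("gene groups must partition the gene set")


# -- scoring --------------------------------------------------------------


def _abs_corr_mean(X: np.ndarray, drop_degenerate: bool = True) -> tuple[float, int]:
    """Mean |Pearson r| over all unordered row pairs of ``X`` (rows = genes).

    Returns ``(score, n_dropped)`` where ``n_dropped`` counts zero-variance
    rows excluded from the evaluation.  Raises if fewer than two usable rows
    remain.
    """
    Xc = X - X.mean(axis=1, keepdims=True)
    ss = np.einsum("ij,ij->i", Xc, Xc)
    keep = ss > _EPS
    dropped = int(X.shape[0] - keep.sum())
    if dropped:
        if not drop_degenerate:
            raise DegenerateScoreError("zero-variance gene in score evaluation")
        Xc = Xc[keep]
        ss = ss[keep]
    g = Xc.shape[0]
    if g < 2:
        raise DegenerateScoreError("fewer than 2 usable (nonzero-variance) genes")
    Xn = Xc / np.sqrt(ss)[:, None]
    R = Xn @ Xn.T
    np.abs(R, out=R)
    # |diag| sums to g exactly up to rounding; subtract it out.
    total = float(R.sum()) - float(np.trace(R))
    return min(total / (g * (g - 1)), 1.0), dropped


def correlation_score(
    matrix: ExpressionMatrix,
    genes: Sequence[str],
    samples: Sequence[str],
) -> float:
    """Correlation score of ``genes`` over ``samples``: mean pairwise |r|.

    Requires at least two genes and three samples; a gene with zero variance
    over the given samples is an error naming the gene (search-path callers
    pre-filter such genes instead, see :func:`find_seed`).
    """
    genes = list(genes)
    samples = list(samples)
    if len(genes) < 2:
        raise ValueError("correlation_score requires at least 2 genes")
    if len(samples) < 3:
        raise ValueError("correlation_score requires at least 3 samples")
    X = matrix.submatrix(genes, samples)
    var = X.var(axis=1)
    if np.any(var <= _EPS / len(samples)):
        offender = genes[int(np.argmax(var <= _EPS / len(samples)))]
        raise DegenerateScoreError(
            f"gene {offender!r} has zero variance over the given samples"
        )
    score, _ = _abs_corr_mean(X, drop_degenerate=False)
    return score


# -- seed gene sets -------------------------------------------------------


def build_seed_geneset(matrix: ExpressionMatrix, spec: SeedSpec) -> list[str]:
    """Materialize a :class:`SeedSpec` against a matrix.

    Explicit sets are intersected with the matrix genes (missing members
    logged); random sets are drawn without replacement under the spec's RNG
    seed; anchor sets take the ``size`` genes with the highest Pearson
    correlation to the anchor gene across all samples (the anchor ranks
    first by self-correlation).
    """
    if spec.mode == "explicit":
        present = [g for g in spec.genes if matrix.has_gene(g)]
        missing = len(spec.genes) - len(present)
        if missing:
            logger.info("seed gene set: %d members absent from matrix", missing)
        if not present:
            raise ValueError("no seed genes present in the matrix")
        return present

    if spec.size > matrix.n_genes:
        raise ValueError(
            f"seed size {spec.size} exceeds gene count {matrix.n_genes}"
        )
    if spec.mode == "random":
        rng = np.random.default_rng(spec.rng_seed)
        rows = np.sort(rng.choice(matrix.n_genes, size=spec.size, replace=False))
        return [matrix.gene_ids[i] for i in rows]

    # anchor_correlated
    if not matrix.has_gene(spec.anchor):
        raise ValueError(f"anchor gene {spec.anchor!r} not in matrix")
    a = matrix.values[matrix.gene_rows([spec.anchor])[0]]
    ac = a - a.mean()
    an = np.sqrt(ac @ ac)
    if an <= _EPS:
        raise ValueError(f"anchor gene {spec.anchor!r} has zero variance")
    Xc = matrix.values - matrix.values.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->i", Xc, Xc))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ ac) / (norms * an)
    r = np.where(np.isfinite(r), r, -np.inf)  # constant genes rank last
    order = np.argsort(-r, kind="stable")[: spec.size]
    order = np.sort(order)  # preserve matrix order in the returned set
    return [matrix.gene_ids[i] for i in order]


# -- greedy search --------------------------------------------------------


def find_seed(
    matrix: ExpressionMatrix,
    genes: Sequence[str],
    m: int,
    iterations: int = 1000,
    rng_seed: int = 0,
    run_id: str = "run",
) -> BiclusterRun:
    """Greedy stochastic search for the m-sample subset maximizing the score.

    Starts from a uniformly random m-subset; every iteration proposes
    replacing one uniformly chosen seed sample with one uniformly chosen
    outside sample and accepts iff the score strictly increases, so the
    trajectory is non-decreasing.  Fully reproducible from ``rng_seed``.
    Genes with zero variance over a candidate sample set are dropped from
    that evaluation (logged once per run).
    """
    genes = list(genes)
    if m > matrix.n_samples:
        raise ValueError(f"m={m} exceeds sample count {matrix.n_samples}")
    if m < 3:
        raise ValueError("sample seed size m must be at least 3")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rows = matrix.gene_rows(genes)
    X = matrix.values[rows, :]
    usable = np.einsum("ij,ij->i", X - X.mean(1, keepdims=True),
                       X - X.mean(1, keepdims=True)) > _EPS
    if int(usable.sum()) < 2:
        raise DegenerateScoreError("fewer than 2 usable (nonzero-variance) genes")

    rng = np.random.default_rng(rng_seed)
    n = matrix.n_samples
    perm = rng.permutation(n)
    members = perm[:m].copy()
    outside = perm[m:].copy()

    score, dropped = _abs_corr_mean(X[:, members])
    warned = dropped > 0
    if warned:
        logger.info("run %s: %d zero-variance genes dropped in scoring", run_id, dropped)
    trajectory = [score]

    if outside.size:
        for _ in range(iterations):
            a = int(rng.integers(m))
            b = int(rng.integers(outside.size))
            old = members[a]
            members[a] = outside[b]
            new_score, dropped = _abs_corr_mean(X[:, members])
            if dropped and not warned:
                logger.info(
                    "run %s: zero-variance genes dropped in scoring", run_id
                )
                warned = True
            if new_score > score:
                score = new_score
                outside[b] = old
                trajectory.append(score)
            else:
                members[a] = old

    seed_ids = [matrix.sample_ids[i] for i in np.sort(members)]
    return BiclusterRun(
        run_id=run_id,
        rng_seed=rng_seed,
        gene_set=genes,
        sample_seed=seed_ids,
        trajectory=trajectory,
        score=score,
    )


def run_ensemble(
    matrix: ExpressionMatrix,
    seed_specs: Sequence[SeedSpec],
    m: int = 10,
    iterations: int = 1000,
    n_runs: int = 1,
    base_rng_seed: int = 0,
) -> list[BiclusterRun]:
    """Independent greedy runs for every seed spec.

    Per-run RNG seeds are ``base_rng_seed + run_index`` (run index global
    over the spec x repeat grid, in deterministic order) and are recorded on
    the returned runs.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    runs: list[BiclusterRun] = []
    run_index = 0
    for si, spec in enumerate(seed_specs):
        genes = build_seed_geneset(matrix, spec)
        for ri in range(n_runs):
            seed = base_rng_seed + run_index
            run = find_seed(
                matrix, genes, m, iterations, rng_seed=seed,
                run_id=f"s{si}r{ri}",
            )
            logger.debug("run %s: seed=%d score=%.4f", run.run_id, seed, run.score)
            runs.append(run)
            run_index += 1
    return runs


# -- refinement and the anticorrelated split -------------------------------


def refine_gene_set(
    matrix: ExpressionMatrix,
    genes: Sequence[str],
    samples: Sequence[str],
    drop_fraction: float = 0.1,
) -> list[str]:
    """Drop the least coherent fraction of a gene set over the seed samples.

    Coherence of a gene is its mean |r| to the rest of the set over the
    seed samples; the bottom ``drop_fraction`` is removed (zero-variance
    genes first).  Stabilizes the reference profile before the split and
    the correlation-vector extension.
    """
    genes = list(genes)
    if not 0 <= drop_fraction < 1:
        raise ValueError("drop_fraction must be in [0, 1)")
    n_drop = int(np.floor(drop_fraction * len(genes)))
    if n_drop == 0:
        return genes
    X = matrix.submatrix(genes, list(samples))
    coh = _mean_abs_corr_per_gene(X)
    order = np.argsort(coh, kind="stable")  # ascending; drop the head
    keep = np.sort(order[n_drop:])
    return [genes[i] for i in keep]


def _mean_abs_corr_per_gene(X: np.ndarray) -> np.ndarray:
    """Per-row mean |r| to all other rows; zero-variance rows get -inf."""
    Xc = X - X.mean(axis=1, keepdims=True)
    ss = np.einsum("ij,ij->i", Xc, Xc)
    ok = ss > _EPS
    out = np.full(X.shape[0], -np.inf)
    if int(ok.sum()) >= 2:
        Xn = Xc[ok] / np.sqrt(ss[ok])[:, None]
        R = np.abs(Xn @ Xn.T)
        g = Xn.shape[0]
        out[ok] = (R.sum(axis=1) - 1.0) / (g - 1)
    return out


def split_gene_groups(
    matrix: ExpressionMatrix,
    genes: Sequence[str],
    samples: Sequence[str],
) -> tuple[list[str], list[str]]:
    """Split a gene set into its two anticorrelated groups.

    The partition is by sign of each gene's loading on the first principal
    component (leading eigenvector) of the gene-gene correlation matrix over
    the seed samples.  When every gene is mutually positively correlated the
    split is degenerate: a warning is logged and the second group is empty.
    Group orientation relative to the correlation-vector reference is fixed
    later (see :func:`forkswitch.extension.orient_groups`).
    """
    genes = list(genes)
    samples = list(samples)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to split")
    if len(samples) < 3:
        raise ValueError("need at least 3 seed samples to split")
    X = matrix.submatrix(genes, samples)
    Xc = X - X.mean(axis=1, keepdims=True)
    ss = np.einsum("ij,ij->i", Xc, Xc)
    ok = ss > _EPS
    Xn = np.zeros_like(Xc)
    Xn[ok] = Xc[ok] / np.sqrt(ss[ok])[:, None]
    C = Xn @ Xn.T
    np.fill_diagonal(C, 1.0)
    w, v = np.linalg.eigh(C)
    lead = v[:, -1]
    # canonical sign: the largest-magnitude loading is positive
    if lead[int(np.argmax(np.abs(lead)))] < 0:
        lead = -lead
    pos = [g for g, l in zip(genes, lead) if l >= 0]
    neg = [g for g, l in zip(genes, lead) if l < 0]
    if not neg or not pos:
        logger.warning(
            "degenerate split: gene set shows no anticorrelated structure"
        )
        return genes, []
    return pos, neg


# -- ensemble consolidation ------------------------------------------------


def cluster_runs_silhouette(
    matrix: ExpressionMatrix,
    runs: Sequence[BiclusterRun],
    cvs: Sequence["CorrelationVector"],
    k_max: int = 10,
    min_sil: float = 0.25,
    refine_fraction: float = 0.1,
) -> list[Bicluster]:
    """Consolidate an ensemble of runs into distinct biclusters.

    Runs are compared through their correlation vectors: the distance
    between two runs is ``1 - |Pearson r|`` of their CVs, so sign-flipped
    duplicates of the same switch coincide.  Average-linkage hierarchical
    clustering is cut at the k in ``2..k_max`` maximizing the mean
    silhouette width; if even the best silhouette falls below ``min_sil``
    the ensemble is declared a single bicluster.  Each cluster is
    represented by its highest-scoring member run, refined and split into
    its anticorrelated gene groups.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if len(runs) < 2:
        raise ValueError("need at least 2 runs to consolidate")
    if len(cvs) != len(runs):
        raise ValueError("need exactly one correlation vector per run")
    universe = cvs[0].gene_ids
    for cv in cvs[1:]:
        if cv.gene_ids != universe:
            raise ValueError("runs have correlation vectors over mismatched gene universes")

    V = np.vstack([cv.values for cv in cvs])
    with np.errstate(invalid="ignore"):
        R = np.corrcoef(V)
    R = np.nan_to_num(R, nan=0.0)
    D = 1.0 - np.abs(R)
    np.clip(D, 0.0, None, out=D)
    np.fill_diagonal(D, 0.0)
    D = (D + D.T) / 2.0

    n = len(runs)
    Z = linkage(squareform(D, checks=False), method="average")
    best_k, best_sil, best_labels = 1, -np.inf, np.ones(n, dtype=int)
    for k in range(2, min(k_max, n - 1) + 1):
        labels = fcluster(Z, t=k, criterion="maxclust")
        if len(np.unique(labels)) < 2:
            continue
        sil = float(silhouette_score(D, labels, metric="precomputed"))
        if sil > best_sil:
            best_k, best_sil, best_labels = k, sil, labels
    if best_sil < min_sil:
        logger.info(
            "silhouette %.3f below gate %.2f: declaring a single bicluster",
            best_sil, min_sil,
        )
        best_labels = np.ones(n, dtype=int)

    biclusters: list[Bicluster] = []
    for label in np.unique(best_labels):
        idx = np.flatnonzero(best_labels == label)
        rep = idx[int(np.argmax([runs[i].score for i in idx]))]
        run = runs[rep]
        refined = refine_gene_set(
            matrix, run.gene_set, run.sample_seed, drop_fraction=refine_fraction
        )
        pos, neg = split_gene_groups(matrix, refined, run.sample_seed)
        biclusters.append(
            Bicluster(
                bicluster_id="",
                sample_seed=list(run.sample_seed),
                gene_set=list(refined),
                group_pos=pos,
                group_neg=neg,
                score=run.score,
            )
        )
    biclusters.sort(key=lambda b: -b.score)
    for i, b in enumerate(biclusters):
        b.bicluster_id = f"B{i + 1}"
    return biclusters
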