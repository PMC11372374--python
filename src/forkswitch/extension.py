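"""Extending a bicluster to the whole transcriptome and all samples.

A bicluster found by the greedy search covers only its seed samples and
seed gene set.  Three extensions make it a genome- and cohort-wide object:

* the **correlation vector** (CV): every gene's Pearson correlation with a
  reference profile built from a coherent core of representative bicluster
  genes — positive CVs follow the reference, negative CVs oppose it;
* the **sample ranking**: greedy accretion ordering of all samples by how
  well they preserve the bicluster's correlation structure;
* **PC1**: each sample's projection on the first principal component of the
  high-|CV| genes, fitted on the top-ranked samples.  Plotted against the
  rank index, PC1 traces the characteristic bifurcating fork of a switch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .io import ExpressionMatrix
from .search import Bicluster, _EPS, _abs_corr_mean

logger = logging.getLogger("forkswitch")

__all__ = [
    "CorrelationVector",
    "SampleRanking",
    "select_representative_genes",
    "compute_cv",
    "orient_groups",
    "sample_sort",
    "compute_pc1",
    "default_cv_context",
]


@dataclass
class CorrelationVector:
    """Per-gene correlation with a bicluster's reference profile.

    ``values`` is aligned with ``gene_ids`` (the full matrix gene universe)
    and bounded by [-1, 1].  ``representative_genes`` are the core genes
    whose per-sample mean defines the reference profile; by construction
    their own CV is positive, which fixes the sign convention of the whole
    vector.
    """

    bicluster_id: str
    gene_ids: list[str]
    values: np.ndarray
    representative_genes: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids),):
            raise ValueError("CV values must align with gene_ids")
        if np.any(np.abs(self.values) > 1 + 1e-9):
            raise ValueError("CV values must lie in [-1, 1]")
        self._index = {g: i for i, g in enumerate(self.gene_ids)}

    def __getitem__(self, gene: str) -> float:
        return float(self.values[self._index[gene]])

    def as_series(self):
        import pandas as pd

        return pd.Series(self.values, index=self.gene_ids, name="cv")


@dataclass
class SampleRanking:
    """The switch position of every sample for one bicluster.

    ``sample_ids`` preserves matrix order; ``rank_index`` is a permutation
    with 1 marking the sample most supportive of the bicluster.  ``pc1``,
    ``forkscale`` and ``fork_labels`` are filled by later stages.
    """

    bicluster_id: str
    sample_ids: list[str]
    rank_index: np.ndarray
    pc1: np.ndarray | None = None
    forkscale: np.ndarray | None = None
    fork_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rank_index = np.asarray(self.rank_index, dtype=int)
        n = len(self.sample_ids)
        if sorted(self.rank_index.tolist()) != list(range(1, n + 1)):
            raise ValueError("rank_index must be a permutation of 1..n_samples")

    @property
    def ordered_samples(self) -> list[str]:
        order = np.argsort(self.rank_index, kind="stable")
        return [self.sample_ids[i] for i in order]

    def fork_sets(self) -> tuple[set[str], set[str]]:
        """(upper fork, lower fork) sample id sets; requires fork labels."""
        if self.fork_labels is None:
            raise ValueError("fork labels not computed")
        uf = {s for s, l in zip(self.sample_ids, self.fork_labels) if l == "UF"}
        lf = {s for s, l in zip(self.sample_ids, self.fork_labels) if l == "LF"}
        return uf, lf


# -- representative genes and the correlation vector ----------------------


def select_representative_genes(
    matrix: ExpressionMatrix,
    bicluster: Bicluster,
    coherence_threshold: float = 0.7,
    max_clusters: int = 12,
    min_cluster_fraction: float = 0.05,
) -> list[str]:
    """Pick a coherent core of bicluster genes for the reference profile.

    Within the larger of the two gene groups, average-linkage clustering of
    ``1 - r`` distances over the seed samples is cut at k = 1..max_clusters;
    the largest cluster whose internal mean pairwise r meets
    ``coherence_threshold`` wins.  Clusters smaller than
    ``min_cluster_fraction`` of the group (and smaller than 4 genes) are
    ignored: a couple of incidentally correlated genes is not a reference
    profile.  If nothing qualifies the whole larger group is used, with a
    warning.
    """
    if len(bicluster.gene_set) < 2:
        raise ValueError("bicluster must have at least 2 genes")
    larger = (
        bicluster.group_pos
        if len(bicluster.group_pos) >= len(bicluster.group_neg)
        else bicluster.group_neg
    )
    if len(larger) < 3:
        return list(larger)
    X = matrix.submatrix(larger, bicluster.sample_seed)
    Xc = X - X.mean(axis=1, keepdims=True)
    ss = np.einsum("ij,ij->i", Xc, Xc)
    ok = ss > _EPS
    Xn = np.zeros_like(Xc)
    Xn[ok] = Xc[ok] / np.sqrt(ss[ok])[:, None]
    C = Xn @ Xn.T
    np.fill_diagonal(C, 1.0)
    D = np.clip(1.0 - C, 0.0, 2.0)
    D = (D + D.T) / 2.0
    Z = linkage(squareform(D, checks=False), method="average")

    min_size = max(2, min(4, len(larger)), int(np.ceil(min_cluster_fraction * len(larger))))
    best: np.ndarray | None = None
    for k in range(1, min(max_clusters, len(larger)) + 1):
        labels = fcluster(Z, t=k, criterion="maxclust") if k > 1 else np.ones(len(larger), int)
        for label in np.unique(labels):
            idx = np.flatnonzero(labels == label)
            if idx.size < min_size:
                continue
            sub = C[np.ix_(idx, idx)]
            mean_r = (sub.sum() - idx.size) / (idx.size * (idx.size - 1))
            if mean_r >= coherence_threshold and (best is None or idx.size > best.size):
                best = idx
    if best is None:
        logger.warning(
            "no gene cluster reaches coherence %.2f; using the whole larger group",
            coherence_threshold,
        )
        return list(larger)
    # prune stragglers: a member whose own mean correlation to the rest of
    # the cluster falls below half the coherence bound is not core material
    sub = C[np.ix_(best, best)]
    member_r = (sub.sum(axis=1) - 1.0) / (best.size - 1)
    keep = best[member_r >= coherence_threshold / 2]
    if keep.size >= 2:
        best = keep
    return [larger[i] for i in best]


def compute_cv(
    matrix: ExpressionMatrix,
    representative_genes: Sequence[str],
    context_samples: Sequence[str],
    bicluster_id: str = "",
) -> CorrelationVector:
    """Correlation of every gene with the representative-gene mean profile.

    The reference profile is the per-sample mean expression of the
    representative genes over the context samples; CV(g) is the Pearson r
    between gene g and that profile across the context samples.  Genes with
    zero variance in the context get CV = 0 (count logged).
    """
    representative_genes = list(representative_genes)
    context_samples = list(context_samples)
    if not representative_genes:
        raise ValueError("representative gene set is empty")
    if len(context_samples) < 3:
        raise ValueError("need at least 3 context samples")
    cols = matrix.sample_cols(context_samples)
    ref = matrix.values[np.ix_(matrix.gene_rows(representative_genes), cols)].mean(axis=0)
    refc = ref - ref.mean()
    refn = np.sqrt(refc @ refc)
    if refn <= _EPS:
        raise ValueError("reference profile is constant over the context samples")
    X = matrix.values[:, cols]
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->i", Xc, Xc))
    ok = norms > _EPS
    cv = np.zeros(matrix.n_genes)
    cv[ok] = (Xc[ok] @ refc) / (norms[ok] * refn)
    n_flat = int((~ok).sum())
    if n_flat:
        logger.info("CV: %d zero-variance genes set to 0", n_flat)
    np.clip(cv, -1.0, 1.0, out=cv)
    return CorrelationVector(
        bicluster_id=bicluster_id,
        gene_ids=list(matrix.gene_ids),
        values=cv,
        representative_genes=representative_genes,
    )


def orient_groups(bicluster: Bicluster, cv: CorrelationVector) -> Bicluster:
    """Relabel gene groups so ``group_pos`` correlates positively with the CV reference."""
    if not bicluster.group_neg:
        return bicluster
    mean_pos = float(np.mean([cv[g] for g in bicluster.group_pos]))
    mean_neg = float(np.mean([cv[g] for g in bicluster.group_neg]))
    if mean_pos < mean_neg:
        bicluster.group_pos, bicluster.group_neg = (
            bicluster.group_neg,
            bicluster.group_pos,
        )
    return bicluster


def default_cv_context(ranking: SampleRanking, m: int) -> list[str]:
    """Context samples for the CV: the top-ranked max(2m, 10% of samples)."""
    n = len(ranking.sample_ids)
    k = min(n, max(2 * m, int(np.ceil(0.1 * n))))
    return ranking.ordered_samples[:k]


# -- sample ranking --------------------------------------------------------


def sample_sort(
    matrix: ExpressionMatrix,
    genes: Sequence[str],
    sample_seed: Sequence[str],
    max_sort_genes: int = 80,
    chunk: int = 256,
    n_accrete: int | None = None,
) -> SampleRanking:
    """Rank all samples by greedy accretion of the correlation score.

    Starting from the seed, the non-member sample whose inclusion yields the
    highest correlation score of the bicluster genes over the augmented set
    is appended, repeatedly, until every sample is placed.  Seed members are
    ranked first, ordered by their leave-one-out score contribution
    (descending); accretion order follows.  Ties are broken by input sample
    order.

    For tractability at cohort scale the sort uses at most
    ``max_sort_genes`` genes — the most coherent ones over the seed samples
    (deterministic).  Scores along the accretion are maintained with
    incremental sufficient statistics, so each step costs one vectorized
    pass over the remaining candidates.  When ``n_accrete`` is given, only
    the first ``n_accrete`` samples are placed by full accretion and the
    remainder are ordered by their augmented score at the last step
    (descending, input order on ties) — a cheap truncation for callers that
    only consume the head of the ranking.
    """
    genes = list(genes)
    seed = list(sample_seed)
    seed_cols = matrix.sample_cols(seed)
    rows = matrix.gene_rows(genes)
    X = matrix.values[rows, :]

    if max_sort_genes is not None and len(genes) > max_sort_genes:
        coh = _mean_abs_corr_rows(X[:, seed_cols])
        keep = np.sort(np.argsort(-coh, kind="stable")[:max_sort_genes])
        X = X[keep, :]
    G, N = X.shape
    if G < 2:
        raise ValueError("need at least 2 usable genes to sort samples")

    # -- seed order: leave-one-out contribution, descending -----------------
    m = len(seed_cols)
    if m >= 4:
        full, _ = _abs_corr_mean(X[:, seed_cols])
        contrib = np.empty(m)
        for i in range(m):
            sub = np.delete(seed_cols, i)
            try:
                loo, _ = _abs_corr_mean(X[:, sub])
            except Exception:
                loo = full
            contrib[i] = full - loo
        seed_order = np.argsort(-contrib, kind="stable")
    else:
        seed_order = np.arange(m)
    ordered_cols = [int(seed_cols[i]) for i in seed_order]

    # -- accretion with incremental statistics ------------------------------
    member = np.zeros(N, dtype=bool)
    member[seed_cols] = True
    cand = np.flatnonzero(~member)  # stays in input order

    s = X[:, seed_cols].sum(axis=1)
    P = X[:, seed_cols] @ X[:, seed_cols].T
    k = m
    steps = 0
    while cand.size:
        best_idx, scores = _best_candidate(X, cand, P, s, k, chunk)
        steps += 1
        if n_accrete is not None and steps > n_accrete:
            # place all remaining samples by their last augmented score
            tail_order = np.argsort(-scores, kind="stable")
            ordered_cols.extend(int(cand[i]) for i in tail_order)
            break
        chosen = int(cand[best_idx])
        x = X[:, chosen]
        P += np.outer(x, x)
        s += x
        k += 1
        ordered_cols.append(chosen)
        cand = np.delete(cand, best_idx)

    rank_index = np.empty(N, dtype=int)
    for rank, col in enumerate(ordered_cols, start=1):
        rank_index[col] = rank
    return SampleRanking(
        bicluster_id="",
        sample_ids=list(matrix.sample_ids),
        rank_index=rank_index,
    )


def _mean_abs_corr_rows(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=1, keepdims=True)
    ss = np.einsum("ij,ij->i", Xc, Xc)
    ok = ss > _EPS
    out = np.full(X.shape[0], -np.inf)
    if int(ok.sum()) >= 2:
        Xn = Xc[ok] / np.sqrt(ss[ok])[:, None]
        R = np.abs(Xn @ Xn.T)
        out[ok] = (R.sum(axis=1) - 1.0) / (Xn.shape[0] - 1)
    return out


def _best_candidate(
    X: np.ndarray,
    cand: np.ndarray,
    P: np.ndarray,
    s: np.ndarray,
    k: int,
    chunk: int,
) -> tuple[int, np.ndarray]:
    """Index (into ``cand``) of the sample maximizing the augmented score.

    Uses the identity: with k members (sums ``s``, product matrix ``P``) and
    candidate x, the augmented covariance numerator is
    ``(k+1)(P + x x^T) - (s+x)(s+x)^T = [(k+1)P - s s^T] + k x x^T - x s^T - s x^T``.
    First occurrence wins on exact ties, matching input sample order.
    Returns the winning index and the full score vector over ``cand``.
    """
    G = X.shape[0]
    B = (k + 1) * P - np.outer(s, s)
    all_scores = np.empty(cand.size)
    best_score = -np.inf
    best_idx = -1
    for start in range(0, cand.size, chunk):
        cols = cand[start : start + chunk]
        Xc = X[:, cols].T  # C x G
        NUM = np.einsum("cg,ch->cgh", Xc, Xc)
        NUM *= float(k)
        NUM += B[None, :, :]
        cross = Xc[:, :, None] * s[None, None, :]
        NUM -= cross
        NUM -= np.swapaxes(cross, 1, 2)
        d = np.diagonal(NUM, axis1=1, axis2=2).copy()
        np.clip(d, _EPS, None, out=d)
        rootd = np.sqrt(d)
        np.abs(NUM, out=NUM)
        NUM /= rootd[:, :, None]
        NUM /= rootd[:, None, :]
        totals = NUM.sum(axis=(1, 2)) - np.einsum("cgg->c", NUM)
        scores = totals / (G * (G - 1))
        all_scores[start : start + len(scores)] = scores
        i = int(np.argmax(scores))
        if scores[i] > best_score:
            best_score = float(scores[i])
            best_idx = start + i
    return best_idx, all_scores


# -- PC1 -------------------------------------------------------------------


def compute_pc1(
    matrix: ExpressionMatrix,
    cv: CorrelationVector,
    ranking: SampleRanking,
    top_fraction: float = 0.3,
    n_top_genes: int = 500,
) -> np.ndarray:
    """Per-sample PC1 values summarizing the switch geometry.

    The ``n_top_genes`` genes with largest |CV| (balanced between CV signs
    when possible) are z-scored over all samples; the first principal
    component is fitted on the top ``top_fraction`` ranked samples and every
    sample is projected onto it.  The sign is fixed so that samples with
    above-median representative-gene expression project positively, making
    the upper fork the one that expresses the reference profile.  The
    result is stored on ``ranking.pc1`` and returned (aligned with
    ``matrix.sample_ids``).
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    if n_top_genes < 2:
        raise ValueError("n_top_genes must be >= 2")
    if n_top_genes > matrix.n_genes:
        logger.warning(
            "n_top_genes=%d exceeds gene count %d; clipping",
            n_top_genes, matrix.n_genes,
        )
        n_top_genes = matrix.n_genes

    vals = cv.values
    pos_order = np.argsort(-vals, kind="stable")
    neg_order = np.argsort(vals, kind="stable")
    half = n_top_genes // 2
    n_pos_avail = int((vals > 0).sum())
    n_neg_avail = int((vals < 0).sum())
    n_pos = min(max(half, n_top_genes - n_neg_avail), n_pos_avail, n_top_genes)
    n_neg = min(n_top_genes - n_pos, n_neg_avail)
    chosen = np.concatenate([pos_order[:n_pos], neg_order[:n_neg]])
    if chosen.size < 2:
        raise ValueError("fewer than 2 genes available for PC1")
    chosen = np.unique(chosen)

    X = matrix.values[chosen, :]
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd <= _EPS] = 1.0
    Z = (X - mu) / sd  # genes x samples

    n = matrix.n_samples
    n_fit = max(3, int(np.ceil(top_fraction * n)))
    fit_cols = matrix.sample_cols(ranking.ordered_samples[:n_fit])
    F = Z[:, fit_cols]
    center = F.mean(axis=1, keepdims=True)
    # first left singular vector of the centered fit matrix = PC1 gene loadings
    U, sv, _ = np.linalg.svd(F - center, full_matrices=False)
    load = U[:, 0]
    pc1 = Z.T @ load
    # anchor the zero point on the cohort's central mass so non-fork
    # samples sit near PC1 = 0 even when the fit set is asymmetric
    pc1 -= np.median(pc1)

    # sign convention: samples rich in the representative profile are positive
    rep_rows = matrix.gene_rows(cv.representative_genes)
    rep_mean = matrix.values[rep_rows, :].mean(axis=0)
    high = rep_mean > np.median(rep_mean)
    if high.any() and pc1[high].mean() < 0:
        pc1 = -pc1
    ranking.pc1 = pc1
    return pc1
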