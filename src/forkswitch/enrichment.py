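"""Gene-set enrichment in CV tails, pathway profiling and sample scoring.

The genes with the highest and lowest correlation-vector values are the
dominant, most strongly regulated genes of the two switch positions.  This
module quantifies (i) the fold enrichment of annotation sets (mitochondrial
inventories, KEGG pathways, ...) in those tails with an exact
hypergeometric test and Benjamini-Hochberg correction, (ii) per-pathway CV
profiles whose mean CV ("dominance") predicts which fork expresses the
pathway more highly, and (iii) a single-sample switch score that places
new samples (e.g. cell lines) on a switch via the difference of mean
z-scored expression between the two tail gene sets, with a gene-resampling
permutation null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .extension import CorrelationVector
from .io import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger("forkswitch")

__all__ = [
    "EnrichmentResult",
    "PathwayProfile",
    "SwitchScore",
    "cv_tails",
    "fold_enrichment",
    "batch_fold_enrichment",
    "pathway_cv_profile",
    "sample_switch_score",
]


@dataclass
class EnrichmentResult:
    """Hypergeometric fold enrichment of one annotation set in one selection."""

    set_name: str
    direction: str  # "UF_tail" or "LF_tail"
    k: int  # annotated genes in the selection
    n: int  # selection size
    K: int  # annotated genes in the universe
    N: int  # universe size
    fold_enrichment: float
    p: float
    q: float | None = None  # BH-adjusted, filled batch-wise


@dataclass
class PathwayProfile:
    """CV-ranked members of a pathway and its dominance statistic."""

    pathway: str
    genes: list[str]  # ranked by CV, descending
    cvs: np.ndarray
    dominance: float  # mean CV of mapped members

    @property
    def predicted_fork(self) -> str:
        """UF when the pathway follows the reference profile, LF when it opposes it."""
        return "UF" if self.dominance >= 0 else "LF"


@dataclass
class SwitchScore:
    """One sample's position on a switch, scored from tail gene sets."""

    sample_id: str
    score_uf: float
    score_lf: float
    delta: float
    p: float
    position: str  # "UF", "LF" or "unassigned"


# -- CV tails --------------------------------------------------------------


def cv_tails(cv: CorrelationVector, tail_size: int) -> tuple[list[str], list[str]]:
    """Top and bottom ``tail_size`` genes by CV value.

    Returns ``(UF_tail, LF_tail)``: the genes most positively and most
    negatively correlated with the reference profile.  Ties are broken by
    lexicographic gene id, so the tails are deterministic.
    """
    if tail_size < 1:
        raise ValueError("tail_size must be >= 1")
    if 2 * tail_size > len(cv.gene_ids):
        raise ValueError(
            f"2 x tail_size = {2 * tail_size} exceeds gene count {len(cv.gene_ids)}"
        )
    order = sorted(range(len(cv.gene_ids)), key=lambda i: (-cv.values[i], cv.gene_ids[i]))
    uf = [cv.gene_ids[i] for i in order[:tail_size]]
    lf_order = sorted(range(len(cv.gene_ids)), key=lambda i: (cv.values[i], cv.gene_ids[i]))
    lf = [cv.gene_ids[i] for i in lf_order[:tail_size]]
    return uf, lf


def tails_by_threshold(
    cv: CorrelationVector, threshold: float
) -> tuple[list[str], list[str]]:
    """Genes with CV >= threshold (UF side) and CV <= -threshold (LF side)."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    uf = [g for g, v in zip(cv.gene_ids, cv.values) if v >= threshold]
    lf = [g for g, v in zip(cv.gene_ids, cv.values) if v <= -threshold]
    return uf, lf


# -- fold enrichment -------------------------------------------------------


def fold_enrichment(
    selection: Sequence[str],
    annotation: Sequence[str],
    universe: Sequence[str],
    set_name: str = "",
    direction: str = "",
) -> EnrichmentResult:
    """Fold enrichment and hypergeometric upper-tail p of an annotation.

    FE = (k/n)/(K/N) with k annotated genes among the n selected, K
    annotated in the universe of N genes; p = P[X >= k] for X hypergeometric.
    Selection and annotation are intersected with the universe first.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    sel = set(selection) & uni
    if not sel:
        raise ValueError("empty selection")
    ann = set(annotation) & uni
    k = len(sel & ann)
    n = len(sel)
    K = len(ann)
    N = len(uni)
    fe = (k / n) / (K / N) if K else float("nan")
    p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
    p = min(max(p, 0.0), 1.0)
    return EnrichmentResult(set_name, direction, k, n, K, N, fe, p)


def batch_fold_enrichment(
    selections: dict[str, Sequence[str]],
    annotations: GeneSetCollection,
    universe: Sequence[str],
) -> list[EnrichmentResult]:
    """Fold enrichment of every annotation set in every selection, BH-corrected.

    ``selections`` maps a direction label (e.g. ``"UF_tail"``) to its gene
    list.  The Benjamini-Hochberg adjustment is applied across the whole
    batch (one CV x one collection), filling ``q`` on each result.
    """
    results: list[EnrichmentResult] = []
    mapped = annotations.restrict_to(universe)
    for direction, selection in selections.items():
        for name in mapped.names():
            res = fold_enrichment(
                selection, mapped[name], universe, set_name=name, direction=direction
            )
            results.append(res)
    if results:
        _, q, _, _ = multipletests([r.p for r in results], method="fdr_bh")
        for r, qi in zip(results, q):
            r.q = float(qi)
    return results


# -- pathway CV profiles ---------------------------------------------------


def pathway_cv_profile(
    cv: CorrelationVector,
    pathways: GeneSetCollection,
    min_genes: int = 3,
) -> list[PathwayProfile]:
    """CV-ranked member profile and dominance for every pathway.

    Dominance is the mean CV of a pathway's mapped members: strongly
    positive dominance predicts higher activity in the upper fork,
    strongly negative in the lower fork.  Pathways mapping fewer than
    ``min_genes`` genes are skipped with a warning.
    """
    index = {g: i for i, g in enumerate(cv.gene_ids)}
    profiles: list[PathwayProfile] = []
    skipped = 0
    for name in pathways.names():
        mapped = [g for g in pathways[name] if g in index]
        if len(mapped) < min_genes:
            skipped += 1
            continue
        vals = np.array([cv.values[index[g]] for g in mapped])
        order = np.argsort(-vals, kind="stable")
        profiles.append(
            PathwayProfile(
                pathway=name,
                genes=[mapped[i] for i in order],
                cvs=vals[order],
                dominance=float(vals.mean()),
            )
        )
    if skipped:
        logger.warning("skipped %d pathways with fewer than %d mapped genes", skipped, min_genes)
    if not profiles:
        raise ValueError("no pathway maps at least %d genes into the matrix" % min_genes)
    return profiles


# -- single-sample switch scoring -----------------------------------------


def sample_switch_score(
    matrix: ExpressionMatrix,
    uf_genes: Sequence[str],
    lf_genes: Sequence[str],
    n_perm: int = 1000,
    rng_seed: int = 0,
    alpha: float = 0.05,
) -> list[SwitchScore]:
    """Place every sample on a switch from its tail-gene expression.

    Each gene is z-scored across samples; ``score_UF`` / ``score_LF`` are
    the mean z of the mapped UF / LF genes and ``delta`` their difference.
    The null draws ``n_perm`` random disjoint gene-set pairs of the same
    sizes from the matrix and computes the permutation probability of
    ``|delta|`` per sample, with the add-one rule (k+1)/(n_perm+1).  A
    sample is assigned UF when delta > 0 and p <= alpha, LF when delta < 0
    and p <= alpha, otherwise unassigned.
    """
    uf = [g for g in uf_genes if matrix.has_gene(g)]
    lf = [g for g in lf_genes if matrix.has_gene(g)]
    dropped = (len(list(uf_genes)) - len(uf)) + (len(list(lf_genes)) - len(lf))
    if dropped:
        logger.info("switch score: %d tail genes absent from matrix", dropped)
    if len(uf) < 3 or len(lf) < 3:
        raise ValueError("each tail must map at least 3 genes into the matrix")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    X = matrix.values
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd[sd <= 1e-12] = 1.0
    Z = (X - mu) / sd

    uf_rows = matrix.gene_rows(uf)
    lf_rows = matrix.gene_rows(lf)
    delta = Z[uf_rows].mean(axis=0) - Z[lf_rows].mean(axis=0)

    rng = np.random.default_rng(rng_seed)
    n_uf, n_lf = len(uf), len(lf)
    exceed = np.zeros(matrix.n_samples, dtype=int)
    abs_delta = np.abs(delta)
    for _ in range(n_perm):
        pick = rng.choice(matrix.n_genes, size=n_uf + n_lf, replace=False)
        d = Z[pick[:n_uf]].mean(axis=0) - Z[pick[n_uf:]].mean(axis=0)
        exceed += np.abs(d) >= abs_delta
    p = (exceed + 1) / (n_perm + 1)

    scores: list[SwitchScore] = []
    uf_mean = Z[uf_rows].mean(axis=0)
    lf_mean = Z[lf_rows].mean(axis=0)
    for j, sid in enumerate(matrix.sample_ids):
        if p[j] <= alpha and delta[j] > 0:
            position = "UF"
        elif p[j] <= alpha and delta[j] < 0:
            position = "LF"
        else:
            position = "unassigned"
        scores.append(
            SwitchScore(
                sample_id=sid,
                score_uf=float(uf_mean[j]),
                score_lf=float(lf_mean[j]),
                delta=float(delta[j]),
                p=float(p[j]),
                position=position,
            )
        )
    return scores
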