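"""Fork geometry, fork membership and switch topology.

Plotting PC1 against the rank index, a switch shows a bifurcating fork: the
upper fork (UF) expresses one anticorrelated gene group, the lower fork
(LF) the other.  The *forkscale* normalizes PC1 so the fork tips sit at
exactly +1 (UF tip) and -1 (LF tip); a small symmetric threshold on the
forkscale (default 0.04) decides fork membership.  Comparing fork sample
sets across biclusters distinguishes independent bistate switches from
multistate switches, where two biclusters share a fork (e.g. a common LF
with two distinct UFs — a tripolar distribution).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .extension import SampleRanking

logger = logging.getLogger("forkswitch")

__all__ = [
    "SwitchTopology",
    "compute_forkscale",
    "assign_forks",
    "intersect_fork_sets",
    "classify_switch_topology",
    "cross_fork_coordinates",
]


@dataclass
class SwitchTopology:
    """Fork-set intersection structure and bistate/multistate classification.

    ``exclusive_counts`` uses UpSet semantics: for every non-empty
    combination of fork memberships it counts the samples belonging to
    exactly that combination, so the counts sum to the size of the union of
    all fork samples.  ``merges`` records the cross-bicluster fork pairs
    whose Jaccard met the merge threshold, and ``state_groups`` the merged
    shared states.
    """

    bicluster_ids: list[str]
    fork_sets: dict[str, set[str]]
    exclusive_counts: dict[tuple[str, ...], int]
    jaccard: dict[tuple[str, str], float]
    merges: list[tuple[str, str, float]]
    state_groups: list[set[str]]
    classification: dict[str, str]


def compute_forkscale(pc1: np.ndarray) -> np.ndarray:
    """Normalize PC1 so the fork tips map to exactly +1 and -1.

    ``forkscale(s) = PC1(s)/max(PC1)`` for non-negative PC1 and
    ``PC1(s)/|min(PC1)|`` otherwise, extrema taken over all samples.  All-zero
    PC1 is a degenerate geometry error; a one-sided distribution (no
    positive or no negative values) is allowed with a warning.
    """
    pc1 = np.asarray(pc1, dtype=float)
    hi = float(pc1.max())
    lo = float(pc1.min())
    if hi <= 0 and lo >= 0:
        raise ValueError("degenerate fork geometry: all PC1 values are zero")
    if hi <= 0 or lo >= 0:
        logger.warning("one-sided PC1 distribution: only one fork is populated")
    out = np.zeros_like(pc1)
    if hi > 0:
        mask = pc1 >= 0
        out[mask] = pc1[mask] / hi
    if lo < 0:
        mask = pc1 < 0
        out[mask] = pc1[mask] / abs(lo)
    return out


def assign_forks(forkscale: np.ndarray, threshold: float = 0.04) -> np.ndarray:
    """Label samples UF / LF / NONE by thresholding the forkscale.

    A sample joins the upper fork when ``forkscale >= threshold`` and the
    lower fork when ``forkscale <= -threshold`` (boundaries inclusive).
    """
    if threshold <= 0:
        raise ValueError("fork threshold must be positive")
    forkscale = np.asarray(forkscale, dtype=float)
    labels = np.full(forkscale.shape, "NONE", dtype=object)
    labels[forkscale >= threshold] = "UF"
    labels[forkscale <= -threshold] = "LF"
    return labels


def label_ranking(ranking: SampleRanking, threshold: float = 0.04) -> SampleRanking:
    """Fill forkscale and fork labels on a ranking that has PC1 values."""
    if ranking.pc1 is None:
        raise ValueError("ranking has no PC1 values")
    ranking.forkscale = compute_forkscale(ranking.pc1)
    ranking.fork_labels = assign_forks(ranking.forkscale, threshold)
    return ranking


def intersect_fork_sets(
    fork_sets: Mapping[str, Iterable[str]],
) -> tuple[dict[tuple[str, ...], int], dict[tuple[str, str], float]]:
    """Exclusive (UpSet) intersection counts and pairwise Jaccard indices.

    For every combination of fork memberships, counts the samples belonging
    to exactly that combination of the named sets.
    """
    sets = {name: set(members) for name, members in fork_sets.items()}
    if len(sets) < 2:
        raise ValueError("need at least 2 fork sets to intersect")
    names = list(sets)
    counts: dict[tuple[str, ...], int] = {}
    union = set().union(*sets.values())
    for sample in union:
        key = tuple(n for n in names if sample in sets[n])
        counts[key] = counts.get(key, 0) + 1
    jaccard: dict[tuple[str, str], float] = {}
    for a, b in combinations(names, 2):
        inter = len(sets[a] & sets[b])
        uni = len(sets[a] | sets[b])
        jaccard[(a, b)] = inter / uni if uni else 0.0
    return counts, jaccard


def classify_switch_topology(
    fork_sets_by_bicluster: Mapping[str, tuple[Iterable[str], Iterable[str]]],
    merge_jaccard: float = 0.5,
) -> SwitchTopology:
    """Merge near-identical forks across biclusters and classify the switches.

    Every cross-bicluster fork pair with Jaccard >= ``merge_jaccard``
    (inclusive) is merged into one shared state.  Biclusters linked through
    a shared state are jointly *multistate* (a shared LF with two distinct
    UFs gives the tripolar pattern); unlinked biclusters are *bistate*.
    """
    fork_sets: dict[str, set[str]] = {}
    bicluster_of: dict[str, str] = {}
    for bid, (uf, lf) in fork_sets_by_bicluster.items():
        fork_sets[f"{bid}_UF"] = set(uf)
        fork_sets[f"{bid}_LF"] = set(lf)
        bicluster_of[f"{bid}_UF"] = bid
        bicluster_of[f"{bid}_LF"] = bid

    counts, jaccard = intersect_fork_sets(fork_sets)

    parent = {name: name for name in fork_sets}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    merges: list[tuple[str, str, float]] = []
    for (a, b), j in jaccard.items():
        if bicluster_of[a] != bicluster_of[b] and j >= merge_jaccard:
            merges.append((a, b, j))
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra

    groups: dict[str, set[str]] = {}
    for name in fork_sets:
        groups.setdefault(find(name), set()).add(name)
    state_groups = [g for g in groups.values() if len(g) > 1]

    bicluster_ids = list(fork_sets_by_bicluster)
    linked: dict[str, set[str]] = {bid: {bid} for bid in bicluster_ids}
    for g in state_groups:
        bids = {bicluster_of[n] for n in g}
        merged = set()
        for bid in bids:
            merged |= linked[bid]
        for bid in merged:
            linked[bid] = merged
    classification = {
        bid: "multistate" if len(linked[bid]) > 1 else "bistate"
        for bid in bicluster_ids
    }
    return SwitchTopology(
        bicluster_ids=bicluster_ids,
        fork_sets=fork_sets,
        exclusive_counts=counts,
        jaccard=jaccard,
        merges=merges,
        state_groups=state_groups,
        classification=classification,
    )


def cross_fork_coordinates(
    ranking_a: SampleRanking, ranking_b: SampleRanking
) -> pd.DataFrame:
    """Per-sample (forkscale_A, forkscale_B) pairs for 2-D switch plots."""
    if ranking_a.forkscale is None or ranking_b.forkscale is None:
        raise ValueError("both rankings need forkscale values")
    set_a, set_b = set(ranking_a.sample_ids), set(ranking_b.sample_ids)
    if set_a != set_b:
        missing = sorted((set_a ^ set_b))
        raise ValueError(f"sample universes differ; mismatched ids: {missing}")
    fb = dict(zip(ranking_b.sample_ids, ranking_b.forkscale))
    return pd.DataFrame(
        {
            "sample": list(ranking_a.sample_ids),
            "forkscale_a": np.asarray(ranking_a.forkscale, dtype=float),
            "forkscale_b": np.array([fb[s] for s in ranking_a.sample_ids]),
        }
    )
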