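"""Downstream summaries of subset collections.

Given a collection of (typically synergistic) subsets this module counts
node and node-pair participation, measures between-subset overlap with the
Jaccard index, clusters the overlap structure with k-means under the
silhouette criterion, and compares per-system participation with the
chance expectation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .gaussian_info import Subset

__all__ = [
    "SystemPartition",
    "membership_matrix",
    "ParticipationMap",
    "participation",
    "pair_participation",
    "jaccard_matrix",
    "cluster_subsets",
    "system_enrichment",
]


@dataclass(frozen=True)
class SystemPartition:
    """Assignment of every node to exactly one named functional system."""

    node_ids: tuple[str, ...]
    labels: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "node_ids", tuple(str(s) for s in self.node_ids))
        object.__setattr__(self, "labels", tuple(str(s) for s in self.labels))
        if len(self.node_ids) != len(self.labels):
            raise ValueError("one label per node is required")
        if len(self.labels) == 0:
            raise ValueError("partition cannot be empty")

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def systems(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for lab in self.labels:
            seen.setdefault(lab)
        return tuple(seen)

    def members(self, system: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.labels) == system)


@dataclass(frozen=True)
class ParticipationMap:
    """Per-node participation counts over a subset collection.

    Conservation: counts sum to k * n_subsets for fixed-size subsets.
    """

    counts: np.ndarray
    n_subsets: int
    k: int

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64).copy()
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)


def participation(subsets: Sequence[Subset], n_nodes: int) -> ParticipationMap:
    """Count how often each node appears across the collection."""
    counts = np.zeros(n_nodes, dtype=np.int64)
    k = len(subsets[0]) if subsets else 0
    for s in subsets:
        idx = s.as_array()
        if idx.max() >= n_nodes:
            raise IndexError(f"subset index {int(idx.max())} >= n_nodes={n_nodes}")
        counts[idx] += 1
    return ParticipationMap(counts=counts, n_subsets=len(subsets), k=k)


def pair_participation(subsets: Sequence[Subset], n_nodes: int) -> np.ndarray:
    """N x N symmetric matrix of co-membership counts over unordered pairs.

    Entry (a, b) counts the subsets containing both a and b; the diagonal
    is zero. The condensed upper triangle holds the N(N-1)/2 pair counts.
    """
    counts = np.zeros((n_nodes, n_nodes), dtype=np.int64)
    for s in subsets:
        idx = s.as_array()
        if idx.max() >= n_nodes:
            raise IndexError(f"subset index {int(idx.max())} >= n_nodes={n_nodes}")
        counts[np.ix_(idx, idx)] += 1
    np.fill_diagonal(counts, 0)
    return counts


def jaccard_matrix(subsets: Sequence[Subset]) -> np.ndarray:
    """Pairwise Jaccard similarity |A & B| / |A | B| between subsets."""
    if len(subsets) < 2:
        raise ValueError("need at least 2 subsets")
    sets = [set(s.indices) for s in subsets]
    if any(len(s) == 0 for s in sets):
        raise ValueError("empty subset in collection")
    m = len(sets)
    sim = np.eye(m)
    for a in range(m):
        for b in range(a + 1, m):
            inter = len(sets[a] & sets[b])
            union = len(sets[a]) + len(sets[b]) - inter
            sim[a, b] = sim[b, a] = inter / union
    return sim


def membership_matrix(subsets: Sequence[Subset], n_nodes: int) -> np.ndarray:
    """Binary subset-by-node membership matrix (alternative cluster features)."""
    m = np.zeros((len(subsets), n_nodes))
    for row, s in enumerate(subsets):
        m[row, s.as_array()] = 1.0
    return m


def cluster_subsets(
    similarity: np.ndarray,
    k_range: tuple[int, int] = (2, 30),
    repetitions: int = 100,
    seed: int = 0,
    features: np.ndarray | None = None,
) -> tuple[np.ndarray, int, dict[int, float]]:
    """K-means over rows of a similarity matrix, k chosen by silhouette.

    Each subset is represented by its row of Jaccard similarities (or by
    the rows of an explicit ``features`` matrix, e.g. binary memberships
    from :func:`membership_matrix`); for each candidate k the best of
    ``repetitions`` k-means initializations is kept and the mean silhouette
    is computed on distance = 1 - similarity. The k with the highest
    silhouette wins. Returns (labels, chosen k, silhouette per k).
    Degenerate input (all rows identical) collapses to a single cluster
    with a warning.
    """
    sim = np.asarray(similarity, dtype=float)
    if sim.ndim != 2 or sim.shape[0] != sim.shape[1]:
        raise ValueError("similarity must be square")
    if not np.allclose(sim, sim.T, atol=1e-10):
        raise ValueError("similarity must be symmetric")
    m = sim.shape[0]
    if features is None:
        features = sim
    elif features.shape[0] != m:
        raise ValueError("features must have one row per subset")
    if np.allclose(sim, sim[0], atol=1e-12):
        warnings.warn(
            "all rows of the similarity matrix are identical; returning one cluster",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.zeros(m, dtype=int), 1, {}

    dist = 1.0 - sim
    lo, hi = k_range
    hi = min(hi, m - 1)
    quality: dict[int, float] = {}
    best_labels: np.ndarray | None = None
    best_k = lo
    best_score = -np.inf
    rng = np.random.default_rng(seed)
    for k in range(lo, hi + 1):
        km = KMeans(
            n_clusters=k,
            n_init=repetitions,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        labels = km.fit_predict(features)
        if len(np.unique(labels)) < 2:
            continue
        score = float(silhouette_score(dist, labels, metric="precomputed"))
        quality[k] = score
        if score > best_score:
            best_score = score
            best_k = k
            best_labels = labels
    if best_labels is None:
        warnings.warn("clustering degenerated; returning one cluster", RuntimeWarning)
        return np.zeros(m, dtype=int), 1, quality
    return best_labels, best_k, quality


def system_enrichment(
    pmap: ParticipationMap, partition: SystemPartition
) -> dict[str, float]:
    """Per-system participation relative to chance.

    For each system, the mean nodal participation count is divided by the
    chance expectation k * n_subsets / N (uniform node selection). Ratios
    above 1 flag over-representation. Size-weighted ratios average to 1.
    """
    if partition.n_nodes != pmap.counts.shape[0]:
        raise ValueError("partition does not cover the participation map's nodes")
    n = partition.n_nodes
    expected = pmap.k * pmap.n_subsets / n
    if expected == 0:
        raise ValueError("empty subset collection; enrichment undefined")
    out: dict[str, float] = {}
    for system in partition.systems:
        members = partition.members(system)
        if members.size == 0:
            raise ValueError(f"system {system!r} has no nodes")
        out[system] = float(pmap.counts[members].mean() / expected)
    return out
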