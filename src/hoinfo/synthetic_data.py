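"""Gaussian synthetic systems with planted redundancy and synergy.

Ground truth for every downstream stage is defined analytically:

- **Redundant blocks** share a latent common cause. Each member loads on a
  unit-variance latent factor with loading ``lam``, giving every within-block
  pair correlation ``lam**2``; such blocks have positive O-information.
- **Synergy motifs** are common-child constructions: ``m`` mutually
  independent parents and a child equal to their standardized sum plus
  Gaussian noise of scale ``sigma_c``. The parents stay pairwise
  uncorrelated while each correlates ``1/sqrt(m + sigma_c**2)`` with the
  child, the canonical Gaussian structure with negative co-information.
- **Distractors** (all unassigned nodes) are independent.

Time series are iid frames from the implied multivariate normal — a static
joint distribution with no temporal memory.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fc_pipeline import TimeSeriesMatrix
from .gaussian_info import CorrelationMatrix, NotPositiveDefiniteError, Subset

__all__ = [
    "RedundantBlock",
    "SynergyMotif",
    "SyntheticSpec",
    "build_correlation",
    "sample_timeseries",
    "planted_benchmark",
    "redundancy_dominated_system",
    "segregated_synergy_system",
    "seven_system_cortex",
]


@dataclass(frozen=True)
class RedundantBlock:
    """Nodes sharing a latent common cause with loading ``lam`` in (0, 1)."""

    members: tuple[int, ...]
    lam: float

    def __post_init__(self):
        if not (0.0 < self.lam < 1.0):
            raise ValueError(f"loading must lie in (0, 1), got {self.lam}")
        if len(self.members) < 2:
            raise ValueError("a redundant block needs at least 2 members")
        if len(set(self.members)) != len(self.members):
            raise ValueError("block members must be distinct")
        object.__setattr__(self, "members", tuple(int(i) for i in self.members))


@dataclass(frozen=True)
class SynergyMotif:
    """Common-child motif: independent parents, child = scaled sum + noise."""

    parents: tuple[int, ...]
    child: int
    sigma_c: float = 0.25

    def __post_init__(self):
        if self.sigma_c <= 0.0:
            raise ValueError(f"child noise sigma_c must be > 0, got {self.sigma_c}")
        if len(self.parents) < 2:
            raise ValueError("a synergy motif needs at least 2 parents")
        members = set(self.parents) | {self.child}
        if len(members) != len(self.parents) + 1:
            raise ValueError("motif parents and child must be distinct nodes")
        object.__setattr__(self, "parents", tuple(int(i) for i in self.parents))
        object.__setattr__(self, "child", int(self.child))

    @property
    def members(self) -> tuple[int, ...]:
        return tuple(sorted((*self.parents, self.child)))

    @property
    def parent_child_correlation(self) -> float:
        m = len(self.parents)
        return 1.0 / math.sqrt(m + self.sigma_c**2)


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a planted-structure Gaussian system.

    Nodes not claimed by any block or motif are independent distractors.
    Blocks and motifs must not overlap: each node belongs to at most one
    structure so the implied correlation matrix is exactly block-diagonal
    (before the global factor) and its positive definiteness can be
    certified at build time.

    ``global_loading`` adds one system-wide latent factor: each member node
    becomes sqrt(1-g^2) * x_i + g * G, raising every member pair's
    correlation toward g^2. This emulates the globally redundant component
    of resting-state FC that makes the full cortex redundancy-dominated.
    ``global_members`` restricts the factor to a node subset (default: all
    nodes); excluding motif members reproduces the observed regime in which
    synergistic subsystems sit apart from the high-FC redundant core.
    """

    n_nodes: int
    redundant_blocks: tuple[RedundantBlock, ...] = ()
    synergy_motifs: tuple[SynergyMotif, ...] = ()
    global_loading: float = 0.0
    global_members: tuple[int, ...] | None = None
    t_points: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if not (0.0 <= self.global_loading < 1.0):
            raise ValueError(f"global_loading must lie in [0, 1), got {self.global_loading}")
        object.__setattr__(self, "redundant_blocks", tuple(self.redundant_blocks))
        object.__setattr__(self, "synergy_motifs", tuple(self.synergy_motifs))
        if self.global_members is not None:
            gm = tuple(sorted(int(i) for i in self.global_members))
            if gm and (gm[0] < 0 or gm[-1] >= self.n_nodes):
                raise ValueError("global_members out of range")
            object.__setattr__(self, "global_members", gm)
        claimed: set[int] = set()
        for struct in (*self.redundant_blocks, *self.synergy_motifs):
            members = set(struct.members)
            if members & claimed:
                raise ValueError(
                    f"nodes {sorted(members & claimed)} assigned to more than one structure"
                )
            if max(members) >= self.n_nodes or min(members) < 0:
                raise ValueError(f"structure members {sorted(members)} out of range")
            claimed |= members

    @property
    def global_member_indices(self) -> np.ndarray:
        if self.global_members is None:
            return np.arange(self.n_nodes)
        return np.asarray(self.global_members, dtype=np.intp)


def _structure_correlation(spec: SyntheticSpec) -> np.ndarray:
    corr = np.eye(spec.n_nodes)
    for block in spec.redundant_blocks:
        rho = block.lam**2
        for a in block.members:
            for b in block.members:
                if a != b:
                    corr[a, b] = rho
    for motif in spec.synergy_motifs:
        r = motif.parent_child_correlation
        for p in motif.parents:
            corr[p, motif.child] = r
            corr[motif.child, p] = r
    return corr


def build_correlation(spec: SyntheticSpec) -> CorrelationMatrix:
    """Analytic correlation matrix implied by the planted structures.

    With a global factor of loading g on member set M, entries become
    (1-g^2) rho + g^2 for pairs inside M, sqrt(1-g^2) rho for mixed pairs,
    and rho elsewhere.
    """
    corr = _structure_correlation(spec)
    g = spec.global_loading
    if g > 0.0:
        members = spec.global_member_indices
        scale = np.ones(spec.n_nodes)
        scale[members] = math.sqrt(1.0 - g * g)
        corr = corr * np.outer(scale, scale)
        corr[np.ix_(members, members)] += g * g
        np.fill_diagonal(corr, 1.0)
    try:
        return CorrelationMatrix(corr)
    except NotPositiveDefiniteError as err:
        raise ValueError(
            f"spec composition yields a non-PD matrix ({err}); "
            "check overlapping or extreme structures"
        ) from err


def sample_timeseries(
    spec: SyntheticSpec,
    n_runs: int = 1,
    sampling_interval: float | None = None,
) -> list[TimeSeriesMatrix]:
    """Draw iid multivariate-normal frames from the implied distribution.

    Returns ``n_runs`` independent runs of ``spec.t_points`` frames each,
    deterministic given ``spec.seed``.
    """
    if spec.t_points < 10 * spec.n_nodes:
        warnings.warn(
            f"t_points={spec.t_points} is below the recommended 10 x n_nodes "
            f"= {10 * spec.n_nodes}; empirical correlations will be noisy",
            RuntimeWarning,
            stacklevel=2,
        )
    corr = build_correlation(spec)
    chol = np.linalg.cholesky(corr.values)
    rng = np.random.default_rng(spec.seed)
    runs = []
    for r in range(n_runs):
        white = rng.standard_normal((spec.t_points, spec.n_nodes))
        runs.append(
            TimeSeriesMatrix(
                values=white @ chol.T,
                node_ids=corr.node_ids,
                sampling_interval=sampling_interval,
                run_id=f"run{r}",
            )
        )
    return runs


def planted_benchmark(
    n_distractors: int,
    motif_parents: int = 3,
    seed: int = 0,
    sigma_c: float = 0.25,
) -> tuple[CorrelationMatrix, Subset]:
    """One synergy motif among independent distractors, with ground truth.

    The motif occupies nodes 0..motif_parents (parents then child) and the
    remaining ``n_distractors`` nodes are independent. Node order is then
    shuffled (deterministically from ``seed``) so that the planted indices
    are not trivially the first ones. Returns the correlation matrix and the
    planted subset; on instances this small the motif can be certified as
    the unique O-information minimizer by exhaustive enumeration.
    """
    total = n_distractors + motif_parents + 1
    if total > 25:
        raise ValueError(
            f"benchmark capped at 25 nodes for exhaustive verification (got {total})"
        )
    spec = SyntheticSpec(
        n_nodes=total,
        synergy_motifs=(
            SynergyMotif(parents=tuple(range(motif_parents)), child=motif_parents, sigma_c=sigma_c),
        ),
        seed=seed,
    )
    corr = build_correlation(spec)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(total)
    vals = corr.values[np.ix_(perm, perm)]
    truth = Subset(int(np.flatnonzero(perm == i)[0]) for i in range(motif_parents + 1))
    return CorrelationMatrix(vals), truth


# ---------------------------------------------------------------------------
# preset study systems
#
# Scaled-down emulations of resting-state cortical FC: tens of nodes instead
# of hundreds, with the same qualitative architecture (a globally redundant
# background, strongly coupled redundant communities, and synergistic
# common-child subsystems whose internal FC is weak).


def redundancy_dominated_system() -> CorrelationMatrix:
    """30-node system where global redundancy swamps diluted synergy.

    Two 5-node redundant communities (loading 0.75), three triad motifs
    (2 parents + child, child noise 0.6), and a strong global factor
    (loading 0.7) on every node. The global factor is strong enough that
    adding any off-motif node to a synergistic triad tips its
    O-information positive, so the fraction of synergistic subsets
    collapses as subset size grows — the behaviour of whole-cortex FC,
    where the full 200-node matrix is heavily redundancy-dominated.
    """
    return build_correlation(
        SyntheticSpec(
            n_nodes=30,
            redundant_blocks=(
                RedundantBlock(tuple(range(5)), 0.75),
                RedundantBlock(tuple(range(5, 10)), 0.75),
            ),
            synergy_motifs=tuple(
                SynergyMotif((10 + 3 * i, 11 + 3 * i), 12 + 3 * i, 0.6) for i in range(3)
            ),
            global_loading=0.7,
        )
    )


def segregated_synergy_system() -> CorrelationMatrix:
    """30-node system whose synergistic subsystem has weak pairwise FC.

    A 5-parent common-child motif (child noise 0.35) sits outside the
    global factor (loading 0.6 on the other 24 nodes, which include two
    5-node redundant communities). Within the motif the parents are
    mutually uncorrelated and only modestly coupled to the child, so the
    synergistic subsystem is nearly invisible to pairwise FC while the
    redundant background carries all the strong correlations — node pairs
    with strong FC essentially never co-occur in synergistic subsets.
    """
    motif = SynergyMotif(tuple(range(10, 15)), 15, 0.35)
    return build_correlation(
        SyntheticSpec(
            n_nodes=30,
            redundant_blocks=(
                RedundantBlock(tuple(range(5)), 0.75),
                RedundantBlock(tuple(range(5, 10)), 0.75),
            ),
            synergy_motifs=(motif,),
            global_loading=0.6,
            global_members=tuple(i for i in range(30) if i not in motif.members),
        )
    )


def seven_system_cortex() -> tuple[CorrelationMatrix, list[str]]:
    """42-node system partitioned into 7 labeled functional systems.

    Each system holds a 4-node redundant core (loading 0.75) plus free
    slots; one 5-parent common-child motif is spread across six different
    systems' free slots and kept outside the global factor (loading 0.6).
    Within-system samples are purely redundant; only subsets spanning
    several systems can assemble the synergistic motif — the regime in
    which synergy lives between, not within, functional systems. Returns
    the matrix and the per-node system labels.
    """
    n_sys, per_sys = 7, 6
    n = n_sys * per_sys
    labels = [f"sys{s}" for s in range(n_sys) for _ in range(per_sys)]
    blocks = tuple(
        RedundantBlock(tuple(range(s * per_sys, s * per_sys + 4)), 0.75)
        for s in range(n_sys)
    )
    motif_nodes = [s * per_sys + 4 for s in range(6)]
    motif = SynergyMotif(tuple(motif_nodes[:5]), motif_nodes[5], 0.35)
    corr = build_correlation(
        SyntheticSpec(
            n_nodes=n,
            redundant_blocks=blocks,
            synergy_motifs=(motif,),
            global_loading=0.6,
            global_members=tuple(i for i in range(n) if i not in motif.members),
        )
    )
    return corr, labels
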