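"""Random sampling and simulated annealing over k-node subsets.

The search space is the set of k-element subsets of the N nodes of a
correlation matrix; the objective is one of the Gaussian information
measures (O-information, total correlation, dual total correlation)
evaluated on the principal submatrix, minimized or maximized.

Annealing follows a geometric cooling schedule T_c(h) = T0 * t_exp**h.
Each step proposes a candidate by replacing m nodes of the current subset
(m in {1, 2, 3} with configurable frequencies) with nodes drawn uniformly
from outside the subset. Strictly better candidates are always accepted;
worse ones with probability exp(-(C_new - C_current) / T_c).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .gaussian_info import (
    CorrelationMatrix,
    Subset,
    _logdet_and_loo,
    omega_from_values,
)

__all__ = [
    "AnnealConfig",
    "AnnealResult",
    "SampleReport",
    "OBJECTIVES",
    "random_subsets",
    "sample_synergy_fraction",
    "anneal",
    "exhaustive_extremum",
    "constrained_sample_by_systems",
]

# replacement-count frequencies; stated as 0.68/0.27/0.04 (sum 0.99) and
# renormalized to a proper distribution with the same ratios
DEFAULT_FLIP_PROBS = (0.68, 0.27, 0.04)


def _objective_tc(vals: np.ndarray) -> float:
    logdet, _ = _logdet_and_loo(vals)
    return -0.5 * logdet


def _objective_dtc(vals: np.ndarray) -> float:
    n = vals.shape[0]
    logdet, loo = _logdet_and_loo(vals)
    return 0.5 * ((1 - n) * logdet + float(np.sum(loo)))


OBJECTIVES = {
    "o_info": omega_from_values,
    "tc": _objective_tc,
    "dtc": _objective_dtc,
}


@dataclass(frozen=True)
class AnnealConfig:
    """Configuration of one simulated-annealing run."""

    k: int
    objective: str = "o_info"
    direction: str = "minimize"
    max_steps: int = 10_000
    t0: float = 1.0
    t_exp: float = 0.99925
    flip_probs: tuple[float, ...] = DEFAULT_FLIP_PROBS
    seed: int = 0

    def __post_init__(self):
        if self.objective not in OBJECTIVES:
            raise ValueError(
                f"objective must be one of {sorted(OBJECTIVES)}, got {self.objective!r}"
            )
        if self.direction not in ("minimize", "maximize"):
            raise ValueError(f"direction must be 'minimize' or 'maximize', got {self.direction!r}")
        if not (0.0 < self.t_exp < 1.0):
            raise ValueError(f"t_exp must lie in (0, 1), got {self.t_exp}")
        if self.t0 < 0.0:
            raise ValueError("t0 must be non-negative")
        if self.k < 3:
            raise ValueError(f"subset size k must be >= 3, got {self.k}")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")
        fp = np.asarray(self.flip_probs, dtype=float)
        if fp.ndim != 1 or fp.size < 1 or (fp < 0).any() or fp.sum() <= 0:
            raise ValueError("flip_probs must be non-negative with positive sum")
        object.__setattr__(self, "flip_probs", tuple(fp / fp.sum()))


@dataclass(frozen=True)
class AnnealResult:
    """Best-ever subset of one annealing run, plus its trace."""

    subset: Subset
    objective_value: float
    trace: tuple[tuple[int, float, float], ...]  # (step, current objective, temperature)
    accepted_moves: int
    seed: int
    converged_step: int  # step at which the best-ever subset was first reached
    rejected_nonfinite: int = 0

    def to_dict(self) -> dict:
        return {
            "subset": list(self.subset.indices),
            "objective_value": self.objective_value,
            "accepted_moves": self.accepted_moves,
            "seed": self.seed,
            "converged_step": self.converged_step,
        }


@dataclass(frozen=True)
class SampleReport:
    """Outcome of random subset sampling classified by O-information sign."""

    k: int
    n_sampled: int
    n_negative: int
    fraction_negative: float
    subsets_negative: tuple[Subset, ...]
    seed: int
    extrapolated_count: int = 0
    mean_omega: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "n_sampled": self.n_sampled,
            "n_negative": self.n_negative,
            "fraction_negative": self.fraction_negative,
            "extrapolated_count": self.extrapolated_count,
            "mean_omega": self.mean_omega,
            "seed": self.seed,
            "subsets_negative": [list(s.indices) for s in self.subsets_negative],
        }


def random_subsets(n_nodes: int, k: int, n_samples: int, seed: int) -> list[Subset]:
    """Draw ``n_samples`` uniform k-subsets of ``range(n_nodes)`` (with
    replacement across draws, without replacement within a draw)."""
    if k > n_nodes:
        raise ValueError(f"cannot draw {k}-subsets from {n_nodes} nodes")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    return [Subset(rng.choice(n_nodes, size=k, replace=False)) for _ in range(n_samples)]


def sample_synergy_fraction(
    corr: CorrelationMatrix,
    k: int,
    n_samples: int,
    seed: int,
    until_negatives: int | None = None,
) -> SampleReport:
    """Estimate the fraction of k-subsets with negative O-information.

    Classification is by strict omega < 0 with no dead band. The default
    mode draws a fixed total of ``n_samples`` subsets; with
    ``until_negatives`` set, sampling instead continues until that many
    negatives have been collected (``n_samples`` then acts as a hard cap on
    the total draws). The extrapolated absolute count is
    fraction * C(N, k), computed with exact integer arithmetic so it stays
    meaningful when C(N, k) overflows float.
    """
    if k < 3:
        raise ValueError("O-information sampling requires k >= 3")
    if k > corr.n_nodes:
        raise ValueError(f"cannot draw {k}-subsets from {corr.n_nodes} nodes")
    n = corr.n_nodes
    rng = np.random.default_rng(seed)
    vals = corr.values
    negatives: list[Subset] = []
    omegas: list[float] = []
    drawn = 0
    while drawn < n_samples:
        s = Subset(rng.choice(n, size=k, replace=False))
        idx = s.as_array()
        omega = omega_from_values(vals[np.ix_(idx, idx)])
        omegas.append(omega)
        drawn += 1
        if omega < 0.0:
            negatives.append(s)
            if until_negatives is not None and len(negatives) >= until_negatives:
                break
    frac = len(negatives) / drawn if drawn else 0.0
    extrapolated = (len(negatives) * math.comb(n, k)) // drawn if drawn else 0
    return SampleReport(
        k=k,
        n_sampled=drawn,
        n_negative=len(negatives),
        fraction_negative=frac,
        subsets_negative=tuple(negatives),
        seed=seed,
        extrapolated_count=extrapolated,
        mean_omega=float(np.mean(omegas)) if drawn else float("nan"),
    )


def anneal(corr: CorrelationMatrix, config: AnnealConfig) -> AnnealResult:
    """Extremize an information objective over k-subsets by simulated annealing.

    Starts from a uniformly random k-subset; runs ``config.max_steps`` steps
    of propose/accept with geometric cooling; returns the best-ever subset
    (not the terminal one). Fully reproducible from ``config.seed``. A
    candidate whose objective is non-finite (numerically singular submatrix)
    is rejected and counted, never fatal.
    """
    n = corr.n_nodes
    k = config.k
    if k >= n:
        raise ValueError(f"subset size {k} must be smaller than the {n}-node system")
    vals = corr.values
    rng = np.random.default_rng(config.seed)
    obj_fn = OBJECTIVES[config.objective]
    sign = 1.0 if config.direction == "minimize" else -1.0

    flip_sizes = np.arange(1, len(config.flip_probs) + 1)
    flip_probs = np.asarray(config.flip_probs)

    current = np.sort(rng.choice(n, size=k, replace=False))
    mask = np.zeros(n, dtype=bool)
    mask[current] = True

    def cost(idx: np.ndarray) -> float:
        try:
            return sign * obj_fn(vals[np.ix_(idx, idx)])
        except Exception:
            return float("nan")

    c_current = cost(current)
    if not np.isfinite(c_current):  # pathological start; re-draw a few times
        for _ in range(100):
            current = np.sort(rng.choice(n, size=k, replace=False))
            c_current = cost(current)
            if np.isfinite(c_current):
                break
        else:
            raise RuntimeError("could not find a finite-objective starting subset")
        mask[:] = False
        mask[current] = True

    best = current.copy()
    c_best = c_current
    best_step = 0
    accepted = 0
    rejected_nonfinite = 0
    trace: list[tuple[int, float, float]] = []

    for h in range(config.max_steps):
        t_c = config.t0 * config.t_exp**h
        m = int(rng.choice(flip_sizes, p=flip_probs))
        m = min(m, k, n - k)
        out_positions = rng.choice(k, size=m, replace=False)
        outside = np.flatnonzero(~mask)
        in_nodes = rng.choice(outside, size=m, replace=False)
        candidate = current.copy()
        candidate[out_positions] = in_nodes
        c_new = cost(candidate)

        if not np.isfinite(c_new):
            rejected_nonfinite += 1
        else:
            accept = c_new < c_current
            if not accept and t_c > 0.0:
                accept = rng.uniform() < math.exp(-(c_new - c_current) / t_c)
            if accept:
                mask[current[out_positions]] = False
                mask[in_nodes] = True
                current = np.sort(candidate)
                c_current = c_new
                accepted += 1
                if c_new < c_best:
                    c_best = c_new
                    best = current.copy()
                    best_step = h
        trace.append((h, sign * c_current, t_c))

    return AnnealResult(
        subset=Subset(best),
        objective_value=sign * c_best,
        trace=tuple(trace),
        accepted_moves=accepted,
        seed=config.seed,
        converged_step=best_step,
        rejected_nonfinite=rejected_nonfinite,
    )


def exhaustive_extremum(
    corr: CorrelationMatrix,
    k: int,
    objective: str = "o_info",
    direction: str = "minimize",
    max_subsets: int = 2_000_000,
) -> tuple[Subset, float]:
    """Ground-truth extremum over all C(N, k) subsets by enumeration.

    Intended for small benchmark instances; refuses problems larger than
    ``max_subsets`` candidate subsets.
    """
    n = corr.n_nodes
    total = math.comb(n, k)
    if total > max_subsets:
        raise ValueError(
            f"C({n},{k}) = {total} exceeds the enumeration bound {max_subsets}"
        )
    obj_fn = OBJECTIVES[objective]
    sign = 1.0 if direction == "minimize" else -1.0
    vals = corr.values
    best_cost = math.inf
    best_idx: tuple[int, ...] | None = None
    for comb in itertools.combinations(range(n), k):
        idx = np.asarray(comb, dtype=np.intp)
        c = sign * obj_fn(vals[np.ix_(idx, idx)])
        if c < best_cost:
            best_cost = c
            best_idx = comb
    assert best_idx is not None
    return Subset(best_idx), sign * best_cost


def constrained_sample_by_systems(
    corr: CorrelationMatrix,
    labels: np.ndarray | list[str],
    n_systems: int,
    k: int,
    n_samples: int,
    seed: int,
    max_retries: int = 1000,
) -> SampleReport:
    """Sample k-subsets constrained to span exactly ``n_systems`` systems.

    Each draw picks ``n_systems`` distinct system labels uniformly, then
    draws a uniform k-subset from the union of their nodes, rejecting draws
    that fail to include at least one node from every chosen system.
    Reports the mean O-information and the fraction with omega < 0.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != corr.n_nodes:
        raise ValueError("one system label per node is required")
    uniq = np.unique(labels)
    if n_systems > uniq.size:
        raise ValueError(f"{n_systems} systems requested but only {uniq.size} labels exist")
    if k < n_systems:
        raise ValueError(f"k={k} cannot touch {n_systems} distinct systems")
    rng = np.random.default_rng(seed)
    vals = corr.values
    negatives: list[Subset] = []
    omegas = np.empty(n_samples)
    for j in range(n_samples):
        for _ in range(max_retries):
            chosen = rng.choice(uniq, size=n_systems, replace=False)
            pool = np.flatnonzero(np.isin(labels, chosen))
            if pool.size < k:
                continue
            idx = np.sort(rng.choice(pool, size=k, replace=False))
            touched = np.unique(labels[idx])
            if touched.size == n_systems:
                break
        else:
            raise RuntimeError(
                f"failed to draw a {k}-subset spanning {n_systems} systems "
                f"after {max_retries} attempts"
            )
        omega = omega_from_values(vals[np.ix_(idx, idx)])
        omegas[j] = omega
        if omega < 0.0:
            negatives.append(Subset(idx))
    frac = len(negatives) / n_samples if n_samples else 0.0
    return SampleReport(
        k=k,
        n_sampled=n_samples,
        n_negative=len(negatives),
        fraction_negative=frac,
        subsets_negative=tuple(negatives),
        seed=seed,
        mean_omega=float(np.mean(omegas)) if n_samples else float("nan"),
    )
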