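"""Closed-form Gaussian estimators of multivariate information measures.

All measures operate on a correlation matrix. Because the underlying time
series are z-scored, the covariance matrix equals the correlation matrix and
every marginal has unit variance, so marginal entropies reduce to
``ln(2*pi*e)/2`` and the joint entropy of a subset is controlled entirely by
the log-determinant of its principal submatrix.

Measures (all in nats):

- joint entropy         H(X)  = ln[(2 pi e)^N |S|] / 2
- total correlation     TC(X) = sum_i H(X_i) - H(X) = -ln|S| / 2
- dual total corr.      DTC(X) = H(X) - sum_i H(X_i | X^-i)
- O-information         O(X) = TC(X) - DTC(X)   (redundancy minus synergy)
- S-information         S(X) = TC(X) + DTC(X) = sum_i I(X_i ; X^-i)
- description complexity C(X) = DTC(X) / N (the second-to-top TSE scale)
- TSE complexity        sum over scales of the mean bipartition MI

Positive O-information marks a redundancy-dominated ensemble; negative marks
a synergy-dominated one.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import linalg as sla

__all__ = [
    "CorrelationMatrix",
    "Subset",
    "InfoSummary",
    "NotPositiveDefiniteError",
    "LN_2PIE",
    "joint_entropy",
    "mutual_info_pair",
    "total_correlation",
    "dual_total_correlation",
    "o_information",
    "co_information",
    "description_complexity",
    "s_information",
    "tse_complexity",
    "subset_matrix",
    "info_summary",
]

LN_2PIE = math.log(2.0 * math.pi * math.e)

#: eigenvalues in (0, JITTER] get diagonal jitter instead of a hard failure
JITTER = 1e-10

DEFAULT_TSE_EXACT_CAP = 16


class NotPositiveDefiniteError(ValueError):
    """Raised when a correlation matrix is not positive definite.

    Carries the offending smallest eigenvalue in ``min_eigenvalue``.
    """

    def __init__(self, min_eigenvalue: float):
        self.min_eigenvalue = float(min_eigenvalue)
        super().__init__(
            "correlation matrix is not positive definite "
            f"(smallest eigenvalue {self.min_eigenvalue:.6g})"
        )


@dataclass(frozen=True)
class Subset:
    """Sorted, duplicate-free node indices into a correlation matrix."""

    indices: tuple[int, ...]

    def __init__(self, indices: Iterable[int]):
        idx = tuple(sorted(int(i) for i in indices))
        if len(idx) == 0:
            raise ValueError("subset must contain at least one node")
        if len(set(idx)) != len(idx):
            raise ValueError(f"subset indices must be distinct, got {idx}")
        if idx[0] < 0:
            raise ValueError(f"subset indices must be non-negative, got {idx}")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self):
        return iter(self.indices)

    def __contains__(self, i) -> bool:
        return int(i) in self.indices

    def as_array(self) -> np.ndarray:
        return np.asarray(self.indices, dtype=np.intp)


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric positive-definite correlation matrix with node labels.

    ``values`` must be symmetric with unit diagonal (both to 1e-12) and
    positive definite. If the smallest eigenvalue lies in ``(0, 1e-10]`` the
    matrix is repaired by adding 1e-10 of diagonal jitter (with a warning);
    a non-positive smallest eigenvalue is an error.
    """

    values: np.ndarray
    node_ids: tuple[str, ...]

    def __init__(self, values: np.ndarray, node_ids: Sequence[str] | None = None):
        vals = np.array(values, dtype=float)
        if vals.ndim != 2 or vals.shape[0] != vals.shape[1]:
            raise ValueError(f"correlation matrix must be square, got shape {vals.shape}")
        n = vals.shape[0]
        if not np.allclose(vals, vals.T, atol=1e-12, rtol=0.0):
            raise ValueError("correlation matrix must be symmetric within 1e-12")
        vals = (vals + vals.T) / 2.0
        if not np.allclose(np.diag(vals), 1.0, atol=1e-12, rtol=0.0):
            raise ValueError("correlation matrix must have unit diagonal within 1e-12")
        np.fill_diagonal(vals, 1.0)
        off = vals[~np.eye(n, dtype=bool)]
        if off.size and (np.abs(off) > 1.0 + 1e-12).any():
            raise ValueError("off-diagonal correlations must lie in [-1, 1]")

        try:
            np.linalg.cholesky(vals)
        except np.linalg.LinAlgError:
            lam_min = float(np.linalg.eigvalsh(vals)[0])
            # eigenvalues at numerical zero (e.g. the exactly rank-deficient
            # matrix left by global signal regression) are repairable;
            # genuinely negative ones are not
            if lam_min <= -1e-12 * n:
                raise NotPositiveDefiniteError(lam_min) from None
            warnings.warn(
                f"near-singular correlation matrix (min eigenvalue {lam_min:.3g}); "
                f"adding diagonal jitter {JITTER:g}",
                RuntimeWarning,
                stacklevel=2,
            )
            vals = vals + JITTER * np.eye(n)
            np.fill_diagonal(vals, 1.0 + JITTER)
            # renormalize back to unit diagonal
            d = np.sqrt(np.diag(vals))
            vals = vals / np.outer(d, d)
            np.fill_diagonal(vals, 1.0)
        else:
            lam_min = float(np.linalg.eigvalsh(vals)[0])
            if 0.0 < lam_min <= JITTER:
                warnings.warn(
                    f"near-singular correlation matrix (min eigenvalue {lam_min:.3g}); "
                    f"adding diagonal jitter {JITTER:g}",
                    RuntimeWarning,
                    stacklevel=2,
                )
                vals = vals + JITTER * np.eye(n)
                d = np.sqrt(np.diag(vals))
                vals = vals / np.outer(d, d)
                np.fill_diagonal(vals, 1.0)

        vals.setflags(write=False)
        if node_ids is None:
            node_ids = tuple(f"n{i}" for i in range(n))
        else:
            node_ids = tuple(str(s) for s in node_ids)
            if len(node_ids) != n:
                raise ValueError(
                    f"{len(node_ids)} node labels supplied for a {n}-node matrix"
                )
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "node_ids", node_ids)

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    def __len__(self) -> int:
        return self.n_nodes


@dataclass(frozen=True)
class InfoSummary:
    """Bundle of information measures for one subset, all in nats."""

    tc: float
    dtc: float
    o_info: float
    s_info: float
    c_desc: float
    n: int
    tse: float | None = None

    def to_dict(self) -> dict:
        d = {
            "tc": self.tc,
            "dtc": self.dtc,
            "o_info": self.o_info,
            "s_info": self.s_info,
            "c_desc": self.c_desc,
            "n": self.n,
        }
        if self.tse is not None:
            d["tse"] = self.tse
        return d


# ---------------------------------------------------------------------------
# log-determinant machinery


def _logdet(mat: np.ndarray) -> float:
    """Log-determinant via Cholesky; raises NotPositiveDefiniteError."""
    try:
        chol = np.linalg.cholesky(mat)
    except np.linalg.LinAlgError:
        lam_min = float(np.linalg.eigvalsh(mat)[0])
        raise NotPositiveDefiniteError(lam_min) from None
    return 2.0 * float(np.sum(np.log(np.diag(chol))))


def _logdet_and_loo(mat: np.ndarray) -> tuple[float, np.ndarray]:
    """Log-determinant of ``mat`` and of all leave-one-out submatrices.

    Uses the identity det(S_{-i}) = det(S) * (S^{-1})_{ii}, valid for any
    invertible S; for PD matrices the inverse diagonal is positive so the
    logarithms are well defined. One factorization serves all N removals.
    """
    try:
        cho = sla.cho_factor(mat, lower=True, check_finite=False)
    except sla.LinAlgError:
        lam_min = float(np.linalg.eigvalsh(mat)[0])
        raise NotPositiveDefiniteError(lam_min) from None
    logdet = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    inv = sla.cho_solve(cho, np.eye(mat.shape[0]), check_finite=False)
    loo = logdet + np.log(np.diag(inv))
    return logdet, loo


def _as_values(corr: CorrelationMatrix | np.ndarray) -> np.ndarray:
    if isinstance(corr, CorrelationMatrix):
        return corr.values
    return np.asarray(corr, dtype=float)


# ---------------------------------------------------------------------------
# measures


def joint_entropy(corr: CorrelationMatrix | np.ndarray) -> float:
    """Differential joint entropy of a zero-mean Gaussian, in nats."""
    vals = _as_values(corr)
    n = vals.shape[0]
    return 0.5 * (n * LN_2PIE + _logdet(vals))


def mutual_info_pair(rho: float) -> float:
    """Gaussian mutual information -ln(1 - rho^2)/2 between two variables."""
    rho = float(rho)
    if abs(rho) >= 1.0:
        raise ValueError(f"|rho| must be < 1 (got {rho}); the pair is singular")
    return -0.5 * math.log1p(-rho * rho)


def total_correlation(corr: CorrelationMatrix | np.ndarray) -> float:
    """Total correlation TC(X) = -ln|S|/2 for a correlation matrix S."""
    return -0.5 * _logdet(_as_values(corr))


def dual_total_correlation(corr: CorrelationMatrix | np.ndarray) -> float:
    """Dual total correlation: joint entropy minus summed residual entropies.

    For unit-variance Gaussians the ln(2*pi*e) terms cancel and
    DTC = [(1 - N) ln|S| + sum_i ln|S_{-i}|] / 2.
    """
    vals = _as_values(corr)
    n = vals.shape[0]
    if n < 2:
        raise ValueError("dual total correlation requires at least 2 nodes")
    logdet, loo = _logdet_and_loo(vals)
    return 0.5 * ((1 - n) * logdet + float(np.sum(loo)))


def o_information(corr: CorrelationMatrix | np.ndarray) -> float:
    """O-information O(X) = TC(X) - DTC(X).

    Positive values indicate redundancy-dominated structure, negative values
    synergy-dominated structure. For fewer than 3 nodes the measure is
    identically zero; a warning is emitted and 0.0 returned.
    """
    vals = _as_values(corr)
    n = vals.shape[0]
    if n < 3:
        warnings.warn(
            f"O-information is identically 0 for {n} < 3 nodes",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    logdet, loo = _logdet_and_loo(vals)
    tc = -0.5 * logdet
    dtc = 0.5 * ((1 - n) * logdet + float(np.sum(loo)))
    return tc - dtc


def co_information(corr: CorrelationMatrix | np.ndarray) -> float:
    """Three-variable co-information via inclusion-exclusion over entropies.

    I(X1;X2;X3) = sum H(Xi) - sum H(pairs) + H(X1,X2,X3); equals the
    O-information for exactly three variables (redundancy minus synergy).
    """
    vals = _as_values(corr)
    if vals.shape[0] != 3:
        raise ValueError(f"co-information is defined for exactly 3 nodes, got {vals.shape[0]}")
    h1 = 3 * (0.5 * LN_2PIE)
    h2 = 0.0
    for i, j in itertools.combinations(range(3), 2):
        h2 += joint_entropy(vals[np.ix_([i, j], [i, j])])
    h3 = joint_entropy(vals)
    return h1 - h2 + h3


def description_complexity(corr: CorrelationMatrix | np.ndarray) -> float:
    """Description complexity C(X) = TC(X) - TC(X)/N - mean_i TC(X^-i).

    The second-to-top scale of the TSE curve; analytically equal to DTC/N.
    """
    vals = _as_values(corr)
    n = vals.shape[0]
    if n < 2:
        raise ValueError("description complexity requires at least 2 nodes")
    logdet, loo = _logdet_and_loo(vals)
    tc = -0.5 * logdet
    mean_tc_loo = float(np.mean(-0.5 * loo))
    return tc - tc / n - mean_tc_loo


def s_information(corr: CorrelationMatrix | np.ndarray) -> float:
    """S-information (exogenous information) S(X) = TC(X) + DTC(X)."""
    vals = _as_values(corr)
    n = vals.shape[0]
    if n < 2:
        raise ValueError("S-information requires at least 2 nodes")
    logdet, loo = _logdet_and_loo(vals)
    tc = -0.5 * logdet
    dtc = 0.5 * ((1 - n) * logdet + float(np.sum(loo)))
    return tc + dtc


def _scale_mean_mi(vals: np.ndarray, logdet_full: float, subsets: Iterable[tuple[int, ...]]) -> float:
    """Mean bipartition MI over the given same-size subsets."""
    n = vals.shape[0]
    total = 0.0
    count = 0
    all_idx = np.arange(n)
    for gamma in subsets:
        g = np.asarray(gamma, dtype=np.intp)
        comp = np.setdiff1d(all_idx, g, assume_unique=True)
        ld_g = _logdet(vals[np.ix_(g, g)]) if len(g) > 1 else 0.0
        ld_c = _logdet(vals[np.ix_(comp, comp)]) if len(comp) > 1 else 0.0
        # I(gamma; complement) = H(g) + H(c) - H(full); entropy constants cancel
        total += 0.5 * (ld_g + ld_c - logdet_full)
        count += 1
    return total / count


def tse_complexity(
    corr: CorrelationMatrix | np.ndarray,
    mode: str = "exact",
    samples_per_scale: int = 1000,
    seed: int | None = None,
    exact_cap: int = DEFAULT_TSE_EXACT_CAP,
) -> float:
    """TSE complexity: summed mean bipartition mutual information per scale.

    For every scale i = 1..floor(N/2) the mutual information I(X^g; X^-g)
    is averaged over subsets g of size i and the scale means are summed.
    When N is even the middle scale i = N/2 enters with weight 1/2, because
    each unordered bipartition at that scale corresponds to two subsets;
    with this weighting the bipartition form agrees exactly with the
    per-scale total-correlation form (i/N * TC(X) - E[TC(X^g)] summed over
    i = 1..N).

    ``mode="exact"`` enumerates all subsets per scale (allowed up to
    ``exact_cap`` nodes, default 16); ``mode="sampled"`` draws
    ``samples_per_scale`` uniform subsets per scale.
    """
    vals = _as_values(corr)
    n = vals.shape[0]
    if n < 2:
        return 0.0
    if mode not in ("exact", "sampled"):
        raise ValueError(f"mode must be 'exact' or 'sampled', got {mode!r}")
    if mode == "exact" and n > exact_cap:
        raise ValueError(
            f"exact TSE enumeration is capped at {exact_cap} nodes (got {n}); "
            "use mode='sampled'"
        )
    if mode == "sampled" and samples_per_scale < 1:
        raise ValueError("samples_per_scale must be >= 1")

    logdet_full = _logdet(vals)
    rng = np.random.default_rng(seed)
    tse = 0.0
    for i in range(1, n // 2 + 1):
        if mode == "exact":
            gammas: Iterable[tuple[int, ...]] = itertools.combinations(range(n), i)
        else:
            gammas = [
                tuple(rng.choice(n, size=i, replace=False))
                for _ in range(samples_per_scale)
            ]
        mean_mi = _scale_mean_mi(vals, logdet_full, gammas)
        weight = 0.5 if (n % 2 == 0 and i == n // 2) else 1.0
        tse += weight * mean_mi
    return tse


def subset_matrix(corr: CorrelationMatrix, subset: Subset | Sequence[int]) -> CorrelationMatrix:
    """Principal submatrix restricted to ``subset``, labels carried along."""
    if not isinstance(subset, Subset):
        subset = Subset(subset)
    idx = subset.as_array()
    if idx.max() >= corr.n_nodes:
        raise IndexError(
            f"subset index {int(idx.max())} out of range for {corr.n_nodes}-node matrix"
        )
    sub = corr.values[np.ix_(idx, idx)]
    labels = [corr.node_ids[i] for i in idx]
    return CorrelationMatrix(sub, labels)


def info_summary(
    corr: CorrelationMatrix | np.ndarray,
    subset: Subset | Sequence[int] | None = None,
    with_tse: bool = False,
    tse_mode: str = "exact",
    tse_samples_per_scale: int = 1000,
    seed: int | None = None,
) -> InfoSummary:
    """Compute the full measure bundle for a matrix or one of its subsets."""
    if subset is not None:
        if not isinstance(corr, CorrelationMatrix):
            corr = CorrelationMatrix(corr)
        corr = subset_matrix(corr, subset)
    vals = _as_values(corr)
    n = vals.shape[0]
    if n < 2:
        return InfoSummary(tc=0.0, dtc=0.0, o_info=0.0, s_info=0.0, c_desc=0.0, n=n,
                           tse=0.0 if with_tse else None)
    logdet, loo = _logdet_and_loo(vals)
    tc = -0.5 * logdet
    dtc = 0.5 * ((1 - n) * logdet + float(np.sum(loo)))
    tse = None
    if with_tse:
        tse = tse_complexity(vals, mode=tse_mode,
                             samples_per_scale=tse_samples_per_scale, seed=seed)
    return InfoSummary(tc=tc, dtc=dtc, o_info=tc - dtc, s_info=tc + dtc,
                       c_desc=dtc / n, n=n, tse=tse)


def omega_from_values(vals: np.ndarray) -> float:
    """O-information of a raw (already validated) PD array; no warnings.

    Fast path for inner loops (annealing, mass sampling): one Cholesky
    factorization yields the full log-determinant and, through the inverse
    diagonal, every leave-one-out log-determinant.
    """
    n = vals.shape[0]
    if n < 3:
        return 0.0
    logdet, loo = _logdet_and_loo(vals)
    tc = -0.5 * logdet
    dtc = 0.5 * ((1 - n) * logdet + float(np.sum(loo)))
    return tc - dtc
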