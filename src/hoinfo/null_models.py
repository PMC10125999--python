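"""Irreducibility null model for candidate synergistic subsets.

A k-node subset with negative O-information may owe its synergy to a
smaller core: for instance, a synergistic triad plus two independent nodes
still shows omega < 0 at k = 5. A subset is *irreducible* (valid) when
removing any single node increases the O-information of the remainder —
every node contributes synergy. Nodes whose removal leaves omega unchanged
or lowers it mark the subset as reducible.

Two equivalent removal mechanics are provided: excluding the node (taking
the (k-1)-node principal submatrix) and knocking it out (zeroing its
correlations while keeping it in the matrix). For Gaussian systems a node
uncorrelated with the rest contributes nothing to TC or DTC, so both give
identical O-information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gaussian_info import CorrelationMatrix, Subset, omega_from_values, subset_matrix

__all__ = ["ValidityReport", "knockout_node", "irreducibility_check"]

DEFAULT_TOLERANCE = 1e-10


@dataclass(frozen=True)
class ValidityReport:
    """Per-node removal deltas and the resulting validity flag.

    ``valid`` is true iff every single-node removal increases the
    O-information by more than the tolerance; exact ties count as reducible.
    """

    subset: Subset
    omega_full: float
    omega_without: tuple[float, ...]
    delta: tuple[float, ...]
    valid: bool
    tolerance: float = DEFAULT_TOLERANCE

    def to_dict(self) -> dict:
        return {
            "subset": list(self.subset.indices),
            "omega_full": self.omega_full,
            "omega_without": list(self.omega_without),
            "delta": list(self.delta),
            "valid": self.valid,
        }


def knockout_node(
    corr: CorrelationMatrix, subset: Subset, i: int
) -> CorrelationMatrix:
    """Subset submatrix with node ``i``'s correlations zeroed.

    The returned matrix keeps all k nodes but disconnects node ``i`` from
    the rest (off-diagonals of its row and column set to zero, unit diagonal
    kept). The result is block-diagonal in {i} and the rest, hence remains
    positive definite.
    """
    if i not in subset:
        raise ValueError(f"node {i} is not a member of subset {subset.indices}")
    sub = subset_matrix(corr, subset)
    pos = subset.indices.index(int(i))
    vals = np.array(sub.values)
    vals[pos, :] = 0.0
    vals[:, pos] = 0.0
    vals[pos, pos] = 1.0
    return CorrelationMatrix(vals, sub.node_ids)


def irreducibility_check(
    corr: CorrelationMatrix,
    subset: Subset,
    tolerance: float = DEFAULT_TOLERANCE,
    mechanism: str = "exclusion",
) -> ValidityReport:
    """Test whether every node of ``subset`` contributes synergy.

    For each member node, the O-information of the subset with that node
    removed is computed (``mechanism="exclusion"``: (k-1)-node submatrix;
    ``mechanism="knockout"``: correlations zeroed — analytically identical
    for Gaussians). The subset is valid iff every removal raises the
    O-information by more than ``tolerance`` nats.
    """
    if len(subset) < 4:
        raise ValueError(
            f"irreducibility requires subsets of >= 4 nodes (got {len(subset)}) "
            "so that every removal leaves at least 3"
        )
    if mechanism not in ("exclusion", "knockout"):
        raise ValueError(f"mechanism must be 'exclusion' or 'knockout', got {mechanism!r}")
    sub = subset_matrix(corr, subset)
    omega_full = omega_from_values(sub.values)
    k = len(subset)
    omega_without: list[float] = []
    for pos in range(k):
        if mechanism == "exclusion":
            keep = [p for p in range(k) if p != pos]
            vals = sub.values[np.ix_(keep, keep)]
        else:
            vals = np.array(sub.values)
            vals[pos, :] = 0.0
            vals[:, pos] = 0.0
            vals[pos, pos] = 1.0
        omega_without.append(omega_from_values(vals))
    delta = tuple(ow - omega_full for ow in omega_without)
    valid = all(d > tolerance for d in delta)
    return ValidityReport(
        subset=subset,
        omega_full=omega_full,
        omega_without=tuple(omega_without),
        delta=delta,
        valid=valid,
        tolerance=tolerance,
    )
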