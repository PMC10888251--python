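"""Steady states of unicyclic kinetic schemes by the diagram method.

For a single catalytic cycle with n states the stationary occupancy of
state i is p_i = Sigma_i / Sigma, where Sigma_i sums, over all spanning
trees of the cycle graph, the product of rate constants along the tree's
edges directed toward state i (King-Altman / Hill directional diagrams),
and Sigma = Sigma_1 + ... + Sigma_n.  The net cycle flux is

    J = (k_1 k_3 ... k_{2n-1} - k_2 k_4 ... k_{2n}) / Sigma

in cycles per enzyme per second; its sign is positive for net
substrate-to-product turnover.

A cycle graph has exactly n spanning trees (delete any one of the n
undirected edges), so the directional sums are enumerated explicitly
rather than transcribed per n.  An independent cross-check,
:func:`steady_state_oracle`, solves the stationary master equation by a
rate-matrix null space instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.linalg import null_space

from .registry import RateSet

__all__ = ["SteadyState", "directional_sums", "steady_state", "steady_state_oracle"]


@dataclass(frozen=True)
class SteadyState:
    """Occupancies p_1..p_n, net cycle flux J (s^-1) and diagram sums."""

    occupancies: np.ndarray
    flux: float
    diagram_sums: np.ndarray
    total_sum: float


@lru_cache(maxsize=None)
def _tree_rate_indices(n: int) -> tuple:
    """0-based rate-constant indices of every directional diagram.

    For each root state r the n spanning trees of the n-cycle are obtained
    by deleting one transition d; the surviving transitions form a path
    whose edges are oriented toward the root.  Transition t (joining
    states t and t+1, 0-based) contributes its forward constant k_{2t+1}
    when the root lies on the t+1 side of the path and its backward
    constant k_{2t+2} otherwise.  Transitions are kept distinct by index,
    so the two parallel transitions of the 2-state cycle are handled
    correctly.
    """
    per_root = []
    for root in range(n):
        trees = []
        for removed in range(n):
            pos_root = (root - removed - 1) % n
            idx = []
            for t in range(n):
                if t == removed:
                    continue
                q = (t - removed - 1) % n  # position of state t on the path
                idx.append(2 * t if pos_root > q else 2 * t + 1)
            trees.append(tuple(idx))
        per_root.append(tuple(trees))
    return tuple(per_root)


def directional_sums(rates: RateSet) -> tuple[np.ndarray, float]:
    """Per-state directional-diagram sums Sigma_i and their total Sigma."""
    n = rates.n_states
    sums = np.empty(n)
    for root, trees in enumerate(_tree_rate_indices(n)):
        sums[root] = float(
            np.sum([np.prod(rates.k[list(tree)]) for tree in trees])
        )
    return sums, float(np.sum(sums))


def steady_state(rates: RateSet) -> SteadyState:
    """Stationary occupancies and net cycle flux by the diagram method."""
    sums, total = directional_sums(rates)
    p = sums / total
    forward = float(np.prod(rates.forward()))
    backward = float(np.prod(rates.backward()))
    flux = (forward - backward) / total
    return SteadyState(occupancies=p, flux=flux, diagram_sums=sums, total_sum=total)


def steady_state_oracle(rates: RateSet) -> SteadyState:
    """Independent steady state from the stationary master equation.

    Builds the rate matrix W (W_ij = rate j->i for i != j, columns summing
    to zero), verifies the null space is one-dimensional, then solves
    W p = 0 with the normalization sum(p) = 1 by Gaussian elimination in
    extended precision (so occupancies spanning many decades keep full
    relative accuracy), and reads the flux off the first transition.
    """
    n = rates.n_states
    W = np.zeros((n, n), dtype=np.longdouble)
    k = rates.k.astype(np.longdouble)
    for i in range(n):
        j = (i + 1) % n
        kf = k[2 * i]      # i -> i+1
        kb = k[2 * i + 1]  # i+1 -> i
        W[j, i] += kf
        W[i, i] -= kf
        W[i, j] += kb
        W[j, j] -= kb
    if null_space(W.astype(float)).shape[1] != 1:
        raise np.linalg.LinAlgError(
            "stationary distribution is not unique for this rate matrix"
        )
    # replace one balance row with the normalization constraint
    A = W.copy()
    A[0, :] = 1.0
    b = np.zeros(n, dtype=np.longdouble)
    b[0] = 1.0
    p = _solve_extended(A, b)
    flux = k[0] * p[0] - k[1] * p[1]
    sums, total = directional_sums(rates)
    return SteadyState(
        occupancies=p.astype(float),
        flux=float(flux),
        diagram_sums=sums,
        total_sum=total,
    )


def _solve_extended(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Gaussian elimination with partial pivoting in numpy longdouble."""
    A = A.copy()
    b = b.copy()
    n = len(b)
    for col in range(n):
        pivot = col + int(np.argmax(np.abs(A[col:, col])))
        if A[pivot, col] == 0:
            raise np.linalg.LinAlgError("singular stationary system")
        if pivot != col:
            A[[col, pivot]] = A[[pivot, col]]
            b[[col, pivot]] = b[[pivot, col]]
        for row in range(col + 1, n):
            factor = A[row, col] / A[col, col]
            A[row, col:] -= factor * A[col, col:]
            b[row] -= factor * b[col]
    x = np.zeros(n, dtype=np.longdouble)
    for row in range(n - 1, -1, -1):
        x[row] = (b[row] - A[row, row + 1:] @ x[row + 1:]) / A[row, row]
    return x
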