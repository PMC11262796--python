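"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive (enumeration, double loops) and never
shares code with the package under test.
"""

from __future__ import annotations

import itertools
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.linalg import null_space


def enumerate_polytope_vertices(
    S: np.ndarray, lb: np.ndarray, ub: np.ndarray, tol: float = 1e-9
) -> np.ndarray:
    """All vertices of {v : S v = 0, lb <= v <= ub} by basis enumeration.

    Parameterises the null space of S (v = N x, dim k) and intersects every
    choice of k box-constraint hyperplanes; feasible intersection points are
    vertices.  Only viable for tiny networks (r <= ~8).
    """
    r = S.shape[1]
    N = null_space(S)
    k = N.shape[1]
    if k == 0:
        return np.zeros((1, r))
    # constraint rows: N x <= ub  and  -N x <= -lb
    A = np.vstack([N, -N])
    b = np.concatenate([ub, -lb])
    vertices = []
    for rows in itertools.combinations(range(A.shape[0]), k):
        M = A[list(rows)]
        if np.linalg.matrix_rank(M) < k:
            continue
        x = np.linalg.lstsq(M, b[list(rows)], rcond=None)[0]
        if np.max(np.abs(M @ x - b[list(rows)])) > tol:
            continue
        if (A @ x <= b + tol).all():
            vertices.append(N @ x)
    if not vertices:
        return np.zeros((0, r))
    return np.array(vertices)


def brute_force_max_flux(
    S: np.ndarray, lb: np.ndarray, ub: np.ndarray, j: int
) -> Optional[float]:
    """Max of coordinate j over the polytope via vertex enumeration; None
    when the polytope has no vertices within tolerance."""
    V = enumerate_polytope_vertices(S, lb, ub)
    if V.shape[0] == 0:
        return None
    return float(V[:, j].max())


def brute_force_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up by explicit min-over-tails double loop."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_idx, i in enumerate(order):
        candidates = []
        for later_rank in range(rank_idx, m):
            jj = order[later_rank]
            candidates.append(p[jj] * m / (later_rank + 1))
        q[i] = min(1.0, min(candidates))
    return q


def brute_force_gpr(expr_tree, assignment: Dict[str, bool]) -> bool:
    """Two-valued evaluation of a nested (op, children) / gene tuple tree."""
    kind = expr_tree[0]
    if kind == "gene":
        return assignment[expr_tree[1]]
    values = [brute_force_gpr(c, assignment) for c in expr_tree[1]]
    return all(values) if kind == "and" else any(values)


def random_small_network(rng: np.random.Generator):
    """A random bounded, feasible network with <= 8 reactions.

    Bounds straddle zero so v = 0 is always feasible, and the finite box
    keeps the polytope bounded — the regime vertex enumeration can certify.
    """
    r = int(rng.integers(3, 9))
    m = int(rng.integers(2, max(3, r - 1)))
    while True:
        S = np.zeros((m, r))
        for j in range(r):
            k = int(rng.integers(1, min(3, m) + 1))
            rows = rng.choice(m, size=k, replace=False)
            S[rows, j] = rng.choice([-2, -1, 1, 2], size=k)
        if np.linalg.matrix_rank(S) < min(m, r):
            continue
        lb = -rng.integers(0, 11, size=r).astype(float)
        ub = rng.integers(1, 11, size=r).astype(float)
        return S, lb, ub
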