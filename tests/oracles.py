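"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's own solver paths: the transportation
optimum is found by enumerating basic feasible solutions (vertices of the
transportation polytope), which is exact for the tiny supports the tests
use.
"""

from itertools import combinations

import numpy as np


def transport_bruteforce(a, b, C, tol=1e-9):
    """Exact transportation optimum via vertex enumeration.

    A vertex of the transportation polytope is supported on at most
    m + n - 1 cells; enumerate every cell subset of that size, solve the
    flow equations, keep feasible solutions, return the minimum cost.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    C = np.asarray(C, dtype=float)
    m, n = C.shape
    cells = [(i, j) for i in range(m) for j in range(n)]
    k = m + n - 1
    best = np.inf
    for basis in combinations(cells, k):
        # rows: row sums (m) + col sums (n-1, last redundant)
        A = np.zeros((m + n - 1, k))
        for col, (i, j) in enumerate(basis):
            A[i, col] = 1.0
            if j < n - 1:
                A[m + j, col] = 1.0
        rhs = np.concatenate([a, b[:-1]])
        sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
        if np.max(np.abs(A @ sol - rhs)) > tol:
            continue  # singular / infeasible basis
        if sol.min() < -tol:
            continue
        cost = sum(C[i, j] * max(t, 0.0) for (i, j), t in zip(basis, sol))
        best = min(best, cost)
    return best


def pairwise_independent_cost(a, b, C):
    """Cost of the independent coupling T = a b^T — a feasible upper bound."""
    return float(np.asarray(a) @ np.asarray(C) @ np.asarray(b))
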