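"""Independent geometric oracles for validating the envelopment LP.

Two routes that never touch :func:`scipy.optimize.linprog`:

* :func:`hull_oracle_1in_1out` — for one input and one output the VRS
  frontier is the least concave monotone envelope of the observed points;
  the Farrell distance is frontier(x_i) / y_i, computable by elementary
  geometry.
* :func:`vertex_oracle` — brute-force enumeration of the vertices of the
  envelopment polytope (every maximal set of active constraints is solved
  as a linear system with numpy); the optimum of a bounded LP is attained
  at a vertex, so the best feasible vertex is the exact answer.  Only
  usable on small instances (cost grows combinatorially in n).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def hull_oracle_1in_1out(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Farrell output distances from the concave-hull frontier (1 input, 1 output).

    The VRS output frontier at x0 is

        F(x0) = max { sum lam_i y_i : sum lam_i x_i <= x0, sum lam = 1, lam >= 0 }

    In one dimension an optimal lam needs at most two support points, so
    F(x0) is the maximum over single points with x_i <= x0 and over all
    pair chords evaluated at x0.  Duplicated x with conflicting y is
    resolved by the maximum (dominated points never support the hull).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or len(x) != len(y):
        raise ValueError("x and y must be 1-D vectors of equal length")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("oracle requires strictly positive data")
    n = len(x)
    theta = np.empty(n)
    for o in range(n):
        x0 = x[o]
        best = np.max(y[x <= x0])  # single support points
        for i in range(n):
            for j in range(i + 1, n):
                xi, xj = x[i], x[j]
                if xi == xj:
                    continue
                if min(xi, xj) <= x0 <= max(xi, xj):
                    t = (x0 - xi) / (xj - xi)
                    best = max(best, y[i] + t * (y[j] - y[i]))
        theta[o] = best / y[o]
    return theta


def vertex_oracle(
    X: np.ndarray,
    Y: np.ndarray,
    dmu_index: int,
    returns_to_scale: str = "vrs",
    feas_tol: float = 1e-7,
) -> float:
    """Exact Farrell distance by enumerating vertices of the envelopment polytope.

    Variables z = (theta, lam_1..lam_n).  Constraints:

        theta * y0 - Y' lam <= 0      (q rows)
        X' lam            <= x0      (p rows)
        -lam              <= 0       (n rows)
        -theta            <= 0       (1 row)
        sum lam            = 1       (VRS only)

    Every vertex is the solution of d linearly independent active
    constraints (d = n + 1); we enumerate all candidate active sets,
    solve the square systems, keep feasible solutions and return the
    maximal theta.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.ndim == 2 and X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    n, p = X.shape
    q = Y.shape[1]
    d = n + 1
    x0, y0 = X[dmu_index], Y[dmu_index]
    vrs = returns_to_scale == "vrs"

    # inequality system G z <= h
    G = np.zeros((q + p + n + 1, d))
    h = np.zeros(q + p + n + 1)
    G[:q, 0] = y0
    G[:q, 1:] = -Y.T
    G[q : q + p, 1:] = X.T
    h[q : q + p] = x0
    G[q + p : q + p + n, 1:] = -np.eye(n)
    G[q + p + n, 0] = -1.0

    rows = list(range(G.shape[0]))
    n_free = d - (1 if vrs else 0)
    best = -np.inf
    for active in combinations(rows, n_free):
        A = G[list(active)]
        b = h[list(active)]
        if vrs:
            eq = np.zeros(d)
            eq[1:] = 1.0
            A = np.vstack([A, eq])
            b = np.append(b, 1.0)
        try:
            z = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            continue
        if not np.all(np.isfinite(z)):
            continue
        if np.all(G @ z <= h + feas_tol):
            if vrs and abs(z[1:].sum() - 1.0) > feas_tol:
                continue
            best = max(best, z[0])
    if not np.isfinite(best):
        raise RuntimeError("no feasible vertex found (degenerate instance?)")
    return best
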