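"""Brute-force LP oracle: exhaustive enumeration of basic feasible solutions.

Independent of scipy.optimize.linprog (pure numpy linear algebra): every
vertex of {v : S v = 0, l <= v <= u} has at least n - rank(S) variables
pinned at a bound, so enumerating all such pinnings and solving the
remaining square-ish system visits every vertex.  For a bounded feasible
LP the optimum is attained at a vertex.
"""
import itertools

import numpy as np

TOL = 1e-9


def enumerate_vertices(S: np.ndarray, bounds: list[tuple[float, float]]):
    n = S.shape[1]
    r = int(np.linalg.matrix_rank(S)) if S.size else 0
    n_pinned = n - r
    vertices = []
    for pinned in itertools.combinations(range(n), n_pinned):
        free = [j for j in range(n) if j not in pinned]
        A = S[:, free] if free else np.zeros((S.shape[0], 0))
        for choice in itertools.product((0, 1), repeat=n_pinned):
            v = np.full(n, np.nan)
            for j, c in zip(pinned, choice):
                v[j] = bounds[j][c]
            b = -S[:, list(pinned)] @ v[list(pinned)] if pinned else np.zeros(S.shape[0])
            if free:
                x, *_ = np.linalg.lstsq(A, b, rcond=None)
                v[free] = x
            if np.max(np.abs(S @ v)) > TOL if S.size else False:
                continue
            if all(bounds[j][0] - TOL <= v[j] <= bounds[j][1] + TOL for j in range(n)):
                vertices.append(v)
    return vertices


def brute_force_max(S: np.ndarray, bounds, objective_index: int) -> float | None:
    """Maximal objective over all basic feasible solutions (None = infeasible)."""
    vertices = enumerate_vertices(S, bounds)
    if not vertices:
        return None
    return max(v[objective_index] for v in vertices)
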