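"""Brute-force vertex-enumeration oracle for small flux LPs.

Independent of the solver under test: enumerates basic feasible solutions
of {v : S.v = 0, lb <= v <= ub} directly.  Only valid when all bounds are
finite (the polytope is then bounded and the LP optimum is attained at a
vertex).  Intended for models with <= 8 reactions.
"""

from __future__ import annotations

from itertools import combinations, product
from typing import List, Tuple

import numpy as np

from crossfeed.core import StoichiometricModel, stoichiometric_matrix

TOL = 1e-9


def enumerate_vertices(model: StoichiometricModel) -> List[np.ndarray]:
    """All vertices of the feasible polytope (may contain duplicates)."""
    S = stoichiometric_matrix(model)
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    assert np.all(np.isfinite(lb)) and np.all(np.isfinite(ub)), "bounds must be finite"
    m, n = S.shape
    rank = np.linalg.matrix_rank(S) if m else 0

    vertices: List[np.ndarray] = []
    if rank == 0:
        # box only: vertices are all bound combinations
        for corner in product(*[(l, u) for l, u in zip(lb, ub)]):
            vertices.append(np.array(corner))
        return vertices

    for free in combinations(range(n), rank):
        SF = S[:, free]
        if np.linalg.matrix_rank(SF) < rank:
            continue
        fixed = [j for j in range(n) if j not in free]
        for corner in product(*[(lb[j], ub[j]) for j in fixed]):
            rhs = -S[:, fixed] @ np.array(corner) if fixed else np.zeros(m)
            sol, residuals, _, _ = np.linalg.lstsq(SF, rhs, rcond=None)
            if np.linalg.norm(SF @ sol - rhs) > 1e-7:
                continue  # inconsistent system: infeasible corner
            v = np.zeros(n)
            v[list(free)] = sol
            for j, val in zip(fixed, corner):
                v[j] = val
            if np.all(v >= lb - 1e-7) and np.all(v <= ub + 1e-7):
                vertices.append(np.clip(v, lb, ub))
    return vertices


def oracle_fba(model: StoichiometricModel) -> Tuple[float, List[np.ndarray]]:
    """(optimal objective, list of optimal vertices) by exhaustive enumeration."""
    c = np.zeros(len(model.reactions))
    idx = {rid: j for j, rid in enumerate(model.reaction_ids)}
    for rid, w in model.objective.items():
        c[idx[rid]] = w
    vertices = enumerate_vertices(model)
    assert vertices, "no feasible vertex found (fixture should contain v=0)"
    values = [float(c @ v) for v in vertices]
    best = max(values)
    optimal = [v for v, val in zip(vertices, values) if val >= best - 1e-6]
    return best, optimal
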