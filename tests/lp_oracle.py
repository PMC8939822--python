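"""Brute-force LP oracle for small flux models.

Independent of the package's solver path: enumerates every basic solution
of  max c'v  s.t.  S v = 0,  l <= v <= u  by choosing rank(S) free
variables and pinning the rest at either bound, then takes the best
feasible candidate.  For a feasible bounded LP the optimum is attained at
a basic feasible solution, so the enumeration is exhaustive.  Only viable
for a handful of reactions (cost ~ C(n, r) * 2^(n-r) linear solves).
"""

from __future__ import annotations

import itertools

import numpy as np
from cobra.util.array import create_stoichiometric_matrix


def enumerate_lp_max(S: np.ndarray, lb: np.ndarray, ub: np.ndarray,
                     c: np.ndarray, tol: float = 1e-7) -> float | None:
    """Maximum of c'v over {v : S v = 0, lb <= v <= ub}, or None if the
    enumeration finds no feasible basic solution."""
    m, n = S.shape
    r = int(np.linalg.matrix_rank(S)) if m and n else 0
    best = None
    for free in itertools.combinations(range(n), r):
        Sf = S[:, free]
        if r and np.linalg.matrix_rank(Sf) < r:
            continue
        fixed = [j for j in range(n) if j not in free]
        for choice in itertools.product(*[(lb[j], ub[j]) for j in fixed]):
            v = np.zeros(n)
            v[fixed] = choice
            rhs = -S[:, fixed] @ v[fixed] if fixed else np.zeros(m)
            if r:
                vf, *_ = np.linalg.lstsq(Sf, rhs, rcond=None)
                v[list(free)] = vf
            if np.max(np.abs(S @ v), initial=0.0) > tol:
                continue
            if np.any(v < lb - tol) or np.any(v > ub + tol):
                continue
            value = float(c @ v)
            if best is None or value > best:
                best = value
    return best


def oracle_fba_optimum(model, objective_id: str) -> float | None:
    """Exhaustively enumerated FBA optimum of a tiny cobra model."""
    S = create_stoichiometric_matrix(model)
    lb = np.array([rxn.lower_bound for rxn in model.reactions])
    ub = np.array([rxn.upper_bound for rxn in model.reactions])
    c = np.array([1.0 if rxn.id == objective_id else 0.0
                  for rxn in model.reactions])
    return enumerate_lp_max(S, lb, ub, c)
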