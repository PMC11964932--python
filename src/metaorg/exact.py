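"""Exhaustive reference computations for small networks.

These brute-force routines are tractable only for toy models (roughly
<= 12 reactions) and exist as independent ground truth for the LP-based
machinery: polytope-vertex enumeration for flux ranges, extreme-ray /
elementary-flux-mode enumeration, and exhaustive search for the smallest
consistent subnetwork containing a core set.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.linalg import null_space

from .network import MetabolicModel

_TOL = 1e-9


def enumerate_polytope_vertices(model: MetabolicModel) -> np.ndarray:
    """All vertices of {v : S v = 0, lb <= v <= ub} (rows of the result).

    The steady-state subspace is parametrized by a nullspace basis N of S;
    the box bounds become linear inequalities in the reduced coordinates, and
    vertices are found by solving every d-subset of active constraints.
    """
    S = model.stoichiometric_matrix().toarray()
    lb, ub = model.bounds_arrays()
    n = len(model.reactions)
    N = null_space(S) if S.size else np.eye(n)
    if N.size == 0:
        return np.zeros((1, n))
    d = N.shape[1]
    # inequalities A t <= b:  N t <= ub  and  -N t <= -lb
    A = np.vstack([N, -N])
    b = np.concatenate([ub, -lb])
    vertices = []
    for rows in combinations(range(A.shape[0]), d):
        Asub = A[list(rows)]
        if np.linalg.matrix_rank(Asub) < d:
            continue
        t, *_ = np.linalg.lstsq(Asub, b[list(rows)], rcond=None)
        if np.max(A @ t - b) <= 1e-7:
            v = N @ t
            if not any(np.allclose(v, w, atol=1e-7) for w in vertices):
                vertices.append(v)
    if not vertices:  # polytope may be a single point (e.g. all bounds zero)
        return np.zeros((0, n))
    return np.array(vertices)


def fva_by_vertex_enumeration(model: MetabolicModel) -> dict[str, tuple[float, float]]:
    """Exact flux ranges as min/max over all polytope vertices."""
    V = enumerate_polytope_vertices(model)
    out = {}
    for j, r in enumerate(model.reactions):
        if V.shape[0] == 0:
            out[r.id] = (0.0, 0.0)
        else:
            out[r.id] = (float(V[:, j].min()), float(V[:, j].max()))
    return out


def is_elementary(model: MetabolicModel, support: set[str]) -> bool:
    """Elementarity test: the nullspace of S restricted to the support must be
    one-dimensional, nonzero on the whole support, and sign-compatible with
    the irreversibility constraints."""
    if not support:
        return False
    idx = [j for j, r in enumerate(model.reactions) if r.id in support]
    if len(idx) != len(support):
        return False
    S = model.stoichiometric_matrix().toarray()
    Ssub = S[:, idx]
    N = null_space(Ssub)
    if N.shape[1] != 1:
        return False
    e = N[:, 0]
    if np.any(np.abs(e) <= 1e-9):
        return False
    # orient so that some admissible sign pattern exists
    lb = np.array([model.reactions[j].lb for j in idx])
    ub = np.array([model.reactions[j].ub for j in idx])
    for sign in (1.0, -1.0):
        v = sign * e
        ok = True
        for vi, l, u in zip(v, lb, ub):
            if vi > 0 and u <= 0:
                ok = False
            if vi < 0 and l >= 0:
                ok = False
        if ok:
            return True
    return False


def enumerate_efms(model: MetabolicModel, through: str | None = None
                   ) -> list[frozenset]:
    """Brute-force enumeration of all elementary flux modes.

    Checks every reaction subset for a one-dimensional, sign-admissible
    steady-state nullspace and keeps the support-minimal ones.  Optionally
    restricted to modes through a given reaction.
    """
    rxn_ids = model.reaction_ids
    n = len(rxn_ids)
    if n > 16:
        raise ValueError("brute-force EFM enumeration limited to 16 reactions")
    candidates = []
    for k in range(1, n + 1):
        for subset in combinations(rxn_ids, k):
            sup = set(subset)
            if any(prev < sup for prev in candidates):
                continue  # not support-minimal
            if is_elementary(model, sup):
                candidates.append(frozenset(sup))
    if through is not None:
        candidates = [s for s in candidates if through in s]
    return candidates


def min_consistent_superset(model: MetabolicModel, core: set[str],
                            epsilon: float = 1e-4) -> int | None:
    """Smallest number of non-core reactions whose union with the core forms
    a flux-consistent subnetwork (exhaustive subset search).

    Returns None when no consistent superset exists.
    """
    from .lp import fva

    noncore = [r for r in model.reaction_ids if r not in core]

    def consistent(rxns: set[str]) -> bool:
        sub = model.subset(rxns)
        ranges = fva(sub, pairs={})
        for fr in ranges:
            if max(fr.vmax, -fr.vmin) < epsilon - 1e-12:
                return False
        return True

    for k in range(0, len(noncore) + 1):
        for extra in combinations(noncore, k):
            if consistent(core | set(extra)):
                return k
    return None
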