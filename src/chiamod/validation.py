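"""Independent validation routines for the committor computation.

The linear-solve committors can be cross-checked in two ways that share no
code with the solver: a dense solve of the same boundary-value problem via
``numpy.linalg.solve``, and direct Monte-Carlo simulation of the random
walk's embedded jump chain (from a node, jump to a uniformly random
neighbor; record which core is hit first).  The jump chain hits the same
cores with the same probabilities as the continuous-time walk, since
committors depend only on the jump skeleton.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from numba import njit


def dense_committors(L: sp.spmatrix, cores) -> np.ndarray:
    """Committor affiliations by dense linear solve (oracle path)."""
    n = L.shape[0]
    m = len(cores)
    A = np.asarray((-L).todense(), dtype=float)
    adj = -A.copy()
    np.fill_diagonal(adj, 0.0)
    is_core = np.zeros(n, dtype=bool)
    for core in cores:
        is_core[np.asarray(core)] = True
    free = np.flatnonzero(~is_core)
    Q = np.zeros((n, m))
    for i, core in enumerate(cores):
        Q[np.asarray(core), i] = 1.0
    if free.size:
        M = A[np.ix_(free, free)]
        for i, core in enumerate(cores):
            b = adj[np.ix_(free, np.asarray(core))].sum(axis=1)
            Q[free, i] = np.linalg.solve(M, b)
    return np.clip(Q, 0.0, 1.0)


@njit(cache=True)
def _walk_kernel(indptr, indices, core_of, n_walks, seed):  # pragma: no cover
    n = core_of.shape[0]
    m = int(core_of.max()) + 1
    hits = np.zeros((n, m), dtype=np.int64)
    np.random.seed(seed)
    for start in range(n):
        if core_of[start] >= 0:
            hits[start, core_of[start]] = n_walks
            continue
        for _ in range(n_walks):
            x = start
            while core_of[x] < 0:
                lo, hi = indptr[x], indptr[x + 1]
                x = indices[lo + np.random.randint(hi - lo)]
            hits[start, core_of[x]] += 1
    return hits


def monte_carlo_affiliations(L: sp.spmatrix, cores, n_walks: int = 50_000,
                             seed: int = 0) -> np.ndarray:
    """Hitting frequencies of the embedded jump chain, one row per node.

    Each non-core node launches ``n_walks`` seeded walks; the returned
    matrix holds the fraction of walks absorbed by each core.
    """
    n = L.shape[0]
    adj = sp.csr_matrix(L).copy()
    adj.setdiag(0)
    adj.eliminate_zeros()
    core_of = np.full(n, -1, dtype=np.int64)
    for i, core in enumerate(cores):
        core_of[np.asarray(core)] = i
    hits = _walk_kernel(adj.indptr.astype(np.int64),
                        adj.indices.astype(np.int64),
                        core_of, n_walks, seed % (2 ** 31))
    return hits / float(n_walks)
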