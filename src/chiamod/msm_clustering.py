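"""Fuzzy module detection by Markov-state-model random-walk clustering.

A continuous-time random walk on a connected component jumps along each
edge at unit rate; its generator is L = A - D (adjacency minus degree
diagonal), a symmetric matrix with row sums zero whose spectrum is
non-positive with a single zero eigenvalue per component.  Metastable
modules show up as a group of near-zero ("dominant") eigenvalues separated
from the rest by a spectral gap: the walk equilibrates quickly inside a
module and only rarely crosses between modules.

The resolution parameter alpha is a timescale: the number of modules m is
the number of eigenvalues with |lambda| < 1/alpha, so large alpha keeps
only the most strongly metastable (highly intraconnected) modules and
decreasing alpha admits less pronounced ones.  Module cores are found by
k-means in the dominant eigenvector embedding; the fuzzy affiliation
q_i(x) of every remaining node is the committor — the probability that the
walk started at x hits core i before any other core — obtained by solving
sparse symmetric positive-definite linear systems.  A threshold theta
turns affiliations into assignments; nodes with max_i q_i(x) < theta form
the transition region that mediates between modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

UNASSIGNED = -1

_DENSE_LIMIT = 600  # components up to this size use a dense eigensolver


def build_generator(component: nx.Graph, nodelist=None) -> tuple[sp.csr_matrix, list]:
    """Generator L = A - D of the unit-rate random walk on a connected
    component.  Returns (L, nodelist); raises on disconnected input."""
    if component.number_of_nodes() < 2:
        raise ValueError("generator needs a component with >= 2 nodes")
    if not nx.is_connected(component):
        raise ValueError("input graph is disconnected; split components first")
    nodelist = list(nodelist) if nodelist is not None else sorted(component.nodes)
    a = nx.to_scipy_sparse_array(component, nodelist=nodelist, format="csr",
                                 dtype=float)
    a = sp.csr_matrix(a)
    deg = np.asarray(a.sum(axis=1)).ravel()
    L = a - sp.diags(deg)
    return sp.csr_matrix(L), nodelist


@dataclass
class SpectrumReport:
    """The k smallest eigenvalues of -L (ascending, first = 0) with
    eigenvectors, implied timescales 1/lambda and the dominant-gap index."""

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns aligned with eigenvalues
    implied_timescales: np.ndarray
    gap_index: int


def dominant_spectrum(L: sp.spmatrix, k: int) -> SpectrumReport:
    """Smallest-magnitude eigenvalues of -L with eigenvectors.

    Dense solve for small components; shift-invert Lanczos otherwise.
    """
    n = L.shape[0]
    if k < 2 or k > n - 1:
        raise ValueError("need 2 <= k <= n - 1")
    A = -L
    if n <= _DENSE_LIMIT:
        w, v = np.linalg.eigh(A.toarray())
        w, v = w[:k], v[:, :k]
    else:
        try:
            w, v = spla.eigsh(sp.csc_matrix(A), k=k, sigma=-1e-8, which="LM")
        except spla.ArpackNoConvergence as exc:
            raise RuntimeError(
                "sparse eigensolver did not converge; raise maxiter or use a "
                "smaller k") from exc
        order = np.argsort(w)
        w, v = w[order], v[:, order]
    w = np.where(np.abs(w) < 1e-10, 0.0, w)
    w[0] = 0.0
    nonzero = w > 0
    timescales = np.full(k, np.inf)
    timescales[nonzero] = 1.0 / w[nonzero]
    gap_index = _dominant_gap(w)
    return SpectrumReport(eigenvalues=w, eigenvectors=v,
                          implied_timescales=timescales, gap_index=gap_index)


def _dominant_gap(eigenvalues: np.ndarray) -> int:
    """Number of eigenvalues before the largest eigengap (the standard
    additive eigengap heuristic; the zero mode always counts).

    Dominant eigenvalues cluster near zero, so ratios between them are
    noisy; the absolute gap max_m (lambda_{m+1} - lambda_m) separates the
    metastable group from the bulk more stably.
    """
    gaps = np.diff(eigenvalues)
    return int(np.argmax(gaps)) + 1


def choose_num_modules(spectrum: SpectrumReport, alpha: float,
                       m_max: int | None = None) -> int:
    """m = number of eigenvalues with |lambda| < 1/alpha (the zero mode
    always counts); clamped to [1, m_max]."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    m = int(np.sum(spectrum.eigenvalues < 1.0 / alpha))
    m = max(1, m)
    if m_max is not None:
        m = min(m, m_max)
    return m


def suggest_alpha(spectrum: SpectrumReport) -> float:
    """Alpha sitting in the dominant spectral gap (geometric mean of the
    flanking implied timescales), so the gap's module count is selected."""
    m = spectrum.gap_index
    w = spectrum.eigenvalues
    if m >= len(w):
        return 1.0 / max(w[-1], 1e-12)
    lam_in = max(w[m - 1], 1e-12)   # largest dominant eigenvalue
    lam_out = max(w[m], 1e-12)      # first non-dominant eigenvalue
    return float(1.0 / np.sqrt(lam_in * lam_out))


def identify_cores(eigenvectors: np.ndarray, m: int,
                   core_fraction: float = 0.2, seed: int = 0,
                   max_restarts: int = 10) -> list[np.ndarray]:
    """Module cores from k-means in the dominant eigenspace.

    Nodes are embedded by the first m eigenvector coordinates and split
    into m hard groups (seeded k-means, multi-restart); the core of a
    group is the ``core_fraction`` of its nodes closest to the group
    centroid (at least one node).  Cores are pairwise disjoint by
    construction.
    """
    from sklearn.cluster import KMeans

    if m < 2:
        raise ValueError("core identification needs m >= 2")
    if not 0.0 < core_fraction <= 1.0:
        raise ValueError("core_fraction must be in (0, 1]")
    emb = np.asarray(eigenvectors[:, :m])
    last_exc = None
    for attempt in range(max_restarts):
        km = KMeans(n_clusters=m, n_init=10, random_state=seed + attempt)
        labels = km.fit_predict(emb)
        if len(set(labels)) == m:
            break
        last_exc = RuntimeError("k-means produced an empty group")
    else:
        raise RuntimeError(
            f"could not find {m} non-empty groups in {max_restarts} restarts"
        ) from last_exc

    cores = []
    for i in range(m):
        members = np.flatnonzero(labels == i)
        dist = np.linalg.norm(emb[members] - km.cluster_centers_[i], axis=1)
        n_core = max(1, int(np.ceil(core_fraction * members.size)))
        cores.append(np.sort(members[np.argsort(dist, kind="stable")[:n_core]]))
    return cores


def committor_affiliations(L: sp.spmatrix, cores: list[np.ndarray]) -> np.ndarray:
    """Affiliation matrix Q with q_i(x) = P[walk from x hits core i first].

    Boundary conditions q_i = 1 on core i and 0 on the other cores; on the
    non-core nodes each q_i solves the sparse symmetric positive-definite
    system (-L restricted to non-core rows/columns) q = (links into core
    i).  Rows of Q sum to 1.
    """
    n = L.shape[0]
    m = len(cores)
    if m < 2:
        raise ValueError("need >= 2 cores")
    core_all = np.concatenate(cores)
    if len(np.unique(core_all)) != len(core_all):
        raise ValueError("cores must be pairwise disjoint")
    is_core = np.zeros(n, dtype=bool)
    is_core[core_all] = True
    free = np.flatnonzero(~is_core)

    Q = np.zeros((n, m))
    for i, core in enumerate(cores):
        Q[core, i] = 1.0
    if free.size == 0:
        return Q

    A = sp.csr_matrix(-L)
    M = A[np.ix_(free, free)]
    _check_reachability(L, free, is_core)
    solve = spla.factorized(sp.csc_matrix(M))
    adjacency = sp.csr_matrix(L).copy()
    adjacency.setdiag(0)
    adjacency.eliminate_zeros()
    for i, core in enumerate(cores):
        b = np.asarray(adjacency[np.ix_(free, core)].sum(axis=1)).ravel()
        Q[free, i] = solve(b)
    Q = np.clip(Q, 0.0, 1.0)
    return Q


def _check_reachability(L: sp.spmatrix, free: np.ndarray, is_core: np.ndarray):
    """Every non-core node must reach some core; otherwise the restricted
    system is singular.  Raise naming the stranded nodes."""
    adj = sp.csr_matrix(L).copy()
    adj.setdiag(0)
    adj.eliminate_zeros()
    reached = set()
    frontier = [int(x) for x in np.flatnonzero(is_core)]
    seen = set(frontier)
    while frontier:
        x = frontier.pop()
        for y in adj.indices[adj.indptr[x]:adj.indptr[x + 1]]:
            y = int(y)
            if y not in seen:
                seen.add(y)
                if not is_core[y]:
                    reached.add(y)
                frontier.append(y)
    stranded = [int(x) for x in free if int(x) not in reached]
    if stranded:
        raise ValueError(f"nodes with no path to any core: {stranded}")


def assign_modules(Q: np.ndarray, theta: float) -> tuple[np.ndarray, np.ndarray]:
    """Threshold affiliations: node -> argmax_i q_i when the maximum
    reaches theta, else UNASSIGNED (transition region).

    For theta <= 0.5 several modules can qualify; the node goes to the
    module of highest affiliation, ties to the lowest module index
    (np.argmax order).
    """
    if not 0.0 < theta <= 1.0:
        raise ValueError("theta must be in (0, 1]")
    best = np.argmax(Q, axis=1)
    qmax = Q[np.arange(Q.shape[0]), best]
    assignment = np.where(qmax >= theta - 1e-12, best, UNASSIGNED)
    transition = np.flatnonzero(assignment == UNASSIGNED)
    return assignment, transition


@dataclass
class FuzzyClustering:
    """Fuzzy clustering of one connected component."""

    nodes: list
    m: int
    Q: np.ndarray
    alpha: float
    theta: float
    assignment: np.ndarray            # per-node module id or UNASSIGNED
    transition_region: np.ndarray     # indices into ``nodes``
    cores: list = field(default_factory=list)
    eigenvalues: np.ndarray = field(default_factory=lambda: np.array([]))
    seed: int = 0

    def assignment_by_node(self) -> dict:
        return {node: int(mod) for node, mod in zip(self.nodes, self.assignment)}

    def to_frame(self):
        import pandas as pd
        df = pd.DataFrame(self.Q, columns=[f"q_{i + 1}" for i in range(self.m)])
        df.insert(0, "node_id", self.nodes)
        df.insert(1, "module_id",
                  ["UNASSIGNED" if a == UNASSIGNED else int(a)
                   for a in self.assignment])
        return df


def cluster_component(component: nx.Graph, alpha: float, theta: float,
                      seed: int = 0, min_nodes: int = 20,
                      core_fraction: float = 0.2,
                      k: int | None = None) -> FuzzyClustering:
    """Full MSM clustering of one connected component.

    Components below ``min_nodes`` bypass clustering and are reported
    whole as a single module, as are resolutions at which only the
    stationary mode is dominant (m = 1).
    """
    nodes = sorted(component.nodes)
    n = len(nodes)
    if n < min_nodes:
        return _single_module(nodes, alpha, theta, seed)
    L, nodelist = build_generator(component, nodes)
    if k is None:
        k = min(n - 1, 25)
    spectrum = dominant_spectrum(L, k)
    m = choose_num_modules(spectrum, alpha, m_max=k)
    if m < 2:
        out = _single_module(nodes, alpha, theta, seed)
        out.eigenvalues = spectrum.eigenvalues
        return out
    cores = identify_cores(spectrum.eigenvectors, m, core_fraction, seed)
    Q = committor_affiliations(L, cores)
    assignment, transition = assign_modules(Q, theta)
    return FuzzyClustering(nodes=nodelist, m=m, Q=Q, alpha=alpha, theta=theta,
                           assignment=assignment, transition_region=transition,
                           cores=[np.asarray(c) for c in cores],
                           eigenvalues=spectrum.eigenvalues, seed=seed)


def _single_module(nodes, alpha, theta, seed) -> FuzzyClustering:
    n = len(nodes)
    return FuzzyClustering(nodes=list(nodes), m=1, Q=np.ones((n, 1)),
                           alpha=alpha, theta=theta,
                           assignment=np.zeros(n, dtype=int),
                           transition_region=np.array([], dtype=int),
                           cores=[np.arange(n)], seed=seed)
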