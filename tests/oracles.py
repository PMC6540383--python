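"""Hand-coded oracles, independent of the implementation paths they check."""

from __future__ import annotations

import itertools
import math
from collections import deque

import numpy as np


def brute_betweenness(g) -> dict:
    """Raw betweenness by explicit BFS shortest-path enumeration over all
    unordered node pairs."""
    nodes = list(g.nodes)
    btw = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = _all_shortest_paths(g, s, t)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            btw[v] += through / len(paths)
    return btw


def _all_shortest_paths(g, s, t):
    """All shortest s-t paths by BFS layering and backward expansion."""
    dist = {s: 0}
    parents = {s: []}
    queue = deque([s])
    while queue:
        x = queue.popleft()
        for y in g.neighbors(x):
            if y not in dist:
                dist[y] = dist[x] + 1
                parents[y] = [x]
                queue.append(y)
            elif dist[y] == dist[x] + 1:
                parents[y].append(x)
    if t not in dist:
        return []

    def build(node):
        if node == s:
            return [[s]]
        return [p + [node] for parent in parents[node] for p in build(parent)]

    return build(t)


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P[X >= k] by direct pmf summation with exact integer binomials."""
    total = math.comb(N, n)
    acc = 0
    for x in range(k, min(K, n) + 1):
        if n - x > N - K:
            continue
        acc += math.comb(K, x) * math.comb(N - K, n - x)
    return acc / total


def fisher_two_sided(table) -> float:
    """Two-sided Fisher exact p by enumerating all tables with the observed
    margins and summing probabilities <= the observed one."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    N = r1 + r2
    total = math.comb(N, c1)

    def prob(x):
        if x < 0 or x > r1 or c1 - x < 0 or c1 - x > r2:
            return 0.0
        return math.comb(r1, x) * math.comb(r2, c1 - x) / total

    p_obs = prob(a)
    return sum(prob(x) for x in range(0, min(r1, c1) + 1)
               if prob(x) <= p_obs * (1 + 1e-12))


def ranksum_two_sided(a, b) -> float:
    """Exact two-sided rank-sum p by enumerating every group-A choice of
    ranks (valid for tie-free pooled samples)."""
    pooled = sorted(list(a) + list(b))
    assert len(set(pooled)) == len(pooled), "exact enumeration needs no ties"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(ranks[v] for v in a)
    na = len(a)
    mean_w = na * (len(pooled) + 1) / 2
    dev_obs = abs(w_obs - mean_w)
    count = total = 0
    for combo in itertools.combinations(range(1, len(pooled) + 1), na):
        total += 1
        if abs(sum(combo) - mean_w) >= dev_obs - 1e-12:
            count += 1
    return count / total


def smoothed_entropy_ref(values, bins: int, sigma: float) -> float:
    """Reference plug-in entropy: explicit histogram, explicit truncated
    Gaussian kernel (radius = int(4*sigma + 0.5), zero-padded), natural-log
    plug-in over occupied cells."""
    x = np.asarray(values, dtype=float)
    if x.ndim == 1:
        counts, _ = np.histogram(x, bins=bins)
        counts = counts.astype(float)
        if sigma > 0:
            counts = _conv1d(counts, _kernel(sigma))
    else:
        counts, _, _ = np.histogram2d(x[:, 0], x[:, 1], bins=bins)
        if sigma > 0:
            kern = _kernel(sigma)
            counts = np.apply_along_axis(_conv1d, 0, counts, kern)
            counts = np.apply_along_axis(_conv1d, 1, counts, kern)
    p = counts.ravel() / counts.sum()
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def _kernel(sigma: float) -> np.ndarray:
    radius = int(4.0 * sigma + 0.5)
    t = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-0.5 * (t / sigma) ** 2)
    return k / k.sum()


def _conv1d(signal: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    radius = (len(kernel) - 1) // 2
    padded = np.concatenate([np.zeros(radius), signal, np.zeros(radius)])
    out = np.empty_like(signal)
    for i in range(len(signal)):
        out[i] = np.dot(padded[i:i + len(kernel)], kernel)
    return out
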