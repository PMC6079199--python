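"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (exhaustive enumeration, direct
definitions) and shares no code with the package implementation.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


def bfs_distances(edges: set[tuple[str, str]], nodes: list[str], src: str) -> dict[str, int]:
    adj: dict[str, list[str]] = {v: [] for v in nodes}
    for u, v in edges:
        adj[u].append(v)
    dist = {src: 0}
    queue = deque([src])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def count_shortest_paths(edges: set[tuple[str, str]], nodes: list[str],
                         s: str, t: str) -> tuple[int, dict[str, int]]:
    """(number of shortest s->t paths, count passing through each node)."""
    if s == t:
        return 0, {}
    dist = bfs_distances(edges, nodes, s)
    if t not in dist:
        return 0, {}
    d = dist[t]
    paths: list[tuple[str, ...]] = []

    def extend(path: tuple[str, ...]) -> None:
        u = path[-1]
        if u == t:
            paths.append(path)
            return
        if len(path) - 1 >= d:
            return
        for a, b in edges:
            if a == u and dist.get(b, 10**9) == len(path):
                extend(path + (b,))

    extend((s,))
    through = {v: 0 for v in nodes}
    for p in paths:
        for v in p[1:-1]:
            through[v] += 1
    return len(paths), through


def brute_betweenness(edges: set[tuple[str, str]], nodes: list[str]) -> dict[str, float]:
    n = len(nodes)
    acc = {v: 0.0 for v in nodes}
    for s, t in itertools.permutations(nodes, 2):
        sigma, through = count_shortest_paths(edges, nodes, s, t)
        if sigma == 0:
            continue
        for v in nodes:
            if v not in (s, t):
                acc[v] += through[v] / sigma
    return {v: acc[v] / ((n - 1) * (n - 2)) for v in nodes}


def brute_closeness(edges: set[tuple[str, str]], nodes: list[str]) -> dict[str, float]:
    """Incoming-distance closeness with reachable-set (r-1)/(n-1) scaling."""
    n = len(nodes)
    out = {}
    for v in nodes:
        d_in = {u: bfs_distances(edges, nodes, u).get(v) for u in nodes}
        reach = [u for u in nodes if u != v and d_in[u] is not None]
        if not reach:
            out[v] = 0.0
            continue
        total = sum(d_in[u] for u in reach)
        r = len(reach) + 1
        out[v] = (len(reach) / total) * ((r - 1) / (n - 1)) if total > 0 else 0.0
    return out


def brute_core_number(edges: set[tuple[str, str]], nodes: list[str]) -> dict[str, int]:
    """Max over node subsets of the minimum within-subset undirected degree."""
    und = {frozenset((u, v)) for u, v in edges if u != v}
    best = {v: 0 for v in nodes}
    for r in range(1, len(nodes) + 1):
        for sub in itertools.combinations(nodes, r):
            ss = set(sub)
            deg = {v: sum(1 for e in und if v in e and e <= ss) for v in sub}
            k = min(deg.values())
            for v in sub:
                best[v] = max(best[v], k)
    return best


def brute_strongly_connected(edges: set[tuple[str, str]], nodes: list[str]) -> list[set[str]]:
    """SCCs by pairwise mutual reachability."""
    reach = {v: set(bfs_distances(edges, nodes, v)) for v in nodes}
    comps: list[set[str]] = []
    seen: set[str] = set()
    for v in nodes:
        if v in seen:
            continue
        comp = {u for u in nodes if u in reach[v] and v in reach[u]}
        comps.append(comp)
        seen |= comp
    return comps


def anova_moments(groups: list[np.ndarray]) -> tuple[float, float]:
    """One-way ANOVA moment estimators (V_L possibly negative, V_E)."""
    n_i = np.array([len(g) for g in groups], float)
    q, n = len(groups), n_i.sum()
    means = np.array([np.mean(g) for g in groups])
    grand = (n_i * means).sum() / n
    ssb = (n_i * (means - grand) ** 2).sum()
    ssw = sum(((np.asarray(g) - m) ** 2).sum() for g, m in zip(groups, means))
    msb, msw = ssb / (q - 1), ssw / (n - q)
    n0 = (n - (n_i**2).sum() / n) / (q - 1)
    return (msb - msw) / n0, msw


def average_ranks(x: np.ndarray) -> np.ndarray:
    """Average ranks with ties, by direct definition."""
    x = np.asarray(x, float)
    out = np.empty_like(x)
    for i, xi in enumerate(x):
        less = np.sum(x < xi)
        equal = np.sum(x == xi)
        out[i] = less + (equal + 1) / 2.0
    return out


def brute_spearman(x: np.ndarray, y: np.ndarray) -> float:
    rx, ry = average_ranks(x), average_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def brute_canonical_correlations(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Canonical correlations via the eigenvalues of Sxx^-1 Sxy Syy^-1 Syx."""
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    sxx = xc.T @ xc
    syy = yc.T @ yc
    sxy = xc.T @ yc
    mat = np.linalg.solve(sxx, sxy) @ np.linalg.solve(syy, sxy.T)
    evals = np.linalg.eigvals(mat)
    evals = np.sort(np.real(evals))[::-1]
    s = min(x.shape[1], y.shape[1])
    return np.sqrt(np.clip(evals[:s], 0, 1))
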