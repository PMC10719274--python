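"""Independent brute-force references used to validate the metric code.

Shortest paths come from a textbook Floyd-Warshall triple loop; betweenness
from explicit enumeration of all simple paths.  Deliberately naive and
separate from the implementation under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def floyd_warshall(W: np.ndarray) -> np.ndarray:
    """All-pairs shortest distances under d = 1/w, by the classic recurrence."""
    n = W.shape[0]
    D = [[0.0 if i == j else (1.0 / W[i][j] if W[i][j] > 0 else math.inf) for j in range(n)] for i in range(n)]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i][k] + D[k][j] < D[i][j]:
                    D[i][j] = D[i][k] + D[k][j]
    return np.array(D)


def path_length_mean(W: np.ndarray) -> tuple[float, int]:
    D = floyd_warshall(W)
    n = D.shape[0]
    finite, unreachable = [], 0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if math.isinf(D[i][j]):
                unreachable += 1
            else:
                finite.append(D[i][j])
    return float(np.mean(finite)), unreachable


def global_efficiency(W: np.ndarray) -> float:
    D = floyd_warshall(W)
    n = D.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and math.isfinite(D[i][j]) and D[i][j] > 0:
                total += 1.0 / D[i][j]
    return total / (n * (n - 1))


def _all_simple_paths(W: np.ndarray, s: int, t: int):
    n = W.shape[0]
    stack = [(s, [s], 0.0)]
    while stack:
        node, path, dist = stack.pop()
        if node == t:
            yield path, dist
            continue
        for nxt in range(n):
            if W[node][nxt] > 0 and nxt not in path:
                stack.append((nxt, path + [nxt], dist + 1.0 / W[node][nxt]))


def betweenness(W: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Fractional shortest-path counts through each node, pairs counted once."""
    n = W.shape[0]
    bc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths = list(_all_simple_paths(W, s, t))
        if not paths:
            continue
        dmin = min(d for _, d in paths)
        shortest = [p for p, d in paths if d <= dmin + tol]
        for p in shortest:
            for v in p[1:-1]:
                bc[v] += 1.0 / len(shortest)
    return bc


def spearman_rho(x, y) -> float:
    """Textbook Spearman: Pearson correlation of average ranks."""
    def ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="mergesort")
        r = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return r

    rx, ry = ranks(x), ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))


def random_weighted_graph(rng: np.random.Generator, n_max: int = 8, connected: bool = False) -> np.ndarray:
    """A small random symmetric weight matrix for oracle batteries."""
    while True:
        n = int(rng.integers(3, n_max + 1))
        density = rng.uniform(0.3, 0.9)
        W = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < density:
                    W[i, j] = W[j, i] = rng.uniform(0.1, 5.0)
        if W.sum() == 0:
            continue
        if connected:
            D = floyd_warshall(W)
            if not np.all(np.isfinite(D)):
                continue
        return W
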