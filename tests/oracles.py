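"""Independent brute-force oracles used by the test suite.

Every oracle here recomputes a statistic from first principles (O(n²)
distance matrices, breadth-first search, explicit enumeration) without
touching the package's KD-tree / graph / rank-based implementations.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np


def dist_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return np.sqrt(((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2))


def brute_neighbor_counts(pts: np.ndarray, radius: float) -> np.ndarray:
    """Closed-ball neighbor counts, self excluded."""
    d = dist_matrix(pts, pts)
    return (d <= radius).sum(axis=1) - 1


def brute_nn_distances(from_pts: np.ndarray, to_pts: np.ndarray,
                       self_pairs: list[tuple[int, int]] | None = None) -> np.ndarray:
    """Per from-point nearest to-point distance; ``self_pairs`` lists
    (from_index, to_index) identities to exclude."""
    d = dist_matrix(from_pts, to_pts)
    if self_pairs:
        for i, j in self_pairs:
            d[i, j] = np.inf
    return d.min(axis=1)


def brute_max_min(from_pts: np.ndarray, to_pts: np.ndarray) -> float:
    """Directed Hausdorff distance by exhaustive max-of-mins."""
    d = dist_matrix(from_pts, to_pts)
    return float(d.min(axis=1).max())


def brute_dbscan(pts: np.ndarray, eps: float, min_size: int) -> np.ndarray:
    """DBSCAN labels via distance matrix + BFS over core points.

    Core: ≥ min_size points (self included) within eps.  Clusters are
    connected components of cores; border points join the lowest cluster
    id; components are canonically ordered by core-centroid (x, y).
    Returns -1 for noise.
    """
    n = len(pts)
    labels = np.full(n, -1, dtype=int)
    if n == 0:
        return labels
    d = dist_matrix(pts, pts)
    within = d <= eps
    core = within.sum(axis=1) >= min_size
    comp = np.full(n, -1, dtype=int)
    n_comp = 0
    for start in range(n):
        if not core[start] or comp[start] != -1:
            continue
        queue = deque([start])
        comp[start] = n_comp
        while queue:
            i = queue.popleft()
            for j in np.flatnonzero(within[i] & core):
                if comp[j] == -1:
                    comp[j] = n_comp
                    queue.append(j)
        n_comp += 1
    order = sorted(
        range(n_comp),
        key=lambda c: tuple(pts[core & (comp == c)].mean(axis=0)),
    )
    rank = {c: i for i, c in enumerate(order)}
    for i in range(n):
        if core[i]:
            labels[i] = rank[comp[i]]
    for i in range(n):
        if core[i]:
            continue
        nbr = [labels[j] for j in np.flatnonzero(within[i]) if core[j]]
        if nbr:
            labels[i] = min(nbr)
    return labels


def brute_mann_whitney_u(a: np.ndarray, b: np.ndarray) -> float:
    """U statistic from explicit pairwise comparisons (ties count 1/2)."""
    a = np.asarray(a, float)[:, None]
    b = np.asarray(b, float)[None, :]
    return float((a > b).sum() + 0.5 * (a == b).sum())


def brute_mann_whitney_p(a, b, two_sided: bool = True) -> float:
    """Exact p by enumerating every labeling, with U from pairwise counts."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pooled = np.concatenate([a, b])
    n, total = len(a), len(pooled)
    u_obs = brute_mann_whitney_u(a, b)
    mid = n * (total - n) / 2.0
    hits = count = 0
    for combo in itertools.combinations(range(total), n):
        mask = np.zeros(total, bool)
        mask[list(combo)] = True
        u = brute_mann_whitney_u(pooled[mask], pooled[~mask])
        count += 1
        if two_sided:
            if abs(u - mid) >= abs(u_obs - mid) - 1e-9:
                hits += 1
        elif u >= u_obs - 1e-9:
            hits += 1
    return hits / count
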