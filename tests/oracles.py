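"""Independent brute-force oracles used to verify the implementation."""

from __future__ import annotations

from itertools import permutations

import numpy as np


def brute_force_radius_edges(points: np.ndarray, radius: float) -> set[tuple[int, int]]:
    """All-pairs thresholding."""
    n = len(points)
    out = set()
    for i in range(n):
        for j in range(i + 1, n):
            if np.hypot(*(points[i] - points[j])) <= radius:
                out.add((i, j))
    return out


def is_delaunay_edge(points: np.ndarray, i: int, j: int, tol: float = 1e-9) -> bool:
    """True iff some circle through points i and j is empty of all other
    points (the empty-circumcircle characterisation of Delaunay edges).

    Checks the diametral circle and every circumcircle through a third
    point; an edge is Delaunay iff at least one of those circles is empty.
    """
    p, q = points[i], points[j]
    others = np.delete(points, [i, j], axis=0)
    if len(others) == 0:
        return True
    # diametral circle (Gabriel edge => Delaunay edge)
    c = (p + q) / 2
    r = np.linalg.norm(p - q) / 2
    if (np.linalg.norm(others - c, axis=1) > r - tol).all():
        return True
    for k in range(len(points)):
        if k in (i, j):
            continue
        s = points[k]
        # circumcentre of (p, q, s)
        d = 2 * (p[0] * (q[1] - s[1]) + q[0] * (s[1] - p[1]) + s[0] * (p[1] - q[1]))
        if abs(d) < tol:
            continue
        ux = (
            (p @ p) * (q[1] - s[1]) + (q @ q) * (s[1] - p[1]) + (s @ s) * (p[1] - q[1])
        ) / d
        uy = (
            (p @ p) * (s[0] - q[0]) + (q @ q) * (p[0] - s[0]) + (s @ s) * (q[0] - p[0])
        ) / d
        centre = np.array([ux, uy])
        r = np.linalg.norm(p - centre)
        rest = np.delete(points, [i, j, k], axis=0)
        if len(rest) == 0 or (np.linalg.norm(rest - centre, axis=1) > r - tol).all():
            return True
    return False


def brute_force_delaunay_edges(points: np.ndarray, cutoff: float) -> set[tuple[int, int]]:
    out = set()
    for i in range(len(points)):
        for j in range(i + 1, len(points)):
            if np.hypot(*(points[i] - points[j])) <= cutoff and is_delaunay_edge(
                points, i, j
            ):
                out.add((i, j))
    return out


def neighbour_tally(edges, labels, categories):
    """Per-node neighbour-type counts by explicit per-edge tally."""
    n = len(labels)
    counts = np.zeros((n, len(categories)), dtype=int)
    idx = {c: k for k, c in enumerate(categories)}
    for a, b in edges:
        counts[a, idx[labels[b]]] += 1
        counts[b, idx[labels[a]]] += 1
    return counts


def cooccurrence_matrix(codes, edges, k):
    C = np.zeros((k, k), dtype=int)
    for a, b in edges:
        C[codes[a], codes[b]] += 1
        C[codes[b], codes[a]] += 1
    return C


def exhaustive_permutation_pvalues(codes, edges, k):
    """Exact permutation p-values by enumerating every ordering of the
    label vector (uniform label shuffle = uniform over orderings).

    Returns (p_attraction, p_avoidance) as k×k arrays:
    p = #{orderings with C* >=/<= C_obs} / n!  (the identity is included,
    so p >= 1/n!).
    """
    codes = np.asarray(codes)
    C_obs = cooccurrence_matrix(codes, edges, k)
    ge = np.zeros((k, k), dtype=int)
    le = np.zeros((k, k), dtype=int)
    total = 0
    for perm in permutations(range(len(codes))):
        Cp = cooccurrence_matrix(codes[list(perm)], edges, k)
        ge += Cp >= C_obs
        le += Cp <= C_obs
        total += 1
    return ge / total, le / total


def bh_adjust_by_hand(pvals):
    """Benjamini–Hochberg step-up adjusted p-values, written out directly."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        val = p[i] * m / (rank_from_top + 1)
        running_min = min(running_min, val)
        adj[i] = min(running_min, 1.0)
    return adj


def exact_ranksum_pvalue(a, b):
    """Two-sided exact rank-sum p-value by enumerating every assignment of
    the pooled values into two groups of the observed sizes."""
    from itertools import combinations

    pooled = np.concatenate([a, b])
    na = len(a)
    ranks = np.argsort(np.argsort(pooled)) + 1  # no ties assumed
    w_obs = ranks[:na].sum()
    mean_w = na * (len(pooled) + 1) / 2
    dev_obs = abs(w_obs - mean_w)
    count = 0
    total = 0
    for idx in combinations(range(len(pooled)), na):
        w = ranks[list(idx)].sum()
        if abs(w - mean_w) >= dev_obs - 1e-12:
            count += 1
        total += 1
    return count / total
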