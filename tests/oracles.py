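"""Independent brute-force oracles used to verify the clustering core.

These deliberately avoid the package's algorithms: the UPGMA oracle recomputes
inter-cluster distances from the original leaf matrix (definitional mean over
cross pairs, O(n^3)), the cophenetic oracle scans merge-order cluster sets, and
the IC oracle enumerates the depth-limited link set explicitly.
"""

from __future__ import annotations

import numpy as np


def upgma_bruteforce(D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Definitional UPGMA: repeatedly merge the closest cluster pair, where the
    inter-cluster distance is the arithmetic mean of all cross-cluster leaf
    pair distances from the ORIGINAL matrix.  Tie rule: smallest
    (min_id, max_id).  Returns (heights, children) in merge order."""
    D = np.asarray(D, dtype=np.float64)
    n = D.shape[0]
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    heights = np.zeros(n - 1)
    children = np.zeros((n - 1, 2), dtype=np.int64)
    for t in range(n - 1):
        best = None
        ids = sorted(clusters)
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                dsum = 0.0
                for la in clusters[a]:
                    for lb in clusters[b]:
                        dsum += D[la, lb]
                d = dsum / (len(clusters[a]) * len(clusters[b]))
                key = (d, min(a, b), max(a, b))
                if best is None or key < best[0]:
                    best = (key, a, b)
        (d, _, _), a, b = best
        heights[t] = d
        children[t] = (min(a, b), max(a, b))
        merged = clusters.pop(a) + clusters.pop(b)
        clusters[n + t] = merged
    return heights, children


def cophenetic_bruteforce(heights: np.ndarray, children: np.ndarray, n: int) -> np.ndarray:
    """(n, n) cophenetic matrix from merge-order cluster sets: the height of
    the first merge whose cluster contains both leaves."""
    members: dict[int, set[int]] = {i: {i} for i in range(n)}
    coph = np.zeros((n, n))
    done = np.eye(n, dtype=bool)
    for t in range(n - 1):
        l, r = children[t]
        merged = members[l] | members[r]
        members[n + t] = merged
        for i in members[l]:
            for j in members[r]:
                coph[i, j] = coph[j, i] = heights[t]
                done[i, j] = done[j, i] = True
    assert done.all()
    return coph


def ic_bruteforce(dend, node_id: int, depth: int = 2) -> float:
    """IC by explicit enumeration of the depth-limited link set (recursion,
    no shared code with the package implementation)."""

    def collect(nd: int, level: int) -> list[float]:
        out = [dend.heights[nd - dend.n_leaves]]
        if level < depth:
            for c in dend.children[nd - dend.n_leaves]:
                if c >= dend.n_leaves:
                    out += collect(int(c), level + 1)
        return out

    hs = collect(int(node_id), 1)
    arr = np.array(hs)
    if len(arr) < 2 or arr.std(ddof=1) == 0:
        return 0.0
    return float((arr[0] - arr.mean()) / arr.std(ddof=1))


def random_distance_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random symmetric matrix of distances in (0, 1); ties almost surely absent."""
    D = rng.uniform(0.05, 1.0, size=(n, n))
    D = (D + D.T) / 2
    np.fill_diagonal(D, 0.0)
    return D
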