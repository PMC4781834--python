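"""Average-linkage (UPGMA) dendrograms, cophenetic distances, ASCII node lists.

The agglomeration is the textbook procedure: start from singleton clusters,
repeatedly merge the closest pair, with the distance between merged clusters
equal to the size-weighted mean of all cross-cluster leaf-pair distances.
Determinism is guaranteed by an explicit tie rule: among pairs at the minimal
distance, the pair with the lexicographically smallest (min_id, max_id) merges
first.  Node ids follow the usual convention — leaves 0..n-1, internal node of
the t-th merge gets id n + t — so the whole tree serializes to a plain text
node list, one line per merge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.cluster.hierarchy as sch

from .connectivity import DistanceMatrix

__all__ = [
    "Dendrogram",
    "average_linkage",
    "cophenetic",
    "cophenetic_matrix",
    "write_node_list",
    "read_node_list",
]


@dataclass
class Dendrogram:
    """Binary merge tree over ``n_leaves`` leaves.

    ``children[t] = (left_id, right_id)`` and ``heights[t]`` describe the t-th
    merge; the new cluster has node id ``n_leaves + t``.  Leaf ids map to the
    in-mask voxel ordering.
    """

    n_leaves: int
    heights: np.ndarray  # (n_leaves - 1,)
    children: np.ndarray  # (n_leaves - 1, 2) int

    _parent: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.heights = np.asarray(self.heights, dtype=np.float64)
        self.children = np.asarray(self.children, dtype=np.int64)
        n = self.n_leaves
        if self.heights.shape != (n - 1,) or self.children.shape != (n - 1, 2):
            raise ValueError("inconsistent dendrogram arrays")
        if np.any(self.heights < 0):
            raise ValueError("negative merge height")

    # -- structure helpers -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return 2 * self.n_leaves - 1

    @property
    def root_id(self) -> int:
        return self.n_nodes - 1

    def is_leaf(self, node_id: int) -> bool:
        return node_id < self.n_leaves

    def height_of(self, node_id: int) -> float:
        """Height of a node (leaves sit at height 0)."""
        if self.is_leaf(node_id):
            return 0.0
        return float(self.heights[node_id - self.n_leaves])

    def children_of(self, node_id: int) -> tuple[int, int]:
        if self.is_leaf(node_id):
            raise ValueError(f"node {node_id} is a leaf")
        l, r = self.children[node_id - self.n_leaves]
        return int(l), int(r)

    def parent_array(self) -> np.ndarray:
        """(n_nodes,) parent id per node; root maps to -1."""
        if self._parent is None:
            parent = np.full(self.n_nodes, -1, dtype=np.int64)
            for t, (l, r) in enumerate(self.children):
                parent[l] = parent[r] = self.n_leaves + t
            self._parent = parent
        return self._parent

    def node_sizes(self) -> np.ndarray:
        """(n_nodes,) number of leaves under each node."""
        sizes = np.ones(self.n_nodes, dtype=np.int64)
        for t, (l, r) in enumerate(self.children):
            sizes[self.n_leaves + t] = sizes[l] + sizes[r]
        return sizes

    def leaves_under(self, node_id: int) -> np.ndarray:
        """Sorted leaf ids below a node (the node's cluster)."""
        out: list[int] = []
        stack = [int(node_id)]
        while stack:
            nd = stack.pop()
            if self.is_leaf(nd):
                out.append(nd)
            else:
                stack.extend(self.children[nd - self.n_leaves])
        return np.array(sorted(out), dtype=np.int64)

    def internal_nodes_under(self, node_id: int) -> np.ndarray:
        """Internal node ids in the subtree rooted at ``node_id`` (inclusive)."""
        out: list[int] = []
        stack = [int(node_id)]
        while stack:
            nd = stack.pop()
            if not self.is_leaf(nd):
                out.append(nd)
                stack.extend(self.children[nd - self.n_leaves])
        return np.array(sorted(out), dtype=np.int64)

    def removal_order(self, node_ids: np.ndarray | None = None) -> np.ndarray:
        """Internal nodes sorted by descending height, ties: later merge first.

        This is the order in which links are removed when cutting the tree;
        with monotone heights it is guaranteed upward-closed (a parent is
        always removed before its children).
        """
        if node_ids is None:
            node_ids = np.arange(self.n_leaves, self.n_nodes)
        node_ids = np.asarray(node_ids, dtype=np.int64)
        h = self.heights[node_ids - self.n_leaves]
        order = np.lexsort((-node_ids, -h))
        return node_ids[order]

    def is_monotone(self, atol: float = 1e-12) -> bool:
        """True if every parent's height >= its internal children's heights."""
        for t, (l, r) in enumerate(self.children):
            h = self.heights[t]
            for c in (l, r):
                if c >= self.n_leaves and self.heights[c - self.n_leaves] > h + atol:
                    return False
        return True

    def to_linkage(self) -> np.ndarray:
        """Export as a scipy linkage matrix (same node-id convention)."""
        sizes = self.node_sizes()
        Z = np.zeros((self.n_leaves - 1, 4))
        Z[:, 0] = self.children[:, 0]
        Z[:, 1] = self.children[:, 1]
        Z[:, 2] = self.heights
        Z[:, 3] = sizes[self.n_leaves :]
        return Z


def average_linkage(dist: DistanceMatrix | np.ndarray) -> Dendrogram:
    """UPGMA agglomeration with deterministic lexicographic tie-breaking.

    Maintains the full inter-cluster distance matrix and applies the
    Lance-Williams average update: after merging clusters of sizes s_i, s_j,
    the distance to any other cluster k is (s_i d_ik + s_j d_jk) / (s_i + s_j),
    i.e. the mean over all cross-cluster leaf pairs.
    """
    if isinstance(dist, DistanceMatrix):
        D = dist.square()
    else:
        D = np.asarray(dist, dtype=np.float64)
        if D.ndim == 1:
            from scipy.spatial.distance import squareform

            D = squareform(D)
    n = D.shape[0]
    if n < 2:
        raise ValueError("need at least 2 leaves")
    if not np.all(np.isfinite(D)):
        raise ValueError("distance matrix contains non-finite values")
    D = D.copy()
    np.fill_diagonal(D, np.inf)

    ids = np.arange(n, dtype=np.int64)  # current cluster id per active slot
    sizes = np.ones(n, dtype=np.int64)
    active = np.ones(n, dtype=bool)
    heights = np.zeros(n - 1)
    children = np.zeros((n - 1, 2), dtype=np.int64)

    for t in range(n - 1):
        m = D.min()
        cand = np.argwhere(np.triu(D == m, k=1))
        if len(cand) > 1:
            # tie rule: smallest (min_id, max_id) over cluster ids
            keys = np.sort(ids[cand], axis=1)
            best = np.lexsort((keys[:, 1], keys[:, 0]))[0]
            i, j = cand[best]
        else:
            i, j = cand[0]
        i, j = int(i), int(j)
        id_i, id_j = int(ids[i]), int(ids[j])
        heights[t] = m
        children[t] = sorted((id_i, id_j))

        si, sj = sizes[i], sizes[j]
        new_row = (si * D[i] + sj * D[j]) / (si + sj)
        D[i, :] = new_row
        D[:, i] = new_row
        D[i, i] = np.inf
        D[j, :] = np.inf
        D[:, j] = np.inf
        sizes[i] = si + sj
        ids[i] = n + t
        active[j] = False

    return Dendrogram(n_leaves=n, heights=heights, children=children)


def cophenetic(dend: Dendrogram, i: int, j: int) -> float:
    """Height of the lowest common ancestor of leaves i and j.

    This is the threshold height at which the two leaves' clusters join.
    """
    n = dend.n_leaves
    for leaf in (i, j):
        if not (0 <= leaf < n):
            raise ValueError(f"invalid leaf id {leaf}")
    if i == j:
        raise ValueError("cophenetic distance needs two distinct leaves")
    parent = dend.parent_array()
    anc = set()
    a = i
    while a != -1:
        anc.add(a)
        a = parent[a]
    b = j
    while b not in anc:
        b = parent[b]
    return dend.height_of(int(b))


def cophenetic_matrix(dend: Dendrogram) -> np.ndarray:
    """Condensed matrix of cophenetic distances over all leaf pairs."""
    return sch.cophenet(dend.to_linkage())


def write_node_list(dend: Dendrogram) -> str:
    """Serialize as the plain-text node list: one line per internal node,
    ``node_id height left_id right_id left_size right_size`` in merge order."""
    sizes = dend.node_sizes()
    lines = []
    for t in range(dend.n_leaves - 1):
        l, r = dend.children[t]
        lines.append(
            f"{dend.n_leaves + t} {dend.heights[t]:.6f} {l} {r} {sizes[l]} {sizes[r]}"
        )
    return "\n".join(lines) + "\n"


def read_node_list(text: str) -> Dendrogram:
    """Parse the ASCII node list; exact inverse of :func:`write_node_list`."""
    rows = []
    for ln, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 6:
            raise ValueError(f"line {ln}: expected 6 fields, got {len(parts)}")
        try:
            node_id = int(parts[0])
            height = float(parts[1])
            left, right = int(parts[2]), int(parts[3])
            lsize, rsize = int(parts[4]), int(parts[5])
        except ValueError as exc:
            raise ValueError(f"line {ln}: {exc}") from None
        rows.append((node_id, height, left, right, lsize, rsize))
    if not rows:
        raise ValueError("empty node list")
    n = len(rows) + 1
    heights = np.zeros(n - 1)
    children = np.zeros((n - 1, 2), dtype=np.int64)
    sizes_seen = {}
    for t, (node_id, height, left, right, lsize, rsize) in enumerate(rows):
        if node_id != n + t:
            raise ValueError(f"line {t + 1}: node id {node_id} out of merge order")
        heights[t] = height
        children[t] = (left, right)
        sizes_seen[node_id] = lsize + rsize
        for cid, csize in ((left, lsize), (right, rsize)):
            expect = 1 if cid < n else sizes_seen.get(cid)
            if expect is not None and expect != csize:
                raise ValueError(f"line {t + 1}: inconsistent size for node {cid}")
    return Dendrogram(n_leaves=n, heights=heights, children=children)
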