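"""Dendrogram dissection: cuts, split tracking, iterative network extraction,
dissociable nodes, and inconsistency-coefficient cut selection.

A cut at level k removes the k-1 greatest-height links, leaving a forest of k
clusters.  Moving from cut k to k+1 splits exactly one cluster in two; tracking
that split identifies the "mother" node.  A mother node whose own cluster and
both child clusters pass the significance predicate is a *dissociable node* —
the unit of hierarchical modular decomposition.  The iterative extraction
scheme cuts the whole-brain tree at an initial cluster count, re-cuts every
oversize cluster inside its own subtree at a halved count, and emits clusters
within the size band [s_min, s_max] as candidate resting-state functional
networks (RFNs).

The inconsistency coefficient (IC) of a link compares its height with the
links immediately below it: IC = (h - mean(L)) / std(L) over the link set L of
the node and its internal children (depth 2).  Plotting the IC of the link
removed at each successive cut gives a per-network IC curve; the first
intersection of two networks' curves selects a common cut level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .tree import Dendrogram

__all__ = [
    "ClusterSet",
    "Cluster",
    "ExtractionConfig",
    "ICCurve",
    "cut",
    "cut_subtree",
    "track_split",
    "dissociable_nodes",
    "extract_rfns",
    "dissect_significant",
    "inconsistency",
    "ic_curve",
    "ic_intersection",
]


@dataclass
class Cluster:
    """One cluster of a cut: the dendrogram node it originates from and its leaves."""

    cluster_id: int
    node_id: int
    leaves: np.ndarray
    size: int


@dataclass
class ClusterSet:
    """Partition of the (sub)tree's leaves produced by a k-cut."""

    cut_level_k: int
    clusters: list[Cluster]

    def __post_init__(self) -> None:
        if len(self.clusters) != self.cut_level_k:
            raise ValueError("cluster count does not match cut level")

    @property
    def sizes(self) -> np.ndarray:
        return np.array([c.size for c in self.clusters])

    def node_ids(self) -> set[int]:
        return {c.node_id for c in self.clusters}

    def labels(self, n_leaves: int) -> np.ndarray:
        """(n_leaves,) cluster_id per leaf; -1 for leaves outside the partition."""
        lab = np.full(n_leaves, -1, dtype=np.int64)
        for c in self.clusters:
            lab[c.leaves] = c.cluster_id
        return lab


@dataclass
class ExtractionConfig:
    """Decision rules of the iterative RFN extraction scheme.

    k_initial is the whole-tree cut count of the first iteration; oversize
    clusters (S > s_max) are re-cut within their own subtree at a count reduced
    by ``halving_factor`` (floored at 2); clusters inside [s_min, s_max] are
    emitted as candidate networks.
    """

    k_initial: int = 64
    s_min: int = 50
    s_max: int = 5000
    halving_factor: int = 2
    max_depth: int = 10

    def validate(self) -> None:
        if not (0 < self.s_min < self.s_max):
            raise ValueError("need 0 < s_min < s_max")
        if self.k_initial < 2:
            raise ValueError("k_initial must be >= 2")
        if self.halving_factor < 2 or self.max_depth < 1:
            raise ValueError("halving_factor >= 2 and max_depth >= 1 required")


@dataclass
class ICCurve:
    """IC of the link removed at each successive cut level of a subtree."""

    k: np.ndarray  # strictly increasing cut levels
    ic: np.ndarray

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=np.int64)
        self.ic = np.asarray(self.ic, dtype=np.float64)
        if np.any(np.diff(self.k) <= 0):
            raise ValueError("cut levels must be strictly increasing")
        if not np.all(np.isfinite(self.ic)):
            raise ValueError("IC values must be finite")


def _forest_roots(dend: Dendrogram, subtree_root: int, removed: set[int]) -> list[int]:
    """Roots of the forest left after removing ``removed`` nodes below (and
    including) ``subtree_root``: surviving nodes whose parent is removed, plus
    the subtree root itself if it survives."""
    roots: list[int] = []
    stack = [int(subtree_root)]
    while stack:
        nd = stack.pop()
        if nd in removed:
            l, r = dend.children_of(nd)
            stack.extend((l, r))
        else:
            roots.append(nd)
    return roots


def cut_subtree(dend: Dendrogram, subtree_root: int, k: int) -> ClusterSet:
    """Cut the subtree rooted at ``subtree_root`` into k clusters by removing
    its k-1 greatest-height links (ties: later merge first)."""
    internal = dend.internal_nodes_under(subtree_root)
    n_sub_leaves = len(internal) + 1
    if not 1 <= k <= n_sub_leaves:
        raise ValueError(f"k={k} out of range 1..{n_sub_leaves}")
    if not dend.is_monotone():
        warnings.warn(
            "non-monotone heights: cut follows node height order, not a height threshold",
            stacklevel=2,
        )
    order = dend.removal_order(internal)
    removed = set(int(x) for x in order[: k - 1])
    roots = sorted(_forest_roots(dend, subtree_root, removed))
    clusters = [
        Cluster(cluster_id=ci + 1, node_id=nd, leaves=dend.leaves_under(nd), size=0)
        for ci, nd in enumerate(roots)
    ]
    for c in clusters:
        c.size = len(c.leaves)
    return ClusterSet(cut_level_k=k, clusters=clusters)


def cut(dend: Dendrogram, k: int) -> ClusterSet:
    """Cut the full dendrogram into k clusters."""
    return cut_subtree(dend, dend.root_id, k)


def track_split(prev: ClusterSet, nxt: ClusterSet) -> tuple[int, Cluster, Cluster]:
    """Identify the unique cluster of ``prev`` split in two at the next cut.

    Returns (mother node_id, child_a, child_b) with children ordered by node id.
    """
    if nxt.cut_level_k != prev.cut_level_k + 1:
        raise ValueError("cuts must be at consecutive levels k and k+1")
    prev_ids = prev.node_ids()
    next_ids = nxt.node_ids()
    gone = prev_ids - next_ids
    new = next_ids - prev_ids
    if len(gone) != 1 or len(new) != 2:
        raise ValueError("cuts do not differ by exactly one split")
    mother_id = gone.pop()
    mother = next(c for c in prev.clusters if c.node_id == mother_id)
    kids = sorted(
        (c for c in nxt.clusters if c.node_id in new), key=lambda c: c.node_id
    )
    union = np.union1d(kids[0].leaves, kids[1].leaves)
    if len(kids[0].leaves) + len(kids[1].leaves) != len(union) or not np.array_equal(
        union, mother.leaves
    ):
        raise ValueError("children do not disjointly union to the mother cluster")
    return mother_id, kids[0], kids[1]


def dissociable_nodes(
    dend: Dendrogram,
    subtree_root: int,
    is_significant: Callable[[int, float], bool],
    min_cc_of: Callable[[np.ndarray], float] | None = None,
) -> list[tuple[int, int, int]]:
    """Nodes whose cluster and both child clusters all pass the significance
    predicate, visiting nodes in descending height order.

    ``is_significant(size, min_internal_cc)`` decides; ``min_cc_of(leaves)``
    supplies the minimum inter-voxel mean CC of a cluster (NaN if omitted, for
    purely size-based predicates).  Returns (node_id, left_id, right_id).
    """

    def stats(node_id: int) -> tuple[int, float]:
        leaves = dend.leaves_under(node_id)
        mc = min_cc_of(leaves) if min_cc_of is not None else float("nan")
        return len(leaves), mc

    out: list[tuple[int, int, int]] = []
    for nd in dend.removal_order(dend.internal_nodes_under(subtree_root)):
        nd = int(nd)
        if not is_significant(*stats(nd)):
            continue
        l, r = dend.children_of(nd)
        if is_significant(*stats(l)) and is_significant(*stats(r)):
            out.append((nd, l, r))
    return out


@dataclass
class ExtractionRecord:
    """Provenance of one cluster seen during iterative extraction."""

    iteration: int
    parent_node: int
    k_used: int
    node_id: int
    size: int
    status: str  # candidate | too_small | oversize_recursed | oversize_maxdepth


def extract_rfns(
    dend: Dendrogram, cfg: ExtractionConfig
) -> tuple[list[Cluster], list[ExtractionRecord]]:
    """Iterative RFN extraction: cut, filter by size band, re-cut oversize
    clusters in their own subtree at a halved count.

    Returns candidate clusters (re-numbered 1..m in node-id order) and the full
    provenance log; oversize clusters at max depth are emitted flagged rather
    than dropped.
    """
    cfg.validate()
    log: list[ExtractionRecord] = []
    candidates: list[Cluster] = []

    def recurse(root: int, k: int, depth: int) -> None:
        n_sub = len(dend.internal_nodes_under(root)) + 1
        k_eff = max(2, min(k, n_sub))
        cs = cut_subtree(dend, root, k_eff)
        for c in cs.clusters:
            rec = ExtractionRecord(
                iteration=depth, parent_node=root, k_used=k_eff, node_id=c.node_id, size=c.size, status=""
            )
            if c.size > cfg.s_max:
                if depth >= cfg.max_depth or dend.is_leaf(c.node_id) or c.node_id == root:
                    rec.status = "oversize_maxdepth"
                    warnings.warn(
                        f"cluster at node {c.node_id} (S={c.size}) still oversize at max depth",
                        stacklevel=2,
                    )
                    candidates.append(c)
                else:
                    rec.status = "oversize_recursed"
                    log.append(rec)
                    recurse(c.node_id, max(2, k_eff // cfg.halving_factor), depth + 1)
                    continue
            elif c.size < cfg.s_min:
                rec.status = "too_small"
            else:
                rec.status = "candidate"
                candidates.append(c)
            log.append(rec)

    recurse(dend.root_id, cfg.k_initial, 1)
    candidates.sort(key=lambda c: c.node_id)
    out = [
        Cluster(cluster_id=ci + 1, node_id=c.node_id, leaves=c.leaves, size=c.size)
        for ci, c in enumerate(candidates)
    ]
    return out, log


def dissect_significant(
    dend: Dendrogram,
    subtree_root: int,
    is_significant: Callable[[int, float], bool],
    min_cc_of: Callable[[np.ndarray], float] | None = None,
    k_max: int | None = None,
) -> tuple[list[tuple[int, int, int]], list[Cluster]]:
    """Dissect an RFN subtree down to cut level ``k_max``.

    Iterates the subtree's nodes in descending height order (the successive
    cuts), recording every dissociable node — a significant cluster splitting
    into two significant clusters.  The extracted sub-networks are the
    significant clusters of the final cut at ``k_max``.  Returns
    (dissociable nodes, sub-network clusters).
    """
    internal = dend.internal_nodes_under(subtree_root)
    n_sub_leaves = len(internal) + 1
    if k_max is None:
        k_max = n_sub_leaves
    k_max = min(k_max, n_sub_leaves)
    order = dend.removal_order(internal)[: max(0, k_max - 1)]

    def stats(node_id: int) -> tuple[int, float]:
        leaves = dend.leaves_under(node_id)
        mc = min_cc_of(leaves) if min_cc_of is not None else float("nan")
        return len(leaves), mc

    sig_cache: dict[int, bool] = {}

    def sig(node_id: int) -> bool:
        if node_id not in sig_cache:
            sig_cache[node_id] = bool(is_significant(*stats(node_id)))
        return sig_cache[node_id]

    # descend: the node removed at step k-1 IS the mother cluster split when
    # moving from cut k-1 to cut k (removal is upward-closed for monotone
    # heights), so dissociability is checked node by node in removal order
    dissociable: list[tuple[int, int, int]] = []
    for nd in order:
        nd = int(nd)
        l, r = dend.children_of(nd)
        if sig(nd) and sig(l) and sig(r):
            dissociable.append((nd, l, r))

    # sub-networks: the significant clusters of the final cut
    final = cut_subtree(dend, subtree_root, k_max)
    terminal = [c for c in final.clusters if sig(c.node_id)]
    terminal.sort(key=lambda c: c.node_id)
    terminal = [
        Cluster(cluster_id=ci + 1, node_id=c.node_id, leaves=c.leaves, size=c.size)
        for ci, c in enumerate(terminal)
    ]
    return dissociable, terminal


def inconsistency(dend: Dendrogram, node_id: int, depth: int = 2) -> float:
    """Inconsistency coefficient of a link.

    Over the link set L = the node plus its internal descendants within
    ``depth`` levels (depth 2 = the node and its immediate children, the "two
    adjacent levels"), IC = (h_node - mean(h(L))) / std(h(L)) with sample std
    (ddof=1); 0 when the std vanishes.
    """
    if dend.is_leaf(node_id) or not (dend.n_leaves <= node_id < dend.n_nodes):
        raise ValueError(f"node {node_id} is not an internal node")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    heights: list[float] = []
    stack = [(int(node_id), 1)]
    while stack:
        nd, level = stack.pop()
        heights.append(dend.height_of(nd))
        if level < depth:
            for c in dend.children_of(nd):
                if not dend.is_leaf(c):
                    stack.append((c, level + 1))
    h = np.array(heights)
    if len(h) < 2:
        return 0.0
    sd = h.std(ddof=1)
    if sd < 1e-300:
        return 0.0
    return float((dend.height_of(node_id) - h.mean()) / sd)


def ic_curve(dend: Dendrogram, subtree_root: int, k_max: int, depth: int = 2) -> ICCurve:
    """IC of the link removed when moving from cut k-1 to cut k, for k = 2..k_max."""
    internal = dend.internal_nodes_under(subtree_root)
    n_sub_leaves = len(internal) + 1
    if not 2 <= k_max <= n_sub_leaves:
        raise ValueError(f"k_max={k_max} out of range 2..{n_sub_leaves}")
    order = dend.removal_order(internal)
    ks = np.arange(2, k_max + 1)
    ics = np.array([inconsistency(dend, int(order[k - 2]), depth=depth) for k in ks])
    return ICCurve(k=ks, ic=ics)


def ic_intersection(a: ICCurve, b: ICCurve) -> tuple[int, float] | None:
    """First crossing of two IC curves over their shared k range.

    Returns (k_star, ic_star): the first k at which the sign of a(k) - b(k)
    differs from the previous k, with ic_star the linearly interpolated value
    of the curves at the crossing.  None (with no crossing) if the curves never
    cross; symmetric in its arguments.
    """
    shared = np.intersect1d(a.k, b.k)
    if shared.size == 0:
        raise ValueError("curves share no k range")
    av = a.ic[np.searchsorted(a.k, shared)]
    bv = b.ic[np.searchsorted(b.k, shared)]
    diff = av - bv
    sign = np.sign(diff)
    for idx in range(1, len(shared)):
        if sign[idx] == 0 or (sign[idx - 1] != 0 and sign[idx] != sign[idx - 1]):
            d0, d1 = diff[idx - 1], diff[idx]
            t = 0.0 if d0 == d1 else d0 / (d0 - d1)
            ic_star = av[idx - 1] + t * (av[idx] - av[idx - 1])
            return int(shared[idx]), float(ic_star)
    return None
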