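"""Sub-dendrogram assembly and cluster report tables.

The significant sub-networks of one functional network are re-assembled into a
reduced *sub-dendrogram*: its leaves are the sub-networks (at their own node
heights in the full tree) and its internal node heights are cophenetic
distances — the threshold height at which two sub-network groups join in the
full dendrogram.  Leaves are labeled in ascending order of their heights.
Report rows carry sizes, heights, focal points (unweighted centroid in mm) and
within-cluster CC summaries.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .connectivity import MeanCCMatrix
from .dissect import Cluster, inconsistency
from .tree import Dendrogram, average_linkage, cophenetic, write_node_list
from .volumes import GrayMask

__all__ = [
    "SubDendrogram",
    "ClusterReportRow",
    "build_subdendrogram",
    "cluster_summary",
    "focal_point",
    "make_report_rows",
    "subdendrogram_newick",
    "write_reports",
]


@dataclass
class SubDendrogram:
    """Reduced tree over significant sub-networks.

    ``tree`` is a dendrogram whose leaf i is ``clusters[i]`` (ordered, and
    labeled 1..m, ascending by their node heights in the full dendrogram);
    ``leaf_heights[i]`` is that cluster's own merge height and ``tree.heights``
    are cophenetic distances in the full dendrogram.
    """

    tree: Dendrogram
    clusters: list[Cluster]
    leaf_heights: np.ndarray

    @property
    def n_subnetworks(self) -> int:
        return len(self.clusters)


def build_subdendrogram(dend: Dendrogram, significant: list[Cluster]) -> SubDendrogram:
    """Assemble the sub-dendrogram of a set of disjoint significant clusters.

    Each cluster must correspond to a node of the full dendrogram; internal
    heights of the reduced tree are the full-tree cophenetic distances between
    the clusters (which form an ultrametric, so average linkage on them
    reconstructs the induced topology exactly).
    """
    if len(significant) < 2:
        raise ValueError("need at least 2 clusters to build a sub-dendrogram")
    seen: set[int] = set()
    for c in significant:
        leaf_set = set(int(x) for x in c.leaves)
        if seen & leaf_set:
            raise ValueError(f"cluster at node {c.node_id} overlaps another cluster")
        seen |= leaf_set

    # label order: ascending cluster node height, ties by node id
    ordered = sorted(significant, key=lambda c: (dend.height_of(c.node_id), c.node_id))
    ordered = [
        Cluster(cluster_id=i + 1, node_id=c.node_id, leaves=c.leaves, size=c.size)
        for i, c in enumerate(ordered)
    ]
    m = len(ordered)
    reps = [int(c.leaves[0]) for c in ordered]
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            D[i, j] = D[j, i] = cophenetic(dend, reps[i], reps[j])
    tree = average_linkage(D)
    leaf_heights = np.array([dend.height_of(c.node_id) for c in ordered])
    return SubDendrogram(tree=tree, clusters=ordered, leaf_heights=leaf_heights)


def _pair_index(n: int, i: np.ndarray, j: np.ndarray) -> np.ndarray:
    """Condensed index of pairs (i < j) in an n-voxel matrix."""
    return (n * i - i * (i + 1) // 2 + (j - i - 1)).astype(np.int64)


def cluster_summary(leaves: np.ndarray, mcc: MeanCCMatrix) -> tuple[float, float, float]:
    """(CC_min, CC_avg, CC_max) over all within-cluster voxel pairs.

    Zeroed (sub-threshold) pairs count as 0 — the minimum is the cluster's
    weakest linkage.
    """
    leaves = np.asarray(leaves, dtype=np.int64)
    if len(leaves) < 2:
        raise ValueError("cluster summary needs at least 2 voxels")
    ii, jj = np.triu_indices(len(leaves), k=1)
    a, b = leaves[ii], leaves[jj]
    lo, hi = np.minimum(a, b), np.maximum(a, b)
    vals = mcc.values[_pair_index(mcc.n_voxels, lo, hi)].astype(np.float64)
    return float(vals.min()), float(vals.mean()), float(vals.max())


def focal_point(leaves: np.ndarray, mask: GrayMask) -> tuple[float, float, float]:
    """Unweighted centroid of the cluster's voxel centers, in mm."""
    leaves = np.asarray(leaves, dtype=np.int64)
    if leaves.size == 0:
        raise ValueError("empty cluster has no focal point")
    coords = mask.coordinates_mm()[leaves]
    return tuple(float(x) for x in coords.mean(axis=0))


@dataclass
class ClusterReportRow:
    """One sub-network's summary line (table analogue)."""

    cluster_id: int
    node_id: int
    size: int
    height: float
    focal_point: tuple[float, float, float]
    cc_min: float
    cc_avg: float
    cc_max: float
    ic: float

    def __post_init__(self) -> None:
        if not (self.cc_min <= self.cc_avg <= self.cc_max):
            raise ValueError("CC summary must satisfy min <= avg <= max")
        if self.size < 1:
            raise ValueError("size must be >= 1")


def make_report_rows(
    dend: Dendrogram,
    subdend: SubDendrogram,
    mcc: MeanCCMatrix,
    mask: GrayMask,
    ic_depth: int = 2,
) -> list[ClusterReportRow]:
    rows = []
    for c, h in zip(subdend.clusters, subdend.leaf_heights):
        cc_min, cc_avg, cc_max = cluster_summary(c.leaves, mcc)
        ic = inconsistency(dend, c.node_id, depth=ic_depth) if not dend.is_leaf(c.node_id) else 0.0
        rows.append(
            ClusterReportRow(
                cluster_id=c.cluster_id,
                node_id=c.node_id,
                size=c.size,
                height=float(h),
                focal_point=focal_point(c.leaves, mask),
                cc_min=cc_min,
                cc_avg=cc_avg,
                cc_max=cc_max,
                ic=float(ic),
            )
        )
    return rows


def subdendrogram_newick(subdend: SubDendrogram) -> str:
    """Newick string with branch lengths equal to height differences.

    Leaf names are the ascending-height labels; tip-to-tip path lengths then
    reproduce 2*coph(i,j) - h_i - h_j.
    """
    tree = subdend.tree
    m = tree.n_leaves

    def h(node_id: int) -> float:
        if node_id < m:
            return float(subdend.leaf_heights[node_id])
        return tree.height_of(node_id)

    def render(node_id: int, parent_h: float | None) -> str:
        if node_id < m:
            name = str(subdend.clusters[node_id].cluster_id)
            body = name
        else:
            l, r = tree.children_of(node_id)
            body = f"({render(l, h(node_id))},{render(r, h(node_id))})"
        if parent_h is None:
            return body
        return f"{body}:{parent_h - h(node_id):.6f}"

    return render(tree.root_id, None) + ";\n"


def parse_newick_heights(newick: str, subdend: SubDendrogram) -> np.ndarray:
    """Re-derive pairwise cophenetic distances from a Newick export.

    Uses scikit-bio's tree parser; for leaves i, j with heights h_i, h_j the
    tip-to-tip path length is 2*coph - h_i - h_j, so coph follows directly.
    Returns the (m, m) cophenetic matrix in cluster-label order.
    """
    from skbio import TreeNode

    t = TreeNode.read(io.StringIO(newick))
    m = subdend.n_subnetworks
    coph = np.zeros((m, m))
    tips = {tip.name: tip for tip in t.tips()}
    for i in range(m):
        for j in range(i + 1, m):
            a = tips[str(subdend.clusters[i].cluster_id)]
            b = tips[str(subdend.clusters[j].cluster_id)]
            path = a.distance(b)
            coph[i, j] = coph[j, i] = (
                path + subdend.leaf_heights[i] + subdend.leaf_heights[j]
            ) / 2.0
    return coph


def write_reports(
    subdend: SubDendrogram | None,
    rows: list[ClusterReportRow],
    mask: GrayMask,
    out_dir,
    prefix: str = "subnetworks",
) -> dict[str, Path]:
    """Write label map (NIfTI), summary TSV, node-list ASCII and Newick tree.

    With no significant clusters, writes only an empty table and warns.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    table_path = out_dir / f"{prefix}.tsv"
    df = pd.DataFrame(
        [
            {
                "cluster_id": r.cluster_id,
                "node_id": r.node_id,
                "size": r.size,
                "height": round(r.height, 6),
                "focal_x_mm": round(r.focal_point[0], 3),
                "focal_y_mm": round(r.focal_point[1], 3),
                "focal_z_mm": round(r.focal_point[2], 3),
                "cc_min": round(r.cc_min, 6),
                "cc_avg": round(r.cc_avg, 6),
                "cc_max": round(r.cc_max, 6),
                "ic": round(r.ic, 6),
            }
            for r in rows
        ],
        columns=[
            "cluster_id", "node_id", "size", "height", "focal_x_mm", "focal_y_mm",
            "focal_z_mm", "cc_min", "cc_avg", "cc_max", "ic",
        ],
    )
    df.to_csv(table_path, sep="\t", index=False)
    written["table"] = table_path

    if subdend is None or subdend.n_subnetworks == 0:
        warnings.warn("no significant sub-networks: skipping label map and trees", stacklevel=2)
        return written

    label_vol = np.zeros(mask.data.shape, dtype=np.int16)
    ix = mask.voxel_indices
    for c in subdend.clusters:
        vox = ix[c.leaves]
        label_vol[vox[:, 0], vox[:, 1], vox[:, 2]] = c.cluster_id
    label_path = out_dir / f"{prefix}_labels.nii.gz"
    nib.save(nib.Nifti1Image(label_vol, mask.affine), str(label_path))
    written["label_map"] = label_path

    nodes_path = out_dir / f"{prefix}_tree.txt"
    nodes_path.write_text(write_node_list(subdend.tree))
    written["node_list"] = nodes_path

    newick_path = out_dir / f"{prefix}.nwk"
    newick_path.write_text(subdendrogram_newick(subdend))
    written["newick"] = newick_path
    return written
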