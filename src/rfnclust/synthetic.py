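"""Synthetic multi-subject resting-state data with planted hierarchical modules.

The generative model is a nested mixture of shared signals.  Every module in a
rooted hierarchy owns a latent time course s_a(t); a voxel belonging to leaf
module m receives

    y_v(t) = sum_{a in ancestors(m) + {m}} w_a * s_a(t)  +  noise_sd * eps_v(t)

with independent unit-variance latent courses and white voxel noise.  The
expected Pearson correlation between voxels in leaves m1, m2 is then the ratio
of shared to total variance:

    E[CC] = sum_{a in common ancestors} w_a^2
            / sqrt(var(m1) * var(m2)),      var(m) = sum_{a} w_a^2 + noise_sd^2

so correlation strictly decreases with tree distance when every level carries a
positive weight — exactly the nested block structure that hierarchical
clustering should recover.  Latent courses are band-limited (< 0.08 Hz by
default) so the planted signal already lives in the resting-state frequency
band; the voxel noise stays white so null correlations keep their exact
T - 2 degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .volumes import GrayMask, TimeSeriesVolume

__all__ = [
    "ModuleNode",
    "SyntheticSpec",
    "GroundTruth",
    "generate_box_mask",
    "generate_dataset",
    "nested_block_spec",
    "write_ground_truth",
]


@dataclass
class ModuleNode:
    """One module in the planted hierarchy.

    ``weight`` is the mixing weight of this node's shared latent course.
    Leaf nodes own a disjoint set of voxels given as indices into the mask
    ordering (lexicographic (x, y, z) over in-mask voxels).
    """

    name: str
    weight: float = 0.0
    children: list["ModuleNode"] = field(default_factory=list)
    voxels: np.ndarray | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def iter_nodes(self):
        yield self
        for c in self.children:
            yield from c.iter_nodes()

    def leaves(self) -> list["ModuleNode"]:
        return [n for n in self.iter_nodes() if n.is_leaf]


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic multi-subject dataset.

    Defaults mirror a typical resting-state acquisition: TR = 2 s and 290
    retained timeframes (300 acquired minus 10 dropped for steady state).
    """

    grid_shape: tuple[int, int, int]
    hierarchy: ModuleNode
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    n_subjects: int = 20
    n_timepoints: int = 290
    tr_s: float = 2.0
    noise_sd: float = 1.0
    smooth_fwhm_mm: float = 0.0
    band_hz: float = 0.08
    seed: int | None = None

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is required: synthetic datasets must be reproducible")
        if min(self.grid_shape) < 1 or len(self.grid_shape) != 3:
            raise ValueError("grid_shape must be 3 positive integers")
        if self.n_timepoints < 10:
            raise ValueError("n_timepoints must be >= 10")
        if self.n_subjects < 1 or self.tr_s <= 0 or self.noise_sd <= 0:
            raise ValueError("n_subjects, tr_s, noise_sd must be positive")
        if self.smooth_fwhm_mm < 0:
            raise ValueError("smooth_fwhm_mm must be non-negative")
        n_total = int(np.prod(self.grid_shape))
        seen: set[int] = set()
        for leaf in self.hierarchy.leaves():
            if leaf.voxels is None:
                raise ValueError(f"leaf module {leaf.name!r} has no voxel set")
            vox = np.asarray(leaf.voxels)
            if vox.size and (vox.min() < 0 or vox.max() >= n_total):
                raise ValueError(f"leaf module {leaf.name!r} has voxels outside the mask")
            overlap = seen.intersection(vox.tolist())
            if overlap:
                raise ValueError(
                    f"leaf module voxel sets overlap (e.g. voxel {min(overlap)})"
                )
            seen.update(vox.tolist())


@dataclass
class GroundTruth:
    """Planted labels and the module hierarchy with expected correlations."""

    leaf_labels: np.ndarray  # (n_voxels,) int; -1 = unstructured background
    leaf_names: list[str]
    module_tree: ModuleNode
    noise_sd: float

    def _variance(self, leaf: ModuleNode, ancestors: dict[str, list[ModuleNode]]) -> float:
        return sum(a.weight**2 for a in ancestors[leaf.name]) + self.noise_sd**2

    def _ancestor_map(self) -> dict[str, list[ModuleNode]]:
        out: dict[str, list[ModuleNode]] = {}

        def walk(node: ModuleNode, chain: list[ModuleNode]) -> None:
            chain = chain + [node]
            if node.is_leaf:
                out[node.name] = chain
            for c in node.children:
                walk(c, chain)

        walk(self.module_tree, [])
        return out

    def expected_cc(self, leaf_a: str, leaf_b: str) -> float:
        """Closed-form expected Pearson CC between voxels of two leaf modules."""
        anc = self._ancestor_map()
        ca, cb = anc[leaf_a], anc[leaf_b]
        shared = 0.0
        for a, b in zip(ca, cb):
            if a is not b:
                break
            shared += a.weight**2
        if leaf_a == leaf_b:
            shared = sum(a.weight**2 for a in ca)
        va = self._variance(ca[-1], anc)
        vb = self._variance(cb[-1], anc)
        return shared / np.sqrt(va * vb)

    def tree_distance(self, leaf_a: str, leaf_b: str) -> int:
        """Number of tree edges between two leaves (0 for the same leaf)."""
        if leaf_a == leaf_b:
            return 0
        anc = self._ancestor_map()
        ca, cb = anc[leaf_a], anc[leaf_b]
        depth = 0
        for a, b in zip(ca, cb):
            if a is not b:
                break
            depth += 1
        return (len(ca) - depth) + (len(cb) - depth)


def generate_box_mask(
    grid_shape,
    exclude=None,
    voxel_size_mm=(3.0, 3.0, 3.0),
) -> GrayMask:
    """Full rectangular mask over ``grid_shape``, minus optional excluded voxels.

    The in-mask voxel ordering is lexicographic in (x, y, z) and shared by every
    downstream matrix and dendrogram.
    """
    grid_shape = tuple(int(s) for s in grid_shape)
    if len(grid_shape) != 3 or min(grid_shape) < 1:
        raise ValueError("grid_shape must be 3 positive integers")
    data = np.ones(grid_shape, dtype=bool)
    if exclude is not None:
        for xyz in exclude:
            data[tuple(xyz)] = False
    if not data.any():
        raise ValueError("mask is empty after exclusions")
    affine = np.diag([*voxel_size_mm, 1.0])
    return GrayMask(data=data, affine=affine)


def _bandlimited_course(rng: np.random.Generator, n: int, tr_s: float, band_hz: float) -> np.ndarray:
    """Unit-variance Gaussian course with power restricted to f < band_hz."""
    x = rng.standard_normal(n)
    freqs = np.fft.rfftfreq(n, d=tr_s)
    spec = np.fft.rfft(x)
    spec[freqs > band_hz] = 0.0
    y = np.fft.irfft(spec, n=n)
    sd = y.std()
    if sd < 1e-12:  # degenerate only for absurdly small n
        raise ValueError("band-limited course degenerated to a constant")
    return (y - y.mean()) / sd


def generate_dataset(
    spec: SyntheticSpec, mask: GrayMask | None = None
) -> tuple[list[TimeSeriesVolume], GrayMask, GroundTruth]:
    """Draw one multi-subject dataset from ``spec``.

    Returns one 4D volume per subject, the mask, and the shared ground truth.
    Bit-identical for identical (spec, seed).
    """
    spec.validate()
    if mask is None:
        mask = generate_box_mask(spec.grid_shape, voxel_size_mm=spec.voxel_size_mm)
    if mask.data.shape != tuple(spec.grid_shape):
        raise ValueError("mask shape does not match spec.grid_shape")

    rng = np.random.default_rng(spec.seed)
    n_vox = mask.n_voxels
    ix = mask.voxel_indices
    leaves = spec.hierarchy.leaves()
    leaf_names = [lf.name for lf in leaves]

    labels = np.full(n_vox, -1, dtype=np.int64)
    for li, leaf in enumerate(leaves):
        labels[np.asarray(leaf.voxels, dtype=np.int64)] = li

    # ancestor chains (root..leaf) per leaf, nodes identified by object
    chains: list[list[ModuleNode]] = []

    def walk(node: ModuleNode, chain: list[ModuleNode]) -> None:
        chain = chain + [node]
        if node.is_leaf:
            chains.append(chain)
        for c in node.children:
            walk(c, chain)

    walk(spec.hierarchy, [])
    chain_by_name = {c[-1].name: c for c in chains}

    all_nodes = list(spec.hierarchy.iter_nodes())
    volumes: list[TimeSeriesVolume] = []
    T = spec.n_timepoints
    for _ in range(spec.n_subjects):
        courses = {
            id(node): _bandlimited_course(rng, T, spec.tr_s, spec.band_hz)
            for node in all_nodes
            if node.weight != 0.0
        }
        ts = rng.standard_normal((n_vox, T)) * spec.noise_sd
        for li, leaf in enumerate(leaves):
            signal = np.zeros(T)
            for node in chain_by_name[leaf.name]:
                if node.weight != 0.0:
                    signal += node.weight * courses[id(node)]
            ts[labels == li] += signal
        data = np.zeros((*spec.grid_shape, T))
        data[ix[:, 0], ix[:, 1], ix[:, 2], :] = ts
        vol = TimeSeriesVolume(data=data, affine=mask.affine.copy(), tr_s=spec.tr_s)
        if spec.smooth_fwhm_mm > 0:
            from .preprocess import smooth_masked

            vol = smooth_masked(vol, mask, spec.smooth_fwhm_mm)
        volumes.append(vol)

    gt = GroundTruth(
        leaf_labels=labels,
        leaf_names=leaf_names,
        module_tree=spec.hierarchy,
        noise_sd=spec.noise_sd,
    )
    return volumes, mask, gt


def nested_block_spec(
    grid_shape,
    network_sub_sizes: list[list[int]],
    cc_within_sub: float = 0.6,
    cc_within_net: float = 0.4,
    cc_between_net: float = 0.05,
    n_subjects: int = 20,
    n_timepoints: int = 290,
    seed: int | None = None,
    **kwargs,
) -> SyntheticSpec:
    """Two-level hierarchy (networks -> sub-networks) with target correlations.

    Mixing weights are solved from the closed-form expected-CC mapping with all
    module voxels normalized to unit total variance: with w_g (global), w_n
    (network), w_s (sub-network) and noise variance sigma^2,

        cc_between_net = w_g^2
        cc_within_net  = w_g^2 + w_n^2
        cc_within_sub  = w_g^2 + w_n^2 + w_s^2
        sigma^2        = 1 - cc_within_sub

    Sub-network voxel blocks are laid out contiguously in mask order starting at
    voxel 0; remaining voxels are unstructured background (pure noise).
    """
    if not (0 <= cc_between_net < cc_within_net < cc_within_sub < 1):
        raise ValueError("need 0 <= cc_between_net < cc_within_net < cc_within_sub < 1")
    w_g = float(np.sqrt(cc_between_net))
    w_n = float(np.sqrt(cc_within_net - cc_between_net))
    w_s = float(np.sqrt(cc_within_sub - cc_within_net))
    noise_sd = float(np.sqrt(1.0 - cc_within_sub))

    total = int(np.prod(grid_shape))
    needed = sum(sum(subs) for subs in network_sub_sizes)
    if needed > total:
        raise ValueError(f"{needed} module voxels do not fit a {total}-voxel grid")

    cursor = 0
    networks = []
    for ni, subs in enumerate(network_sub_sizes):
        children = []
        for si, size in enumerate(subs):
            vox = np.arange(cursor, cursor + size, dtype=np.int64)
            cursor += size
            children.append(ModuleNode(name=f"net{ni}/sub{si}", weight=w_s, voxels=vox))
        networks.append(ModuleNode(name=f"net{ni}", weight=w_n, children=children))
    root = ModuleNode(name="root", weight=w_g, children=networks)

    return SyntheticSpec(
        grid_shape=tuple(grid_shape),
        hierarchy=root,
        n_subjects=n_subjects,
        n_timepoints=n_timepoints,
        noise_sd=noise_sd,
        seed=seed,
        **kwargs,
    )


def write_ground_truth(gt: GroundTruth, mask: GrayMask, out_dir) -> None:
    """Persist ground truth as a labels TSV plus a parent-child tree edge list."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ix = mask.voxel_indices
    with open(out_dir / "ground_truth_labels.tsv", "w") as fh:
        fh.write("voxel\tx\ty\tz\tleaf\n")
        for v, (x, y, z) in enumerate(ix):
            lab = gt.leaf_labels[v]
            name = gt.leaf_names[lab] if lab >= 0 else "background"
            fh.write(f"{v}\t{x}\t{y}\t{z}\t{name}\n")
    with open(out_dir / "ground_truth_tree.tsv", "w") as fh:
        fh.write("parent\tchild\texpected_cc_under_child\n")

        def walk(node: ModuleNode) -> None:
            for c in node.children:
                lv = c.leaves()
                cc = gt.expected_cc(lv[0].name, lv[-1].name) if len(lv) > 1 else gt.expected_cc(
                    lv[0].name, lv[0].name
                )
                fh.write(f"{node.name}\t{c.name}\t{cc:.6f}\n")
                walk(c)

        walk(gt.module_tree)
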