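"""Thresholded voxel-pair correlation matrices and the clustering distance matrix.

Per subject, Pearson correlations between all in-mask voxel time courses are
thresholded at CC >= tau (default 0.3, corresponding to distance <= 0.7);
sub-threshold entries are set to 0.  Thresholded matrices are averaged
voxel-wise over subjects, and the mean matrix maps to distances d = 1 - CC for
positive mean CC, with every remaining pair set to a large sentinel distance so
that unconnected voxels merge last.

All pairwise matrices use condensed upper-triangle storage in the shared mask
voxel ordering; per-subject values are kept at single precision (a 13k-voxel
mask already implies ~85M pairs).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import squareform

from .volumes import GrayMask, TimeSeriesVolume

__all__ = [
    "CCMatrix",
    "MeanCCMatrix",
    "DistanceMatrix",
    "subject_cc",
    "cc_from_timeseries",
    "threshold_cc",
    "retained_fraction",
    "group_average",
    "to_distance",
    "cc_histogram",
    "save_condensed",
    "load_condensed",
]


@dataclass
class CCMatrix:
    """Condensed symmetric voxel-pair correlation matrix.

    ``values`` holds the upper triangle (scipy condensed order) over the
    n_voxels in-mask voxels; the unit diagonal is implicit.  ``tau`` records
    the applied threshold, or None if unthresholded.
    """

    values: np.ndarray
    n_voxels: int
    tau: float | None = None

    def __post_init__(self) -> None:
        expect = self.n_voxels * (self.n_voxels - 1) // 2
        if self.values.shape != (expect,):
            raise ValueError(
                f"condensed length {self.values.shape} does not match n_voxels={self.n_voxels}"
            )

    def square(self) -> np.ndarray:
        """Full symmetric matrix with unit diagonal (small-n convenience)."""
        m = squareform(self.values.astype(np.float64))
        np.fill_diagonal(m, 1.0)
        return m


@dataclass
class MeanCCMatrix(CCMatrix):
    """Group-averaged thresholded CC matrix; optionally keeps the subject stack."""

    n_subjects: int = 0
    stack: np.ndarray | None = field(default=None, repr=False)  # (n_subjects, n_pairs)


@dataclass
class DistanceMatrix:
    """Condensed distance matrix feeding average-linkage clustering."""

    values: np.ndarray
    n_voxels: int
    d_max_sentinel: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values)):
            raise ValueError("distance matrix contains non-finite values")

    def square(self) -> np.ndarray:
        return squareform(self.values.astype(np.float64))


def cc_from_timeseries(ts: np.ndarray) -> CCMatrix:
    """Pairwise Pearson CC of row time courses; errors on zero-variance rows."""
    ts = np.asarray(ts, dtype=np.float64)
    if ts.ndim != 2:
        raise ValueError("expected (n_voxels, n_timepoints)")
    n_vox, t = ts.shape
    if t < 10:
        raise ValueError(f"need at least 10 timepoints, got {t}")
    sd = ts.std(axis=1)
    dead = np.flatnonzero(sd < 1e-30)
    if dead.size:
        raise ValueError(f"voxel {dead[0]} has zero temporal variance")
    cc = np.corrcoef(ts)
    np.clip(cc, -1.0, 1.0, out=cc)
    np.fill_diagonal(cc, 0.0)
    return CCMatrix(values=squareform(cc, checks=False).astype(np.float32), n_voxels=n_vox)


def subject_cc(vol: TimeSeriesVolume, mask: GrayMask) -> CCMatrix:
    """Unthresholded voxel-pair Pearson correlations for one subject."""
    return cc_from_timeseries(vol.timeseries(mask))


def threshold_cc(cc: CCMatrix, tau: float = 0.3) -> CCMatrix:
    """Keep entries with CC >= tau verbatim (boundary inclusive); zero the rest."""
    if not 0 <= tau < 1:
        raise ValueError("tau must lie in [0, 1)")
    vals = np.where(cc.values >= tau, cc.values, 0.0).astype(np.float32)
    return CCMatrix(values=vals, n_voxels=cc.n_voxels, tau=tau)


def retained_fraction(cc: CCMatrix) -> float:
    """Fraction of off-diagonal voxel pairs surviving the threshold."""
    if cc.tau is None:
        raise ValueError("retained_fraction requires a thresholded matrix")
    return float(np.count_nonzero(cc.values)) / cc.values.size


def group_average(ccs: list[CCMatrix], keep_stack: bool = False, drop_zeros: bool = False) -> MeanCCMatrix:
    """Voxel-wise arithmetic mean of thresholded per-subject matrices.

    By default sub-threshold entries contribute 0 to the mean.  With
    ``drop_zeros`` the mean runs over surviving subjects only (excluded from
    the denominator) — an alternative averaging convention kept behind a flag.
    """
    if not ccs:
        raise ValueError("no matrices to average")
    first = ccs[0]
    if first.tau is None:
        raise ValueError("group_average requires thresholded matrices")
    for c in ccs[1:]:
        if c.n_voxels != first.n_voxels or c.tau != first.tau:
            raise ValueError("matrices differ in n_voxels or tau")
    stack = np.stack([c.values for c in ccs]).astype(np.float32)
    # accumulate in double so the result is independent of subject order
    if drop_zeros:
        counts = np.count_nonzero(stack, axis=0)
        with np.errstate(invalid="ignore"):
            mean = np.where(
                counts > 0, stack.sum(axis=0, dtype=np.float64) / np.maximum(counts, 1), 0.0
            )
    else:
        mean = stack.mean(axis=0, dtype=np.float64)
    return MeanCCMatrix(
        values=mean.astype(np.float32),
        n_voxels=first.n_voxels,
        tau=first.tau,
        n_subjects=len(ccs),
        stack=stack if keep_stack else None,
    )


def to_distance(mcc: MeanCCMatrix, d_max: float = 9.0) -> DistanceMatrix:
    """d = 1 - meanCC where meanCC > 0; sentinel d_max elsewhere.

    The sentinel stands in for "unconnected" pairs; any value > 2 works, and
    must stay > 2 so it can never collide with an attainable distance.
    """
    if not d_max > 2:
        raise ValueError("d_max must exceed 2 (attainable distances reach 2)")
    vals = mcc.values.astype(np.float64)
    d = np.where(vals > 0, 1.0 - vals, d_max)
    return DistanceMatrix(values=d, n_voxels=mcc.n_voxels, d_max_sentinel=float(d_max))


def cc_histogram(mcc: MeanCCMatrix, bin_width: float = 0.006) -> np.ndarray:
    """Histogram of nonzero mean-CC values over equal bins covering (0, 1].

    Returns a structured-friendly (n_bins, 2) array of (bin_low, count);
    counts sum to the number of nonzero entries.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = int(np.ceil(1.0 / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    vals = mcc.values[mcc.values > 0]
    counts, _ = np.histogram(vals, bins=edges)
    # np.histogram treats bins as half-open [lo, hi) except the last; values at
    # exactly 1.0 land in the final bin either way.
    return np.column_stack([edges[:-1], counts])


def save_condensed(path, matrix: CCMatrix | DistanceMatrix, mask: GrayMask | None = None) -> None:
    """Write a condensed matrix as .npy plus a JSON sidecar with its contract."""
    path = Path(path)
    np.save(path, matrix.values)
    meta: dict = {"n_voxels": matrix.n_voxels}
    if isinstance(matrix, MeanCCMatrix):
        meta.update(kind="mean_cc", tau=matrix.tau, n_subjects=matrix.n_subjects)
    elif isinstance(matrix, CCMatrix):
        meta.update(kind="cc", tau=matrix.tau)
    else:
        meta.update(kind="distance", d_max_sentinel=matrix.d_max_sentinel)
    if mask is not None:
        meta["voxel_ordering_hash"] = mask.ordering_hash()
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(meta, fh, indent=1)


def load_condensed(path):
    path = Path(path)
    values = np.load(path)
    with open(path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    n = meta["n_voxels"]
    kind = meta["kind"]
    if kind == "distance":
        return DistanceMatrix(values=values, n_voxels=n, d_max_sentinel=meta["d_max_sentinel"])
    if kind == "mean_cc":
        return MeanCCMatrix(values=values, n_voxels=n, tau=meta["tau"], n_subjects=meta["n_subjects"])
    return CCMatrix(values=values, n_voxels=n, tau=meta["tau"])
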