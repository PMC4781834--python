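"""Core spatial containers: 4D BOLD time-series volumes and binary gray-matter masks.

All pairwise matrices and dendrogram leaves in this package index voxels by the
*mask ordering*: in-mask voxels sorted lexicographically by their (x, y, z) grid
indices.  Fixing this convention once, here, removes index-mismatch bugs between
the connectivity, clustering and reporting stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["TimeSeriesVolume", "GrayMask", "load_volume", "load_mask"]


@dataclass
class TimeSeriesVolume:
    """A single subject's BOLD run: a 4D (x, y, z, t) array plus geometry.

    Parameters
    ----------
    data : 4D float array, (nx, ny, nz, nt)
    affine : (4, 4) voxel-to-mm transform; must be invertible.
    tr_s : repetition time in seconds (sampling interval of the t axis).
    """

    data: np.ndarray
    affine: np.ndarray
    tr_s: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D (x, y, z, t) data, got ndim={self.data.ndim}")
        if self.data.shape[3] < 10:
            raise ValueError(f"need at least 10 timepoints, got {self.data.shape[3]}")
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        if not self.tr_s > 0:
            raise ValueError("tr_s must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Per-axis voxel edge lengths in mm, from the affine column norms."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def timeseries(self, mask: "GrayMask") -> np.ndarray:
        """Return the (n_voxels, nt) matrix of in-mask voxel time courses."""
        if mask.data.shape != self.shape:
            raise ValueError(
                f"mask shape {mask.data.shape} does not match volume shape {self.shape}"
            )
        ix = mask.voxel_indices
        return self.data[ix[:, 0], ix[:, 1], ix[:, 2], :]

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.data.astype(np.float32), self.affine)
        img.header.set_zooms((*self.voxel_size_mm, self.tr_s))
        return img

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))


@dataclass
class GrayMask:
    """Binary 3D mask of voxels entering the analysis.

    ``voxel_indices`` enumerates in-mask voxels in the canonical lexicographic
    (x, y, z) order shared by every matrix and dendrogram in the package.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={self.data.ndim}")
        if not self.data.any():
            raise ValueError("mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def voxel_indices(self) -> np.ndarray:
        """(n_voxels, 3) int array of in-mask grid indices, lexicographic in (x, y, z)."""
        # np.argwhere iterates the C-ordered array, which is exactly the
        # lexicographic (x, y, z) ordering for an (nx, ny, nz) grid.
        return np.argwhere(self.data)

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def coordinates_mm(self) -> np.ndarray:
        """(n_voxels, 3) mm coordinates of in-mask voxel centers."""
        ix = self.voxel_indices
        homog = np.c_[ix, np.ones(len(ix))]
        return (homog @ self.affine.T)[:, :3]

    def ordering_hash(self) -> str:
        """Stable hex digest of the voxel ordering, for provenance sidecars."""
        import hashlib

        return hashlib.sha256(self.voxel_indices.astype(np.int64).tobytes()).hexdigest()[:16]

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.uint8), self.affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))


def load_volume(path, tr_s: float | None = None) -> TimeSeriesVolume:
    """Read a 4D NIfTI file; TR taken from the header unless overridden."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if tr_s is None:
        zooms = img.header.get_zooms()
        tr_s = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0
    return TimeSeriesVolume(data=data, affine=img.affine, tr_s=tr_s)


def load_mask(path) -> GrayMask:
    img = nib.load(str(path))
    return GrayMask(data=np.asarray(img.dataobj) > 0, affine=img.affine)
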