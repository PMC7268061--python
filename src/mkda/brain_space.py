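"""Voxel grids, masks, world<->voxel mapping and cluster labeling.

Everything downstream operates on a fixed :class:`VoxelGrid` (2 mm
isotropic MNI-aligned by default) restricted to a binary gray-matter
:class:`Mask`. Contiguity for cluster-extent statistics follows SPM's
18-neighbour convention by default; 6 and 26 are also available.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import nibabel as nib
import numpy as np
from scipy import ndimage

CONNECTIVITIES = (6, 18, 26)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity not in CONNECTIVITIES:
        raise ValueError(f"connectivity must be one of {CONNECTIVITIES}")
    return ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])


@dataclass(frozen=True)
class VoxelGrid:
    """A 3-D sampling grid defined by a world-from-voxel affine and a shape."""

    affine: np.ndarray
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        object.__setattr__(self, "affine", aff)
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError("shape must be 3 positive integers")
        object.__setattr__(self, "shape", shape)

    @property
    def voxel_size(self) -> np.ndarray:
        """mm per axis: column norms of the affine's linear part."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @classmethod
    def mni_2mm(cls) -> "VoxelGrid":
        """The standard MNI152 2 mm grid (91 x 109 x 91)."""
        affine = np.array(
            [
                [-2.0, 0.0, 0.0, 90.0],
                [0.0, 2.0, 0.0, -126.0],
                [0.0, 0.0, 2.0, -72.0],
                [0.0, 0.0, 0.0, 1.0],
            ]
        )
        return cls(affine=affine, shape=(91, 109, 91))


def _round_half_away(v: np.ndarray) -> np.ndarray:
    # round-half-away-from-zero, unlike numpy's banker's rounding
    return np.sign(v) * np.floor(np.abs(v) + 0.5)


def mm_to_voxel(grid: VoxelGrid, points_mm: np.ndarray) -> np.ndarray:
    """Map mm coordinates to integer voxel indices (nearest voxel).

    Rounding is half-away-from-zero. Indices may fall outside the array
    bounds; callers decide whether that is an error.
    """
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    inv = np.linalg.inv(grid.affine)
    vox = pts @ inv[:3, :3].T + inv[:3, 3]
    out = _round_half_away(vox).astype(int)
    return out[0] if np.asarray(points_mm).ndim == 1 else out


def voxel_to_mm(grid: VoxelGrid, ijk: np.ndarray) -> np.ndarray:
    """Map voxel indices to the mm coordinates of their centers."""
    idx = np.atleast_2d(np.asarray(ijk, dtype=float))
    mm = idx @ grid.affine[:3, :3].T + grid.affine[:3, 3]
    return mm[0] if np.asarray(ijk).ndim == 1 else mm


@dataclass(frozen=True)
class Mask:
    """Binary analysis mask on a voxel grid."""

    grid: VoxelGrid
    inside: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.inside).astype(bool)
        if arr.shape != self.grid.shape:
            raise ValueError(f"mask shape {arr.shape} != grid shape {self.grid.shape}")
        if not arr.any():
            raise ValueError("empty mask: no inside voxels")
        object.__setattr__(self, "inside", arr)

    @property
    def n_voxels(self) -> int:
        return int(self.inside.sum())

    @property
    def voxel_indices(self) -> np.ndarray:
        """(n, 3) integer indices of in-mask voxels, scan order."""
        return np.argwhere(self.inside)

    def fingerprint(self) -> str:
        h = hashlib.sha1()
        h.update(np.ascontiguousarray(self.grid.affine).tobytes())
        h.update(np.ascontiguousarray(self.inside).tobytes())
        return h.hexdigest()[:16]


@dataclass(frozen=True)
class LabelMap:
    """Connected-component labeling: 0 = background, labels 1..n_clusters."""

    grid: VoxelGrid
    labels: np.ndarray
    sizes: np.ndarray  # sizes[k-1] is the voxel count of cluster k

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)


def connected_components(
    binary: np.ndarray, grid: VoxelGrid, connectivity: int = 18
) -> LabelMap:
    """Label maximal connected sets of a binary map.

    Labels are renumbered so cluster 1 is the first encountered in C-order
    array scan, making the output deterministic across scipy versions.
    """
    arr = np.asarray(binary).astype(bool)
    if arr.shape != grid.shape:
        raise ValueError("binary map shape does not match grid")
    raw, n = ndimage.label(arr, structure=_structure(connectivity))
    if n == 0:
        return LabelMap(grid=grid, labels=raw, sizes=np.zeros(0, dtype=int))
    flat = raw.ravel()
    nz = np.flatnonzero(flat)
    first_seen, order_idx = np.unique(flat[nz], return_index=True)
    order = first_seen[np.argsort(nz[order_idx])]  # labels by first occurrence
    remap = np.zeros(n + 1, dtype=raw.dtype)
    remap[order] = np.arange(1, n + 1)
    labels = remap[raw]
    sizes = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    return LabelMap(grid=grid, labels=labels, sizes=sizes.astype(int))


def max_cluster_size(binary: np.ndarray, grid: VoxelGrid, connectivity: int = 18) -> int:
    """Size in voxels of the largest connected cluster (0 if empty)."""
    arr = np.asarray(binary).astype(bool)
    if not arr.any():
        return 0
    raw, n = ndimage.label(arr, structure=_structure(connectivity))
    return int(np.bincount(raw.ravel())[1:].max())


def load_mask(path: Union[str, Path]) -> Mask:
    """Load a NIfTI volume as a binary mask (nonzero = inside)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got {data.ndim}-D")
    grid = VoxelGrid(affine=np.asarray(img.affine), shape=data.shape)
    inside = data > 0
    if not inside.any():
        raise ValueError("empty mask")
    return Mask(grid=grid, inside=inside)


def write_map(data: np.ndarray, grid: VoxelGrid, path: Union[str, Path]) -> None:
    """Write a voxel map on a grid to NIfTI-1."""
    arr = np.asarray(data)
    if arr.shape != grid.shape:
        raise ValueError("map shape does not match grid")
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    img = nib.Nifti1Image(arr, grid.affine)
    nib.save(img, str(path))


def load_map(path: Union[str, Path]) -> tuple[np.ndarray, VoxelGrid]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got {data.ndim}-D")
    return data, VoxelGrid(affine=np.asarray(img.affine), shape=data.shape)
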