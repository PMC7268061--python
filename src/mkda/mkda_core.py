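"""The MKDA statistic: contrast indicator maps and the summary density map.

For each contrast a binary *contrast indicator map* (CIM) marks every voxel
whose center lies within the kernel radius (10 mm by default) of any of the
contrast's peaks. The summary density map is the weighted proportion of
CIMs active at each voxel,

    P(v) = sum_c w_c I_c(v) / sum_c w_c,    w_c = sqrt(N_c) * delta(design_c)

with delta = 0.75 for fixed-effects contrasts and 1.00 for random-effects
ones. P(v) is the "z" / Maxstat statistic reported for clusters: a weighted
percentage of contrasts activating near v, *not* a Gaussian deviate.
Because each contrast contributes at most one indicator regardless of how
many peaks it reports, a study listing many nearby peaks cannot dominate
the map.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .brain_space import Mask, VoxelGrid, mm_to_voxel
from .foci_io import Contrast, StudySet


@dataclass(frozen=True)
class KernelSpec:
    """Spherical smoothing kernel; a voxel is in the kernel iff its center
    is within `radius` mm (closed ball) of the peak's voxel center."""

    radius: float = 10.0

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("kernel radius must be >= 0")


@dataclass(frozen=True)
class WeightScheme:
    """sqrt(N) weighting with a design multiplier down-weighting
    fixed-effects contrasts."""

    delta_fixed: float = 0.75
    delta_random: float = 1.0

    def __post_init__(self) -> None:
        for d in (self.delta_fixed, self.delta_random):
            if not (0 < d <= 1):
                raise ValueError("design deltas must lie in (0, 1]")

    def delta(self, design: str) -> float:
        return self.delta_fixed if design == "fixed" else self.delta_random


def contrast_weight(contrast: Contrast, scheme: WeightScheme = WeightScheme()) -> float:
    """w_c = sqrt(N_c) * delta(design_c)."""
    if contrast.n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    return math.sqrt(contrast.n_participants) * scheme.delta(contrast.design)


def kernel_offsets(kernel: KernelSpec, grid: VoxelGrid) -> np.ndarray:
    """Integer voxel offsets whose center-to-center mm distance is <= radius.

    Supports anisotropic voxels; always contains (0,0,0) and is symmetric
    under negation.
    """
    vs = grid.voxel_size
    bounds = [int(np.floor(kernel.radius / s)) for s in vs]
    ax = [np.arange(-b, b + 1) for b in bounds]
    dx, dy, dz = np.meshgrid(*ax, indexing="ij")
    offs = np.stack([dx.ravel(), dy.ravel(), dz.ravel()], axis=1)
    mm = offs * vs  # center-to-center displacement in mm per axis
    keep = (mm**2).sum(axis=1) <= kernel.radius**2 + 1e-9
    return offs[keep]


@dataclass(frozen=True)
class ContrastIndicatorMap:
    """Binary map of voxels within the kernel of any focus of one contrast."""

    contrast_id: str
    grid: VoxelGrid
    data: np.ndarray  # bool, mask-clipped

    @property
    def n_active(self) -> int:
        return int(self.data.sum())


def _contrast_flat_indices(
    foci_vox: np.ndarray, offsets: np.ndarray, shape: tuple[int, int, int]
) -> np.ndarray:
    """Unique flat indices of the union of kernel spheres around foci
    (voxel indices), clipped to the array bounds. Mask not yet applied."""
    pts = foci_vox[:, None, :] + offsets[None, :, :]  # (n_foci, n_off, 3)
    pts = pts.reshape(-1, 3)
    ok = np.all((pts >= 0) & (pts < np.array(shape)), axis=1)
    pts = pts[ok]
    if pts.size == 0:
        return np.zeros(0, dtype=np.intp)
    flat = np.ravel_multi_index((pts[:, 0], pts[:, 1], pts[:, 2]), shape)
    return np.unique(flat)


def build_cim(
    contrast: Contrast,
    grid: VoxelGrid,
    mask: Mask,
    kernel: KernelSpec = KernelSpec(),
) -> ContrastIndicatorMap:
    """Stamp the kernel around each focus and clip to the mask.

    Foci are snapped to their nearest voxel center first; membership is
    then exact on the voxel lattice. Duplicate foci are idempotent (binary
    union). A focus whose whole sphere misses the mask simply contributes
    nothing.
    """
    foci_vox = mm_to_voxel(grid, contrast.foci_xyz)
    offs = kernel_offsets(kernel, grid)
    flat = _contrast_flat_indices(np.atleast_2d(foci_vox), offs, grid.shape)
    data = np.zeros(grid.n_voxels, dtype=bool)
    data[flat] = True
    data = data.reshape(grid.shape) & mask.inside
    return ContrastIndicatorMap(contrast_id=contrast.contrast_id, grid=grid, data=data)


@dataclass(frozen=True)
class DensityMap:
    """Weighted proportion of contrasts active at each voxel, in [0, 1]."""

    grid: VoxelGrid
    data: np.ndarray  # float, zero outside mask
    provenance: dict = field(default_factory=dict)

    @property
    def max(self) -> float:
        return float(self.data.max())


def make_provenance(
    kernel: KernelSpec, scheme: WeightScheme, mask: Mask, n_contrasts: int,
    sum_weights: float,
) -> dict:
    """Analysis identity carried by density maps and null distributions so
    thresholds are never applied across incompatible analyses."""
    return {
        "kernel_radius": float(kernel.radius),
        "delta_fixed": float(scheme.delta_fixed),
        "delta_random": float(scheme.delta_random),
        "mask": mask.fingerprint(),
        "n_contrasts": int(n_contrasts),
        "sum_weights": float(sum_weights),
    }


def summary_density(
    cims: Sequence[ContrastIndicatorMap],
    weights: Sequence[float],
    mask: Mask | None = None,
) -> DensityMap:
    """P(v) = sum_c w_c I_c(v) / sum_c w_c over aligned CIMs."""
    if len(cims) == 0:
        raise ValueError("empty CIM list")
    if len(weights) != len(cims):
        raise ValueError("weights must align with CIMs")
    w = np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    grid = cims[0].grid
    for c in cims[1:]:
        if c.grid.shape != grid.shape or not np.array_equal(c.grid.affine, grid.affine):
            raise ValueError("CIMs are not on a common grid")
    acc = np.zeros(grid.shape, dtype=float)
    for c, wc in zip(cims, w):
        acc += wc * c.data
    acc /= w.sum()
    if mask is not None:
        acc *= mask.inside
    prov = {"n_contrasts": len(cims), "sum_weights": float(w.sum())}
    return DensityMap(grid=grid, data=acc, provenance=prov)


def studyset_flat_cims(
    studyset: StudySet,
    grid: VoxelGrid,
    mask: Mask,
    kernel: KernelSpec = KernelSpec(),
    scheme: WeightScheme = WeightScheme(),
) -> tuple[list[np.ndarray], np.ndarray]:
    """Per-contrast in-mask flat CIM indices and weights (fast path shared
    with the Monte-Carlo and permutation machinery)."""
    offs = kernel_offsets(kernel, grid)
    mask_flat = mask.inside.ravel()
    idx_list = []
    for c in studyset.contrasts:
        vox = np.atleast_2d(mm_to_voxel(grid, c.foci_xyz))
        flat = _contrast_flat_indices(vox, offs, grid.shape)
        idx_list.append(flat[mask_flat[flat]])
    w = np.array([contrast_weight(c, scheme) for c in studyset.contrasts])
    return idx_list, w


def density_from_flat(
    idx_list: Sequence[np.ndarray], weights: np.ndarray, grid: VoxelGrid
) -> np.ndarray:
    """Accumulate weighted flat CIM indices into a normalized density array."""
    acc = np.zeros(grid.n_voxels, dtype=float)
    for flat, wc in zip(idx_list, weights):
        acc[flat] += wc
    acc /= weights.sum()
    return acc.reshape(grid.shape)


def density_map(
    studyset: StudySet,
    grid: VoxelGrid,
    mask: Mask,
    kernel: KernelSpec = KernelSpec(),
    scheme: WeightScheme = WeightScheme(),
) -> DensityMap:
    """Summary density map for a StudySet in one call."""
    idx_list, w = studyset_flat_cims(studyset, grid, mask, kernel, scheme)
    data = density_from_flat(idx_list, w, grid)
    prov = make_provenance(kernel, scheme, mask, len(studyset.contrasts), float(w.sum()))
    return DensityMap(grid=grid, data=data, provenance=prov)
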