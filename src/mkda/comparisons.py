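"""Conjunction and subtraction analyses between two meta-analytic domains.

Conjunction follows the minimum-statistic-over-corrected-maps logic: a
voxel is conjointly active iff it is significant (combined height/extent
criterion, FWER-corrected) in *both* domains; conjoint clusters smaller
than 10 voxels are discarded. Subtraction compares the two domains' raw
density maps; its null exchanges contrast-to-domain labels (group sizes
preserved), which is the exchangeable quantity under "no domain
difference" — relocating foci cannot generate that null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .brain_space import Mask, VoxelGrid, connected_components, voxel_to_mm
from .foci_io import StudySet
from .mkda_core import (
    DensityMap,
    KernelSpec,
    WeightScheme,
    density_from_flat,
    studyset_flat_cims,
)
from .mc_inference import SignificanceMap, ThresholdSpec, exceedance_threshold


@dataclass(frozen=True)
class ConjunctionCluster:
    cluster_id: int
    size: int
    peak_ijk: tuple[int, int, int]
    peak_mm: tuple[float, float, float]
    max_density_a: float
    max_density_b: float
    mean_max_density: float


@dataclass(frozen=True)
class ConjunctionResult:
    grid: VoxelGrid
    conjunction: np.ndarray  # bool
    labels: np.ndarray
    clusters: tuple[ConjunctionCluster, ...]
    min_cluster: int


def _grids_equal(a: VoxelGrid, b: VoxelGrid) -> bool:
    return a.shape == b.shape and np.array_equal(a.affine, b.affine)


def conjunction(
    sig_a: SignificanceMap,
    sig_b: SignificanceMap,
    dens_a: DensityMap,
    dens_b: DensityMap,
    min_cluster: int = 10,
    connectivity: int = 18,
) -> ConjunctionResult:
    """Voxelwise AND of two combined significance maps, cluster-filtered.

    Per surviving cluster the peak is the scan-order-first voxel maximising
    the mean of the two densities; both domains' in-cluster maxima and
    their mean are reported (the per-cluster "Maxstat").
    """
    for other in (sig_b.grid, dens_a.grid, dens_b.grid):
        if not _grids_equal(sig_a.grid, other):
            raise ValueError("inputs are not on a common grid")
    grid = sig_a.grid
    conj = sig_a.combined & sig_b.combined
    lab = connected_components(conj, grid, connectivity)

    keep = np.flatnonzero(lab.sizes >= min_cluster) + 1
    filtered = np.where(np.isin(lab.labels, keep), lab.labels, 0)
    conj_f = filtered > 0

    mean_dens = 0.5 * (dens_a.data + dens_b.data)
    clusters = []
    for new_id, k in enumerate(keep, start=1):
        in_k = lab.labels == k
        vals = np.where(in_k, mean_dens, -np.inf)
        peak_flat = int(np.argmax(vals))  # scan-order-first maximum
        peak_ijk = np.unravel_index(peak_flat, grid.shape)
        peak_mm = voxel_to_mm(grid, np.array(peak_ijk))
        ma = float(dens_a.data[in_k].max())
        mb = float(dens_b.data[in_k].max())
        clusters.append(
            ConjunctionCluster(
                cluster_id=new_id,
                size=int(lab.sizes[k - 1]),
                peak_ijk=tuple(int(i) for i in peak_ijk),
                peak_mm=tuple(float(v) for v in peak_mm),
                max_density_a=ma,
                max_density_b=mb,
                mean_max_density=0.5 * (ma + mb),
            )
        )
    # renumber surviving labels 1..n in original scan order
    remap = np.zeros(lab.n_clusters + 1, dtype=filtered.dtype)
    remap[keep] = np.arange(1, len(keep) + 1)
    labels = remap[filtered]
    return ConjunctionResult(
        grid=grid, conjunction=conj_f, labels=labels,
        clusters=tuple(clusters), min_cluster=min_cluster,
    )


@dataclass(frozen=True)
class DifferenceResult:
    grid: VoxelGrid
    difference: np.ndarray  # density_A - density_B
    upper_threshold: float
    lower_threshold: float
    positive: np.ndarray  # bool: A > B significant
    negative: np.ndarray  # bool: B > A significant
    n_iterations: int
    seed: int


def subtraction(
    set_a: StudySet,
    set_b: StudySet,
    grid: VoxelGrid,
    mask: Mask,
    kernel: KernelSpec = KernelSpec(),
    scheme: WeightScheme = WeightScheme(),
    spec: ThresholdSpec = ThresholdSpec(),
) -> DifferenceResult:
    """Difference of two density maps with a label-permutation FWER null.

    Observed statistic: density_A - density_B. Null: contrasts from both
    domains are pooled and randomly reassigned to the two labels (group
    sizes preserved); per iteration the whole-brain maximum and minimum of
    the permuted difference are recorded, yielding separate upper and lower
    thresholds at ``spec.fwer_p`` per tail. Per-contrast indicator maps are
    fixed under this null, so they are precomputed once.
    """
    if len(set_a.contrasts) == 0 or len(set_b.contrasts) == 0:
        raise ValueError("both study sets must be non-empty")

    idx_a, w_a = studyset_flat_cims(set_a, grid, mask, kernel, scheme)
    idx_b, w_b = studyset_flat_cims(set_b, grid, mask, kernel, scheme)
    dens_a = density_from_flat(idx_a, w_a, grid)
    dens_b = density_from_flat(idx_b, w_b, grid)
    observed = dens_a - dens_b

    idx_all = idx_a + idx_b
    w_all = np.concatenate([w_a, w_b])
    n_a, n_total = len(idx_a), len(idx_all)

    master = np.random.SeedSequence(spec.seed)
    maxima = np.empty(spec.n_iterations)
    minima = np.empty(spec.n_iterations)
    for i, child in enumerate(master.spawn(spec.n_iterations)):
        rng = np.random.default_rng(child)
        perm = rng.permutation(n_total)
        grp_a = perm[:n_a]
        grp_b = perm[n_a:]
        da = density_from_flat([idx_all[j] for j in grp_a], w_all[grp_a], grid)
        db = density_from_flat([idx_all[j] for j in grp_b], w_all[grp_b], grid)
        diff = (da - db)[mask.inside]
        maxima[i] = diff.max()
        minima[i] = diff.min()

    upper = exceedance_threshold(maxima, spec.fwer_p)
    lower = -exceedance_threshold(-minima, spec.fwer_p)
    positive = (observed >= upper) & mask.inside
    negative = (observed <= lower) & mask.inside
    return DifferenceResult(
        grid=grid, difference=observed,
        upper_threshold=upper, lower_threshold=lower,
        positive=positive, negative=negative,
        n_iterations=spec.n_iterations, seed=spec.seed,
    )
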