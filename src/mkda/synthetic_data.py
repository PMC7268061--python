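"""Synthetic StudySet generator with known ground truth.

Emulates the statistical structure the meta-analysis assumes: peaks nested
in contrasts nested in studies, heterogeneous sample sizes, a mix of
fixed- and random-effects designs, convergent activation at planted
centers (Bernoulli activation per contrast, isotropic Gaussian spatial
jitter) plus uniformly placed noise foci. Defaults mirror a typical small
neuroimaging meta-analysis: 15 studies contributing 1-3 contrasts each,
sample sizes uniform on 8..30, 15% fixed-effects, activation probability
0.8 with 4 mm jitter and 2-8 noise foci per contrast.

The generator does not emulate publication bias, coordinate rounding to
whole mm, or anatomically structured (non-uniform) noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .brain_space import Mask, VoxelGrid, mm_to_voxel, voxel_to_mm
from .foci_io import Contrast, Focus, StudySet
from .mkda_core import KernelSpec, kernel_offsets


@dataclass(frozen=True)
class PlantedCenter:
    """A convergence center: contrasts activate it with probability
    `activation_prob`, displaced by isotropic Gaussian jitter (mm sd)."""

    xyz: tuple[float, float, float]
    activation_prob: float = 0.8
    jitter_sd: float = 4.0

    def __post_init__(self) -> None:
        if not (0 <= self.activation_prob <= 1):
            raise ValueError("activation_prob must be in [0, 1]")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    n_studies: int = 15
    contrasts_per_study: tuple[int, int] = (1, 3)  # discrete uniform, inclusive
    n_range: tuple[int, int] = (8, 30)  # participants, discrete uniform
    fixed_prop: float = 0.15  # probability a contrast is fixed-effects
    centers: tuple[PlantedCenter, ...] = ()
    noise_foci: tuple[int, int] = (2, 8)  # per contrast, discrete uniform
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.fixed_prop <= 1):
            raise ValueError("fixed_prop must be in [0, 1]")
        object.__setattr__(self, "centers", tuple(self.centers))


@dataclass(frozen=True)
class GroundTruth:
    centers: tuple[PlantedCenter, ...]
    expected_proportions: tuple[float, ...]  # per-center activation probability
    truth_mask: np.ndarray  # voxels within kernel radius of any center


def toy_mask(shape: tuple[int, int, int] = (40, 48, 40), voxel_mm: float = 2.0) -> Mask:
    """Procedural ellipsoid "toy brain": an axis-aligned ellipsoid filling
    ~90% of each grid dimension, centered, on an isotropic grid whose
    origin puts (0,0,0) mm at the grid center."""
    shape = tuple(int(s) for s in shape)
    center = (np.array(shape) - 1) / 2.0
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = -center * voxel_mm
    grid = VoxelGrid(affine=affine, shape=shape)
    semi = 0.45 * np.array(shape)
    idx = np.indices(shape)
    r2 = sum(((idx[i] - center[i]) / semi[i]) ** 2 for i in range(3))
    return Mask(grid=grid, inside=r2 <= 1.0)


def truth_mask_for_centers(
    centers: Sequence[PlantedCenter], mask: Mask, kernel: KernelSpec = KernelSpec()
) -> np.ndarray:
    """In-mask voxels within the kernel radius of any planted center."""
    grid = mask.grid
    offs = kernel_offsets(kernel, grid)
    out = np.zeros(grid.shape, dtype=bool)
    for c in centers:
        vox = mm_to_voxel(grid, np.array(c.xyz))
        pts = vox[None, :] + offs
        ok = np.all((pts >= 0) & (pts < np.array(grid.shape)), axis=1)
        pts = pts[ok]
        out[pts[:, 0], pts[:, 1], pts[:, 2]] = True
    return out & mask.inside


def _jittered_focus(
    center: PlantedCenter, mask: Mask, rng: np.random.Generator, max_tries: int = 100
) -> Focus:
    """Center + Gaussian jitter, resampled until in-mask (then snapped to
    the nearest in-mask voxel center as a last resort)."""
    grid = mask.grid
    cx = np.array(center.xyz, dtype=float)
    for _ in range(max_tries):
        pt = cx + rng.normal(0.0, center.jitter_sd, size=3)
        vox = mm_to_voxel(grid, pt)
        if np.all(vox >= 0) and np.all(vox < np.array(grid.shape)) and mask.inside[tuple(vox)]:
            return Focus(float(pt[0]), float(pt[1]), float(pt[2]))
    vox_all = mask.voxel_indices
    mm_all = voxel_to_mm(grid, vox_all)
    nearest = mm_all[np.argmin(((mm_all - cx) ** 2).sum(axis=1))]
    return Focus(float(nearest[0]), float(nearest[1]), float(nearest[2]))


def simulate_studyset(
    config: SimulationConfig, mask: Mask, domain_label: str = "synthetic"
) -> tuple[StudySet, GroundTruth]:
    """Draw a StudySet from the generative model; fully seeded.

    Every planted center must lie inside the mask. Each contrast activates
    each center independently with its probability; noise foci are uniform
    over in-mask voxel centers.
    """
    grid = mask.grid
    for c in config.centers:
        vox = mm_to_voxel(grid, np.array(c.xyz))
        inside = (
            np.all(vox >= 0) and np.all(vox < np.array(grid.shape))
            and mask.inside[tuple(vox)]
        )
        if not inside:
            raise ValueError(f"planted center {c.xyz} is outside the mask")

    rng = np.random.default_rng(config.seed)
    vox_all = mask.voxel_indices
    contrasts = []
    for s in range(config.n_studies):
        study_id = f"study{s:03d}"
        k = int(rng.integers(config.contrasts_per_study[0], config.contrasts_per_study[1] + 1))
        for j in range(k):
            n = int(rng.integers(config.n_range[0], config.n_range[1] + 1))
            design = "fixed" if rng.random() < config.fixed_prop else "random"
            foci: list[Focus] = []
            for center in config.centers:
                if rng.random() < center.activation_prob:
                    foci.append(_jittered_focus(center, mask, rng))
            n_noise = int(rng.integers(config.noise_foci[0], config.noise_foci[1] + 1))
            if n_noise > 0:
                pick = rng.integers(0, len(vox_all), size=n_noise)
                for mm in np.atleast_2d(voxel_to_mm(grid, vox_all[pick])):
                    foci.append(Focus(float(mm[0]), float(mm[1]), float(mm[2])))
            if not foci:  # a contrast must report at least one peak
                pick = int(rng.integers(0, len(vox_all)))
                mm = voxel_to_mm(grid, vox_all[pick])
                foci.append(Focus(float(mm[0]), float(mm[1]), float(mm[2])))
            contrasts.append(
                Contrast(
                    contrast_id=f"{study_id}_c{j}", study_id=study_id,
                    n_participants=n, design=design, foci=tuple(foci),
                )
            )
    truth = GroundTruth(
        centers=config.centers,
        expected_proportions=tuple(c.activation_prob for c in config.centers),
        truth_mask=truth_mask_for_centers(config.centers, mask),
    )
    return StudySet(domain_label=domain_label, contrasts=tuple(contrasts)), truth


def simulate_two_domains(
    config_a: SimulationConfig,
    config_b: SimulationConfig,
    shared_centers: Sequence[PlantedCenter],
    mask: Mask,
) -> tuple[StudySet, StudySet, GroundTruth]:
    """Two domains sharing the listed centers (appended to both configs).

    The returned GroundTruth covers the *shared* centers only; each
    domain's exclusive truth can be derived from its own config via
    :func:`truth_mask_for_centers`. If the two configs carry the same seed,
    domain B's is offset by one so the domains are independent draws.
    """
    shared = tuple(shared_centers)
    from dataclasses import replace

    cfg_a = replace(config_a, centers=tuple(config_a.centers) + shared)
    cfg_b = replace(
        config_b, centers=tuple(config_b.centers) + shared,
        seed=config_b.seed if config_b.seed != config_a.seed else config_b.seed + 1,
    )
    set_a, _ = simulate_studyset(cfg_a, mask, domain_label="domain_A")
    set_b, _ = simulate_studyset(cfg_b, mask, domain_label="domain_B")
    truth = GroundTruth(
        centers=shared,
        expected_proportions=tuple(c.activation_prob for c in shared),
        truth_mask=truth_mask_for_centers(shared, mask),
    )
    return set_a, set_b, truth
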