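import numpy as np
import pytest

from mkda.brain_space import Mask, VoxelGrid
from mkda.foci_io import Contrast, Focus, StudySet


@pytest.fixture
def grid2mm():
    """2 mm isotropic grid, origin at the array corner."""
    return VoxelGrid(affine=np.diag([2.0, 2.0, 2.0, 1.0]), shape=(24, 24, 24))


@pytest.fixture
def full_mask(grid2mm):
    return Mask(grid=grid2mm, inside=np.ones(grid2mm.shape, dtype=bool))


def make_contrast(cid, foci_mm, n=16, design="random", study=None):
    return Contrast(
        contrast_id=cid,
        study_id=study or f"study_{cid}",
        n_participants=n,
        design=design,
        foci=tuple(Focus(float(x), float(y), float(z)) for x, y, z in foci_mm),
    )


def make_studyset(contrasts, label="test"):
    return StudySet(domain_label=label, contrasts=tuple(contrasts))


def random_studyset(rng, grid, n_contrasts=None, max_foci=5, label="rand"):
    """Random StudySet with foci at voxel centers of the given grid."""
    from mkda.brain_space import voxel_to_mm

    n_contrasts = n_contrasts or int(rng.integers(1, 11))
    contrasts = []
    for i in range(n_contrasts):
        n_foci = int(rng.integers(1, max_foci + 1))
        vox = np.column_stack([rng.integers(0, s, size=n_foci) for s in grid.shape])
        mm = np.atleast_2d(voxel_to_mm(grid, vox))
        contrasts.append(
            make_contrast(
                f"c{i}",
                mm,
                n=int(rng.integers(5, 40)),
                design="fixed" if rng.random() < 0.3 else "random",
            )
        )
    return make_studyset(contrasts, label=label)


def naive_density(studyset, grid, mask, radius=10.0, scheme=None):
    """Brute-force per-voxel weighted proportion: loop voxels x contrasts,
    min distance from voxel center to any (snapped) focus <= radius.

    Independent oracle for the density map; shares only the stated
    convention (foci snapped to voxel centers, closed-ball membership).
    """
    from mkda.brain_space import mm_to_voxel, voxel_to_mm
    from mkda.mkda_core import WeightScheme, contrast_weight

    scheme = scheme or WeightScheme()
    weights = [contrast_weight(c, scheme) for c in studyset.contrasts]
    dens = np.zeros(grid.shape)
    vox_idx = np.argwhere(mask.inside)
    centers_mm = voxel_to_mm(grid, vox_idx)
    for c, w in zip(studyset.contrasts, weights):
        snapped = np.atleast_2d(mm_to_voxel(grid, c.foci_xyz))
        foci_mm = np.atleast_2d(voxel_to_mm(grid, snapped))
        d2 = ((centers_mm[:, None, :] - foci_mm[None, :, :]) ** 2).sum(axis=2)
        active = (d2.min(axis=1) <= radius**2 + 1e-9).astype(float)
        dens[tuple(vox_idx.T)] += w * active
    # numpy pairwise sum, matching the package's stated normalisation
    dens /= np.asarray(weights).sum()
    return dens
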