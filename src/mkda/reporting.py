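"""Cluster tables and machine-readable result export.

One row per significant cluster: peak coordinates (mm), size in voxels,
volume in mm^3 and the peak density ("Maxstat"), grouped by the criterion
that produced it — height, extent at each primary alpha, conjunction, or a
subtraction direction. Anatomical labels are deliberately out of scope;
rows carry coordinates only.
"""

from __future__ import annotations

import platform
from dataclasses import asdict, dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .brain_space import connected_components, voxel_to_mm
from .comparisons import ConjunctionResult, DifferenceResult
from .mc_inference import SignificanceMap
from .mkda_core import DensityMap

COLUMNS = ["cluster_id", "criterion", "x", "y", "z", "size_voxels",
           "volume_mm3", "maxstat"]


@dataclass(frozen=True)
class ClusterRow:
    cluster_id: int
    criterion: str
    x: float
    y: float
    z: float
    size_voxels: int
    volume_mm3: float
    maxstat: float


def _rows_for_binary(
    binary: np.ndarray, density: DensityMap, criterion: str, connectivity: int
) -> list[ClusterRow]:
    grid = density.grid
    lab = connected_components(binary, grid, connectivity)
    rows = []
    for k in range(1, lab.n_clusters + 1):
        in_k = lab.labels == k
        vals = np.where(in_k, density.data, -np.inf)
        peak_flat = int(np.argmax(vals))  # scan-order-first maximal voxel
        ijk = np.unravel_index(peak_flat, grid.shape)
        mm = voxel_to_mm(grid, np.array(ijk))
        rows.append(
            ClusterRow(
                cluster_id=k,
                criterion=criterion,
                x=float(mm[0]), y=float(mm[1]), z=float(mm[2]),
                size_voxels=int(lab.sizes[k - 1]),
                volume_mm3=float(lab.sizes[k - 1] * grid.voxel_volume),
                maxstat=float(density.data[in_k].max()),
            )
        )
    rows.sort(key=lambda r: -r.size_voxels)
    return rows


def cluster_table(
    result: Union[SignificanceMap, ConjunctionResult, DifferenceResult],
    density: DensityMap,
    connectivity: int = 18,
) -> list[ClusterRow]:
    """Tabulate significant clusters, sorted by criterion then size.

    Criterion order mirrors the conventional table layout: height first,
    then extent at increasing primary alpha; conjunction or the two
    subtraction directions stand alone. Cluster ids are re-assigned within
    each criterion, descending size.
    """
    if result.grid.shape != density.grid.shape or not np.array_equal(
        result.grid.affine, density.grid.affine
    ):
        raise ValueError("result and density are not on a common grid")

    rows: list[ClusterRow] = []
    if isinstance(result, SignificanceMap):
        rows += _rows_for_binary(result.height, density, "height", connectivity)
        for alpha in sorted(result.extent):
            rows += _rows_for_binary(
                result.extent[alpha], density, f"extent@{alpha:g}", connectivity
            )
    elif isinstance(result, ConjunctionResult):
        for c in result.clusters:
            rows.append(
                ClusterRow(
                    cluster_id=c.cluster_id,
                    criterion="conjunction",
                    x=c.peak_mm[0], y=c.peak_mm[1], z=c.peak_mm[2],
                    size_voxels=c.size,
                    volume_mm3=float(c.size * result.grid.voxel_volume),
                    maxstat=c.mean_max_density,
                )
            )
        rows.sort(key=lambda r: -r.size_voxels)
    elif isinstance(result, DifferenceResult):
        rows += _rows_for_binary(result.positive, density, "A>B", connectivity)
        rows += _rows_for_binary(result.negative, density, "B>A", connectivity)
    else:
        raise TypeError(f"cannot tabulate {type(result).__name__}")

    out = []
    counter: dict[str, int] = {}
    for r in rows:
        counter[r.criterion] = counter.get(r.criterion, 0) + 1
        out.append(
            ClusterRow(**{**asdict(r), "cluster_id": counter[r.criterion]})
        )
    return out


def write_report(rows: Sequence[ClusterRow], path: Union[str, Path]) -> None:
    """Write cluster rows as TSV (header-only file when empty)."""
    df = pd.DataFrame([asdict(r) for r in rows], columns=COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_report(path: Union[str, Path]) -> list[ClusterRow]:
    df = pd.read_csv(path, sep="\t")
    return [ClusterRow(**{k: row[k] for k in COLUMNS}) for _, row in df.iterrows()]


def run_manifest(config: dict, path: Union[str, Path]) -> None:
    """Record every analysis parameter plus environment versions so a run
    can be audited and reproduced; two identical runs differ only in the
    timestamp."""
    import nibabel
    import scipy

    payload = {
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": config,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "nibabel": nibabel.__version__,
        },
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True), encoding="utf-8")
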