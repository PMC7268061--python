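"""Reading, validating and normalising activation-peak coordinate data.

The unit of analysis in MKDA is the *contrast*: one statistical comparison
from a published neuroimaging study, carrying its reported peak coordinates
(foci), its sample size and whether the original analysis used fixed or
random effects. Contrasts are nested within studies; a :class:`StudySet`
bundles every contrast belonging to one functional domain (e.g. "body
ownership" or "interoception").

Two on-disk formats are supported: a plain TSV/CSV table with one row per
focus, and the Sleuth/BrainMap text foci format. Coordinates reported in
Talairach space can be mapped to MNI with a pluggable affine (Lancaster
pooled transform by default).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SPACES = ("MNI", "TAL")
DESIGNS = ("fixed", "random")

#: Lancaster et al. pooled MNI(SPM)->Talairach affine ("icbm_spm2tal").
ICBM2TAL = np.array(
    [
        [0.9254, 0.0024, -0.0118, -1.0207],
        [-0.0048, 0.9316, -0.0871, -1.7667],
        [0.0152, 0.0883, 0.8924, 4.0926],
        [0.0, 0.0, 0.0, 1.0],
    ]
)

#: Default Talairach->MNI mapping: inverse of the pooled Lancaster affine.
TAL2MNI = np.linalg.inv(ICBM2TAL)


@dataclass(frozen=True)
class Focus:
    """A single activation peak in millimetre stereotactic coordinates."""

    x: float
    y: float
    z: float
    space: str = "MNI"

    def __post_init__(self) -> None:
        for v in (self.x, self.y, self.z):
            if not math.isfinite(v):
                raise ValueError(f"focus coordinate not finite: {(self.x, self.y, self.z)}")
        if self.space not in SPACES:
            raise ValueError(f"unknown space {self.space!r}; expected one of {SPACES}")

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass(frozen=True)
class Contrast:
    """One study contrast: foci nested under a sample size and design."""

    contrast_id: str
    study_id: str
    n_participants: int
    design: str
    foci: tuple[Focus, ...]

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError(
                f"contrast {self.contrast_id!r}: n_participants must be >= 1, "
                f"got {self.n_participants}"
            )
        if self.design not in DESIGNS:
            raise ValueError(f"contrast {self.contrast_id!r}: design must be one of {DESIGNS}")
        if len(self.foci) == 0:
            raise ValueError(f"contrast {self.contrast_id!r} has no foci")
        object.__setattr__(self, "foci", tuple(self.foci))

    @property
    def foci_xyz(self) -> np.ndarray:
        """(n_foci, 3) array of coordinates in mm."""
        return np.array([f.xyz for f in self.foci])


@dataclass(frozen=True)
class StudySet:
    """All contrasts of one domain, the input to a single meta-analysis."""

    domain_label: str
    contrasts: tuple[Contrast, ...]

    def __post_init__(self) -> None:
        if len(self.contrasts) == 0:
            raise ValueError("StudySet must contain at least one contrast")
        object.__setattr__(self, "contrasts", tuple(self.contrasts))
        ids = [c.contrast_id for c in self.contrasts]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate contrast ids in StudySet: {dupes}")

    def __len__(self) -> int:
        return len(self.contrasts)

    @property
    def spaces(self) -> set[str]:
        return {f.space for c in self.contrasts for f in c.foci}


@dataclass(frozen=True)
class DatasetSummary:
    n_studies: int
    n_contrasts: int
    n_participants_total: int


def _unique_contrast_ids(pairs: Sequence[tuple[str, str]]) -> list[str]:
    """Contrast ids from (study, contrast) pairs; composed only on collision."""
    raw = [c for _, c in pairs]
    if len(set(raw)) == len(raw):
        return list(raw)
    return [f"{s}|{c}" for s, c in pairs]


def parse_contrast_table(source: Union[str, Path]) -> StudySet:
    """Parse a TSV/CSV foci table into a :class:`StudySet`.

    Expected columns: ``study, contrast, n, design, space, x, y, z`` — one
    row per focus. A missing ``design`` column defaults every contrast to
    random effects (logged). Rows with a missing coordinate are rejected
    with their position; non-positive sample sizes are a hard error naming
    the contrast.
    """
    import csv

    try:
        df = pd.read_csv(source, sep=None, engine="python")
    except (pd.errors.EmptyDataError, csv.Error):
        raise ValueError("no contrasts parsed: empty input") from None
    if df.empty:
        raise ValueError("no contrasts parsed: empty input")

    required = {"study", "contrast", "n", "space", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    if "design" not in df.columns:
        logger.warning("no 'design' column; defaulting all contrasts to random effects")
        df = df.assign(design="random")

    for col in ("x", "y", "z"):
        bad = df.index[df[col].isna()]
        if len(bad):
            raise ValueError(f"row {bad[0]}: missing coordinate in column {col!r}")

    # preserve first-appearance order of (study, contrast) pairs and row order within
    groups: dict[tuple[str, str], list[int]] = {}
    for i, (s, c) in enumerate(zip(df["study"].astype(str), df["contrast"].astype(str))):
        groups.setdefault((s, c), []).append(i)

    ids = _unique_contrast_ids(list(groups))
    contrasts = []
    for cid, ((study, _raw), rows) in zip(ids, groups.items()):
        sub = df.iloc[rows]
        n = int(sub["n"].iloc[0])
        if n <= 0:
            raise ValueError(f"contrast {cid!r}: non-positive sample size {n}")
        design = str(sub["design"].iloc[0]).strip().lower()
        space = str(sub["space"].iloc[0]).strip().upper()
        foci = tuple(
            Focus(float(r.x), float(r.y), float(r.z), space=space)
            for r in sub.itertuples()
        )
        contrasts.append(
            Contrast(contrast_id=cid, study_id=study, n_participants=n,
                     design=design, foci=foci)
        )
    if not contrasts:
        raise ValueError("no contrasts parsed")
    label = Path(source).stem if isinstance(source, (str, Path)) else "studyset"
    return StudySet(domain_label=str(label), contrasts=tuple(contrasts))


def write_contrast_table(studyset: StudySet, path: Union[str, Path]) -> None:
    """Write a StudySet back to the tabular format (lossless round trip)."""
    rows = []
    for c in studyset.contrasts:
        for f in c.foci:
            rows.append(
                dict(study=c.study_id, contrast=c.contrast_id, n=c.n_participants,
                     design=c.design, space=f.space, x=f.x, y=f.y, z=f.z)
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def parse_sleuth(source: Union[str, Path]) -> StudySet:
    """Parse a Sleuth-style text foci file.

    Layout::

        // Reference=MNI
        // StudyA: some contrast
        // Subjects=12
        40 8 4
        -38 6 2

        // StudyB: other contrast
        // Subjects=20
        ...

    The ``Reference`` header must declare MNI or Talairach before any focus
    and applies to every block; each block needs a ``Subjects`` line.
    """
    text = Path(source).read_text(encoding="utf-8")
    space: str | None = None
    blocks: list[dict] = []
    current: dict | None = None

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("//"):
            body = line[2:].strip()
            low = body.lower()
            if low.startswith("reference="):
                ref = body.split("=", 1)[1].strip().lower()
                if ref in ("mni", "mni152", "icbm"):
                    space = "MNI"
                elif ref in ("talairach", "tal"):
                    space = "TAL"
                else:
                    raise ValueError(f"line {lineno}: unknown reference space {ref!r}")
            elif low.startswith("subjects="):
                if current is None:
                    raise ValueError(f"line {lineno}: Subjects line outside a study block")
                current["subjects"] = int(body.split("=", 1)[1])
            else:
                current = {"header": body, "subjects": None, "foci": [], "line": lineno}
                blocks.append(current)
        else:
            if space is None:
                raise ValueError(f"line {lineno}: focus before a '// Reference=' header")
            if current is None:
                raise ValueError(f"line {lineno}: focus outside a study block")
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(
                    f"line {lineno}: expected 3 coordinates, got {len(parts)}"
                )
            current["foci"].append(tuple(float(p) for p in parts))

    if space is None:
        raise ValueError("no '// Reference=' header found")
    if not blocks:
        raise ValueError("no contrasts parsed")

    pairs = []
    for b in blocks:
        header = b["header"]
        study = header.split(":", 1)[0].strip() if ":" in header else header
        pairs.append((study, header))
    ids = _unique_contrast_ids(pairs)

    contrasts = []
    for cid, (study, _), b in zip(ids, pairs, blocks):
        if b["subjects"] is None:
            raise ValueError(f"block {b['header']!r}: missing '// Subjects=' line")
        if not b["foci"]:
            raise ValueError(f"block {b['header']!r}: no foci")
        foci = tuple(Focus(x, y, z, space=space) for x, y, z in b["foci"])
        contrasts.append(
            Contrast(contrast_id=cid, study_id=study, n_participants=b["subjects"],
                     design="random", foci=foci)
        )
    label = Path(source).stem if isinstance(source, (str, Path)) else "studyset"
    return StudySet(domain_label=str(label), contrasts=tuple(contrasts))


def write_sleuth(studyset: StudySet, path: Union[str, Path], space: str = "MNI") -> None:
    lines = [f"// Reference={'MNI' if space == 'MNI' else 'Talairach'}"]
    for c in studyset.contrasts:
        lines.append("")
        header = c.contrast_id if ":" in c.contrast_id else f"{c.study_id}: {c.contrast_id}"
        lines.append(f"// {header}")
        lines.append(f"// Subjects={c.n_participants}")
        for f in c.foci:
            lines.append(f"{f.x:g} {f.y:g} {f.z:g}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def resolve_transform(transform: Union[str, np.ndarray, None]) -> np.ndarray:
    """Resolve a named or explicit Talairach->MNI affine to a 4x4 matrix."""
    if transform is None or (isinstance(transform, str) and transform == "lancaster"):
        return TAL2MNI
    if isinstance(transform, str):
        if transform == "identity":
            return np.eye(4)
        raise ValueError(f"unknown transform {transform!r}")
    mat = np.asarray(transform, dtype=float)
    if mat.shape != (4, 4):
        raise ValueError("explicit transform must be a 4x4 affine")
    return mat


def to_common_space(
    studyset: StudySet, transform: Union[str, np.ndarray, None] = "lancaster"
) -> StudySet:
    """Map every Talairach focus to MNI with the given affine.

    MNI foci pass through unchanged. The default is the Lancaster pooled
    transform; ``"identity"`` or any explicit invertible 4x4 affine may be
    substituted (the choice should be recorded alongside any results, since
    reported cluster coordinates depend on it).
    """
    mat = resolve_transform(transform)
    new_contrasts = []
    for c in studyset.contrasts:
        foci = []
        for f in c.foci:
            if f.space == "MNI":
                foci.append(f)
            else:
                v = mat @ np.array([f.x, f.y, f.z, 1.0])
                foci.append(Focus(float(v[0]), float(v[1]), float(v[2]), space="MNI"))
        new_contrasts.append(replace(c, foci=tuple(foci)))
    return replace(studyset, contrasts=tuple(new_contrasts))


def summarize(studyset: StudySet) -> DatasetSummary:
    """Counts of studies, contrasts and participants.

    Participants are counted once per study; if a study's contrasts report
    different sample sizes (multi-experiment papers), the per-study maximum
    is used.
    """
    per_study_n: dict[str, int] = {}
    for c in studyset.contrasts:
        per_study_n[c.study_id] = max(per_study_n.get(c.study_id, 0), c.n_participants)
    return DatasetSummary(
        n_studies=len(per_study_n),
        n_contrasts=len(studyset.contrasts),
        n_participants_total=int(sum(per_study_n.values())),
    )
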