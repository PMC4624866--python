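"""Image/table I/O and quality control.

Containers for 4D BOLD runs on a voxel grid, rigid-body motion traces and
subject phenotype records, plus the two QC rules applied before any analysis:
discarding initial volumes (magnetization equilibration) and excluding runs
whose motion exceeds 2.0 mm translation or 2.0 degrees rotation on any single
axis at any timepoint.  The motion rule is applied to absolute parameter values
relative to the reference volume and uses a strict ">" — a trace touching
exactly 2.0 is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import DomainError, FormatError

PHENO_COLUMNS = [
    "subject_id",
    "group",
    "age",
    "sex",
    "education_years",
    "thq",
    "duration_months",
]


@dataclass(frozen=True)
class VolumeGrid:
    """Axis-aligned voxel grid: dimensions, voxel size and world origin (mm).

    Voxel indices are 0-based; world mm coordinates are origin + index * size.
    """

    dims: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(int(d) < 1 for d in self.dims):
            raise DomainError(f"grid dims must be 3 positive integers, got {self.dims}")
        if len(self.voxel_size_mm) != 3 or any(s <= 0 for s in self.voxel_size_mm):
            raise DomainError(f"voxel sizes must be positive, got {self.voxel_size_mm}")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "voxel_size_mm", tuple(float(s) for s in self.voxel_size_mm))
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))

    @classmethod
    def isotropic(cls, dims: Sequence[int], voxel_size_mm: float,
                  origin_mm: Sequence[float] = (0.0, 0.0, 0.0)) -> "VolumeGrid":
        return cls(tuple(dims), (voxel_size_mm,) * 3, tuple(origin_mm))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.voxel_size_mm) + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff

    def index_to_mm(self, index: Sequence[int]) -> tuple[float, float, float]:
        return tuple(
            float(self.origin_mm[a] + index[a] * self.voxel_size_mm[a]) for a in range(3)
        )


@dataclass
class BoldRun:
    """One subject's 4D BOLD time series (x, y, z, t) with its TR and grid."""

    data: np.ndarray
    tr_seconds: float
    grid: VolumeGrid

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise FormatError(f"BOLD data must be 4D, got {self.data.ndim}D")
        if self.data.shape[:3] != self.grid.dims:
            raise FormatError(
                f"data spatial shape {self.data.shape[:3]} does not match grid {self.grid.dims}"
            )
        if self.data.shape[3] < 8:
            raise DomainError("a BOLD run needs at least 8 timepoints")
        if self.tr_seconds <= 0:
            raise DomainError("tr_seconds must be positive")
        if not np.all(np.isfinite(self.data)):
            raise DomainError("BOLD data must be finite")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]


@dataclass
class MotionTrace:
    """Rigid-body realignment parameters: T x 3 translations (mm), T x 3 rotations (deg)."""

    translations_mm: np.ndarray
    rotations_deg: np.ndarray

    def __post_init__(self) -> None:
        self.translations_mm = np.atleast_2d(np.asarray(self.translations_mm, dtype=float))
        self.rotations_deg = np.atleast_2d(np.asarray(self.rotations_deg, dtype=float))
        if self.translations_mm.shape != self.rotations_deg.shape or self.translations_mm.shape[1] != 3:
            raise FormatError("motion trace needs matching T x 3 translation and rotation blocks")
        if not (np.all(np.isfinite(self.translations_mm)) and np.all(np.isfinite(self.rotations_deg))):
            raise DomainError("motion parameters must be finite")

    @property
    def n_timepoints(self) -> int:
        return self.translations_mm.shape[0]


@dataclass
class SubjectRecord:
    """Group membership (1 = patient, 2 = control) and clinical covariates."""

    subject_id: str
    group: int
    age_years: float
    sex: int  # 0/1 coding
    education_years: float
    thq: Optional[float] = None  # 0-100 severity score, patients only
    duration_months: Optional[float] = None  # patients only

    def __post_init__(self) -> None:
        if self.group not in (1, 2):
            raise DomainError(f"group must be 1 or 2, got {self.group}")
        if self.sex not in (0, 1):
            raise DomainError(f"sex must be coded 0/1, got {self.sex}")
        for name in ("thq", "duration_months"):
            v = getattr(self, name)
            if v is not None and np.isfinite(v) and v < 0:
                raise DomainError(f"{name} must be non-negative")


@dataclass(frozen=True)
class MotionScreenResult:
    keep: bool
    kind: Optional[str] = None  # "translation" | "rotation"
    axis: Optional[int] = None
    timepoint: Optional[int] = None
    value: Optional[float] = None


# ---------------------------------------------------------------------------
# NIfTI I/O


def read_bold_nifti(path) -> BoldRun:
    """Read a 4D NIfTI-1 run; TR is taken from the 4th pixdim."""
    img = nib.load(str(path))
    if img.ndim != 4:
        raise FormatError(f"{path}: expected a 4D BOLD image, got {img.ndim}D")
    zooms = img.header.get_zooms()
    grid = VolumeGrid(
        dims=tuple(int(d) for d in img.shape[:3]),
        voxel_size_mm=tuple(float(abs(z)) for z in zooms[:3]),
        origin_mm=tuple(float(v) for v in img.affine[:3, 3]),
    )
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 0.0
    if tr <= 0:
        raise FormatError(f"{path}: TR missing from NIfTI header")
    return BoldRun(np.asarray(img.dataobj, dtype=np.float64), tr, grid)


def write_bold_nifti(run: BoldRun, path) -> None:
    img = nib.Nifti1Image(run.data.astype(np.float32), run.grid.affine)
    img.header.set_zooms(tuple(run.grid.voxel_size_mm) + (run.tr_seconds,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))


def write_map_nifti(values: np.ndarray, grid: VolumeGrid, path) -> None:
    """Write a 3D statistical/amplitude map; NaN marks undefined voxels."""
    values = np.asarray(values, dtype=np.float32)
    if values.ndim != 3:
        raise FormatError(f"map must be 3D, got {values.ndim}D")
    if values.shape != grid.dims:
        raise FormatError(f"map shape {values.shape} does not match grid {grid.dims}")
    img = nib.Nifti1Image(values, grid.affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def read_map_nifti(path) -> tuple[np.ndarray, VolumeGrid]:
    img = nib.load(str(path))
    if img.ndim != 3:
        raise FormatError(f"{path}: expected a 3D map, got {img.ndim}D")
    grid = VolumeGrid(
        dims=tuple(int(d) for d in img.shape),
        voxel_size_mm=tuple(float(abs(z)) for z in img.header.get_zooms()[:3]),
        origin_mm=tuple(float(v) for v in img.affine[:3, 3]),
    )
    return np.asarray(img.dataobj, dtype=np.float64), grid


# ---------------------------------------------------------------------------
# Motion traces and phenotype table


def write_motion_trace(trace: MotionTrace, path) -> None:
    """6-column whitespace-delimited text: 3 translations (mm), 3 rotations (deg)."""
    np.savetxt(str(path), np.hstack([trace.translations_mm, trace.rotations_deg]), fmt="%.8f")


def read_motion_trace(path) -> MotionTrace:
    arr = np.atleast_2d(np.loadtxt(str(path)))
    if arr.shape[1] != 6:
        raise FormatError(f"{path}: motion file must have 6 columns, got {arr.shape[1]}")
    return MotionTrace(arr[:, :3], arr[:, 3:])


def write_phenotype(records: Sequence[SubjectRecord], path) -> None:
    rows = [
        {
            "subject_id": r.subject_id,
            "group": r.group,
            "age": r.age_years,
            "sex": r.sex,
            "education_years": r.education_years,
            "thq": r.thq,
            "duration_months": r.duration_months,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=PHENO_COLUMNS).to_csv(str(path), sep="\t", index=False)


def read_phenotype(path) -> list[SubjectRecord]:
    df = pd.read_csv(str(path), sep="\t")
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: phenotype table missing columns {missing}")

    def _opt(v):
        return None if pd.isna(v) else float(v)

    return [
        SubjectRecord(
            subject_id=str(row.subject_id),
            group=int(row.group),
            age_years=float(row.age),
            sex=int(row.sex),
            education_years=float(row.education_years),
            thq=_opt(row.thq),
            duration_months=_opt(row.duration_months),
        )
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# QC rules


def discard_initial_volumes(run: BoldRun, n_discard: int = 10) -> BoldRun:
    """Drop the first ``n_discard`` volumes (signal-equilibration period)."""
    if n_discard < 0:
        raise DomainError("n_discard must be non-negative")
    if n_discard >= run.n_timepoints:
        raise DomainError(
            f"cannot discard {n_discard} of {run.n_timepoints} volumes"
        )
    if n_discard == 0:
        return replace(run, data=run.data.copy())
    return replace(run, data=run.data[..., n_discard:].copy())


def screen_motion(
    trace: MotionTrace,
    max_translation_mm: float = 2.0,
    max_rotation_deg: float = 2.0,
) -> MotionScreenResult:
    """Exclude a run iff any translation axis exceeds ``max_translation_mm`` (mm)
    or any rotation axis exceeds ``max_rotation_deg`` (deg) in absolute value at
    any timepoint.  Strict inequality: values exactly at the limit are kept."""
    if trace.n_timepoints == 0:
        raise DomainError("empty motion trace")
    for kind, block, limit in (
        ("translation", trace.translations_mm, max_translation_mm),
        ("rotation", trace.rotations_deg, max_rotation_deg),
    ):
        absblock = np.abs(block)
        if np.any(absblock > limit):
            t, axis = np.unravel_index(int(np.argmax(absblock)), absblock.shape)
            return MotionScreenResult(
                keep=False, kind=kind, axis=int(axis), timepoint=int(t),
                value=float(block[t, axis]),
            )
    return MotionScreenResult(keep=True)
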