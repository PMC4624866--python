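"""Synthetic resting-state cohort generator with known planted effects.

Emulates the acquisition this pipeline targets — ~240-volume runs at TR = 2 s
on a 3 mm isotropic grid — with fully controlled ground truth so every
downstream stage (QC, spectral, ANOVA, cluster correction, correlations) can be
tested without any real scans:

* band-limited oscillatory signal of group-dependent amplitude in chosen ROIs
  (FFT masking of white noise, so the signal is broadband within its band);
* per-voxel linear drift and broadband white noise;
* smooth six-parameter motion traces, a designated fraction of which exceed the
  2.0 mm / 2.0 deg exclusion limits;
* clinical covariates (age, sex, education, THQ severity score, tinnitus
  duration) with optional planted correlation between a covariate and the
  noiseless ROI amplitude.

The planted band-signal *shape* is drawn once per ROI from the cohort seed and
shared across subjects; each subject scales it by base_amplitude x group
multiplier x a lognormal subject factor.  Group effects on band ALFF are
therefore exact amplitude ratios, and the subject factor supplies the
between-subject spread that covariate couplings attach to.  All randomness
derives from the single cohort seed through named substreams: identical spec
=> bit-identical cohort.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import scipy.ndimage as ndi

from .errors import DegenerateInputError, DomainError, InvalidBandError
from .io_qc import (
    BoldRun,
    MotionTrace,
    SubjectRecord,
    VolumeGrid,
    write_bold_nifti,
    write_motion_trace,
    write_phenotype,
)
from .spectral import FrequencyBand

# named substreams off the cohort master seed
_SIGNAL, _NOISE, _DRIFT, _MOTION, _JITTER, _COVARIATE, _SHUFFLE, _PHENO = range(11, 19)

# Default clinical covariate moments (age in years, education in years,
# THQ on its 0-100 scale, duration in months) for patients / controls.
_AGE = {1: (41.5, 14.6), 2: (46.0, 12.2)}
_EDUCATION = {1: (10.7, 1.9), 2: (11.1, 1.5)}
_P_MALE = {1: 24 / 39, 2: 21 / 41}
_THQ_MEAN, _THQ_SD = 43.5, 21.3
_DURATION_MEAN, _DURATION_SD = 36.9, 36.4


def _rng(*keys: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(k) for k in keys]))


@dataclass(frozen=True)
class RoiDefinition:
    """A set of grid voxels carrying a planted band-limited signal."""

    name: str
    voxel_set: tuple  # tuple of (i, j, k) triples
    band: FrequencyBand
    base_amplitude: float  # target sample SD of the planted series, signal units
    group1_multiplier: float = 1.0
    group2_multiplier: float = 1.0

    def __post_init__(self) -> None:
        voxels = tuple(sorted(tuple(int(v) for v in vox) for vox in self.voxel_set))
        if not voxels:
            raise DomainError(f"ROI {self.name!r} has an empty voxel set")
        if any(len(v) != 3 for v in voxels):
            raise DomainError("ROI voxels must be (i, j, k) triples")
        object.__setattr__(self, "voxel_set", voxels)
        if self.base_amplitude < 0:
            raise DomainError("base_amplitude must be >= 0")
        if self.group1_multiplier < 0 or self.group2_multiplier < 0:
            raise DomainError("group multipliers must be >= 0")

    def mask(self, dims: Sequence[int]) -> np.ndarray:
        m = np.zeros(tuple(dims), dtype=bool)
        idx = np.asarray(self.voxel_set)
        if idx.min() < 0 or np.any(idx >= np.asarray(dims)):
            raise DomainError(f"ROI {self.name!r} has voxels outside the grid {tuple(dims)}")
        m[idx[:, 0], idx[:, 1], idx[:, 2]] = True
        return m

    def multiplier(self, group: int) -> float:
        return self.group1_multiplier if group == 1 else self.group2_multiplier


def ball_roi(
    name: str,
    center: Sequence[int],
    radius_voxels: float,
    dims: Sequence[int],
    band: FrequencyBand,
    base_amplitude: float,
    group1_multiplier: float = 1.0,
    group2_multiplier: float = 1.0,
) -> RoiDefinition:
    """Convenience ROI: all grid voxels within a Euclidean radius of a centre."""
    grids = np.indices(tuple(dims))
    dist2 = sum((grids[a] - int(center[a])) ** 2 for a in range(3))
    voxels = np.argwhere(dist2 <= radius_voxels ** 2)
    return RoiDefinition(name, tuple(map(tuple, voxels)), band, base_amplitude,
                         group1_multiplier, group2_multiplier)


@dataclass(frozen=True)
class CouplingSpec:
    """Planted correlation between a clinical covariate and an ROI's noiseless
    planted amplitude across group-1 subjects."""

    covariate_name: str  # "thq" | "duration_months"
    roi_name: str
    band_name: str
    target_r: float

    def __post_init__(self) -> None:
        if abs(self.target_r) > 1:
            raise DomainError("|target_r| must be <= 1")
        if self.covariate_name not in ("thq", "duration_months"):
            raise DomainError("covariate_name must be 'thq' or 'duration_months'")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full description of a synthetic cohort; the single source of randomness."""

    n_group1: int = 12
    n_group2: int = 12
    grid_dims: tuple[int, int, int] = (24, 28, 24)
    voxel_size_mm: float = 3.0
    n_timepoints: int = 240
    tr_seconds: float = 2.0
    roi_list: tuple[RoiDefinition, ...] = ()
    baseline: float = 1000.0
    noise_sd: float = 10.0
    drift_slope_sd: float = 0.02  # signal units per volume
    subject_amplitude_sd: float = 0.3  # lognormal sigma of the per-subject factor
    covariate_couplings: tuple[CouplingSpec, ...] = ()
    motion_outlier_fraction: float = 0.0
    n_initial_discard: int = 10  # motion traces cover the retained volumes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group1 < 2 or self.n_group2 < 2:
            raise DomainError("each group needs at least 2 subjects")
        if self.tr_seconds <= 0 or self.voxel_size_mm <= 0:
            raise DomainError("tr_seconds and voxel_size_mm must be positive")
        if self.n_timepoints < 8 + self.n_initial_discard:
            raise DomainError("n_timepoints too small for the discard window")
        if not 0 <= self.motion_outlier_fraction <= 1:
            raise DomainError("motion_outlier_fraction must lie in [0, 1]")
        if self.noise_sd < 0 or self.drift_slope_sd < 0 or self.subject_amplitude_sd < 0:
            raise DomainError("noise/drift/jitter scales must be >= 0")
        object.__setattr__(self, "grid_dims", tuple(int(d) for d in self.grid_dims))
        object.__setattr__(self, "roi_list", tuple(self.roi_list))
        object.__setattr__(self, "covariate_couplings", tuple(self.covariate_couplings))
        names = [r.name for r in self.roi_list]
        if len(set(names)) != len(names):
            raise DomainError("ROI names must be unique")
        for c in self.covariate_couplings:
            if c.roi_name not in names:
                raise DomainError(f"coupling refers to unknown ROI {c.roi_name!r}")
        for roi in self.roi_list:
            roi.mask(self.grid_dims)  # validates bounds

    @property
    def grid(self) -> VolumeGrid:
        return VolumeGrid.isotropic(self.grid_dims, self.voxel_size_mm)

    @property
    def n_subjects(self) -> int:
        return self.n_group1 + self.n_group2


@dataclass(frozen=True)
class SubjectPlan:
    """Ground truth for one subject: seeds, designation and planted amplitudes."""

    index: int
    subject_id: str
    group: int
    is_motion_outlier: bool
    amplitudes: dict  # roi name -> exact planted sample SD for this subject
    record: SubjectRecord


# ---------------------------------------------------------------------------
# Signal primitives


def plant_band_signal(
    n_timepoints: int,
    tr_seconds: float,
    band: FrequencyBand,
    target_sd: float,
    seed,
) -> np.ndarray:
    """Zero-mean series whose one-sided spectrum is zero outside the band and
    whose sample SD (ddof=1) equals ``target_sd`` exactly.

    Construction: white Gaussian noise -> FFT -> zero all bins outside
    [f_low, f_high) (DC always zeroed) -> inverse FFT -> rescale.  ``seed`` may
    be an int or a numpy Generator.
    """
    if n_timepoints < 8:
        raise DomainError("plant_band_signal needs n_timepoints >= 8")
    if target_sd < 0:
        raise DomainError("target_sd must be >= 0")
    nyquist = 0.5 / tr_seconds
    if band.f_low >= nyquist or band.f_high > nyquist + 1e-12:
        raise InvalidBandError(
            f"band [{band.f_low}, {band.f_high}) must lie within (0, {nyquist}] Hz"
        )
    freqs = np.fft.rfftfreq(n_timepoints, d=tr_seconds)
    keep = band.contains(freqs) & (freqs > 0)
    if not keep.any():
        raise InvalidBandError(
            f"band {band.name} covers no bin at N={n_timepoints}, TR={tr_seconds}"
        )
    if target_sd == 0:
        return np.zeros(n_timepoints)
    rng = seed if isinstance(seed, np.random.Generator) else _rng(int(seed))
    white = rng.standard_normal(n_timepoints)
    spectrum = np.fft.rfft(white)
    spectrum[~keep] = 0.0
    x = np.fft.irfft(spectrum, n=n_timepoints)
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("masked noise draw collapsed to zero")
    return x * (target_sd / sd)


def plant_covariate(x: Sequence[float], target_r: float, seed) -> np.ndarray:
    """Covariate y = r z(x) + sqrt(1 - r^2) e with e ~ N(0, 1) independent;
    the population correlation of y with x is exactly ``target_r``."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise DomainError("plant_covariate needs a vector of length >= 3")
    if abs(target_r) > 1:
        raise DomainError("|target_r| must be <= 1")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("x is constant; coupling undefined")
    z = (x - x.mean()) / sd
    rng = seed if isinstance(seed, np.random.Generator) else _rng(int(seed))
    e = rng.standard_normal(x.size)
    return target_r * z + np.sqrt(1.0 - target_r ** 2) * e


# ---------------------------------------------------------------------------
# Cohort planning


def _roi_shapes(spec: SyntheticSpec) -> dict[str, np.ndarray]:
    """Unit-SD band-limited shape per ROI, shared by every subject."""
    return {
        roi.name: plant_band_signal(
            spec.n_timepoints, spec.tr_seconds, roi.band, 1.0,
            _rng(spec.seed, _SIGNAL, i),
        )
        for i, roi in enumerate(spec.roi_list)
    }


def _subject_factor(spec: SyntheticSpec, subject_seed: int) -> float:
    if spec.subject_amplitude_sd == 0:
        return 1.0
    rng = _rng(spec.seed, _JITTER, subject_seed)
    return float(np.exp(spec.subject_amplitude_sd * rng.standard_normal()))


def subject_amplitudes(spec: SyntheticSpec, group: int, subject_seed: int) -> dict[str, float]:
    """Exact planted sample SD per ROI for one subject (the noiseless ground
    truth that covariate couplings and recovery tests refer to)."""
    factor = _subject_factor(spec, subject_seed)
    return {
        roi.name: roi.base_amplitude * roi.multiplier(group) * factor
        for roi in spec.roi_list
    }


def _motion_outlier_designation(spec: SyntheticSpec) -> np.ndarray:
    """Per-subject outlier flags: k = round(fraction * n) per group, assigned to
    the first k of each group after a seeded shuffle."""
    flags = np.zeros(spec.n_subjects, dtype=bool)
    offsets = {1: 0, 2: spec.n_group1}
    sizes = {1: spec.n_group1, 2: spec.n_group2}
    for group in (1, 2):
        k = round(spec.motion_outlier_fraction * sizes[group])
        if k == 0:
            continue
        order = _rng(spec.seed, _SHUFFLE, group).permutation(sizes[group])
        flags[offsets[group] + order[:k]] = True
    return flags


def _draw_phenotype(spec: SyntheticSpec, index: int, group: int) -> dict:
    rng = _rng(spec.seed, _PHENO, index)
    mean, sd = _AGE[group]
    age = float(np.clip(rng.normal(mean, sd), 20.0, 70.0))
    sex = int(rng.random() < _P_MALE[group])
    mean, sd = _EDUCATION[group]
    education = float(np.clip(rng.normal(mean, sd), 8.0, None))
    thq = duration = None
    if group == 1:
        thq = float(np.clip(rng.normal(_THQ_MEAN, _THQ_SD), 0.0, 100.0))
        duration = float(np.clip(rng.normal(_DURATION_MEAN, _DURATION_SD), 1.0, None))
    return dict(age_years=age, sex=sex, education_years=education,
                thq=thq, duration_months=duration)


def cohort_plan(spec: SyntheticSpec) -> list[SubjectPlan]:
    """Deterministic per-subject ground truth: ids, groups, motion-outlier
    designation, planted ROI amplitudes and covariates (couplings applied)."""
    outliers = _motion_outlier_designation(spec)
    groups = [1] * spec.n_group1 + [2] * spec.n_group2
    ids = [
        f"tin{idx + 1:03d}" if g == 1 else f"con{idx + 1 - spec.n_group1:03d}"
        for idx, g in enumerate(groups)
    ]
    amplitudes = [subject_amplitudes(spec, groups[i], i) for i in range(spec.n_subjects)]
    pheno = [_draw_phenotype(spec, i, groups[i]) for i in range(spec.n_subjects)]

    group1_idx = [i for i in range(spec.n_subjects) if groups[i] == 1]
    for ci, coupling in enumerate(spec.covariate_couplings):
        x = np.array([amplitudes[i][coupling.roi_name] for i in group1_idx])
        y = plant_covariate(x, coupling.target_r, _rng(spec.seed, _COVARIATE, ci))
        if coupling.covariate_name == "thq":
            values = np.clip(_THQ_MEAN + _THQ_SD * y, 0.0, 100.0)
        else:
            values = np.clip(_DURATION_MEAN + _DURATION_SD * y, 1.0, None)
        for j, i in enumerate(group1_idx):
            pheno[i][coupling.covariate_name] = float(values[j])

    plans = []
    for i in range(spec.n_subjects):
        record = SubjectRecord(subject_id=ids[i], group=groups[i], **pheno[i])
        plans.append(
            SubjectPlan(
                index=i, subject_id=ids[i], group=groups[i],
                is_motion_outlier=bool(outliers[i]),
                amplitudes=amplitudes[i], record=record,
            )
        )
    return plans


# ---------------------------------------------------------------------------
# Run generation


def _generate_motion(spec: SyntheticSpec, subject_seed: int, outlier: bool) -> MotionTrace:
    n = spec.n_timepoints - spec.n_initial_discard
    rng = _rng(spec.seed, _MOTION, subject_seed)
    params = np.zeros((n, 6))
    peaks = rng.uniform(0.05, 0.6, size=6) * 2.0  # well below the 2.0 limit
    if outlier:
        axis = int(rng.integers(6))
        peaks[axis] = rng.uniform(1.1, 1.75) * 2.0  # 2.2 .. 3.5, one axis over
    for p in range(6):
        walk = np.cumsum(rng.standard_normal(n))
        walk = ndi.gaussian_filter1d(walk, sigma=max(2.0, n / 20.0), mode="nearest")
        walk -= walk[0]  # motion is relative to the reference volume
        extent = np.abs(walk).max()
        if extent > 0:
            params[:, p] = walk / extent * peaks[p]
    return MotionTrace(params[:, :3], params[:, 3:])


def generate_subject_run(
    spec: SyntheticSpec,
    record: SubjectRecord,
    subject_seed: int,
    motion_outlier: bool = False,
    roi_shapes: Optional[dict] = None,
    amplitudes: Optional[dict] = None,
) -> tuple[BoldRun, MotionTrace]:
    """One subject's 4D run (baseline + drift + noise + planted ROI signals)
    and motion trace.  ``subject_seed`` is the subject's index substream."""
    if record.group not in (1, 2):
        raise DomainError("record.group must be 1 or 2")
    if roi_shapes is None:
        roi_shapes = _roi_shapes(spec)
    if amplitudes is None:
        amplitudes = subject_amplitudes(spec, record.group, subject_seed)
    dims, n_t = spec.grid_dims, spec.n_timepoints
    data = np.full(dims + (n_t,), float(spec.baseline))
    if spec.drift_slope_sd > 0:
        slopes = _rng(spec.seed, _DRIFT, subject_seed).normal(0.0, spec.drift_slope_sd, dims)
        data += slopes[..., None] * np.arange(n_t)
    if spec.noise_sd > 0:
        data += spec.noise_sd * _rng(spec.seed, _NOISE, subject_seed).standard_normal(
            dims + (n_t,)
        )
    for roi in spec.roi_list:
        amp = amplitudes[roi.name]
        if amp == 0:
            continue
        series = roi_shapes[roi.name] * amp
        idx = np.asarray(roi.voxel_set)
        data[idx[:, 0], idx[:, 1], idx[:, 2], :] += series
    run = BoldRun(data, spec.tr_seconds, spec.grid)
    trace = _generate_motion(spec, subject_seed, motion_outlier)
    return run, trace


def iter_cohort(
    spec: SyntheticSpec, with_plan: bool = False
) -> Iterator[tuple]:
    """Yield (run, motion, record[, plan]) per subject without holding the whole
    cohort in memory.  Deterministic: same spec => bit-identical cohort."""
    shapes = _roi_shapes(spec)
    for plan in cohort_plan(spec):
        run, trace = generate_subject_run(
            spec, plan.record, plan.index, motion_outlier=plan.is_motion_outlier,
            roi_shapes=shapes, amplitudes=plan.amplitudes,
        )
        if with_plan:
            yield run, trace, plan.record, plan
        else:
            yield run, trace, plan.record


def generate_cohort(spec: SyntheticSpec) -> list[tuple[BoldRun, MotionTrace, SubjectRecord]]:
    """Materialize the full cohort (group 1 first, then group 2)."""
    return list(iter_cohort(spec))


def write_cohort(spec: SyntheticSpec, outdir) -> dict:
    """Serialize a cohort: one 4D NIfTI + motion text file per subject and a
    phenotype TSV.  Returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"bold": [], "motion": [], "phenotype": str(outdir / "participants.tsv")}
    records = []
    for run, trace, record in iter_cohort(spec):
        bold_path = outdir / f"{record.subject_id}_bold.nii.gz"
        motion_path = outdir / f"{record.subject_id}_motion.txt"
        write_bold_nifti(run, bold_path)
        write_motion_trace(trace, motion_path)
        paths["bold"].append(str(bold_path))
        paths["motion"].append(str(motion_path))
        records.append(record)
    write_phenotype(records, paths["phenotype"])
    return paths
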