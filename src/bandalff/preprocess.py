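"""Temporal detrending and isotropic Gaussian spatial smoothing.

The broad 0.01-0.08 Hz temporal band-pass customary in resting-state pipelines
is intentionally NOT applied here: band restriction happens in the spectral
domain per sub-band, and the fALFF denominator needs the full detrended
spectrum (0-0.25 Hz at TR = 2 s).  See docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import scipy.ndimage as ndi
import scipy.signal

from .errors import DomainError
from .io_qc import BoldRun, VolumeGrid

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def fwhm_to_sigma(fwhm: float) -> float:
    """Gaussian sigma for a given full width at half maximum (same units)."""
    return fwhm * FWHM_TO_SIGMA


def detrend_linear(series: np.ndarray, axis: int = -1) -> np.ndarray:
    """Remove the least-squares straight line from each series along ``axis``.

    The result has exactly zero mean and zero OLS slope; applying it twice is
    a no-op (projection).
    """
    series = np.asarray(series, dtype=float)
    if series.shape[axis] < 3:
        raise DomainError("detrending needs at least 3 timepoints")
    return scipy.signal.detrend(series, axis=axis, type="linear")


def detrend_run(run: BoldRun) -> BoldRun:
    return replace(run, data=detrend_linear(run.data, axis=-1))


def smooth_gaussian(data: np.ndarray, fwhm_mm: float, grid: VolumeGrid) -> np.ndarray:
    """Separable 3D Gaussian smoothing of a 3D map or 4D run (spatial axes only).

    sigma per axis = fwhm_mm / (2 sqrt(2 ln 2)) / voxel_size_mm; the kernel is
    normalized (uniform fields are unchanged) and boundaries use nearest-edge
    replication.  fwhm_mm = 0 is the identity.
    """
    data = np.asarray(data, dtype=float)
    if fwhm_mm < 0:
        raise DomainError("fwhm_mm must be non-negative")
    if data.ndim not in (3, 4):
        raise DomainError("smoothing expects a 3D map or 4D run")
    if data.shape[:3] != grid.dims:
        raise DomainError(f"data shape {data.shape[:3]} does not match grid {grid.dims}")
    if fwhm_mm == 0:
        return data.copy()
    sigma_vox = [fwhm_to_sigma(fwhm_mm) / s for s in grid.voxel_size_mm]
    if data.ndim == 4:
        sigma_vox = sigma_vox + [0.0]
    return ndi.gaussian_filter(data, sigma=sigma_vox, mode="nearest")


def smooth_run(run: BoldRun, fwhm_mm: float) -> BoldRun:
    return replace(run, data=smooth_gaussian(run.data, fwhm_mm, run.grid))
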