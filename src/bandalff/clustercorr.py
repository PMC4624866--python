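"""Monte Carlo cluster-extent correction (AlphaSim-style) and cluster reporting.

The family-wise error of voxelwise tests at a lenient per-voxel threshold is
controlled by discarding supra-threshold clusters smaller than a null-calibrated
extent.  The null is simulated directly: per iteration a Gaussian noise volume
is smoothed at the analysis FWHM, standardized within the mask, thresholded
two-tailed at the voxel p, and the maximum cluster size across both signs is
recorded.  The extent threshold is the smallest k whose exceedance frequency is
<= alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.ndimage as ndi
import scipy.stats

from .errors import DomainError, UnattainableAlphaError
from .groupstats import critical_t
from .io_qc import VolumeGrid
from .preprocess import fwhm_to_sigma

_STRUCTURES = {
    6: ndi.generate_binary_structure(3, 1),
    18: ndi.generate_binary_structure(3, 2),
    26: ndi.generate_binary_structure(3, 3),
}


def _structure(connectivity: int) -> np.ndarray:
    try:
        return _STRUCTURES[int(connectivity)]
    except KeyError:
        raise DomainError(f"connectivity must be 6, 18 or 26, got {connectivity}")


def find_clusters(binary: np.ndarray, connectivity: int = 26) -> tuple[np.ndarray, np.ndarray]:
    """Label connected components of a 3D boolean array.

    Returns (labels, sizes) where labels[i,j,k] in 0..n_clusters (0 = background)
    are assigned in lexicographic scan order and sizes[c-1] is the voxel count
    of cluster c.
    """
    binary = np.asarray(binary, dtype=bool)
    if binary.ndim != 3:
        raise DomainError("find_clusters expects a 3D boolean array")
    labels, n = ndi.label(binary, structure=_structure(connectivity))
    sizes = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    return labels, sizes


@dataclass(frozen=True)
class AlphaSimConfig:
    mask: np.ndarray  # 3D boolean
    voxel_p: float = 0.05  # two-tailed per-voxel threshold
    alpha: float = 0.05  # target family-wise rate
    n_iterations: int = 1000
    fwhm_mm: float = 6.0  # simulated smoothness (= applied analysis smoothing)
    voxel_size_mm: float = 3.0
    connectivity: int = 26
    seed: int = 0

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 3 or not mask.any():
            raise DomainError("mask must be a non-empty 3D boolean array")
        object.__setattr__(self, "mask", mask)
        if not 0 < self.voxel_p < 1:
            raise DomainError("voxel_p must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise DomainError("alpha must lie in (0, 1)")
        if self.n_iterations < 100:
            raise DomainError("n_iterations must be >= 100")
        if self.fwhm_mm < 0 or self.voxel_size_mm <= 0:
            raise DomainError("fwhm_mm must be >= 0 and voxel_size_mm > 0")
        _structure(self.connectivity)


@dataclass
class AlphaSimResult:
    max_cluster_sizes: np.ndarray  # per-iteration maximum (voxels)
    max_size_counts: np.ndarray  # histogram, index = size in voxels
    threshold_voxels: int
    threshold_mm3: float
    config: AlphaSimConfig

    def exceedance_probability(self, k: int) -> float:
        """Simulated P(max null cluster >= k voxels)."""
        return float(np.mean(self.max_cluster_sizes >= k))


def simulate_null_max_cluster(
    mask: np.ndarray,
    voxel_p: float,
    fwhm_mm: float,
    voxel_size_mm: float,
    connectivity: int,
    rng: np.random.Generator,
) -> int:
    """One null iteration: smoothed standardized Gaussian field, two-tailed
    threshold, maximum cluster size across the positive and negative signs."""
    field_ = rng.standard_normal(mask.shape)
    sigma_vox = fwhm_to_sigma(fwhm_mm) / voxel_size_mm
    if sigma_vox > 0:
        field_ = ndi.gaussian_filter(field_, sigma=sigma_vox, mode="nearest")
    inmask = field_[mask]
    field_ = (field_ - inmask.mean()) / inmask.std()
    zthr = scipy.stats.norm.ppf(1.0 - voxel_p / 2.0)
    best = 0
    for excursion in (field_ > zthr, field_ < -zthr):
        _, sizes = find_clusters(excursion & mask, connectivity)
        if sizes.size:
            best = max(best, int(sizes.max()))
    return best


def alphasim_threshold(config: AlphaSimConfig) -> AlphaSimResult:
    """Monte Carlo cluster-extent threshold controlling FWER at ``config.alpha``.

    Deterministic given the seed.  Raises :class:`UnattainableAlphaError` when
    no extent <= mask size achieves the requested alpha.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    maxes = np.empty(config.n_iterations, dtype=int)
    for it in range(config.n_iterations):
        maxes[it] = simulate_null_max_cluster(
            config.mask, config.voxel_p, config.fwhm_mm, config.voxel_size_mm,
            config.connectivity, rng,
        )
    sorted_maxes = np.sort(maxes)
    n = maxes.size
    # exceedance(k) = frac(max >= k) is non-increasing in k; find smallest k <= alpha
    threshold = None
    for k in range(1, int(sorted_maxes[-1]) + 2):
        exceed = (n - np.searchsorted(sorted_maxes, k, side="left")) / n
        if exceed <= config.alpha:
            threshold = k
            break
    mask_size = int(config.mask.sum())
    if threshold is None or threshold > mask_size:
        raise UnattainableAlphaError(
            f"alpha={config.alpha} not attainable: required extent exceeds mask size {mask_size}"
        )
    voxel_volume = config.voxel_size_mm ** 3
    return AlphaSimResult(
        max_cluster_sizes=maxes,
        max_size_counts=np.bincount(maxes),
        threshold_voxels=int(threshold),
        threshold_mm3=float(threshold * voxel_volume),
        config=config,
    )


def mm3_to_voxel_threshold(threshold_mm3: float, voxel_volume_mm3: float) -> int:
    """Smallest voxel count whose volume strictly exceeds ``threshold_mm3``
    (a 'cluster size > V mm^3' convention: 3591 mm^3 at 27 mm^3/voxel -> 134)."""
    if threshold_mm3 < 0 or voxel_volume_mm3 <= 0:
        raise DomainError("volumes must be positive")
    return int(np.floor(threshold_mm3 / voxel_volume_mm3)) + 1


@dataclass(frozen=True)
class Cluster:
    size_voxels: int
    size_mm3: float
    peak_t: float
    peak_index: tuple[int, int, int]  # 0-based voxel index
    peak_mm: tuple[float, float, float]
    sign: str  # "positive" | "negative"


@dataclass
class ClusterReport:
    clusters: list[Cluster]
    threshold_voxels: int
    critical_t: float
    df: int

    def __len__(self) -> int:
        return len(self.clusters)

    def to_dataframe(self):
        import pandas as pd

        rows = [
            {
                "sign": c.sign,
                "size_voxels": c.size_voxels,
                "size_mm3": c.size_mm3,
                "peak_t": c.peak_t,
                "peak_i": c.peak_index[0],
                "peak_j": c.peak_index[1],
                "peak_k": c.peak_index[2],
                "peak_x_mm": c.peak_mm[0],
                "peak_y_mm": c.peak_mm[1],
                "peak_z_mm": c.peak_mm[2],
            }
            for c in self.clusters
        ]
        return pd.DataFrame(
            rows,
            columns=["sign", "size_voxels", "size_mm3", "peak_t",
                     "peak_i", "peak_j", "peak_k",
                     "peak_x_mm", "peak_y_mm", "peak_z_mm"],
        )


def threshold_statmap(
    t_map: np.ndarray,
    df: int,
    voxel_p: float,
    threshold_voxels: int,
    grid: VolumeGrid,
    connectivity: int = 26,
    mask: Optional[np.ndarray] = None,
    cluster_masks: Optional[list] = None,
) -> ClusterReport:
    """Cluster-corrected report of a signed t map.

    Binarizes at +/- the two-tailed critical t for ``voxel_p``, labels positive
    and negative excursions separately, keeps clusters of size >=
    ``threshold_voxels`` and reports extent, signed peak t and peak location.
    If ``cluster_masks`` is a list, a boolean mask per retained cluster is
    appended to it (in report order).
    """
    t_map = np.asarray(t_map, dtype=float)
    if t_map.ndim != 3 or t_map.shape != grid.dims:
        raise DomainError("t_map must be 3D on the given grid")
    if threshold_voxels < 1:
        raise DomainError("threshold_voxels must be >= 1")
    if mask is None:
        mask = np.isfinite(t_map)
    else:
        mask = np.asarray(mask, dtype=bool) & np.isfinite(t_map)
    tc = critical_t(voxel_p, df)
    clusters: list[Cluster] = []
    for sign, excursion in (("positive", t_map > tc), ("negative", t_map < -tc)):
        labels, sizes = find_clusters(excursion & mask, connectivity)
        for c, size in enumerate(sizes, start=1):
            if size < threshold_voxels:
                continue
            cmask = labels == c
            tvals = np.where(cmask, t_map, np.nan)
            flat_peak = int(np.nanargmax(np.abs(tvals)))
            peak_index = tuple(int(v) for v in np.unravel_index(flat_peak, t_map.shape))
            clusters.append(
                Cluster(
                    size_voxels=int(size),
                    size_mm3=float(size * grid.voxel_volume_mm3),
                    peak_t=float(t_map[peak_index]),
                    peak_index=peak_index,
                    peak_mm=grid.index_to_mm(peak_index),
                    sign=sign,
                )
            )
            if cluster_masks is not None:
                cluster_masks.append(cmask)
    order = np.argsort([-c.size_voxels for c in clusters], kind="stable")
    clusters = [clusters[i] for i in order]
    if cluster_masks is not None:
        reordered = [cluster_masks[i] for i in order]
        cluster_masks[:] = reordered
    return ClusterReport(clusters=clusters, threshold_voxels=int(threshold_voxels),
                         critical_t=tc, df=int(df))
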