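"""Desk-scale validation experiments for the whole pipeline.

Each function builds a synthetic cohort with known ground truth, runs the
relevant pipeline stages from scratch, and measures how well the planted
structure is recovered: p-value calibration under the null, family-wise error
of the cluster-extent correction, detection of a planted group x band
interaction, recovery of a planted amplitude-covariate correlation, and the
motion-exclusion arithmetic.  The acceptance script and the validation tests
both drive these entry points.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .clustercorr import (
    AlphaSimConfig,
    alphasim_threshold,
    simulate_null_max_cluster,
    threshold_statmap,
)
from .groupstats import extract_cluster_means, partial_corr, pearson_corr, voxelwise_mixed_anova
from .io_qc import screen_motion
from .pipeline import collect_band_maps
from .simulate import CouplingSpec, SyntheticSpec, ball_roi, iter_cohort
from .spectral import band_by_name


def _subseed(seed: int, *keys: int) -> int:
    return int(np.random.SeedSequence([int(seed), *map(int, keys)]).generate_state(1)[0] % (2 ** 31))


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    return float(2.0 * np.logical_and(a, b).sum() / denom) if denom else 0.0


def null_calibration_experiment(
    seed: int,
    n_per_group: int = 20,
    grid_dims: Sequence[int] = (24, 28, 24),
    n_timepoints: int = 240,
    voxel_p: float = 0.05,
) -> dict:
    """Fraction of in-mask voxels with p < voxel_p per ANOVA effect on a pure
    noise cohort (no planted effects, no smoothing, raw band ALFF).

    Under correct calibration each fraction sits in a binomial band around
    voxel_p with V independent voxels.
    """
    spec = SyntheticSpec(
        n_group1=n_per_group, n_group2=n_per_group, grid_dims=tuple(grid_dims),
        n_timepoints=n_timepoints, roi_list=(), seed=seed,
    )
    cohort = collect_band_maps(
        iter_cohort(spec), spec.grid, metrics=("alff",), fwhm_mm=0.0, screen=False,
    )
    stats = voxelwise_mixed_anova(
        cohort.maps["alff"]["slow-4"], cohort.maps["alff"]["slow-5"], cohort.groups,
    )
    n_voxels = int(np.prod(spec.grid_dims))
    half_band = 2.576 * np.sqrt(voxel_p * (1 - voxel_p) / n_voxels)
    return {
        "fractions": {
            effect: float(np.mean(stats.p_map(effect) < voxel_p))
            for effect in ("group", "band", "interaction")
        },
        "n_voxels": n_voxels,
        "band99": (voxel_p - half_band, voxel_p + half_band),
        "df": stats.df,
    }


def fwer_experiment(
    seed: int,
    grid_dims: Sequence[int] = (24, 28, 24),
    voxel_p: float = 0.05,
    alpha: float = 0.05,
    fwhm_mm: float = 6.0,
    n_iterations: int = 1000,
    n_null: int = 200,
    voxel_size_mm: float = 3.0,
    connectivity: int = 26,
) -> dict:
    """Estimate the extent threshold, then measure the realized family-wise
    cluster false-positive rate on fresh null simulations of the same smoothed
    Gaussian process."""
    mask = np.ones(tuple(grid_dims), dtype=bool)
    sim = alphasim_threshold(
        AlphaSimConfig(
            mask=mask, voxel_p=voxel_p, alpha=alpha, n_iterations=n_iterations,
            fwhm_mm=fwhm_mm, voxel_size_mm=voxel_size_mm,
            connectivity=connectivity, seed=_subseed(seed, 1),
        )
    )
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
    hits = 0
    for _ in range(n_null):
        biggest = simulate_null_max_cluster(
            mask, voxel_p, fwhm_mm, voxel_size_mm, connectivity, rng
        )
        hits += biggest >= sim.threshold_voxels
    return {
        "threshold_voxels": sim.threshold_voxels,
        "threshold_mm3": sim.threshold_mm3,
        "fwer": hits / n_null,
        "n_null": n_null,
    }


def _interaction_spec(seed: int, n_per_group: int, grid_dims, radius: float,
                      group1_multiplier: float) -> SyntheticSpec:
    dims = tuple(grid_dims)
    center = tuple(d // 2 for d in dims)
    roi = ball_roi(
        "interaction-roi", center, radius, dims, band_by_name("slow4"),
        base_amplitude=10.0, group1_multiplier=group1_multiplier,
        group2_multiplier=1.0,
    )
    return SyntheticSpec(
        n_group1=n_per_group, n_group2=n_per_group, grid_dims=dims,
        n_timepoints=240, roi_list=(roi,), seed=seed,
    )


def interaction_recovery_experiment(
    seed: int,
    n_replicates: int = 10,
    n_per_group: int = 20,
    grid_dims: Sequence[int] = (24, 28, 24),
    roi_radius: float = 5.0,
    group1_multiplier: float = 1.5,
    voxel_p: float = 0.05,
    alpha: float = 0.05,
    fwhm_mm: float = 6.0,
    alphasim_iterations: int = 1000,
) -> dict:
    """Detect a planted group x band interaction as a corrected interaction
    cluster overlapping the ROI (Dice > 0.5), across replicate cohorts.

    The extent threshold is estimated once (same mask, smoothness and df for
    every replicate) and applied to each replicate's interaction t map.
    """
    mask = np.ones(tuple(grid_dims), dtype=bool)
    sim = alphasim_threshold(
        AlphaSimConfig(
            mask=mask, voxel_p=voxel_p, alpha=alpha,
            n_iterations=alphasim_iterations, fwhm_mm=fwhm_mm,
            voxel_size_mm=3.0, seed=_subseed(seed, 3),
        )
    )
    dices, detected = [], []
    for rep in range(n_replicates):
        spec = _interaction_spec(
            _subseed(seed, 4, rep), n_per_group, grid_dims, roi_radius,
            group1_multiplier,
        )
        roi_mask = spec.roi_list[0].mask(spec.grid_dims)
        cohort = collect_band_maps(
            iter_cohort(spec), spec.grid, metrics=("alff_norm",), fwhm_mm=fwhm_mm,
        )
        stats = voxelwise_mixed_anova(
            cohort.maps["alff_norm"]["slow-4"], cohort.maps["alff_norm"]["slow-5"],
            cohort.groups,
        )
        cluster_masks: list = []
        threshold_statmap(
            stats.t_interaction, stats.df, voxel_p, sim.threshold_voxels,
            spec.grid, mask=mask, cluster_masks=cluster_masks,
        )
        best = max((dice_coefficient(cm, roi_mask) for cm in cluster_masks), default=0.0)
        dices.append(best)
        detected.append(best > 0.5)
    return {
        "dice": dices,
        "n_detected": int(sum(detected)),
        "n_replicates": n_replicates,
        "threshold_voxels": sim.threshold_voxels,
    }


def fisher_interval(rho: float, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Sampling interval for a sample correlation around a true rho (Fisher z)."""
    import scipy.stats

    z = np.arctanh(rho)
    half = scipy.stats.norm.ppf(0.5 + confidence / 2.0) / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def correlation_recovery_experiment(
    seed: int,
    n_replicates: int = 20,
    n_patients: int = 39,
    target_r: float = 0.5,
    grid_dims: Sequence[int] = (16, 18, 16),
    roi_radius: float = 3.0,
    fwhm_mm: float = 6.0,
) -> dict:
    """Recover a planted covariate coupling (THQ vs ROI amplitude) through the
    full measurement chain: preprocess -> normalized slow-4 ALFF -> ROI mean ->
    Pearson r, plus the covariate-adjusted estimate (age, sex, education)."""
    dims = tuple(grid_dims)
    center = tuple(d // 2 for d in dims)
    lo, hi = fisher_interval(target_r, n_patients)
    r_values, r_partial_values = [], []
    for rep in range(n_replicates):
        roi = ball_roi("coupled-roi", center, roi_radius, dims,
                       band_by_name("slow4"), base_amplitude=10.0)
        spec = SyntheticSpec(
            n_group1=n_patients, n_group2=2, grid_dims=dims, n_timepoints=240,
            roi_list=(roi,),
            covariate_couplings=(CouplingSpec("thq", "coupled-roi", "slow-4", target_r),),
            seed=_subseed(seed, 5, rep),
        )
        cohort = collect_band_maps(
            iter_cohort(spec), spec.grid, metrics=("alff_norm",), fwhm_mm=fwhm_mm,
            screen=False,
        )
        g1 = cohort.groups == 1
        values = extract_cluster_means(
            cohort.maps["alff_norm"]["slow-4"], roi.mask(dims)
        )[g1]
        thq = np.array([r.thq for r in cohort.records])[g1]
        covariates = np.column_stack(
            [
                [r.age_years for r in cohort.records],
                [r.sex for r in cohort.records],
                [r.education_years for r in cohort.records],
            ]
        )[g1]
        r, _ = pearson_corr(values, thq)
        rp, _ = partial_corr(values, thq, covariates)
        r_values.append(r)
        r_partial_values.append(rp)
    r_values = np.asarray(r_values)
    r_partial_values = np.asarray(r_partial_values)
    return {
        "r": r_values.tolist(),
        "r_partial": r_partial_values.tolist(),
        "interval": (lo, hi),
        "n_within_interval": int(np.sum((r_values >= lo) & (r_values <= hi))),
        "mean_abs_partial_shift": float(np.mean(np.abs(r_partial_values - r_values))),
        "n_replicates": n_replicates,
        "n_patients": n_patients,
    }


def motion_exclusion_experiment(
    seed: int,
    n_patients: int = 41,
    n_controls: int = 41,
    n_outlier_patients: int = 2,
) -> dict:
    """Screen a synthetic cohort in which exactly ``n_outlier_patients`` of the
    patient runs exceed the 2.0 mm / 2.0 deg limits; report retained counts."""
    spec = SyntheticSpec(
        n_group1=n_patients, n_group2=n_controls, grid_dims=(6, 6, 6),
        n_timepoints=40, roi_list=(),
        motion_outlier_fraction=n_outlier_patients / n_patients,
        seed=seed,
    )
    retained = {1: 0, 2: 0}
    excluded = {1: 0, 2: 0}
    for _, trace, record in iter_cohort(spec):
        if screen_motion(trace).keep:
            retained[record.group] += 1
        else:
            excluded[record.group] += 1
    return {
        "patients_retained": retained[1],
        "patients_excluded": excluded[1],
        "controls_retained": retained[2],
        "controls_excluded": excluded[2],
    }
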