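"""End-to-end orchestration: simulate/load -> QC -> preprocess -> band maps ->
mixed ANOVA -> Monte Carlo cluster correction -> regional correlations.

Every stage is a pure function of (inputs, config, seed); a run with the same
configuration reproduces identical outputs.  `run_full_pipeline` writes each
stage's products under ``outdir/derivatives/<stage>/`` plus a provenance JSON
recording the resolved configuration, seeds and output checksums.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from .clustercorr import AlphaSimConfig, ClusterReport, alphasim_threshold, threshold_statmap
from .errors import ConfigError
from .groupstats import (
    StatMaps,
    extract_cluster_means,
    partial_corr,
    pearson_corr,
    voxelwise_mixed_anova,
)
from .io_qc import (
    BoldRun,
    MotionTrace,
    SubjectRecord,
    VolumeGrid,
    discard_initial_volumes,
    read_bold_nifti,
    read_motion_trace,
    read_phenotype,
    screen_motion,
    write_map_nifti,
)
from .preprocess import detrend_run, smooth_run
from .simulate import (
    CouplingSpec,
    RoiDefinition,
    SyntheticSpec,
    ball_roi,
    iter_cohort,
)
from .spectral import band_by_name, compute_band_maps

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "cohort": {
        "n_group1": 12,
        "n_group2": 12,
        "grid_dims": [24, 28, 24],
        "voxel_size_mm": 3.0,
        "n_timepoints": 240,
        "tr_seconds": 2.0,
        "baseline": 1000.0,
        "noise_sd": 10.0,
        "drift_slope_sd": 0.02,
        "subject_amplitude_sd": 0.3,
        "motion_outlier_fraction": 0.0,
        "rois": [
            {
                "name": "planted-roi",
                "center": [12, 14, 12],
                "radius_voxels": 5,
                "band": "slow-4",
                "base_amplitude": 10.0,
                "group1_multiplier": 1.5,
                "group2_multiplier": 1.0,
            }
        ],
        "couplings": [
            {"covariate": "thq", "roi": "planted-roi", "band": "slow-4", "target_r": 0.5}
        ],
    },
    "qc": {"n_discard": 10, "max_translation_mm": 2.0, "max_rotation_deg": 2.0},
    "preprocess": {"fwhm_mm": 6.0, "detrend": "linear"},
    "analysis": {"metrics": ["alff_norm", "falff"], "bands": ["slow-4", "slow-5"]},
    "cluster": {
        "voxel_p": 0.05,
        "alpha": 0.05,
        "iterations": 1000,
        "connectivity": 26,
        "fwhm_mm": 6.0,
    },
}


def merge_config(overrides: Optional[dict] = None) -> dict:
    """Defaults overlaid with a (possibly nested, partial) override dict."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)

    def merge(base: dict, extra: dict, path: str) -> None:
        for key, value in extra.items():
            if key not in base:
                raise ConfigError(f"unknown config field {path + key!r}")
            if isinstance(base[key], dict) and isinstance(value, dict):
                merge(base[key], value, path + key + ".")
            else:
                base[key] = value

    if overrides:
        merge(cfg, overrides, "")
    return cfg


def spec_from_config(config: dict) -> SyntheticSpec:
    c = config["cohort"]
    dims = tuple(int(d) for d in c["grid_dims"])
    rois = []
    for r in c["rois"]:
        rois.append(
            ball_roi(
                r["name"], r["center"], r["radius_voxels"], dims,
                band_by_name(r["band"]), r["base_amplitude"],
                r.get("group1_multiplier", 1.0), r.get("group2_multiplier", 1.0),
            )
        )
    couplings = tuple(
        CouplingSpec(k["covariate"], k["roi"], k["band"], k["target_r"])
        for k in c["couplings"]
    )
    return SyntheticSpec(
        n_group1=c["n_group1"], n_group2=c["n_group2"], grid_dims=dims,
        voxel_size_mm=c["voxel_size_mm"], n_timepoints=c["n_timepoints"],
        tr_seconds=c["tr_seconds"], roi_list=tuple(rois), baseline=c["baseline"],
        noise_sd=c["noise_sd"], drift_slope_sd=c["drift_slope_sd"],
        subject_amplitude_sd=c["subject_amplitude_sd"],
        covariate_couplings=couplings,
        motion_outlier_fraction=c["motion_outlier_fraction"],
        n_initial_discard=config["qc"]["n_discard"],
        seed=config["seed"],
    )


@dataclass
class CohortMaps:
    """Per-band map stacks (subjects x grid) for the retained subjects."""

    maps: dict  # metric -> band name -> (n, x, y, z)
    records: list[SubjectRecord]
    excluded: list[dict]
    grid: VolumeGrid
    mask: np.ndarray
    plans: Optional[list] = None

    @property
    def groups(self) -> np.ndarray:
        return np.array([r.group for r in self.records])


def collect_band_maps(
    subjects,
    grid: VolumeGrid,
    bands: Sequence[str] = ("slow-4", "slow-5"),
    metrics: Sequence[str] = ("alff_norm",),
    n_discard: int = 10,
    fwhm_mm: float = 6.0,
    max_translation_mm: float = 2.0,
    max_rotation_deg: float = 2.0,
    mask: Optional[np.ndarray] = None,
    screen: bool = True,
    detrend: bool = True,
) -> CohortMaps:
    """QC + preprocessing + spectral maps for a stream of subjects.

    ``subjects`` yields (run, motion, record) or (run, motion, record, plan)
    tuples; runs are consumed one at a time so a large cohort never resides in
    memory at once.
    """
    band_objs = [band_by_name(b) for b in bands]
    if mask is None:
        mask = np.ones(grid.dims, dtype=bool)
    normalize = "alff_norm" in metrics
    stacks: dict = {m: {b.name: [] for b in band_objs} for m in metrics}
    records: list[SubjectRecord] = []
    plans: list = []
    excluded: list[dict] = []
    for item in subjects:
        run, motion, record = item[:3]
        plan = item[3] if len(item) > 3 else None
        if screen:
            verdict = screen_motion(motion, max_translation_mm, max_rotation_deg)
            if not verdict.keep:
                excluded.append(
                    {"subject_id": record.subject_id, "kind": verdict.kind,
                     "axis": verdict.axis, "timepoint": verdict.timepoint,
                     "value": verdict.value}
                )
                continue
        run = discard_initial_volumes(run, n_discard)
        if detrend:
            run = detrend_run(run)
        if fwhm_mm > 0:
            run = smooth_run(run, fwhm_mm)
        bm = compute_band_maps(run, mask=mask, bands=band_objs, normalize=normalize)
        for metric in metrics:
            source = getattr(bm, metric)
            for b in band_objs:
                stacks[metric][b.name].append(source[b.name])
        records.append(record)
        if plan is not None:
            plans.append(plan)
    maps = {
        m: {b: np.stack(v) if v else np.empty((0,) + grid.dims) for b, v in per.items()}
        for m, per in stacks.items()
    }
    return CohortMaps(maps=maps, records=records, excluded=excluded, grid=grid,
                      mask=mask, plans=plans or None)


def load_cohort_dir(data_dir) -> tuple[list[tuple], VolumeGrid]:
    """Read a serialized cohort (participants.tsv + per-subject bold/motion)."""
    data_dir = Path(data_dir)
    records = read_phenotype(data_dir / "participants.tsv")
    subjects = []
    grid = None
    for record in records:
        run = read_bold_nifti(data_dir / f"{record.subject_id}_bold.nii.gz")
        motion = read_motion_trace(data_dir / f"{record.subject_id}_motion.txt")
        grid = run.grid
        subjects.append((run, motion, record))
    if grid is None:
        raise ConfigError(f"no subjects found in {data_dir}")
    return subjects, grid


def _alphasim_seed(master_seed: int) -> int:
    return int(np.random.SeedSequence([int(master_seed), 2]).generate_state(1)[0] % (2 ** 31))


def _checksum(arr: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: dict
    cohort: CohortMaps
    stat_maps: dict  # metric -> StatMaps
    threshold_voxels: int
    threshold_mm3: float
    cluster_reports: dict  # metric -> effect -> ClusterReport
    correlations: pd.DataFrame
    provenance: dict


def run_full_pipeline(config: Optional[dict] = None, outdir=None,
                      data_dir=None) -> PipelineResult:
    """Execute every stage on a synthetic cohort (default) or a serialized one.

    Writes per-stage outputs and a provenance JSON when ``outdir`` is given.
    """
    config = merge_config(config)
    bands = list(config["analysis"]["bands"])
    metrics = list(config["analysis"]["metrics"])
    qc, pp, cl = config["qc"], config["preprocess"], config["cluster"]

    if data_dir is not None:
        subjects, grid = load_cohort_dir(data_dir)
        subject_iter = iter(subjects)
    else:
        spec = spec_from_config(config)
        grid = spec.grid
        subject_iter = iter_cohort(spec, with_plan=True)

    cohort = collect_band_maps(
        subject_iter, grid, bands=bands, metrics=metrics,
        n_discard=qc["n_discard"], fwhm_mm=pp["fwhm_mm"],
        detrend=pp.get("detrend", "linear") != "none",
        max_translation_mm=qc["max_translation_mm"],
        max_rotation_deg=qc["max_rotation_deg"],
    )
    groups = cohort.groups

    stat_maps: dict = {}
    for metric in metrics:
        stat_maps[metric] = voxelwise_mixed_anova(
            cohort.maps[metric][bands[0]], cohort.maps[metric][bands[1]],
            groups, cohort.mask,
        )

    sim = alphasim_threshold(
        AlphaSimConfig(
            mask=cohort.mask, voxel_p=cl["voxel_p"], alpha=cl["alpha"],
            n_iterations=cl["iterations"], fwhm_mm=cl["fwhm_mm"],
            voxel_size_mm=grid.voxel_size_mm[0], connectivity=cl["connectivity"],
            seed=_alphasim_seed(config["seed"]),
        )
    )

    cluster_reports: dict = {}
    cluster_masks: dict = {}
    for metric in metrics:
        cluster_reports[metric] = {}
        cluster_masks[metric] = {}
        for effect in ("group", "band", "interaction"):
            masks: list = []
            cluster_reports[metric][effect] = threshold_statmap(
                stat_maps[metric].effect(effect), stat_maps[metric].df,
                cl["voxel_p"], sim.threshold_voxels, grid,
                connectivity=cl["connectivity"], mask=cohort.mask,
                cluster_masks=masks,
            )
            cluster_masks[metric][effect] = masks

    correlations = _correlation_stage(cohort, stat_maps, cluster_masks, bands, metrics)

    provenance = {
        "package_version": _version,
        "config": config,
        "n_retained": len(cohort.records),
        "n_excluded": len(cohort.excluded),
        "alphasim": {
            "seed": _alphasim_seed(config["seed"]),
            "threshold_voxels": sim.threshold_voxels,
            "threshold_mm3": sim.threshold_mm3,
        },
        "checksums": {
            f"{metric}.t_{effect}": _checksum(np.nan_to_num(stat_maps[metric].effect(effect)))
            for metric in metrics for effect in ("group", "band", "interaction")
        },
    }

    result = PipelineResult(
        config=config, cohort=cohort, stat_maps=stat_maps,
        threshold_voxels=sim.threshold_voxels, threshold_mm3=sim.threshold_mm3,
        cluster_reports=cluster_reports, correlations=correlations,
        provenance=provenance,
    )
    if outdir is not None:
        _write_outputs(result, Path(outdir), grid)
    return result


def _correlation_stage(cohort: CohortMaps, stat_maps, cluster_masks, bands, metrics):
    """Pearson + covariate-adjusted correlations of per-cluster means (group-1
    subjects) with the clinical scores, for both bands of every significant
    group-effect cluster; the larger-|t| band is flagged."""
    groups = cohort.groups
    g1 = groups == 1
    rows = []
    if g1.sum() >= 5:
        covariates = np.column_stack(
            [
                [r.age_years for r in cohort.records],
                [r.sex for r in cohort.records],
                [r.education_years for r in cohort.records],
            ]
        )[g1]
        clinical = {
            "thq": np.array([np.nan if r.thq is None else r.thq for r in cohort.records])[g1],
            "duration_months": np.array(
                [np.nan if r.duration_months is None else r.duration_months
                 for r in cohort.records]
            )[g1],
        }
        for metric in metrics:
            for ci, cmask in enumerate(cluster_masks[metric]["group"]):
                band_t = {
                    b: float(np.nanmean(np.abs(np.where(cmask, stat_maps[metric].effect("group"), np.nan))))
                    for b in bands
                }
                for band in bands:
                    values = extract_cluster_means(cohort.maps[metric][band], cmask)[g1]
                    for cov_name, cov_values in clinical.items():
                        ok = np.isfinite(cov_values)
                        if ok.sum() < 5 or np.ptp(values[ok]) == 0 or np.ptp(cov_values[ok]) == 0:
                            continue
                        r, p = pearson_corr(values[ok], cov_values[ok])
                        rp, pp_ = partial_corr(values[ok], cov_values[ok], covariates[ok])
                        rows.append(
                            {
                                "metric": metric, "cluster": ci, "band": band,
                                "covariate": cov_name, "n": int(ok.sum()),
                                "r": r, "p": p, "r_partial": rp, "p_partial": pp_,
                            }
                        )
    return pd.DataFrame(
        rows, columns=["metric", "cluster", "band", "covariate", "n",
                       "r", "p", "r_partial", "p_partial"],
    )


def _write_outputs(result: PipelineResult, outdir: Path, grid: VolumeGrid) -> None:
    deriv = outdir / "derivatives"
    for stage in ("qc", "stats", "cluster", "correlations"):
        (deriv / stage).mkdir(parents=True, exist_ok=True)
    pd.DataFrame(result.cohort.excluded).to_csv(
        deriv / "qc" / "excluded.tsv", sep="\t", index=False
    )
    for metric, maps in result.stat_maps.items():
        for effect in ("group", "band", "interaction"):
            write_map_nifti(
                maps.effect(effect).astype(np.float32), grid,
                deriv / "stats" / f"t_{metric}_{effect}.nii.gz",
            )
    with open(deriv / "stats" / "design.json", "w") as fh:
        json.dump(
            {"df": result.stat_maps[next(iter(result.stat_maps))].df,
             "n1": int(np.sum(result.cohort.groups == 1)),
             "n2": int(np.sum(result.cohort.groups == 2))},
            fh, indent=2,
        )
    tables = []
    for metric, per_effect in result.cluster_reports.items():
        for effect, report in per_effect.items():
            df = report.to_dataframe()
            if df.empty:
                continue
            df.insert(0, "effect", effect)
            df.insert(0, "metric", metric)
            tables.append(df)
    if tables:
        combined = pd.concat(tables, ignore_index=True)
    else:
        combined = pd.DataFrame(
            columns=["metric", "effect", "sign", "size_voxels", "size_mm3", "peak_t",
                     "peak_i", "peak_j", "peak_k", "peak_x_mm", "peak_y_mm", "peak_z_mm"]
        )
    combined.to_csv(deriv / "cluster" / "clusters.tsv", sep="\t", index=False)
    with open(deriv / "cluster" / "threshold.json", "w") as fh:
        json.dump(
            {"threshold_voxels": result.threshold_voxels,
             "threshold_mm3": result.threshold_mm3},
            fh, indent=2,
        )
    result.correlations.to_csv(
        deriv / "correlations" / "correlations.tsv", sep="\t", index=False
    )
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(result.provenance, fh, indent=2, default=str)
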