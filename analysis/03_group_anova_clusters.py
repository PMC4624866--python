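#!/usr/bin/env python
"""Voxelwise 2x2 mixed ANOVA with Monte Carlo cluster-extent correction.

Loads the cached band maps, runs the group (patients vs controls) x band
(slow-4 vs slow-5) mixed-design ANOVA voxel by voxel for normalized ALFF and
fALFF, estimates the FWER-controlling cluster-extent threshold by AlphaSim-type
simulation (voxel p < 0.05, alpha = 0.05, FWHM 6 mm, 1000 iterations), and
writes corrected cluster tables (extent, peak t, peak coordinates) shaped like
a findings table.

Run after 02:  python analysis/03_group_anova_clusters.py
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from bandalff import (
    AlphaSimConfig,
    VolumeGrid,
    alphasim_threshold,
    threshold_statmap,
    voxelwise_mixed_anova,
)

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def main() -> None:
    with open(RESULTS / "study_config.json") as fh:
        config = json.load(fh)
    data = np.load(SCRATCH / "band_maps.npz", allow_pickle=False)
    grid = VolumeGrid.isotropic(config["cohort"]["grid_dims"],
                                config["cohort"]["voxel_size_mm"])
    groups = data["groups"]
    cl = config["cluster"]

    sim = alphasim_threshold(
        AlphaSimConfig(
            mask=np.ones(grid.dims, bool), voxel_p=cl["voxel_p"], alpha=cl["alpha"],
            n_iterations=cl["iterations"], fwhm_mm=cl["fwhm_mm"],
            voxel_size_mm=grid.voxel_size_mm[0], connectivity=cl["connectivity"],
            seed=config["seed"] + 1,
        )
    )
    print(f"Cluster-extent threshold (voxel p<{cl['voxel_p']}, alpha={cl['alpha']}, "
          f"FWHM {cl['fwhm_mm']} mm, {cl['iterations']} iterations): "
          f"{sim.threshold_voxels} voxels = {sim.threshold_mm3:.0f} mm^3")

    tables = []
    for metric, key in (("alff_norm", "alff_norm"), ("falff", "falff")):
        stats = voxelwise_mixed_anova(
            data[f"{key}_slow4"].astype(float), data[f"{key}_slow5"].astype(float),
            groups,
        )
        np.savez_compressed(
            SCRATCH / f"statmaps_{metric}.npz", t_group=stats.t_group,
            t_band=stats.t_band, t_interaction=stats.t_interaction,
            df=stats.df,
        )
        for effect in ("group", "band", "interaction"):
            report = threshold_statmap(
                stats.effect(effect), stats.df, cl["voxel_p"],
                sim.threshold_voxels, grid, connectivity=cl["connectivity"],
            )
            df = report.to_dataframe()
            df.insert(0, "effect", effect)
            df.insert(0, "metric", metric)
            tables.append(df)
            peaks = ", ".join(
                f"{c.sign[0]}{c.size_voxels}vx(t={c.peak_t:.2f})" for c in report.clusters
            ) or "none"
            print(f"  {metric:9s} {effect:12s} df={stats.df}: "
                  f"{len(report)} corrected cluster(s): {peaks}")

    combined = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    combined.to_csv(RESULTS / "cluster_table.tsv", sep="\t", index=False)
    with open(RESULTS / "cluster_threshold.json", "w") as fh:
        json.dump({"threshold_voxels": sim.threshold_voxels,
                   "threshold_mm3": sim.threshold_mm3}, fh, indent=2)
    print(f"Cluster table written to {RESULTS / 'cluster_table.tsv'}")


if __name__ == "__main__":
    main()
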