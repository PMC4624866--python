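#!/usr/bin/env python
"""Regional amplitude vs clinical score correlations in the patient group.

For each corrected group-effect cluster (both metrics), extracts every
patient's mean normalized ALFF / fALFF in both bands and correlates it with
THQ severity and tinnitus duration — plain Pearson r plus the partial
correlation adjusted for age, sex and education.  The planted ground truth is
an r = 0.5 THQ coupling to the slow-4 ROI amplitude; duration is uncoupled.

Run after 03:  python analysis/04_regional_correlations.py
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from bandalff import (
    VolumeGrid,
    extract_cluster_means,
    partial_corr,
    pearson_corr,
    threshold_statmap,
)

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"


def main() -> None:
    with open(RESULTS / "study_config.json") as fh:
        config = json.load(fh)
    with open(RESULTS / "cluster_threshold.json") as fh:
        threshold = json.load(fh)["threshold_voxels"]
    data = np.load(SCRATCH / "band_maps.npz", allow_pickle=False)
    grid = VolumeGrid.isotropic(config["cohort"]["grid_dims"],
                                config["cohort"]["voxel_size_mm"])
    g1 = data["groups"] == 1
    covariates = np.column_stack([data["age"], data["sex"], data["education"]])[g1]
    clinical = {"thq": data["thq"][g1], "duration_months": data["duration"][g1]}

    rows = []
    for metric in ("alff_norm", "falff"):
        stats = np.load(SCRATCH / f"statmaps_{metric}.npz")
        cluster_masks: list = []
        report = threshold_statmap(
            stats["t_group"], int(stats["df"]), config["cluster"]["voxel_p"],
            threshold, grid, connectivity=config["cluster"]["connectivity"],
            cluster_masks=cluster_masks,
        )
        for ci, (cluster, cmask) in enumerate(zip(report.clusters, cluster_masks)):
            band_means = {
                band: extract_cluster_means(
                    data[f"{metric}_{band.replace('-', '')}"].astype(float), cmask
                )[g1]
                for band in ("slow-4", "slow-5")
            }
            for band, values in band_means.items():
                for cov_name, cov in clinical.items():
                    ok = np.isfinite(cov)
                    r, p = pearson_corr(values[ok], cov[ok])
                    rp, pp = partial_corr(values[ok], cov[ok], covariates[ok])
                    rows.append(
                        {"metric": metric, "cluster": ci, "sign": cluster.sign,
                         "size_voxels": cluster.size_voxels, "band": band,
                         "covariate": cov_name, "n": int(ok.sum()),
                         "r": round(r, 3), "p": round(p, 4),
                         "r_partial": round(rp, 3), "p_partial": round(pp, 4)}
                    )

    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "correlation_table.tsv", sep="\t", index=False)
    print("Correlations of cluster-mean amplitude with clinical scores "
          f"({int(g1.sum())} patients):")
    print(table.to_string(index=False))
    planted = table[(table.band == "slow-4") & (table.covariate == "thq")]
    if not planted.empty:
        print("\nPlanted effect (slow-4 amplitude vs THQ, target r = 0.5): "
              f"observed r = {planted.r.max():.3f} in the best-matching cluster")
    print("Duration was left uncoupled; its correlations estimate the null.")


if __name__ == "__main__":
    main()
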