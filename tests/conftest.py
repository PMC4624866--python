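import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from bandalff import SyntheticSpec, ball_roi, band_by_name


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def tiny_spec():
    """Small, fast cohort spec with one slow-4 ROI carrying a group effect."""
    dims = (10, 10, 8)
    roi = ball_roi("roi", (5, 5, 4), 2, dims, band_by_name("slow4"),
                   base_amplitude=10.0, group1_multiplier=1.5, group2_multiplier=1.0)
    return SyntheticSpec(
        n_group1=3, n_group2=3, grid_dims=dims, n_timepoints=60,
        roi_list=(roi,), seed=11,
    )


def splitplot_anova_oracle(y4, y5, group):
    """Independent cell-means split-plot ANOVA for a balanced 2 (group) x
    2 (band, within-subject) design.

    Computes the classical sums of squares directly from cell/subject means and
    returns the three F ratios.  Used only as a cross-check oracle for the
    closed-form t statistics (t^2 must equal F).
    """
    y4 = np.asarray(y4, float)
    y5 = np.asarray(y5, float)
    group = np.asarray(group)
    y = np.stack([y4, y5], axis=1)  # (subjects, bands)
    g1, g2 = group == 1, group == 2
    n = int(g1.sum())
    assert n == int(g2.sum()), "oracle assumes a balanced design"
    a = b = 2
    grand = y.mean()
    subj_means = y.mean(axis=1)
    group_means = np.array([y[g1].mean(), y[g2].mean()])
    band_means = y.mean(axis=0)
    cell_means = np.array([y[g1].mean(axis=0), y[g2].mean(axis=0)])  # (group, band)

    ss_group = b * n * ((group_means - grand) ** 2).sum()
    ss_subj = b * sum(
        ((subj_means[gm] - group_means[i]) ** 2).sum() for i, gm in enumerate((g1, g2))
    )
    ss_band = a * n * ((band_means - grand) ** 2).sum()
    ss_inter = n * (
        (cell_means - group_means[:, None] - band_means[None, :] + grand) ** 2
    ).sum()
    ss_within = sum(
        ((y[gm] - subj_means[gm][:, None] - cell_means[i][None, :]
          + group_means[i]) ** 2).sum()
        for i, gm in enumerate((g1, g2))
    )
    df_subj = a * (n - 1)
    df_within = a * (n - 1) * (b - 1)
    f_group = (ss_group / (a - 1)) / (ss_subj / df_subj)
    f_band = (ss_band / (b - 1)) / (ss_within / df_within)
    f_inter = (ss_inter / ((a - 1) * (b - 1))) / (ss_within / df_within)
    return {"group": f_group, "band": f_band, "interaction": f_inter}
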