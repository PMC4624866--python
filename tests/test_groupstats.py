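"""Mixed 2x2 ANOVA closed forms, correlations and voxelwise statistics."""

import numpy as np
import pytest

from bandalff import (
    critical_t,
    extract_cluster_means,
    mixed_anova_2x2,
    partial_corr,
    pearson_corr,
    voxelwise_mixed_anova,
    voxelwise_regression,
)
from bandalff.errors import (
    CollinearityError,
    DegenerateInputError,
    DomainError,
)
from conftest import splitplot_anova_oracle

# worked 2+2 design: group1 (slow5, slow4) = (1,3),(2,5); group2 = (5,5),(6,7)
Y4 = np.array([3.0, 5.0, 5.0, 7.0])
Y5 = np.array([1.0, 2.0, 5.0, 6.0])
G = np.array([1, 1, 2, 2])


class TestMixedAnova2x2:
    def test_worked_example_t_values(self):
        res = mixed_anova_2x2(Y4, Y5, G)
        assert res["interaction"].t == pytest.approx(2.8284, abs=1e-4)
        assert res["band"].t == pytest.approx(4.2426, abs=1e-4)
        assert res["group"].t == pytest.approx(-2.8284, abs=1e-4)
        assert all(r.df == 2 for r in res.values())

    def test_t_squared_equals_oracle_f_on_random_balanced_designs(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 21))
            y4 = rng.standard_normal(2 * n)
            y5 = rng.standard_normal(2 * n)
            g = np.repeat([1, 2], n)
            res = mixed_anova_2x2(y4, y5, g)
            oracle = splitplot_anova_oracle(y4, y5, g)
            for effect in ("group", "band", "interaction"):
                assert res[effect].t ** 2 == pytest.approx(oracle[effect], abs=1e-8, rel=1e-8)

    def test_matches_pingouin_mixed_anova(self, rng):
        import pandas as pd
        import pingouin as pg

        n = 8
        y4 = rng.standard_normal(2 * n)
        y5 = rng.standard_normal(2 * n)
        g = np.repeat([1, 2], n)
        df = pd.DataFrame(
            {
                "subject": np.tile(np.arange(2 * n), 2),
                "group": np.tile(g, 2),
                "band": np.repeat(["slow4", "slow5"], 2 * n),
                "y": np.concatenate([y4, y5]),
            }
        )
        aov = pg.mixed_anova(df, dv="y", within="band", between="group",
                             subject="subject").set_index("Source")
        res = mixed_anova_2x2(y4, y5, g)
        assert res["group"].t ** 2 == pytest.approx(aov.loc["group", "F"], rel=1e-6)
        assert res["band"].t ** 2 == pytest.approx(aov.loc["band", "F"], rel=1e-6)
        assert res["interaction"].t ** 2 == pytest.approx(aov.loc["Interaction", "F"], rel=1e-6)

    def test_label_swap_flips_group_and_interaction_signs_only(self):
        res = mixed_anova_2x2(Y4, Y5, G)
        swapped = mixed_anova_2x2(Y4, Y5, np.where(G == 1, 2, 1))
        assert swapped["group"].t == pytest.approx(-res["group"].t)
        assert swapped["interaction"].t == pytest.approx(-res["interaction"].t)
        assert swapped["band"].t == pytest.approx(res["band"].t)

    def test_identical_values_degenerate(self):
        with pytest.raises(DegenerateInputError):
            mixed_anova_2x2([1, 1, 1, 1], [1, 1, 1, 1], G)

    def test_group_of_one_rejected(self):
        with pytest.raises(DomainError):
            mixed_anova_2x2([1, 2, 3], [1, 2, 3], [1, 2, 2])


class TestVoxelwiseMixedAnova:
    def test_per_voxel_results_match_scalar_path(self, rng):
        n = 6
        y4 = rng.standard_normal((2 * n, 3, 3, 2))
        y5 = rng.standard_normal((2 * n, 3, 3, 2))
        g = np.repeat([1, 2], n)
        maps = voxelwise_mixed_anova(y4, y5, g)
        scalar = mixed_anova_2x2(y4[:, 1, 2, 0], y5[:, 1, 2, 0], g)
        assert maps.t_group[1, 2, 0] == pytest.approx(scalar["group"].t)
        assert maps.t_band[1, 2, 0] == pytest.approx(scalar["band"].t)
        assert maps.t_interaction[1, 2, 0] == pytest.approx(scalar["interaction"].t)
        assert maps.df == 2 * n - 2

    def test_degenerate_voxels_masked_not_raised(self, rng):
        y4 = rng.standard_normal((6, 2, 2, 2))
        y5 = rng.standard_normal((6, 2, 2, 2))
        y4[:, 0, 0, 0] = 1.0
        y5[:, 0, 0, 0] = 1.0
        maps = voxelwise_mixed_anova(y4, y5, [1, 1, 1, 2, 2, 2])
        assert np.isnan(maps.t_group[0, 0, 0])
        assert np.isfinite(maps.t_group[1, 1, 1])

    def test_out_of_mask_is_nan(self, rng):
        y4 = rng.standard_normal((6, 2, 2, 2))
        y5 = rng.standard_normal((6, 2, 2, 2))
        mask = np.zeros((2, 2, 2), bool)
        mask[0, 0, 0] = True
        maps = voxelwise_mixed_anova(y4, y5, [1, 1, 1, 2, 2, 2], mask)
        assert np.isfinite(maps.t_group[0, 0, 0])
        assert np.isnan(maps.t_group[1, 1, 1])


class TestCriticalT:
    def test_reference_value_df78(self):
        assert critical_t(0.05, 78) == pytest.approx(1.9908, abs=1e-4)

    def test_normal_limit(self):
        assert critical_t(0.05, 10 ** 6) == pytest.approx(1.9600, abs=1e-3)

    def test_threshold_shrinks_as_p_grows(self):
        assert critical_t(0.9999, 30) < 0.001
        assert critical_t(0.01, 30) > critical_t(0.05, 30)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(DomainError):
            critical_t(0.0, 10)
        with pytest.raises(DomainError):
            critical_t(0.05, 0)


class TestPearsonCorr:
    def test_perfect_and_anti_correlation(self):
        assert pearson_corr([1, 2, 3], [1, 2, 3])[0] == pytest.approx(1.0)
        assert pearson_corr([1, 2, 3], [3, 2, 1])[0] == pytest.approx(-1.0)

    def test_hand_computed_r(self):
        # centered x = (-2,-1,0,1,2), centered y = (-1.2,-2.2,0.8,-0.2,2.8):
        # sum xy = 10, sum x^2 = 10, sum y^2 = 14.8 -> r = 10/sqrt(148)
        r, p = pearson_corr([1, 2, 3, 4, 5], [2, 1, 4, 3, 6])
        assert r == pytest.approx(10 / np.sqrt(148), abs=1e-12)
        assert 0 < p < 1

    def test_matches_scipy(self, rng):
        import scipy.stats

        x, y = rng.standard_normal((2, 30))
        r, p = pearson_corr(x, y)
        ref = scipy.stats.pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_input_degenerate(self):
        with pytest.raises(DegenerateInputError):
            pearson_corr([1, 1, 1], [1, 2, 3])


class TestPartialCorr:
    def test_single_covariate_matches_closed_form(self, rng):
        x, y, z = rng.standard_normal((3, 5))
        rxy = pearson_corr(x, y)[0]
        rxz = pearson_corr(x, z)[0]
        ryz = pearson_corr(y, z)[0]
        expected = (rxy - rxz * ryz) / np.sqrt((1 - rxz ** 2) * (1 - ryz ** 2))
        assert partial_corr(x, y, z)[0] == pytest.approx(expected, abs=1e-10)

    def test_no_covariates_equals_pearson(self, rng):
        x, y = rng.standard_normal((2, 20))
        assert partial_corr(x, y, None) == pearson_corr(x, y)

    def test_identity_relation_with_independent_covariates(self, rng):
        x = rng.standard_normal(30)
        cov = rng.standard_normal((30, 3))
        r, p = partial_corr(x, x.copy(), cov)
        assert r == pytest.approx(1.0)

    def test_covariate_driven_variable_decorrelated(self, rng):
        rs = []
        for _ in range(50):
            age = rng.standard_normal(40)
            x = rng.standard_normal(40)
            y = 2.0 * age
            rs.append(partial_corr(x, y + 1e-6 * rng.standard_normal(40), age)[0])
        assert np.abs(np.mean(rs)) < 4 / np.sqrt(40)

    def test_rank_deficient_covariates_rejected(self, rng):
        x, y = rng.standard_normal((2, 20))
        c = rng.standard_normal(20)
        with pytest.raises(CollinearityError):
            partial_corr(x, y, np.column_stack([c, 2 * c]))


class TestVoxelwiseRegression:
    def test_exact_linear_voxel_flagged_infinite(self, rng):
        age = rng.uniform(20, 70, 10)
        maps = rng.standard_normal((10, 2, 2, 1))
        maps[:, 0, 0, 0] = 2.0 * age + 1.0
        t = voxelwise_regression(maps, age)
        assert np.isinf(t[0, 0, 0]) and t[0, 0, 0] > 0
        assert np.isfinite(t[1, 1, 0])

    def test_shift_invariance_of_slope_t(self, rng):
        age = rng.uniform(20, 70, 15)
        maps = rng.standard_normal((15, 3, 3, 3))
        t1 = voxelwise_regression(maps, age)
        t2 = voxelwise_regression(maps, age + 100.0)
        np.testing.assert_allclose(t1, t2, rtol=1e-8)

    def test_constant_covariate_degenerate(self, rng):
        with pytest.raises(DegenerateInputError):
            voxelwise_regression(rng.standard_normal((5, 2, 2, 2)), np.ones(5))

    def test_matches_scipy_linregress_per_voxel(self, rng):
        import scipy.stats

        cov = rng.standard_normal(12)
        maps = rng.standard_normal((12, 2, 1, 1))
        t = voxelwise_regression(maps, cov)
        lr = scipy.stats.linregress(cov, maps[:, 1, 0, 0])
        assert t[1, 0, 0] == pytest.approx(lr.slope / lr.stderr, rel=1e-8)


class TestExtractClusterMeans:
    def test_single_voxel_cluster_returns_that_voxel(self, rng):
        maps = rng.standard_normal((5, 3, 3, 3))
        mask = np.zeros((3, 3, 3), bool)
        mask[1, 2, 0] = True
        np.testing.assert_allclose(extract_cluster_means(maps, mask), maps[:, 1, 2, 0])

    def test_uniform_map_returns_constant(self):
        maps = np.full((4, 2, 2, 2), 3.3)
        mask = np.ones((2, 2, 2), bool)
        np.testing.assert_allclose(extract_cluster_means(maps, mask), 3.3)

    def test_empty_mask_rejected(self, rng):
        with pytest.raises(DomainError):
            extract_cluster_means(rng.standard_normal((4, 2, 2, 2)), np.zeros((2, 2, 2), bool))
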