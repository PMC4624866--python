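"""Synthetic cohort generator: planted signals, covariates, motion, determinism."""

import numpy as np
import pytest

from bandalff import (
    SyntheticSpec,
    amplitude_spectrum,
    ball_roi,
    band_alff,
    band_by_name,
    cohort_plan,
    generate_cohort,
    generate_subject_run,
    iter_cohort,
    plant_band_signal,
    plant_covariate,
    screen_motion,
)
from bandalff.errors import DegenerateInputError, DomainError, InvalidBandError
from bandalff.simulate import subject_amplitudes
from bandalff.spectral import FrequencyBand

SLOW4 = band_by_name("slow4")


class TestPlantBandSignal:
    def test_spectrum_zero_outside_band(self):
        x = plant_band_signal(230, 2.0, SLOW4, 1.0, seed=7)
        spec = amplitude_spectrum(x, 2.0)
        outside = (spec.frequencies < 0.027 - 1e-12) | (spec.frequencies >= 0.073)
        assert np.all(spec.amplitudes[outside] <= 1e-12)

    def test_sample_sd_matches_target_exactly(self):
        x = plant_band_signal(230, 2.0, SLOW4, 1.0, seed=7)
        assert x.std(ddof=1) == pytest.approx(1.0, abs=1e-9)
        assert abs(x.mean()) < 1e-12

    def test_zero_target_gives_zero_series(self):
        assert np.all(plant_band_signal(230, 2.0, SLOW4, 0.0, seed=1) == 0)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(InvalidBandError):
            plant_band_signal(230, 2.0, FrequencyBand("hi", 0.3, 0.4), 1.0, seed=1)

    def test_negative_sd_rejected(self):
        with pytest.raises(DomainError):
            plant_band_signal(230, 2.0, SLOW4, -1.0, seed=1)

    def test_deterministic_given_seed(self):
        a = plant_band_signal(230, 2.0, SLOW4, 1.0, seed=42)
        b = plant_band_signal(230, 2.0, SLOW4, 1.0, seed=42)
        np.testing.assert_array_equal(a, b)


class TestPlantCovariate:
    def test_perfect_coupling_exact(self, rng):
        x = rng.standard_normal(20)
        y = plant_covariate(x, 1.0, seed=0)
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(1.0)

    def test_zero_coupling_independent(self, rng):
        n = 2000
        x = rng.standard_normal(n)
        y = plant_covariate(x, 0.0, seed=1)
        assert abs(np.corrcoef(x, y)[0, 1]) < 4 / np.sqrt(n)

    def test_monte_carlo_mean_sample_r_near_target(self, rng):
        # 500 independent draws at n=39, target r=0.5
        rs = []
        for seed in range(500):
            x = np.random.default_rng(1000 + seed).standard_normal(39)
            y = plant_covariate(x, 0.5, seed=seed)
            rs.append(np.corrcoef(x, y)[0, 1])
        assert np.mean(rs) == pytest.approx(0.5, abs=0.03)

    def test_constant_x_degenerate(self):
        with pytest.raises(DegenerateInputError):
            plant_covariate(np.ones(10), 0.5, seed=0)


@pytest.fixture
def noiseless_spec():
    dims = (8, 8, 6)
    roi = ball_roi("roi", (4, 4, 3), 1.5, dims, SLOW4, base_amplitude=1.0,
                   group1_multiplier=1.5, group2_multiplier=1.0)
    return SyntheticSpec(
        n_group1=2, n_group2=2, grid_dims=dims, n_timepoints=60,
        roi_list=(roi,), baseline=0.0, noise_sd=0.0, drift_slope_sd=0.0,
        subject_amplitude_sd=0.0, seed=3,
    )


class TestGenerateSubjectRun:
    def test_non_roi_voxels_constant_without_noise(self, noiseless_spec):
        plan = cohort_plan(noiseless_spec)[0]
        run, _ = generate_subject_run(noiseless_spec, plan.record, plan.index)
        roi_mask = noiseless_spec.roi_list[0].mask(noiseless_spec.grid_dims)
        outside = run.data[~roi_mask]
        assert np.ptp(outside, axis=-1).max() == 0.0

    def test_group_amplitude_ratio_exact_in_band_alff(self, noiseless_spec):
        # ALFF is linear in signal scale: multipliers 1.5 vs 1.0 give ratio 1.5
        spec = noiseless_spec
        roi_mask = spec.roi_list[0].mask(spec.grid_dims)
        alffs = []
        for run, _, record in iter_cohort(spec):
            sp = amplitude_spectrum(run.data[roi_mask], spec.tr_seconds)
            alffs.append(np.mean(band_alff(sp, SLOW4)))
        g1 = np.mean(alffs[:2])
        g2 = np.mean(alffs[2:])
        assert g1 / g2 == pytest.approx(1.5, abs=1e-6)

    def test_designated_outlier_flagged_by_motion_screen(self, noiseless_spec):
        import dataclasses

        spec = dataclasses.replace(noiseless_spec, motion_outlier_fraction=0.5)
        for _, trace, _, plan in iter_cohort(spec, with_plan=True):
            assert screen_motion(trace).keep != plan.is_motion_outlier

    def test_motion_trace_covers_retained_volumes(self, noiseless_spec):
        _, trace = generate_subject_run(
            noiseless_spec, cohort_plan(noiseless_spec)[0].record, 0
        )
        assert trace.n_timepoints == noiseless_spec.n_timepoints - 10


class TestGenerateCohort:
    def test_sizes_and_group_order(self, tiny_spec):
        import dataclasses

        spec = dataclasses.replace(tiny_spec, n_group1=4, n_group2=5)
        cohort = generate_cohort(spec)
        assert len(cohort) == 9
        assert [r.group for _, _, r in cohort] == [1] * 4 + [2] * 5

    def test_bit_identical_on_rerun(self, tiny_spec):
        a = generate_cohort(tiny_spec)
        b = generate_cohort(tiny_spec)
        for (run_a, tr_a, rec_a), (run_b, tr_b, rec_b) in zip(a, b):
            np.testing.assert_array_equal(run_a.data, run_b.data)
            np.testing.assert_array_equal(tr_a.translations_mm, tr_b.translations_mm)
            assert rec_a == rec_b

    def test_outlier_count_follows_rounding_rule(self, tiny_spec):
        import dataclasses

        spec = dataclasses.replace(
            tiny_spec, n_group1=4, n_group2=4, motion_outlier_fraction=0.25
        )
        plans = cohort_plan(spec)
        assert sum(p.is_motion_outlier for p in plans) == 2
        assert sum(p.is_motion_outlier for p in plans if p.group == 1) == 1

    def test_covariate_coupling_planted_at_target_r(self):
        from bandalff import CouplingSpec

        dims = (6, 6, 6)
        roi = ball_roi("roi", (3, 3, 3), 1.5, dims, SLOW4, base_amplitude=10.0)
        spec = SyntheticSpec(
            n_group1=200, n_group2=2, grid_dims=dims, n_timepoints=32,
            roi_list=(roi,), subject_amplitude_sd=0.3,
            covariate_couplings=(CouplingSpec("thq", "roi", "slow-4", 0.5),),
            seed=8,
        )
        plans = cohort_plan(spec)
        amps = [p.amplitudes["roi"] for p in plans if p.group == 1]
        thq = [p.record.thq for p in plans if p.group == 1]
        r = np.corrcoef(amps, thq)[0, 1]
        assert r == pytest.approx(0.5, abs=0.15)

    def test_effect_monotonicity_in_group1_multiplier(self, noiseless_spec):
        import dataclasses

        roi0 = noiseless_spec.roi_list[0]
        alff_means = []
        outside_data = []
        for mult in (1.0, 1.5, 2.0):
            roi = dataclasses.replace(roi0, group1_multiplier=mult)
            spec = dataclasses.replace(noiseless_spec, roi_list=(roi,))
            roi_mask = roi.mask(spec.grid_dims)
            runs = [run for run, _, rec in iter_cohort(spec) if rec.group == 1]
            sp = amplitude_spectrum(np.stack([r.data[roi_mask] for r in runs]), 2.0)
            alff_means.append(np.mean(band_alff(sp, SLOW4)))
            outside_data.append(np.stack([r.data[~roi_mask] for r in runs]))
        assert alff_means[0] < alff_means[1] < alff_means[2]
        np.testing.assert_array_equal(outside_data[0], outside_data[1])

    def test_invalid_spec_rejected(self):
        with pytest.raises(DomainError):
            SyntheticSpec(n_group1=1, n_group2=5)
        with pytest.raises(DomainError):
            SyntheticSpec(motion_outlier_fraction=1.5)


class TestWriteCohort(object):
    def test_round_trip_through_files(self, tiny_spec, tmp_path):
        from bandalff import write_cohort
        from bandalff.pipeline import load_cohort_dir

        paths = write_cohort(tiny_spec, tmp_path)
        assert len(paths["bold"]) == tiny_spec.n_subjects
        subjects, grid = load_cohort_dir(tmp_path)
        assert grid.dims == tiny_spec.grid_dims
        run0, motion0, rec0 = subjects[0]
        ref = generate_cohort(tiny_spec)[0]
        np.testing.assert_allclose(run0.data, ref[0].data.astype(np.float32), rtol=1e-6)
        assert rec0.subject_id == ref[2].subject_id
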