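"""Phantom generator: geometry, ground truth, forward models, calibration."""

import dataclasses

import numpy as np
import pytest

from hypoperf import (
    PhantomSpec,
    RoiSphere,
    calibrate_noise,
    make_roi_labels,
    quantify_series,
    simulate_asl_series,
    simulate_cohort,
    simulate_pet_image,
    simulate_truth_cbf,
    split_pairs,
)
from hypoperf.pet_proc import normalize_global
from hypoperf.synthetic import (
    ROI_LABELS,
    RoiOverlapError,
    measured_roi_cov,
    subject_multiplier,
    truth_template,
)


class TestRoiLabels:
    def test_default_spec_has_six_populated_labels(self, labels):
        present, counts = np.unique(labels[labels > 0], return_counts=True)
        assert set(present) == set(ROI_LABELS.values())
        assert (counts >= 8).all()

    def test_every_brain_voxel_has_exactly_one_label(self, spec, labels):
        # labels partition the brain: nonzero inside, zero outside
        brain = labels > 0
        assert brain.sum() > 0
        assert np.all(labels[~brain] == 0)

    def test_labels_invariant_across_subjects(self, spec):
        assert np.array_equal(make_roi_labels(spec), make_roi_labels(spec))

    def test_two_disjoint_spheres(self):
        spec = PhantomSpec(
            roi_geometry={
                "thalamus": RoiSphere((9.0, 11.0, 6.0), 1.5),
                "globus_pallidum": RoiSphere((14.0, 11.0, 6.0), 1.5),
            }
        )
        labels = make_roi_labels(spec)
        assert set(np.unique(labels)) == {0, 1, 3, 5, 6}

    def test_overlap_names_colliding_rois(self):
        spec = PhantomSpec(
            roi_geometry={
                "thalamus": RoiSphere((11.0, 11.0, 6.0), 2.0),
                "globus_pallidum": RoiSphere((12.0, 11.0, 6.0), 2.0),
            }
        )
        with pytest.raises(RoiOverlapError, match="thalamus.*globus_pallidum"):
            make_roi_labels(spec)

    def test_roi_outside_brain_rejected(self):
        spec = PhantomSpec(
            roi_geometry={"thalamus": RoiSphere((1.0, 1.0, 1.0), 2.0)}
        )
        with pytest.raises(ValueError, match="outside"):
            make_roi_labels(spec)


class TestTruthCbf:
    def test_null_effect_gives_identical_conditions(self, labels):
        spec = PhantomSpec(effect_fraction={n: 0.0 for n in ROI_LABELS})
        eu = simulate_truth_cbf(spec, 0, "eu", labels)
        hypo = simulate_truth_cbf(spec, 0, "hypo", labels)
        assert np.array_equal(eu.cbf, hypo.cbf)

    def test_thalamus_ratio_exact_without_subject_sd(self, labels):
        spec = PhantomSpec(between_subject_sd=0.0)
        eu = simulate_truth_cbf(spec, 0, "eu", labels)
        hypo = simulate_truth_cbf(spec, 0, "hypo", labels)
        thal = labels == ROI_LABELS["thalamus"]
        assert hypo.cbf[thal].mean() / eu.cbf[thal].mean() == pytest.approx(1.10, rel=1e-12)

    def test_template_effect_structure(self, spec, labels):
        eu = truth_template(spec, "eu", labels)
        hypo = truth_template(spec, "hypo", labels)
        for name, label in ROI_LABELS.items():
            roi = labels == label
            ratio = hypo.cbf[roi].mean() / eu.cbf[roi].mean()
            assert ratio == pytest.approx(1.0 + spec.effect_fraction[name], rel=1e-12)

    def test_population_ratio_matches_effect(self, labels):
        # population-average hypo/eu per ROI stays at 1 + effect_fraction
        spec = dataclasses.replace(PhantomSpec(seed=3), n_subjects=200)
        for name in ("thalamus", "white_matter"):
            roi = labels == ROI_LABELS[name]
            ratios = []
            for s in range(spec.n_subjects):
                eu = simulate_truth_cbf(spec, s, "eu", labels)
                hypo = simulate_truth_cbf(spec, s, "hypo", labels)
                ratios.append(hypo.cbf[roi].mean() / eu.cbf[roi].mean())
            assert np.mean(ratios) == pytest.approx(1.0 + spec.effect_fraction[name], abs=0.01)

    def test_zero_outside_brain_positive_inside(self, labels, truth_eu):
        assert np.all(truth_eu.cbf[labels == 0] == 0.0)
        assert np.all(truth_eu.cbf[labels > 0] > 0.0)

    def test_subject_multiplier_shared_across_conditions(self, spec):
        assert subject_multiplier(spec, 3) == subject_multiplier(spec, 3)
        assert subject_multiplier(spec, 3) != subject_multiplier(spec, 4)

    def test_bad_subject_index(self, spec):
        with pytest.raises(ValueError):
            simulate_truth_cbf(spec, spec.n_subjects, "eu")


class TestForwardAsl:
    def test_exact_inverse_round_trip(self, spec, labels, truth_eu, m0_map, rng):
        series = simulate_asl_series(truth_eu, m0_map, spec.acq, 0.0, 140, rng)
        recovered = quantify_series(series)
        brain = labels > 0
        rel = np.abs(recovered.cbf[brain] - truth_eu.cbf[brain]) / truth_eu.cbf[brain]
        assert rel.max() < 1e-6

    def test_140_frames_make_70_pairs(self, spec, truth_eu, m0_map, rng):
        series = simulate_asl_series(truth_eu, m0_map, spec.acq, 0.0, 140, rng)
        assert len(split_pairs(series)) == 70

    def test_odd_frame_count_rejected(self, spec, truth_eu, m0_map, rng):
        with pytest.raises(ValueError, match="even"):
            simulate_asl_series(truth_eu, m0_map, spec.acq, 0.0, 7, rng)

    def test_roi_mean_unbiased_under_noise(self, spec, labels, truth_eu, m0_map):
        # pooled 70-pair ROI mean over replicates stays within 2 SE of truth
        thal = labels == ROI_LABELS["thalamus"]
        estimates = []
        for rep in range(60):
            rng = np.random.default_rng(900 + rep)
            series = simulate_asl_series(
                truth_eu, m0_map, spec.acq, spec.asl_noise_sd, 140, rng
            )
            estimates.append(quantify_series(series).cbf[thal].mean())
        se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(np.mean(estimates) - truth_eu.cbf[thal].mean()) < 2 * se

    def test_tag_order_convention(self, spec, truth_eu, m0_map, rng):
        series = simulate_asl_series(truth_eu, m0_map, spec.acq, 0.0, 4, rng)
        assert series.frame_labels == ("tag", "control", "tag", "control")


class TestForwardPet:
    def test_identity_when_scale_one_noise_zero(self, truth_eu, rng):
        out = simulate_pet_image(truth_eu, 1.0, 0.0, rng)
        assert np.array_equal(out, truth_eu.cbf)

    def test_normalization_recovers_truth_pattern(self, labels, truth_eu, rng):
        out = simulate_pet_image(truth_eu, 37.5, 0.0, rng)
        brain = labels > 0
        norm = normalize_global(out, brain)
        expected = truth_eu.cbf * (50.0 / truth_eu.cbf[brain].mean())
        assert np.allclose(norm.cbf[brain], expected[brain], rtol=1e-9)

    def test_nonpositive_scale_rejected(self, truth_eu, rng):
        with pytest.raises(ValueError):
            simulate_pet_image(truth_eu, 0.0, 0.1, rng)


class TestCohort:
    def test_same_seed_bit_identical(self, small_spec):
        t1, d1 = simulate_cohort(small_spec)
        t2, d2 = simulate_cohort(small_spec)
        assert np.array_equal(t1.labels, t2.labels)
        key = (0, "hypo")
        assert np.array_equal(d1[key]["asl"].data, d2[key]["asl"].data)
        assert np.array_equal(d1[key]["pet"][0], d2[key]["pet"][0])

    def test_different_seeds_differ(self, small_spec):
        other = dataclasses.replace(small_spec, seed=small_spec.seed + 1)
        _, d1 = simulate_cohort(small_spec)
        _, d2 = simulate_cohort(other)
        assert not np.array_equal(d1[(0, "eu")]["asl"].data, d2[(0, "eu")]["asl"].data)

    def test_structure(self, small_spec):
        truth, data = simulate_cohort(small_spec)
        assert set(data) == {(s, c) for s in range(2) for c in ("eu", "hypo")}
        assert data[(0, "eu")]["asl"].n_frames == small_spec.n_asl_frames
        assert len(data[(0, "eu")]["pet"]) == small_spec.n_pet_repeats
        assert len(truth.injected_motion[(0, "eu")]) == small_spec.n_asl_frames


class TestCalibration:
    def test_zero_target_rejected(self, spec):
        with pytest.raises(ValueError):
            calibrate_noise(spec, "pet", 0.0)

    def test_measured_cov_monotone_in_noise(self, spec):
        lo = measured_roi_cov(spec, "pet", 0.1, seed=1)
        hi = measured_roi_cov(spec, "pet", 0.6, seed=1)
        assert lo < hi

    def test_pet_calibration_hits_target(self, spec):
        sd = calibrate_noise(spec, "pet", 0.06, seed=21)
        measured = measured_roi_cov(spec, "pet", sd, seed=22)
        assert 0.045 <= measured <= 0.075

    def test_unreachable_target_reports_bracket(self, spec):
        with pytest.raises(ValueError, match="bracketed"):
            calibrate_noise(spec, "pet", 1e-6, seed=1)


class TestSpecValidation:
    def test_odd_frames_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(n_asl_frames=141)

    def test_negative_baseline_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(baseline_cbf={"thalamus": -5.0})

    def test_effect_fraction_floor(self):
        with pytest.raises(ValueError):
            PhantomSpec(effect_fraction={"thalamus": -1.5})
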