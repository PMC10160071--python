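import numpy as np
import pytest

from ramantda import (
    CohortSpec,
    default_profiles,
    generate_cohort,
    holdout_cohort,
    separable_cohort,
    study_cohort,
    STUDY_PATIENT_COUNTS,
    STUDY_PATIENT_LABELS,
    HOLDOUT_PATIENT_LABELS,
)

from conftest import COARSE_GRID


@pytest.fixture(scope="module")
def cohort():
    return study_cohort(seed=11, grid=COARSE_GRID)


class TestStudyCohort:
    def test_composition(self, cohort):
        assert len(cohort) == 400
        patients = cohort.patient_order
        assert len(patients) == 10
        counts = [len(cohort.patient_indices(p)) for p in patients]
        assert counts == list(STUDY_PATIENT_COUNTS)
        labels = [cohort.patient_label(p) for p in patients]
        assert labels == list(STUDY_PATIENT_LABELS)

    def test_benign_class_size(self, cohort):
        assert int(np.sum(cohort.labels == 0)) == 100  # 32 + 31 + 37

    def test_seed_changes_intensities_not_composition(self, cohort):
        other = study_cohort(seed=12, grid=COARSE_GRID)
        assert other.patient_order == cohort.patient_order
        assert np.array_equal(other.labels, cohort.labels)
        assert not np.allclose(other[0].intensities, cohort[0].intensities)


class TestHoldoutCohort:
    def test_one_spectrum_per_new_patient(self):
        ds = holdout_cohort(seed=5, grid=COARSE_GRID)
        assert len(ds) == 10
        assert len(ds.patient_order) == 10
        assert ds.labels.tolist() == list(HOLDOUT_PATIENT_LABELS)

    def test_patient_ids_disjoint_from_study(self):
        d1 = study_cohort(seed=5, grid=COARSE_GRID)
        d2 = holdout_cohort(seed=5, grid=COARSE_GRID)
        assert not set(d1.patient_order) & set(d2.patient_order)


class TestGenerateCohort:
    def test_seeded_determinism(self):
        spec = CohortSpec((3, 2), (0, 1), seed=9)
        a = generate_cohort(spec, grid=COARSE_GRID)
        b = generate_cohort(spec, grid=COARSE_GRID)
        for s1, s2 in zip(a, b):
            assert np.array_equal(s1.intensities, s2.intensities)

    def test_zero_noise_matches_closed_form(self):
        profiles = default_profiles(noise_std=0.0)
        spec = CohortSpec((2, 2), (0, 0), patient_effect_std=0.0,
                          patient_shift_std=0.0, seed=1)
        ds = generate_cohort(spec, profiles=profiles, grid=COARSE_GRID)
        expected = profiles[0].evaluate(COARSE_GRID)
        for s in ds:
            assert np.array_equal(s.intensities, expected)

    def test_missing_profile_rejected(self):
        spec = CohortSpec((2,), (3,), seed=0)
        profiles = {0: default_profiles()[0]}
        with pytest.raises(ValueError, match="profile"):
            generate_cohort(spec, profiles=profiles)

    def test_mismatched_spec_lengths(self):
        with pytest.raises(ValueError):
            CohortSpec((2, 2), (0,))

    def test_within_patient_dispersion_below_between_class(self):
        spec = CohortSpec((6, 6, 6, 6), (0, 0, 3, 3), patient_effect_std=0.03, seed=2)
        ds = generate_cohort(spec, grid=COARSE_GRID)
        means = {}
        for p in ds.patient_order:
            idx = ds.patient_indices(p)
            means[p] = np.mean([ds[i].intensities for i in idx], axis=0)
        labels = {p: ds.patient_label(p) for p in ds.patient_order}
        class_mean = {
            lab: np.mean([m for p, m in means.items() if labels[p] == lab], axis=0)
            for lab in (0, 3)
        }
        within = np.mean([
            np.linalg.norm(means[p] - class_mean[labels[p]]) for p in means
        ])
        between = np.linalg.norm(class_mean[0] - class_mean[3])
        assert within < between

    def test_gaussian_line_shape_supported(self):
        profiles = default_profiles(line_shape="gaussian")
        spec = CohortSpec((2,), (0,), seed=0)
        ds = generate_cohort(spec, profiles=profiles, grid=COARSE_GRID)
        assert np.all(np.isfinite(ds[0].intensities))


def test_separable_cohort_has_larger_class_contrast():
    base = study_cohort(seed=1, grid=COARSE_GRID)
    sep = separable_cohort(seed=1, grid=COARSE_GRID)
    assert sep.patient_order == base.patient_order

    def contrast(ds):
        y = ds.labels
        m0 = np.mean([s.intensities for s, l in zip(ds, y) if l == 0], axis=0)
        m3 = np.mean([s.intensities for s, l in zip(ds, y) if l == 3], axis=0)
        return np.linalg.norm(m0 - m3)

    assert contrast(sep) > 1.5 * contrast(base)
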