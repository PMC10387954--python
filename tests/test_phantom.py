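"""Phantom generator: ground-truth construction, acquisition simulation, cohorts."""
import numpy as np
import pytest

from oracles import approximation_bias
from t1relax.phantom import (
    Parcel,
    build_phantom,
    default_phantom_spec,
    default_protocol,
    generate_cohort,
    simulate_acquisition,
)
from t1relax.segmentation import CSF, GM
from t1relax.t1fit import fit_volume


class TestBuildPhantom:
    def test_null_configuration_makes_groups_identical(self):
        spec = default_phantom_spec(group_effect_ms={}, ventricle_scale_old=1.0)
        young = build_phantom(spec, "young", seed=5)
        old = build_phantom(spec, "old", seed=5)
        np.testing.assert_array_equal(young.true_t1, old.true_t1)
        np.testing.assert_array_equal(young.tissue_labels, old.tissue_labels)

    def test_group_effect_is_exact_in_truth(self):
        spec = default_phantom_spec(group_effect_ms={5: 150.0}, ventricle_scale_old=1.0)
        young = build_phantom(spec, "young", seed=6)
        old = build_phantom(spec, "old", seed=6)
        in_roi = (young.roi_labels == 5) & (young.tissue_labels != CSF)
        diff = old.true_t1[in_roi] - young.true_t1[in_roi]
        assert np.allclose(diff, 150.0)
        other = (young.roi_labels == 6) & (young.tissue_labels != CSF)
        assert np.allclose(old.true_t1[other] - young.true_t1[other], 0.0)

    def test_ventricle_enlargement_matches_geometric_count(self):
        # oracle: count voxels inside the scaled ellipsoids independently
        spec = default_phantom_spec(ventricle_scale_old=1.5, csf_shell_fraction=0.0)
        old = build_phantom(spec, "old", seed=7)
        shape = spec.shape
        idx = np.indices(shape)
        inside = np.zeros(shape, dtype=bool)
        for c in spec.ventricle_centers:
            acc = sum(
                ((idx[d] - c[d]) / (spec.ventricle_radii[d] * 1.5)) ** 2 for d in range(3)
            )
            inside |= acc <= 1.0
        brain = old.brain_mask
        assert (old.tissue_labels == CSF).sum() == int((inside & brain).sum())
        young = build_phantom(spec, "young", seed=7)
        ratio = (old.tissue_labels == CSF).sum() / (young.tissue_labels == CSF).sum()
        assert ratio == pytest.approx(1.5**3, rel=0.15)  # discretization slack

    def test_overlapping_parcels_rejected(self):
        spec = default_phantom_spec()
        clash = spec.parcels + (Parcel(99, "GM", "ellipsoid", (18.0, 28.0, 7.5, 2.0, 2.0, 2.0)),)
        spec.parcels = clash
        with pytest.raises(ValueError, match="overlap"):
            build_phantom(spec, "young", seed=8)

    def test_deterministic_given_seed(self):
        spec = default_phantom_spec()
        a = build_phantom(spec, "old", seed=9)
        b = build_phantom(spec, "old", seed=9)
        np.testing.assert_array_equal(a.true_t1, b.true_t1)
        c = build_phantom(spec, "old", seed=10)
        assert not np.array_equal(a.true_t1, c.true_t1)

    def test_pve_shell_t1_is_mixture(self):
        spec = default_phantom_spec(subject_sd_ms=0.0)
        s = build_phantom(spec, "old", seed=11)
        shell_in_caudate = s.shell_mask & (s.roi_labels == 3)
        assert shell_in_caudate.any()
        f = spec.csf_shell_fraction
        expected = f * 3500.0 + (1 - f) * (1300.0 + 150.0)  # caudate L carries the old shift
        assert np.allclose(s.true_t1[shell_in_caudate], expected)


class TestSimulateAcquisition:
    def test_noiseless_end_to_end_recovery(self, protocol):
        # every brain voxel must fit to its oracle-predicted value:
        # true T1 + the pre-computed approximation bias, within one grid step
        spec = default_phantom_spec(subject_sd_ms=0.0)
        truth = build_phantom(spec, "young", seed=12)
        subj = simulate_acquisition(truth, protocol, noise_sigma=0.0,
                                    structural_noise_sigma=0.0, seed=0)
        t1map = fit_volume(subj.flash, protocol, mask=subj.brain_mask)
        for true_val in np.unique(truth.true_t1[truth.brain_mask]):
            expected = true_val + approximation_bias(float(true_val))
            voxels = t1map.t1[(truth.true_t1 == true_val) & truth.brain_mask]
            assert np.abs(voxels - expected).max() <= 1.0 + 1e-9

    def test_seeding_contract(self, protocol):
        truth = build_phantom(default_phantom_spec(), "young", seed=13)
        a = simulate_acquisition(truth, protocol, noise_sigma=0.02, seed=1)
        b = simulate_acquisition(truth, protocol, noise_sigma=0.02, seed=1)
        c = simulate_acquisition(truth, protocol, noise_sigma=0.02, seed=2)
        np.testing.assert_array_equal(a.flash[0], b.flash[0])
        assert not np.array_equal(a.flash[0], c.flash[0])

    def test_rician_converges_to_gaussian_at_high_snr(self, protocol):
        truth = build_phantom(default_phantom_spec(), "young", seed=14)
        gm = truth.tissue_labels == GM
        g = simulate_acquisition(truth, protocol, noise_sigma=0.02,
                                 noise_model="gaussian", seed=3)
        r = simulate_acquisition(truth, protocol, noise_sigma=0.02,
                                 noise_model="rician", seed=3)
        for gv, rv in zip(g.flash, r.flash):
            assert abs(gv[gm].mean() - rv[gm].mean()) / gv[gm].mean() < 0.01

    def test_invalid_b1_scale_rejected(self, protocol):
        truth = build_phantom(default_phantom_spec(), "young", seed=15)
        with pytest.raises(ValueError, match="b1_scale"):
            simulate_acquisition(truth, protocol, b1_scale=0.0)

    def test_structural_contrast_ordering(self, young_subject):
        s = young_subject
        means = [s.structural[s.tissue_labels == k].mean() for k in (1, 2, 3)]
        assert means[0] < means[1] < means[2]


class TestGenerateCohort:
    def test_cohort_sizes(self):
        spec = default_phantom_spec()
        subjects = generate_cohort(spec, n_young=3, n_old=2, seed=16)
        groups = [s.group_label for s in subjects]
        assert groups.count("young") == 3 and groups.count("old") == 2
        assert len({s.subject_id for s in subjects}) == 5

    def test_empty_group_allowed_here_fails_downstream(self):
        subjects = generate_cohort(default_phantom_spec(), n_young=0, n_old=2, seed=17)
        assert all(s.group_label == "old" for s in subjects)

    def test_regeneration_is_bitwise_identical(self):
        spec = default_phantom_spec()
        a = generate_cohort(spec, n_young=1, n_old=1, seed=18)
        b = generate_cohort(spec, n_young=1, n_old=1, seed=18)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.true_t1, sb.true_t1)
            for va, vb in zip(sa.flash, sb.flash):
                np.testing.assert_array_equal(va, vb)


class TestCsfRemovalRationale:
    def test_enlarged_ventricles_bias_only_without_removal(self, protocol):
        # the old group's enlarged ventricles push a partial-volume shell
        # into the ventricle-adjacent caudate; with (dilated) CSF removal
        # the measured mean matches the pure-tissue reference, without it
        # the mean is biased upward
        from t1relax.roi import RoiRecord, measure_roi
        from t1relax.segmentation import remove_csf, segment_three_class

        spec = default_phantom_spec(subject_sd_ms=0.0)
        truth = build_phantom(spec, "old", seed=19)
        subj = simulate_acquisition(truth, protocol, noise_sigma=spec.noise_sigma, seed=20)
        labels = segment_three_class(subj.structural, subj.brain_mask)
        t1map = fit_volume(subj.flash, protocol, mask=subj.brain_mask)
        cleaned = remove_csf(t1map, labels, dilation=1)

        biases = {"with": [], "without": []}
        for roi_id in (3, 4):
            rec = RoiRecord(roi_id, f"caudate{roi_id}", "subcortical", "L", "GM")
            pure = (
                (subj.roi_labels == roi_id)
                & (subj.tissue_labels == GM)
                & ~subj.shell_mask
            )
            reference = t1map.t1[pure].mean()
            m_with = measure_roi(cleaned, subj.roi_labels, labels, rec)
            m_without = measure_roi(t1map, subj.roi_labels, labels, rec)
            biases["with"].append(m_with.mean_t1_ms - reference)
            biases["without"].append(m_without.mean_t1_ms - reference)
        assert abs(np.mean(biases["with"])) < 8.0
        assert np.mean(biases["without"]) > 15.0
        assert np.mean(biases["without"]) > 3 * abs(np.mean(biases["with"]))
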