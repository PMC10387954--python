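"""Grid-search T1 fitter: exactness, oracle equivalence, noise response."""
import numpy as np
import pytest

from oracles import approximation_bias, brute_force_fit, spgr_signal
from t1relax.signal_model import AcquisitionProtocol, TissueState, flash_signal, predicted_signal
from t1relax.t1fit import T1Grid, despot1_fit, fit_volume, fit_voxel

PROT = AcquisitionProtocol()


def full_model_signals(t1, m0=1000.0, t2star=50.0, protocol=PROT):
    return [
        spgr_signal(m0, t1, t2star, protocol.tr_ms, protocol.te_ms, a)
        for a in protocol.flip_angles_deg
    ]


class TestGrid:
    def test_default_spans_one_to_4000_ms(self):
        v = T1Grid().values()
        assert v[0] == 1.0 and v[-1] == 4000.0 and len(v) == 4000
        assert np.all(np.diff(v) == 1.0)

    @pytest.mark.parametrize(
        "kwargs", [{"t1_min_ms": -1.0}, {"t1_min_ms": 4000.0}, {"step_ms": 0.0},
                   {"t1_max_ms": 0.5, "step_ms": 1.0}]
    )
    def test_invalid_grids_rejected(self, kwargs):
        with pytest.raises(ValueError):
            T1Grid(**kwargs)


class TestFitVoxel:
    def test_self_consistent_data_inverts_exactly(self):
        # data generated by the prediction equation itself must fit exactly
        c = 50.0
        intensities = [c] + [
            predicted_signal(c, 3.0, a, PROT.tr_ms, 1000.0)
            for a in PROT.non_reference_angles_deg
        ]
        fit = fit_voxel(intensities, PROT)
        assert fit.t1_ms == 1000.0
        assert fit.residual == pytest.approx(0.0, abs=1e-20)
        assert fit.valid and not fit.boundary

    def test_full_model_fit_matches_brute_force_oracle(self):
        # full-model data carries the small-angle approximation bias; the
        # production fitter must land exactly where the exhaustive search does
        signals = full_model_signals(1200.0)
        expect_t1, expect_sse = brute_force_fit(
            signals, PROT.flip_angles_deg, 3.0, PROT.tr_ms
        )
        fit = fit_voxel(signals, PROT)
        assert fit.t1_ms == expect_t1
        assert fit.residual == pytest.approx(expect_sse, rel=1e-9)
        assert expect_t1 < 1200.0  # bias is an underestimate at these settings

    def test_oracle_equivalence_on_random_voxels(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            t1 = rng.uniform(200.0, 3500.0)
            m0 = rng.uniform(500.0, 2000.0)
            signals = np.array(full_model_signals(t1, m0=m0))
            signals += rng.normal(0.0, 0.02 * signals[0], size=4)
            if signals[0] <= 0:
                continue
            expect_t1, expect_sse = brute_force_fit(
                signals, PROT.flip_angles_deg, 3.0, PROT.tr_ms
            )
            fit = fit_voxel(signals, PROT)
            assert fit.t1_ms == expect_t1
            assert fit.residual == pytest.approx(expect_sse, rel=1e-9, abs=1e-12)

    @pytest.mark.parametrize(
        "intensities",
        [[0.0, 0.0, 0.0, 0.0], [-5.0, 10.0, 20.0, 15.0], [np.nan, 10.0, 20.0, 15.0]],
    )
    def test_background_and_bad_voxels_marked_invalid(self, intensities):
        fit = fit_voxel(intensities, PROT)
        assert not fit.valid
        assert np.isnan(fit.t1_ms)

    def test_true_t1_beyond_grid_saturates_at_boundary(self):
        # self-consistent data (no approximation bias) with T1 above the
        # grid maximum must pin the argmin to the upper grid endpoint
        c = 50.0
        intensities = [c] + [
            predicted_signal(c, 3.0, a, PROT.tr_ms, 6000.0)
            for a in PROT.non_reference_angles_deg
        ]
        fit = fit_voxel(intensities, PROT)
        assert fit.t1_ms == 4000.0
        assert fit.boundary and not fit.valid
        # full-model data additionally carries the (negative) approximation
        # bias, which pulls even a 6000 ms voxel back inside the grid
        assert not fit_voxel(full_model_signals(6000.0), PROT).boundary


class TestFitVolume:
    def test_two_class_phantom_recovers_oracle_values(self):
        shape = (16, 16, 4)
        t1_vol = np.full(shape, 800.0)
        t1_vol[8:] = 1400.0
        tissue = TissueState(m0=1000.0, t1_ms=t1_vol, t2star_ms=50.0)
        images = [
            flash_signal(tissue, PROT.tr_ms, PROT.te_ms, a) for a in PROT.flip_angles_deg
        ]
        t1map = fit_volume(images, PROT)
        for true_val, region in [(800.0, t1map.t1[:8]), (1400.0, t1map.t1[8:])]:
            expected = true_val + approximation_bias(true_val)
            assert np.unique(region) == pytest.approx(expected, abs=1.0)

    def test_empty_mask_gives_empty_valid_mask(self):
        images = [np.full((4, 4, 2), v) for v in (10.0, 15.0, 30.0, 25.0)]
        t1map = fit_volume(images, PROT, mask=np.zeros((4, 4, 2), dtype=bool))
        assert not t1map.valid_mask.any()
        assert np.isnan(t1map.t1).all()

    def test_permuting_images_with_protocol_leaves_result_unchanged(self):
        rng = np.random.default_rng(3)
        images = [rng.uniform(5.0, 50.0, (6, 6, 2)) for _ in PROT.flip_angles_deg]
        base = fit_volume(images, PROT)
        order = [2, 0, 3, 1]
        perm_prot = AcquisitionProtocol(
            flip_angles_deg=tuple(PROT.flip_angles_deg[i] for i in order)
        )
        perm = fit_volume([images[i] for i in order], perm_prot)
        np.testing.assert_array_equal(base.t1, perm.t1)
        np.testing.assert_array_equal(base.valid_mask, perm.valid_mask)

    def test_shape_mismatch_names_offending_image(self):
        images = [np.ones((4, 4, 2))] * 3 + [np.ones((4, 4, 3))]
        with pytest.raises(ValueError, match="image 3"):
            fit_volume(images, PROT)
        with pytest.raises(ValueError, match="angles"):
            fit_volume(images[:3], PROT)

    def test_deterministic(self):
        rng = np.random.default_rng(9)
        images = [rng.uniform(5.0, 50.0, (5, 5, 2)) for _ in PROT.flip_angles_deg]
        a, b = fit_volume(images, PROT), fit_volume(images, PROT)
        np.testing.assert_array_equal(a.t1, b.t1)
        np.testing.assert_array_equal(a.residual, b.residual)


class TestDespot1:
    def test_exact_on_noiseless_data(self):
        prot = AcquisitionProtocol(flip_angles_deg=(5.0, 15.0, 30.0), reference_angle_deg=5.0)
        signals = [
            spgr_signal(1000.0, 1000.0, 50.0, prot.tr_ms, prot.te_ms, a)
            for a in prot.flip_angles_deg
        ]
        assert despot1_fit(signals, prot) == pytest.approx(1000.0, rel=1e-6)

    def test_degenerate_slope_returns_none(self):
        # I = sin(a)/(1-cos(a)) makes I/sin = I/tan + 1 exactly: slope 1,
        # the T1 -> infinity limit, so no estimate is returned
        prot = AcquisitionProtocol(flip_angles_deg=(5.0, 15.0, 30.0), reference_angle_deg=5.0)
        a = np.deg2rad(np.array(prot.flip_angles_deg))
        intensities = np.sin(a) / (1.0 - np.cos(a))
        assert despot1_fit(intensities, prot) is None
        # fewer than 2 positive intensities also yields no estimate
        assert despot1_fit([10.0, 0.0, 0.0], prot) is None

    def test_agrees_with_grid_fit_up_to_documented_bias(self):
        # DESPOT1 is exact on full-model data; the grid fit carries the
        # approximation bias, quantified independently per T1
        for t1 in range(300, 3001, 300):
            signals = full_model_signals(float(t1))
            d1 = despot1_fit(signals, PROT)
            grid_t1 = fit_voxel(signals, PROT).t1_ms
            bias = approximation_bias(float(t1))
            assert d1 == pytest.approx(t1, rel=1e-6)
            assert abs(grid_t1 - d1) <= abs(bias) + 1.0 + 1e-6


class TestNoiseResponse:
    def _fit_errors(self, sigma_frac, rng):
        t1_true = rng.uniform(500.0, 2500.0, 300)
        tissue = TissueState(m0=1000.0, t1_ms=t1_true, t2star_ms=50.0)
        clean = np.stack(
            [flash_signal(tissue, PROT.tr_ms, PROT.te_ms, a) for a in PROT.flip_angles_deg]
        )
        baseline = np.array([fit_voxel(clean[:, i], PROT).t1_ms for i in range(clean.shape[1])])
        noisy = clean + rng.normal(0.0, sigma_frac * clean[0].mean(), clean.shape)
        fitted = np.array([fit_voxel(noisy[:, i], PROT).t1_ms for i in range(clean.shape[1])])
        return np.abs(fitted - baseline) / baseline

    def test_error_grows_with_noise(self):
        rng = np.random.default_rng(12)
        medians = [np.nanmedian(self._fit_errors(s, rng)) for s in (0.0, 0.01, 0.02, 0.05)]
        assert medians[0] == 0.0
        assert all(a <= b for a, b in zip(medians, medians[1:]))

    def test_snr50_noise_error_below_five_percent(self):
        # at SNR 50 (sigma = 2% of the mean reference signal) the median
        # noise-induced error on top of the deterministic bias stays small
        rng = np.random.default_rng(13)
        assert np.nanmedian(self._fit_errors(0.02, rng)) < 0.05
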