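"""HRF, design matrices, AR(1) GLM, and minimum-difference contrasts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from favint import AcquisitionSpec, generate_block_sequence
from favint.containers import ContrastImage
from favint.first_level import (
    build_design_matrix,
    canonical_hrf,
    condition_boxcar,
    contrast_image,
    convolved_regressor,
    dct_highpass_basis,
    fit_glm_ar1,
    integration_contrast,
    min_difference_contrast,
    trim_dummies,
)
from favint.synth import (
    GroundTruth,
    drift_basis,
    make_integration_truth,
    simulate_subject_bold,
    _FWHM_TO_SIGMA,
)


class TestHrf:
    def test_zero_at_origin(self):
        assert canonical_hrf(2.0)[0] == 0.0

    def test_peak_near_gamma_mode(self):
        # mode of the response gamma density (shape 6, scale 1) is 5 s
        h = canonical_hrf(0.01)
        assert abs(np.argmax(h) * 0.01 - 5.0) <= 0.02

    def test_positive_lobe_dominates_undershoot(self):
        assert canonical_hrf(0.1).sum() > 0

    def test_unit_peak(self):
        assert canonical_hrf(0.5).max() == pytest.approx(1.0)

    def test_matches_reference_spm_kernel(self):
        # independent oracle: nilearn's SPM HRF with the same parameters
        nilearn_hrf = pytest.importorskip("nilearn.glm.first_level.hemodynamic_models")
        ref = nilearn_hrf.spm_hrf(2.0, oversampling=50)
        ref = ref / ref.max()
        ours = canonical_hrf(2.0, oversample=50)
        n = min(len(ref), len(ours))
        assert np.corrcoef(ours[:n], ref[:n])[0, 1] > 0.999


class TestDesignMatrix:
    def test_unconvolved_boxcar_mass(self, integration_seq, small_spec):
        # 12 blocks x 8 s / TR 2 s = 48 scan-weights per modality
        for cond in ("A", "V", "AV"):
            box = condition_boxcar(integration_seq, cond, small_spec)
            assert box.sum() == pytest.approx(48.0)

    def test_no_motion_gives_conditions_hp_intercept_only(self, integration_seq, small_spec):
        dm = build_design_matrix(integration_seq, small_spec, motion=None)
        assert set(dm.names) == {"A", "V", "AV", "intercept"} | {
            f"hp_{k}" for k in range(1, len(dm.hp_columns) + 1)
        }

    def test_zero_motion_columns_are_dropped(self, integration_seq, small_spec):
        dm = build_design_matrix(
            integration_seq, small_spec, motion=np.zeros((small_spec.n_scans, 6))
        )
        assert not any(n.startswith("motion") for n in dm.names)

    def test_nonzero_motion_included(self, integration_seq, small_spec):
        motion = np.zeros((small_spec.n_scans, 6))
        motion[:, 2] = np.sin(np.arange(small_spec.n_scans) / 10)
        dm = build_design_matrix(integration_seq, small_spec, motion=motion)
        assert "motion_3" in dm.names

    def test_block_past_scan_window_names_block(self, integration_seq):
        tiny = AcquisitionSpec(tr=2.0, n_scans=10)
        with pytest.raises(ValueError, match="extends past"):
            build_design_matrix(integration_seq, tiny)

    def test_highpass_removes_subcutoff_cosine(self, small_spec):
        # any pure cosine below 1/128 Hz must be annihilated by projection
        n, tr = small_spec.n_scans, small_spec.tr
        hp = dct_highpass_basis(n, tr)
        basis = np.column_stack([hp, np.ones(n)])
        t = np.arange(n) * tr
        for freq in (1 / 300.0, 1 / 250.0, 1 / 200.0):
            drift = np.cos(2 * np.pi * freq * t + 0.7)
            resid = drift - basis @ np.linalg.lstsq(basis, drift, rcond=None)[0]
            assert resid.var() < 0.01 * drift.var()
        # exact annihilation of the basis's own shapes
        k = np.arange(n)
        own = np.cos(np.pi * 2 * (2 * k + 1) / (2 * n))
        resid = own - basis @ np.linalg.lstsq(basis, own, rcond=None)[0]
        assert resid.var() < 1e-20

    def test_simulated_drift_projected_out(self, small_spec, integration_seq):
        # the simulator's drift shapes live inside the high-pass span
        dm = build_design_matrix(integration_seq, small_spec)
        basis = np.column_stack(
            [dm.matrix[:, dm.hp_columns], np.ones(small_spec.n_scans)]
        )
        drift = drift_basis(small_spec.n_scans) @ np.array([1.3, -0.8])
        resid = drift - basis @ np.linalg.lstsq(basis, drift, rcond=None)[0]
        assert resid.var() < 1e-20


class TestGlm:
    def test_rho_zero_equals_plain_ols(self, small_spec, integration_seq, noiseless_truth):
        truth = make_integration_truth(small_spec, "HC", seed=5)
        bold = simulate_subject_bold(small_spec, integration_seq, truth, seed=6)
        dm = build_design_matrix(integration_seq, small_spec)
        fit0 = fit_glm_ar1(bold, dm, rho=0.0)
        y = trim_dummies(bold).data.reshape(-1, small_spec.n_scans).T
        beta_ols = np.linalg.lstsq(dm.matrix, y, rcond=None)[0]
        got = fit0.betas
        expect = beta_ols[:, fit0.mask.ravel()]
        assert np.allclose(got, expect, atol=1e-10)

    def test_noiseless_recovery_to_machine_precision(
        self, small_spec, integration_seq, noiseless_truth
    ):
        from scipy.ndimage import gaussian_filter

        bold = simulate_subject_bold(small_spec, integration_seq, noiseless_truth, seed=1)
        dm = build_design_matrix(integration_seq, small_spec)
        fit = fit_glm_ar1(bold, dm, rho=0.2)
        sigma = [small_spec.smooth_fwhm_mm / _FWHM_TO_SIGMA / v
                 for v in small_spec.voxel_size_mm]
        for cond in ("A", "V", "AV"):
            smoothed = gaussian_filter(noiseless_truth.beta_maps[cond], sigma)
            err = np.abs(fit.beta_map(cond)[fit.mask] - smoothed[fit.mask])
            assert err.max() < 1e-8

    def test_whitened_residuals_are_white_at_matched_rho(self, small_spec, integration_seq):
        truth = make_integration_truth(small_spec, "HC", seed=8)
        bold = simulate_subject_bold(small_spec, integration_seq, truth, seed=9)
        dm = build_design_matrix(integration_seq, small_spec)
        fit = fit_glm_ar1(bold, dm, rho=0.2)
        from favint.first_level import ar1_whitening_matrix

        w = ar1_whitening_matrix(small_spec.n_scans, 0.2)
        y = trim_dummies(bold).data.reshape(-1, small_spec.n_scans).T[:, fit.mask.ravel()]
        resid = w @ y - (w @ dm.matrix) @ fit.betas
        x = resid - resid.mean(axis=0)
        ac1 = (x[1:] * x[:-1]).sum(0) / (x**2).sum(0)
        assert abs(ac1[:500].mean()) < 0.05

    def test_rank_deficient_design_lists_columns(self, small_spec, integration_seq):
        dm = build_design_matrix(integration_seq, small_spec)
        dm.matrix[:, dm.names.index("V")] = dm.matrix[:, dm.names.index("A")]
        truth = make_integration_truth(small_spec, "HC", seed=2)
        bold = simulate_subject_bold(small_spec, integration_seq, truth, seed=3)
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_glm_ar1(bold, dm)


@pytest.fixture(scope="module")
def fit(small_spec, integration_seq, noiseless_truth):
    bold = simulate_subject_bold(small_spec, integration_seq, noiseless_truth, seed=4)
    dm = build_design_matrix(integration_seq, small_spec)
    return fit_glm_ar1(bold, dm)


class TestContrasts:
    def test_unit_weight_returns_beta_map(self, fit):
        av = contrast_image(fit, {"AV": 1.0})
        assert np.allclose(av.values[fit.mask], fit.beta_map("AV")[fit.mask])

    def test_contrast_linearity(self, fit):
        a = contrast_image(fit, {"AV": 1.0, "A": -1.0}).values
        b = contrast_image(fit, {"A": 1.0, "V": -1.0}).values
        c = contrast_image(fit, {"AV": 1.0, "V": -1.0}).values
        assert np.allclose(a[fit.mask] + b[fit.mask], c[fit.mask], atol=1e-12)

    def test_zero_weights_give_zero_map(self, fit):
        z = contrast_image(fit, np.zeros(fit.design.n_regressors))
        assert np.all(z.values[fit.mask] == 0)

    def test_confound_weight_warns(self, fit):
        with pytest.warns(UserWarning, match="confound"):
            contrast_image(fit, {"intercept": 1.0})

    def test_min_identity_on_fitted_betas(self, fit):
        integ = integration_contrast(fit)
        alt = fit.beta_map("AV") - np.maximum(fit.beta_map("A"), fit.beta_map("V"))
        assert np.allclose(integ.values[fit.mask], alt[fit.mask], atol=1e-12)


class TestMinDifference:
    @staticmethod
    def _img(vals, name="d"):
        return ContrastImage(values=np.asarray(vals, float), affine=np.eye(4), name=name)

    def test_simple_minimum(self):
        m = min_difference_contrast(
            [self._img([[[2.0]]]), self._img([[[0.5]]])]
        )
        assert m.values[0, 0, 0] == 0.5
        m2 = min_difference_contrast([self._img([[[-0.3]]]), self._img([[[1.2]]])])
        assert m2.values[0, 0, 0] == -0.3

    def test_grid_mismatch_fails(self):
        with pytest.raises(ValueError, match="grid mismatch"):
            min_difference_contrast(
                [self._img(np.zeros((2, 2, 2))), self._img(np.zeros((3, 2, 2)))]
            )

    def test_brute_force_identity_with_max_criterion(self):
        # min(AV-A, AV-V) == AV - max(A, V) on random beta triplets
        rng = np.random.default_rng(123)
        a, v, av = rng.normal(size=(3, 10_000))
        lhs = np.minimum(av - a, av - v)
        rhs = av - np.maximum(a, v)
        assert np.array_equal(lhs, rhs)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(
        st.lists(st.floats(-1e6, 1e6), min_size=8, max_size=8),
        min_size=2, max_size=4,
    ))
    def test_minimum_bounded_by_every_input(self, rows):
        imgs = [self._img(np.asarray(r).reshape(2, 2, 2)) for r in rows]
        m = min_difference_contrast(imgs).values
        for img in imgs:
            assert np.all(m <= img.values + 1e-12)
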