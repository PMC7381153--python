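"""Seed extraction, hemodynamic deconvolution, and PPI regression."""

import numpy as np
import pytest

from favint import AcquisitionSpec, generate_block_sequence
from favint.first_level import (
    build_design_matrix,
    canonical_hrf,
    condition_boxcar,
    fit_glm_ar1,
    integration_contrast,
    trim_dummies,
)
from favint.ppi import (
    build_ppi_model,
    deconvolve_bold,
    extract_seed_timecourse,
    hrf_convolution_matrix,
    ppi_contrast,
)
from favint.synth import make_integration_truth, n_scans_for, simulate_subject_bold
from favint.topography import PeakCoordinate, find_individual_peak


@pytest.fixture(scope="module")
def seq():
    return generate_block_sequence("integration", seed=60)


@pytest.fixture(scope="module")
def spec(seq):
    return AcquisitionSpec(tr=2.0, n_scans=n_scans_for(seq, 2.0), grid_shape=(8, 8, 8))


@pytest.fixture(scope="module")
def subject(spec, seq):
    truth = make_integration_truth(spec, "SAD", seed=61)
    bold = simulate_subject_bold(spec, seq, truth, seed=62)
    design = build_design_matrix(seq, spec)
    return trim_dummies(bold), design, truth


class TestSeedExtraction:
    def test_2mm_sphere_on_3mm_grid_is_single_voxel(self, subject, spec):
        bold, design, _ = subject
        mm = spec.voxel_to_mm(np.array([4, 4, 4]))
        peak = PeakCoordinate("s", mm, 1.0)
        # count in-sphere voxels directly from the lattice geometry
        ijk = np.stack(np.meshgrid(*[np.arange(8)] * 3, indexing="ij"), -1)
        centers = ijk @ spec.affine[:3, :3].T + spec.affine[:3, 3]
        n_in = (((centers - mm) ** 2).sum(-1) <= 4.0).sum()
        assert n_in == 1
        tc = extract_seed_timecourse(bold, peak, design, radius_mm=2.0)
        assert tc.shape == (spec.n_scans,)

    def test_output_orthogonal_to_nuisance(self, subject, spec):
        bold, design, _ = subject
        peak = PeakCoordinate("s", spec.voxel_to_mm(np.array([3, 3, 3])), 1.0)
        tc = extract_seed_timecourse(bold, peak, design)
        keep = set(design.condition_columns)
        for j, name in enumerate(design.names):
            if name not in keep:
                assert abs(design.matrix[:, j] @ tc) < 1e-8

    def test_empty_sphere_fails(self, subject, spec):
        bold, design, _ = subject
        far = PeakCoordinate("s", np.array([500.0, 500.0, 500.0]), 1.0)
        with pytest.raises(ValueError, match="no in-mask voxels"):
            extract_seed_timecourse(bold, far, design)

    def test_pure_task_voxel_equals_projected_series(self, spec, seq):
        truth = make_integration_truth(spec, "HC", seed=63)
        truth.innovation_sd = 0.0
        truth.drift_amplitude = 0.0
        bold = trim_dummies(simulate_subject_bold(spec, seq, truth, seed=64))
        design = build_design_matrix(seq, spec)
        vox = (4, 4, 4)
        peak = PeakCoordinate("s", spec.voxel_to_mm(np.array(vox)), 1.0)
        tc = extract_seed_timecourse(bold, peak, design)
        raw = bold.data[vox]
        keep = set(design.condition_columns)
        nuis = design.matrix[:, [j for j, n in enumerate(design.names) if n not in keep]]
        expect = raw - nuis @ np.linalg.lstsq(nuis, raw, rcond=None)[0]
        assert np.allclose(tc, expect, atol=1e-10)


class TestDeconvolution:
    def test_zero_series_gives_zero_latent(self):
        z = deconvolve_bold(np.zeros(100), tr=2.0)
        assert np.allclose(z, 0.0)

    def test_roundtrip_on_band_limited_signal(self):
        from scipy.ndimage import gaussian_filter1d

        n, tr = 200, 2.0
        h = hrf_convolution_matrix(n, tr)
        rng = np.random.default_rng(0)
        for _ in range(5):
            latent = gaussian_filter1d(rng.standard_normal(n), 4)
            s = h @ latent
            rec = h @ deconvolve_bold(s, tr=tr)
            assert np.linalg.norm(rec - s) / np.linalg.norm(s) < 0.05

    def test_boxcar_transitions_recovered(self):
        n, tr = 150, 2.0
        h = hrf_convolution_matrix(n, tr)
        box = np.zeros(n)
        box[40:60] = 1.0
        latent = deconvolve_bold(h @ box, tr=tr)
        d = np.diff(latent)
        rise = int(np.argmax(d))
        fall = int(np.argmin(d))
        assert abs(rise - 39) <= 2
        assert abs(fall - 59) <= 2

    def test_latent_interaction_differs_from_bold_level_product(self, spec, seq):
        # the reason deconvolution exists: forming the product at the BOLD
        # level is not equivalent to reconvolving the latent-level product
        rng = np.random.default_rng(1)
        from scipy.ndimage import gaussian_filter1d

        latent = gaussian_filter1d(rng.standard_normal(spec.n_scans), 3)
        h = hrf_convolution_matrix(spec.n_scans, spec.tr)
        psych = condition_boxcar(seq, "AV", spec)
        psych = psych - psych.mean()
        latent_level = h @ (latent * psych)
        bold_level = (h @ latent) * psych
        r = np.corrcoef(latent_level, bold_level)[0, 1]
        assert r < 0.99


class TestPPIModel:
    def test_zero_latent_gives_zero_interactions(self, spec, seq):
        model = build_ppi_model(np.zeros(spec.n_scans), seq, spec)
        for v in model.interaction.values():
            assert np.allclose(v, 0.0)

    def test_constant_latent_proportional_to_convolved_psych(self, spec, seq):
        model = build_ppi_model(np.ones(spec.n_scans), seq, spec)
        h = hrf_convolution_matrix(spec.n_scans, spec.tr)
        for cond, v in model.interaction.items():
            assert np.allclose(v, h @ model.psych[cond], atol=1e-10)

    def test_design_full_rank_on_generic_data(self, spec, seq):
        rng = np.random.default_rng(2)
        from scipy.ndimage import gaussian_filter1d

        latent = gaussian_filter1d(rng.standard_normal(spec.n_scans), 3)
        model = build_ppi_model(latent, seq, spec)
        m = model.design.matrix
        assert np.linalg.matrix_rank(m) == m.shape[1]

    def test_interaction_contrast_obeys_min_max_identity(self, subject, spec, seq):
        bold, design, _ = subject
        rng = np.random.default_rng(3)
        from scipy.ndimage import gaussian_filter1d

        latent = gaussian_filter1d(rng.standard_normal(spec.n_scans), 3)
        model = build_ppi_model(latent, seq, spec, design=design)
        fit = fit_glm_ar1(bold, model.design)
        integ = ppi_contrast(bold, model)
        alt = fit.beta_map("ppi_AV") - np.maximum(
            fit.beta_map("ppi_A"), fit.beta_map("ppi_V")
        )
        assert np.allclose(integ.values[fit.mask], alt[fit.mask], atol=1e-10)


class TestPPIRecovery:
    def _subject_target_value(self, spec, seq, gain, seed):
        target_mm = spec.voxel_to_mm(np.array([1.0, 1.0, 4.0]))
        truth = make_integration_truth(
            spec, "SAD", seed=seed, ppi_gain={"AV": gain}, ppi_target_mm=target_mm
        )
        bold = simulate_subject_bold(spec, seq, truth, seed=seed + 1)
        design = build_design_matrix(seq, spec)
        fit = fit_glm_ar1(bold, design)
        peak = find_individual_peak(
            integration_contrast(fit), np.ones(spec.grid_shape, bool)
        )
        tc = extract_seed_timecourse(trim_dummies(bold), peak, design)
        model = build_ppi_model(deconvolve_bold(tc, tr=spec.tr), seq, spec, design=design)
        pmap = ppi_contrast(bold, model)
        inv = np.linalg.inv(spec.affine)
        ijk = tuple(np.round(inv[:3, :3] @ target_mm + inv[:3, 3]).astype(int))
        return pmap.values[ijk]

    def test_planted_coupling_detected_against_null_group(self, spec, seq):
        # the max-criterion PPI statistic is conservatively (negatively)
        # biased under the null, so the unbiased quantity is the group
        # difference: planted-gain group vs zero-gain group
        n_sub = 12
        planted = np.array([
            self._subject_target_value(spec, seq, 1.0, 1000 + 7 * s)
            for s in range(n_sub)
        ])
        null_a = np.array([
            self._subject_target_value(spec, seq, 0.0, 5000 + 7 * s)
            for s in range(n_sub)
        ])
        null_b = np.array([
            self._subject_target_value(spec, seq, 0.0, 9000 + 7 * s)
            for s in range(n_sub)
        ])
        diff = planted.mean() - null_a.mean()
        se_diff = np.sqrt(planted.var(ddof=1) / n_sub + null_a.var(ddof=1) / n_sub)
        assert diff > 2 * se_diff
        null_diff = null_a.mean() - null_b.mean()
        se_null = np.sqrt(null_a.var(ddof=1) / n_sub + null_b.var(ddof=1) / n_sub)
        assert abs(null_diff) < 2 * se_null
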