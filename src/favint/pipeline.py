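"""End-to-end orchestration: simulate -> fit -> group -> topography -> PPI -> ROI.

``run_pipeline`` executes the whole analysis on a simulated two-group cohort
and writes every output (cohort CSV, events TSVs, contrast and statistic
NIfTIs, cluster/peak tables, YAML reports, JSON manifest) into a run
directory.  All randomness derives from the single config seed, so an
identical config yields byte-identical numeric outputs.
"""

from __future__ import annotations

import time
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io
from .acquisition import AcquisitionSpec, _SITE_SERIES
from .containers import BoldDataset, ContrastImage
from .first_level import (
    build_design_matrix,
    contrast_image,
    fit_glm_ar1,
    integration_contrast,
    sensitivity_contrast,
    trim_dummies,
)
from .group import cluster_fwe, second_level_glm, severity_correlation
from .ppi import build_ppi_model, deconvolve_bold, extract_seed_timecourse, ppi_contrast
from .roi_stats import (
    basis_deconstruction,
    cohort_table_tests,
    extract_roi_means,
    sensitivity_tests,
)
from .synth import (
    generate_block_sequence,
    generate_cohort,
    make_integration_truth,
    make_sensitivity_truth,
    n_scans_for,
    simulate_subject_bold,
)
from .topography import (
    axis_difference_tests,
    coordinate_severity_correlation,
    find_individual_peak,
    group_centroid,
    peaks_to_frame,
)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of one simulated study run.

    Thresholds follow the standard whole-brain convention (voxel p < 0.001,
    cluster-level FWE p < 0.05); the AR coefficient and high-pass cutoff are
    the first-level error-model constants.  ``n_per_group`` and ``n_perm``
    set the problem scale of the demo run.
    """

    seed: int = 0
    n_per_group: int = 12
    site: str = "G"
    gap_s: float = 8.0
    ar_rho: float = 0.2
    hp_cutoff_hz: float = 1.0 / 128.0
    voxel_p: float = 0.001
    cluster_fwe_p: float = 0.05
    n_perm: int = 500
    connectivity: int = 18
    smooth_fwhm_mm: float = 8.0
    # simulator truth
    integration_gain_hc: float = 0.5
    integration_gain_sad: float = 1.0
    peak_jitter_sd_mm: float = 4.0
    blob_fwhm_mm: float = 16.0
    ppi_gain_sad: float = 0.8
    ppi_gain_hc: float = 0.0
    ppi_target_mm: tuple[float, float, float] = (12.0, -54.0, 0.0)
    simulate_sensitivity: bool = True
    write_bold: bool = False
    seed_radius_mm: float = 2.0

    def __post_init__(self) -> None:
        for name in ("voxel_p", "cluster_fwe_p"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.site not in _SITE_SERIES:
            raise ValueError(f"unknown site {self.site!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "ppi_target_mm" in d:
            d["ppi_target_mm"] = tuple(d["ppi_target_mm"])
        return cls(**d)


def _sub_seeds(seed: int, n: int) -> list[int]:
    """Derived stage seeds, all below 2**31."""
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _significant_mask(labels_img, table, alpha) -> Optional[np.ndarray]:
    if labels_img is None or table.empty:
        return None
    sig = table[table["p_fwe"] < alpha]
    if sig.empty:
        return None
    # labels were re-ordered by size; recover via sizes
    mask = np.zeros(labels_img.shape, dtype=bool)
    sizes = np.bincount(labels_img.ravel())
    for _, row in sig.iterrows():
        cand = np.nonzero(sizes == row["size_vx"])[0]
        for lab in cand:
            if lab == 0:
                continue
            mask |= labels_img == lab
    return mask if mask.any() else None


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run the full simulated study; returns a summary dict.

    Stages: cohort simulation, per-subject BOLD simulation and first-level
    GLM (integration experiment, plus voice/face localizers when enabled),
    whole-sample and group-difference second-level inference with
    permutation cluster FWE, topography of individual maxima, PPI
    connectivity, ROI post-hoc statistics, and the cohort-table tests.
    """
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "contrasts").mkdir(exist_ok=True)
    seeds = _sub_seeds(config.seed, 8)
    summary: dict = {"config": config.to_dict(), "seeds": seeds}

    # --- cohort -----------------------------------------------------------
    cohort = generate_cohort(config.n_per_group, seed=seeds[0])
    cohort.to_csv(out / "cohort.csv", index=False)
    demo = cohort_table_tests(cohort)
    io.save_table(demo, out / "demographics_tests.tsv")

    # --- per-subject simulation + first level -----------------------------
    tr = _SITE_SERIES[config.site]["tr"]
    rng_sub = np.random.SeedSequence(seeds[1]).spawn(len(cohort))
    sub_seeds = [int(s.generate_state(1)[0] % 2**31) for s in rng_sub]

    bolds: list[BoldDataset] = []
    seqs, designs = [], []
    integ_maps, av_a_maps, av_v_maps = [], [], []
    spec = None
    for i, row in cohort.iterrows():
        seq = generate_block_sequence("integration", gap=config.gap_s, seed=sub_seeds[i])
        if spec is None:
            spec = AcquisitionSpec(
                tr=tr,
                n_scans=n_scans_for(seq, tr),
                smooth_fwhm_mm=config.smooth_fwhm_mm,
            )
        truth = make_integration_truth(
            spec,
            group=row["group"],
            seed=sub_seeds[i] + 1,
            group_gains={
                "HC": config.integration_gain_hc,
                "SAD": config.integration_gain_sad,
            },
            peak_jitter_sd_mm=config.peak_jitter_sd_mm,
            blob_fwhm_mm=config.blob_fwhm_mm,
            ar_rho=config.ar_rho,
            ppi_gain={
                "AV": config.ppi_gain_sad if row["group"] == "SAD" else config.ppi_gain_hc
            },
            ppi_target_mm=np.asarray(config.ppi_target_mm),
        )
        bold = simulate_subject_bold(
            spec, seq, truth, seed=sub_seeds[i] + 2, subject_id=row["subject_id"]
        )
        io.save_events(seq.to_events(), out / f"{row['subject_id']}_events.tsv")
        if config.write_bold:
            io.save_bold(bold, out / f"{row['subject_id']}_bold.nii.gz",
                         out / f"{row['subject_id']}_motion.txt")
        design = build_design_matrix(seq, spec, motion=None, hp_cutoff_hz=config.hp_cutoff_hz)
        fit = fit_glm_ar1(bold, design, rho=config.ar_rho)
        integ = integration_contrast(fit)
        integ_maps.append(integ)
        av_a_maps.append(contrast_image(fit, {"AV": 1.0, "A": -1.0}, name="AV-A"))
        av_v_maps.append(contrast_image(fit, {"AV": 1.0, "V": -1.0}, name="AV-V"))
        io.save_contrast(integ, out / "contrasts" / f"{row['subject_id']}_integration.nii.gz",
                         dof=fit.dof)
        bolds.append(trim_dummies(bold))
        seqs.append(seq)
        designs.append(design)
    summary["n_scans"] = spec.n_scans

    # --- second level -----------------------------------------------------
    covars = cohort[["age", "gender", "site"]]
    groups = list(cohort["group"])
    fit_all = second_level_glm(integ_maps, covariates=covars,
                               contrast_name="integration mean")
    table_all, labels_all = cluster_fwe(
        fit_all, voxel_p=config.voxel_p, n_perm=config.n_perm,
        seed=seeds[2], connectivity=config.connectivity, return_labels=True,
    )
    io.save_table(table_all, out / "clusters_whole_sample.tsv")
    fit_diff = second_level_glm(integ_maps, groups=groups, covariates=covars,
                                contrast_name="integration SAD-HC")
    table_diff, labels_diff = cluster_fwe(
        fit_diff, voxel_p=config.voxel_p, n_perm=config.n_perm,
        seed=seeds[3], connectivity=config.connectivity, return_labels=True,
    )
    io.save_table(table_diff, out / "clusters_sad_vs_hc.tsv")
    io.save_contrast(
        ContrastImage(values=fit_all.statmap.t_values, affine=spec.affine,
                      name="t integration mean", subject_id="group"),
        out / "tmap_whole_sample.nii.gz", sidecar=False)
    io.save_contrast(
        ContrastImage(values=fit_diff.statmap.t_values, affine=spec.affine,
                      name="t integration SAD-HC", subject_id="group"),
        out / "tmap_sad_vs_hc.nii.gz", sidecar=False)
    summary["n_sig_clusters_whole_sample"] = int((table_all["p_fwe"] < config.cluster_fwe_p).sum()) if not table_all.empty else 0
    summary["n_sig_clusters_sad_vs_hc"] = int((table_diff["p_fwe"] < config.cluster_fwe_p).sum()) if not table_diff.empty else 0

    from .group import _threshold_t

    # arm-2 search region: the whole-sample integration cluster(s)
    roi_mask = _significant_mask(labels_all, table_all, config.cluster_fwe_p)
    if roi_mask is None:
        # fall back to the suprathreshold voxels of the whole-sample map
        roi_mask = _threshold_t(fit_all.statmap.t_values, fit_all.statmap.dof,
                                config.voxel_p, "greater")
    io.save_mask(roi_mask, spec.affine, out / "integration_roi.nii.gz")

    # PPI seed region and post-hoc ROI: the cluster(s) where the groups
    # differ in the integration effect
    diff_mask = _significant_mask(labels_diff, table_diff, config.cluster_fwe_p)
    if diff_mask is None:
        diff_mask = _threshold_t(fit_diff.statmap.t_values, fit_diff.statmap.dof,
                                 config.voxel_p, "greater")
    if not diff_mask.any():
        diff_mask = roi_mask
    io.save_mask(diff_mask, spec.affine, out / "sad_vs_hc_roi.nii.gz")

    # --- topography -------------------------------------------------------
    peaks = [find_individual_peak(m, roi_mask, mask_name="integration_roi")
             for m in integ_maps]
    io.save_table(peaks_to_frame(peaks), out / "peaks.tsv")
    is_sad = cohort["group"].to_numpy() == "SAD"
    p_sad = [p for p, s in zip(peaks, is_sad) if s]
    p_hc = [p for p, s in zip(peaks, is_sad) if not s]
    axis_tests = axis_difference_tests(p_sad, p_hc, n_hemispheres=1)
    io.save_table(axis_tests, out / "topography_axis_tests.tsv")
    r_y, p_y = coordinate_severity_correlation(peaks, cohort["lsas"], axis="y")
    topo_report = {
        "centroid_sad": [float(v) for v in group_centroid(p_sad)],
        "centroid_hc": [float(v) for v in group_centroid(p_hc)],
        "lsas_y_correlation": {"r": r_y, "p": p_y},
    }
    io.save_yaml(topo_report, out / "topography.yaml")
    summary["topography"] = topo_report

    # --- PPI --------------------------------------------------------------
    ppi_maps = []
    for bold, seq, design, integ in zip(bolds, seqs, designs, integ_maps):
        peak = find_individual_peak(integ, diff_mask, mask_name="seed")
        seed_tc = extract_seed_timecourse(bold, peak, design,
                                          radius_mm=config.seed_radius_mm)
        latent = deconvolve_bold(seed_tc, tr=spec.tr)
        model = build_ppi_model(latent, seq, spec, design=design)
        ppi_maps.append(ppi_contrast(bold, model, rho=config.ar_rho))
    fit_ppi = second_level_glm(ppi_maps, groups=groups, covariates=covars,
                               contrast_name="ppi integration SAD-HC")
    table_ppi = cluster_fwe(
        fit_ppi, voxel_p=config.voxel_p, n_perm=config.n_perm,
        seed=seeds[4], connectivity=config.connectivity,
    )
    io.save_table(table_ppi, out / "clusters_ppi_sad_vs_hc.tsv")
    summary["n_sig_clusters_ppi"] = int((table_ppi["p_fwe"] < config.cluster_fwe_p).sum()) if not table_ppi.empty else 0

    # --- ROI post-hoc stats ----------------------------------------------
    integ_vals = [extract_roi_means(m, diff_mask) for m in integ_maps]
    ava_vals = [extract_roi_means(m, diff_mask) for m in av_a_maps]
    avv_vals = [extract_roi_means(m, diff_mask) for m in av_v_maps]
    deconstruct = basis_deconstruction(ava_vals, avv_vals, groups)
    r_sev, p_sev = severity_correlation(integ_vals, cohort["lsas"])
    roi_report = {
        "integration": sensitivity_tests(integ_vals, groups),
        "basis_min_is_av_a": {
            g: list(v) for g, v in deconstruct["min_is_av_a_counts"].items()
        },
        "av_a_group_t": deconstruct.get("av_a_group_t"),
        "av_v_group_t": deconstruct.get("av_v_group_t"),
        "lsas_correlation": {"r": r_sev, "p": p_sev},
    }
    roi_df = pd.DataFrame(
        {"subject_id": cohort["subject_id"], "group": groups,
         "integration": integ_vals, "av_a": ava_vals, "av_v": avv_vals}
    )

    if config.simulate_sensitivity:
        for exp, preferred, others, key in (
            ("voice", "V", ("A", "E"), "voice_sensitivity"),
            ("face", "F", ("H", "O", "S"), "face_sensitivity"),
        ):
            vals = []
            for i, row in cohort.iterrows():
                seq_s = generate_block_sequence(exp, seed=sub_seeds[i] + 10)
                spec_s = AcquisitionSpec(
                    tr=tr, n_scans=n_scans_for(seq_s, tr),
                    smooth_fwhm_mm=config.smooth_fwhm_mm)
                truth_s = make_sensitivity_truth(
                    spec_s, exp, seed=sub_seeds[i] + 11, ar_rho=config.ar_rho)
                bold_s = simulate_subject_bold(
                    spec_s, seq_s, truth_s, seed=sub_seeds[i] + 12,
                    subject_id=row["subject_id"])
                design_s = build_design_matrix(seq_s, spec_s,
                                               hp_cutoff_hz=config.hp_cutoff_hz)
                fit_s = fit_glm_ar1(bold_s, design_s, rho=config.ar_rho)
                cmap = sensitivity_contrast(fit_s, preferred, others)
                vals.append(extract_roi_means(cmap, diff_mask))
            roi_report[key] = sensitivity_tests(vals, groups)
            roi_df[key] = vals

    io.save_table(roi_df, out / "roi_subject_values.tsv")
    io.save_yaml(roi_report, out / "roi_report.yaml")
    summary["roi"] = roi_report

    # --- manifest ---------------------------------------------------------
    import favint

    io.save_manifest(
        out / "manifest.json",
        config=config.to_dict(),
        seeds=seeds,
        favint_version=favint.__version__,
        numpy_version=np.__version__,
        elapsed_s=round(time.time() - t0, 2),
    )
    summary["elapsed_s"] = time.time() - t0
    return summary
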