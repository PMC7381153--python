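"""Psychophysiological interaction (PPI) analysis.

The PPI asks whether the coupling between a seed region and the rest of the
brain changes with the experimental condition.  Because BOLD is a convolved
measurement, the interaction must be formed at the latent ("neural") level:
the seed time course is extracted from a small sphere around the subject's
peak voxel (adjusted for effects of interest), deconvolved against the HRF
on a regularized discrete-cosine basis, multiplied with the centred
condition indicator, and reconvolved.  The physiological, psychological and
interaction terms enter a voxelwise GLM; the integration PPI statistic is
the voxelwise minimum of the interaction differences (AV-A, AV-V), the
connectivity analogue of AV - max(A, V).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import toeplitz

from .acquisition import AcquisitionSpec
from .containers import BoldDataset, ContrastImage
from .first_level import (
    DesignMatrix,
    canonical_hrf,
    condition_boxcar,
    contrast_image,
    fit_glm_ar1,
    min_difference_contrast,
    trim_dummies,
)
from .synth import BlockSequence
from .topography import PeakCoordinate

__all__ = [
    "PPIModel",
    "hrf_convolution_matrix",
    "extract_seed_timecourse",
    "deconvolve_bold",
    "build_ppi_model",
    "ppi_contrast",
]


def hrf_convolution_matrix(n_scans: int, tr: float, **hrf_kwargs) -> np.ndarray:
    """Lower-triangular Toeplitz operator for HRF convolution at the scan grid.

    ``H @ z`` equals the causal convolution of a latent series ``z`` with
    the unit-peak canonical HRF sampled at ``tr`` (scaled by ``tr`` so it
    matches integrating a continuous-time convolution).
    """
    hrf = canonical_hrf(tr, **hrf_kwargs) * tr
    col = np.zeros(n_scans)
    k = min(len(hrf), n_scans)
    col[:k] = hrf[:k]
    return toeplitz(col, np.zeros(n_scans))


def extract_seed_timecourse(
    bold: BoldDataset,
    peak: PeakCoordinate,
    design: DesignMatrix,
    radius_mm: float = 2.0,
    keep: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """Mean seed series from a sphere around the peak, nuisance-adjusted.

    Voxels whose centres lie within ``radius_mm`` of the peak coordinate are
    averaged (on a 3 mm grid the default 2 mm sphere holds exactly the peak
    voxel).  Design columns *outside* the effects-of-interest set ``keep``
    (default: the condition regressors) - i.e. motion, the high-pass basis
    and the intercept - are regressed out.
    """
    bold = trim_dummies(bold)
    if bold.n_volumes != design.n_scans:
        raise ValueError("BOLD length does not match the design")
    shape = bold.data.shape[:3]
    ijk = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), -1)
    mm = ijk @ bold.affine[:3, :3].T + bold.affine[:3, 3]
    dist2 = ((mm - peak.mni_mm) ** 2).sum(-1)
    in_sphere = (dist2 <= radius_mm**2) & bold.mask
    if not in_sphere.any():
        raise ValueError(
            f"sphere of radius {radius_mm} mm around {peak.mni_mm} contains "
            "no in-mask voxels"
        )
    series = bold.data[in_sphere].mean(axis=0)

    keep = tuple(design.condition_columns) if keep is None else tuple(keep)
    nuisance_idx = [j for j, name in enumerate(design.names) if name not in keep]
    if nuisance_idx:
        z = design.matrix[:, nuisance_idx]
        series = series - z @ np.linalg.lstsq(z, series, rcond=None)[0]
    return series


def deconvolve_bold(
    series: np.ndarray,
    n_scans: Optional[int] = None,
    tr: float = 2.0,
    ridge: float = 1e-4,
    hrf_matrix: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Regularized inversion of the HRF convolution operator.

    The latent series is parameterized on the full orthonormal
    discrete-cosine basis ``B``; coefficients solve the ridge problem
    ``min ||H B c - s||^2 + alpha ||c||^2`` with ``alpha = ridge *
    trace(G'G) / n`` (``G = H B``), a flat-prior stand-in for the classical
    empirical-Bayes deconvolution.  The default penalty is small enough that
    reconvolution reproduces smooth band-limited inputs to within a few
    percent while still suppressing the amplification of high-frequency
    noise by the near-singular HRF operator.
    """
    series = np.asarray(series, dtype=float)
    if not np.all(np.isfinite(series)):
        raise ValueError("series contains non-finite values")
    n = len(series) if n_scans is None else n_scans
    h = hrf_convolution_matrix(n, tr) if hrf_matrix is None else hrf_matrix
    # orthonormal DCT-II basis, constant term included
    k = np.arange(n)
    basis = np.cos(np.pi * np.outer(2 * k + 1, np.arange(n)) / (2 * n))
    basis[:, 0] *= np.sqrt(1.0 / n)
    basis[:, 1:] *= np.sqrt(2.0 / n)
    g = h @ basis
    gtg = g.T @ g
    alpha = ridge * np.trace(gtg) / n
    coef = np.linalg.solve(gtg + alpha * np.eye(n), g.T @ series)
    return basis @ coef


@dataclass
class PPIModel:
    """Assembled PPI design for one subject.

    ``physio`` is the reconvolved latent seed series; ``psych`` maps each
    condition to its centred scan-grid indicator; ``interaction`` maps each
    condition to ``convolve(latent * psych_c)``.  ``design`` is the full
    matrix (physio + condition regressors + interactions + intercept).
    """

    physio: np.ndarray
    psych: dict[str, np.ndarray]
    interaction: dict[str, np.ndarray]
    design: DesignMatrix

    def __post_init__(self) -> None:
        n = len(self.physio)
        for d in (self.psych, self.interaction):
            for name, v in d.items():
                if len(v) != n:
                    raise ValueError(f"regressor {name!r} length {len(v)} != {n}")

    def interaction_name(self, condition: str) -> str:
        return f"ppi_{condition}"


def build_ppi_model(
    latent: np.ndarray,
    seq: BlockSequence,
    spec: AcquisitionSpec,
    design: Optional[DesignMatrix] = None,
    rank_check: bool = True,
) -> PPIModel:
    """Form the PPI regressors at the latent level and assemble the design.

    For each condition ``c`` the psychological vector is the scan-grid
    boxcar centred over the scan window; the interaction regressor is the
    reconvolution ``H @ (latent * psych_c)``.  The physiological regressor
    is the reconvolved latent series.  Condition, high-pass and intercept
    columns of ``design`` (the subject's first-level design, built if
    omitted) are carried over so task-evoked and drift variance is modelled
    alongside the interaction terms.
    """
    latent = np.asarray(latent, dtype=float)
    if len(latent) != spec.n_scans:
        raise ValueError(f"latent length {len(latent)} != n_scans {spec.n_scans}")
    if design is None:
        from .first_level import build_design_matrix

        design = build_design_matrix(seq, spec)
    h = hrf_convolution_matrix(spec.n_scans, spec.tr)
    physio = h @ latent
    psych, interaction = {}, {}
    for cond in seq.conditions:
        box = condition_boxcar(seq, cond, spec)
        box = box - box.mean()
        psych[cond] = box
        interaction[cond] = h @ (latent * box)

    cols = [physio]
    names = ["physio"]
    condition_columns = {}
    for cond in seq.conditions:
        condition_columns[cond] = len(cols)
        cols.append(design.column(cond))
        names.append(cond)
    inter_idx = {}
    for cond in seq.conditions:
        inter_idx[cond] = len(cols)
        cols.append(interaction[cond])
        names.append(f"ppi_{cond}")
    confound = []
    for j in design.hp_columns:
        confound.append(len(cols))
        cols.append(design.matrix[:, j])
        names.append(design.names[j])
    confound.append(len(cols))
    cols.append(np.ones(spec.n_scans))
    names.append("intercept")
    matrix = np.column_stack(cols)
    if rank_check and np.any(latent != 0):
        rank = np.linalg.matrix_rank(matrix)
        if rank < matrix.shape[1]:
            raise ValueError(
                f"PPI design is rank deficient (rank {rank} < {matrix.shape[1]}): "
                "interaction regressors are collinear with physio/psych terms"
            )
    ppi_design = DesignMatrix(
        matrix=matrix,
        names=names,
        condition_columns={f"ppi_{c}": i for c, i in inter_idx.items()},
        confound_columns=confound,
        hp_columns=[],
    )
    return PPIModel(physio=physio, psych=psych, interaction=interaction, design=ppi_design)


def ppi_contrast(
    bold: BoldDataset,
    model: PPIModel,
    bimodal: str = "AV",
    unimodal: tuple[str, str] = ("A", "V"),
    rho: float = 0.2,
) -> ContrastImage:
    """Fit the PPI GLM and return the integration interaction statistic.

    Uses the same AR(1)-prewhitened machinery as the first level, then forms
    the voxelwise minimum of the interaction differences
    ``ppi_AV - ppi_A`` and ``ppi_AV - ppi_V`` - positive where coupling
    with the seed increases specifically under audiovisual stimulation.
    """
    fit = fit_glm_ar1(bold, model.design, rho=rho)
    diffs = [
        contrast_image(
            fit,
            {f"ppi_{bimodal}": 1.0, f"ppi_{u}": -1.0},
            name=f"ppi_{bimodal}-ppi_{u}",
        )
        for u in unimodal
    ]
    return min_difference_contrast(
        diffs, name=f"ppi:{bimodal}-max({','.join(unimodal)})"
    )
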