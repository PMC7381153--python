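"""Per-subject GLM: HRF, design matrices, AR(1) prewhitening, contrasts.

The model is the standard block-design GLM: each condition is a boxcar over
its blocks convolved with the canonical double-gamma HRF; six realignment
parameters, a discrete-cosine high-pass basis (cutoff 1/128 Hz) and an
intercept complete the design.  The error term is a fixed first-order
autoregressive process (coefficient 0.2 by default, the additional white
component being absorbed into the innovation variance), handled by
prewhitening data and design before ordinary least squares.

The multisensory integration statistic is the minimum-difference contrast
``min(AV - A, AV - V)``, algebraically identical to ``AV - max(A, V)``; the
same operation serves voice-sensitivity ``min(V - A, V - E)`` and
face-sensitivity ``min(F - H, F - O, F - S)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.stats import gamma as gamma_dist

from .acquisition import AcquisitionSpec
from .containers import BoldDataset, ContrastImage
from .synth import BlockSequence

__all__ = [
    "DesignMatrix",
    "GlmFit",
    "BoldDataset",
    "ContrastImage",
    "canonical_hrf",
    "condition_boxcar",
    "convolved_regressor",
    "build_design_matrix",
    "dct_highpass_basis",
    "trim_dummies",
    "ar1_whitening_matrix",
    "fit_glm_ar1",
    "contrast_image",
    "min_difference_contrast",
    "integration_contrast",
    "sensitivity_contrast",
]


def canonical_hrf(
    tr: float,
    duration: float = 32.0,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_dispersion: float = 1.0,
    undershoot_dispersion: float = 1.0,
    undershoot_ratio: float = 1.0 / 6.0,
    oversample: int = 1,
) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, sampled at ``tr``.

    Difference of two gamma densities (response peaking near 5 s, undershoot
    near 15 s, weighted 1:1/6), sampled on ``[0, duration)`` at ``tr /
    oversample`` and scaled to unit peak.  This is the de-facto standard
    kernel of block-design fMRI analysis; all parameters are in seconds.
    """
    if tr <= 0:
        raise ValueError(f"tr must be positive, got {tr}")
    dt = tr / oversample
    t = np.arange(0, duration, dt)
    h = gamma_dist.pdf(t, peak_delay / peak_dispersion, scale=peak_dispersion)
    h = h - undershoot_ratio * gamma_dist.pdf(
        t, undershoot_delay / undershoot_dispersion, scale=undershoot_dispersion
    )
    peak = h.max()
    if peak > 0:
        h = h / peak
    return h


def condition_boxcar(seq: BlockSequence, condition: str, spec: AcquisitionSpec) -> np.ndarray:
    """Scan-resolution boxcar: fractional block coverage of each TR bin.

    Entry ``i`` is the fraction of ``[i*tr, (i+1)*tr)`` occupied by blocks of
    ``condition``; for blocks aligned to the TR grid the column sums to
    total stimulation time / TR.
    """
    n, tr = spec.n_scans, spec.tr
    box = np.zeros(n)
    for label, onset, dur in seq.blocks:
        if label != condition:
            continue
        if onset + dur > n * tr + 1e-9:
            raise ValueError(
                f"block ({label!r}, onset={onset}, duration={dur}) extends past "
                f"the scan window of {n * tr} s"
            )
        lo, hi = onset / tr, (onset + dur) / tr
        i0, i1 = int(np.floor(lo)), int(np.ceil(hi))
        for i in range(max(i0, 0), min(i1, n)):
            box[i] += max(0.0, min(hi, i + 1) - max(lo, i))
    return box


def convolved_regressor(
    seq: BlockSequence,
    condition: str,
    spec: AcquisitionSpec,
    oversample: int = 16,
    **hrf_kwargs,
) -> np.ndarray:
    """Boxcar (x) HRF regressor sampled at scan times.

    The boxcar is built on a fine grid (``tr / oversample``), convolved with
    the unit-peak HRF sampled on the same grid, and read out at scan onsets.
    """
    n, tr = spec.n_scans, spec.tr
    dt = tr / oversample
    n_fine = n * oversample
    fine = np.zeros(n_fine)
    t_fine = np.arange(n_fine) * dt
    for label, onset, dur in seq.blocks:
        if label != condition:
            continue
        if onset + dur > n * tr + 1e-9:
            raise ValueError(
                f"block ({label!r}, onset={onset}, duration={dur}) extends past "
                f"the scan window of {n * tr} s"
            )
        fine[(t_fine >= onset - 1e-9) & (t_fine < onset + dur - 1e-9)] = 1.0
    hrf = canonical_hrf(tr, oversample=oversample, **hrf_kwargs)
    conv = np.convolve(fine, hrf)[:n_fine] * dt
    return conv[::oversample]


def dct_highpass_basis(n_scans: int, tr: float, cutoff_hz: float = 1.0 / 128.0) -> np.ndarray:
    """Discrete-cosine columns spanning all frequencies below ``cutoff_hz``.

    Column ``k`` has frequency ``k / (2 * n_scans * tr)``; orders run from 1
    up to ``floor(2 * n_scans * tr * cutoff_hz)``.  Unit-norm columns; the
    constant term is left to the design intercept.
    """
    n_orders = int(np.floor(2 * n_scans * tr * cutoff_hz))
    n = np.arange(n_scans)
    cols = [
        np.sqrt(2.0 / n_scans) * np.cos(np.pi * k * (2 * n + 1) / (2 * n_scans))
        for k in range(1, n_orders + 1)
    ]
    if not cols:
        return np.zeros((n_scans, 0))
    return np.stack(cols, axis=-1)


@dataclass
class DesignMatrix:
    """Scans-by-regressors design with named, typed column groups."""

    matrix: np.ndarray
    names: list[str]
    condition_columns: dict[str, int]
    confound_columns: list[int]
    hp_columns: list[int]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("design matrix must be 2D")
        if len(self.names) != self.matrix.shape[1]:
            raise ValueError("one name per design column required")
        if len(set(self.names)) != len(self.names):
            raise ValueError("design column names must be unique")
        overlap = set(self.condition_columns.values()) & set(self.confound_columns)
        if overlap:
            raise ValueError(f"condition and confound column sets overlap: {overlap}")

    @property
    def n_scans(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_regressors(self) -> int:
        return self.matrix.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    def weights(self, mapping: dict[str, float]) -> np.ndarray:
        """Contrast weight vector from a {column name: weight} mapping."""
        w = np.zeros(self.n_regressors)
        for name, value in mapping.items():
            w[self.names.index(name)] = value
        return w


def build_design_matrix(
    seq: BlockSequence,
    spec: AcquisitionSpec,
    motion: Optional[np.ndarray] = None,
    hp_cutoff_hz: float = 1.0 / 128.0,
    oversample: int = 16,
    **hrf_kwargs,
) -> DesignMatrix:
    """Assemble the first-level design: conditions, motion, high-pass, intercept.

    Motion columns with zero variance (e.g. the all-zero default tables of
    simulated still subjects) are dropped, since they would make the design
    rank deficient.  A block extending past ``n_scans * tr`` raises, naming
    the block.
    """
    cols, names = [], []
    condition_columns = {}
    for cond in seq.conditions:
        condition_columns[cond] = len(cols)
        cols.append(convolved_regressor(seq, cond, spec, oversample=oversample, **hrf_kwargs))
        names.append(cond)
    confound_columns: list[int] = []
    if motion is not None:
        motion = np.atleast_2d(np.asarray(motion, dtype=float))
        if motion.size and motion.shape[0] != spec.n_scans:
            raise ValueError(
                f"motion table has {motion.shape[0]} rows, expected {spec.n_scans}"
            )
        for j in range(motion.shape[1] if motion.size else 0):
            if np.ptp(motion[:, j]) == 0:
                continue
            confound_columns.append(len(cols))
            cols.append(motion[:, j])
            names.append(f"motion_{j + 1}")
    hp = dct_highpass_basis(spec.n_scans, spec.tr, hp_cutoff_hz)
    hp_columns = list(range(len(cols), len(cols) + hp.shape[1]))
    for k in range(hp.shape[1]):
        cols.append(hp[:, k])
        names.append(f"hp_{k + 1}")
    confound_columns.append(len(cols))
    cols.append(np.ones(spec.n_scans))
    names.append("intercept")
    return DesignMatrix(
        matrix=np.column_stack(cols),
        names=names,
        condition_columns=condition_columns,
        confound_columns=confound_columns,
        hp_columns=hp_columns,
    )


def trim_dummies(bold: BoldDataset) -> BoldDataset:
    """Drop the leading pre-equilibrium volumes (and motion rows).

    Block onsets are referenced to the first retained scan throughout, so no
    timing shift is needed.  A dataset already at ``n_scans`` volumes is
    returned unchanged.
    """
    nd = bold.spec.n_dummy
    if bold.n_volumes == bold.spec.n_scans or nd == 0:
        return bold
    if bold.n_volumes != bold.spec.n_total:
        raise ValueError(
            f"cannot trim: {bold.n_volumes} volumes, expected "
            f"{bold.spec.n_total} (with dummies) or {bold.spec.n_scans}"
        )
    return BoldDataset(
        data=bold.data[..., nd:],
        spec=bold.spec,
        mask=bold.mask,
        motion=None if bold.motion is None else bold.motion[nd:],
        subject_id=bold.subject_id,
    )


def ar1_whitening_matrix(n: int, rho: float) -> np.ndarray:
    """Whitening transform for AR(1) errors with coefficient ``rho``.

    Rows implement ``y_t - rho * y_{t-1}`` with the first row scaled by
    ``sqrt(1 - rho^2)``, so ``W e`` is white when ``e`` is stationary AR(1).
    """
    if not -1 < rho < 1:
        raise ValueError(f"AR coefficient must lie in (-1, 1), got {rho}")
    w = np.eye(n)
    w[0, 0] = np.sqrt(1.0 - rho**2)
    idx = np.arange(1, n)
    w[idx, idx - 1] = -rho
    return w


@dataclass
class GlmFit:
    """Voxelwise GLM estimates on the in-mask voxels.

    ``betas`` is (n_regressors, n_voxels_in_mask); maps are reconstructed on
    the full grid with NaN outside the mask.
    """

    betas: np.ndarray
    sigma2: np.ndarray
    dof: int
    whitening_rho: float
    design: DesignMatrix
    mask: np.ndarray
    affine: np.ndarray
    subject_id: str = "sub-00"

    def beta_map(self, name: str) -> np.ndarray:
        out = np.full(self.mask.shape, np.nan)
        out[self.mask] = self.betas[self.design.names.index(name)]
        return out


def _collinear_columns(x: np.ndarray, names: Sequence[str]) -> list[str]:
    r = np.linalg.qr(x, mode="r")
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps
    return [names[j] for j in np.nonzero(diag <= tol)[0]]


def fit_glm_ar1(
    bold: BoldDataset,
    design: DesignMatrix,
    rho: float = 0.2,
    variance_threshold: float = 1e-12,
) -> GlmFit:
    """Prewhitened ordinary least squares with a fixed AR(1) coefficient.

    Data and design are premultiplied by the AR(1) whitening transform for
    ``rho`` (``rho = 0`` reduces to plain OLS), then solved per voxel.
    Voxels with near-zero temporal variance are excluded from the fit
    (NaN in output maps).  Residual variance uses ``dof = n_scans -
    rank(design)``.
    """
    bold = trim_dummies(bold)
    n = design.n_scans
    if bold.n_volumes != n:
        raise ValueError(
            f"BOLD has {bold.n_volumes} volumes but the design has {n} rows"
        )
    if not np.all(np.isfinite(bold.data)):
        raise ValueError("BOLD data contain non-finite values")
    y = bold.data.reshape(-1, n).T  # scans x voxels
    mask = bold.mask.ravel() & (y.var(axis=0) > variance_threshold)
    y = y[:, mask]

    w = ar1_whitening_matrix(n, rho)
    xw = w @ design.matrix
    rank = np.linalg.matrix_rank(xw)
    if rank < design.n_regressors:
        bad = _collinear_columns(xw, design.names)
        raise ValueError(f"rank-deficient design (rank {rank} < {design.n_regressors}); "
                         f"suspect columns: {bad}")
    yw = w @ y
    betas, _, _, _ = np.linalg.lstsq(xw, yw, rcond=None)
    resid = yw - xw @ betas
    dof = int(n - rank)
    sigma2 = (resid**2).sum(axis=0) / dof
    return GlmFit(
        betas=betas,
        sigma2=sigma2,
        dof=dof,
        whitening_rho=rho,
        design=design,
        mask=mask.reshape(bold.mask.shape),
        affine=bold.affine,
        subject_id=bold.subject_id,
    )


def contrast_image(fit: GlmFit, weights, name: Optional[str] = None) -> ContrastImage:
    """Voxelwise contrast estimate ``w' beta`` as a 3D map.

    ``weights`` is either a vector over all regressors or a
    {column name: weight} mapping.  Nonzero weight on confound columns is
    allowed but flagged with a warning.
    """
    if isinstance(weights, dict):
        label = name or "+".join(f"{v:+g}*{k}" for k, v in weights.items())
        weights = fit.design.weights(weights)
    else:
        label = name or "contrast"
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (fit.design.n_regressors,):
        raise ValueError(
            f"weight vector has shape {weights.shape}, expected "
            f"({fit.design.n_regressors},)"
        )
    flagged = [
        fit.design.names[j]
        for j in fit.design.confound_columns + fit.design.hp_columns
        if weights[j] != 0
    ]
    if flagged:
        warnings.warn(f"nonzero contrast weight on confound columns: {flagged}")
    vals = np.full(fit.mask.shape, np.nan)
    vals[fit.mask] = weights @ fit.betas
    return ContrastImage(values=vals, affine=fit.affine, name=label, subject_id=fit.subject_id)


def min_difference_contrast(
    differences: Sequence[ContrastImage], name: Optional[str] = None
) -> ContrastImage:
    """Voxelwise minimum across difference maps - the integration statistic.

    ``min(AV-A, AV-V)`` requires the bimodal response to exceed the larger
    unimodal response (the max criterion); the same minimum over other
    difference sets yields voice- and face-sensitivity.
    """
    if len(differences) < 2:
        raise ValueError("need at least two difference maps")
    ref = differences[0]
    stack = []
    for d in differences:
        if d.values.shape != ref.values.shape:
            raise ValueError(
                f"grid mismatch: {d.values.shape} vs {ref.values.shape}"
            )
        stack.append(d.values)
    label = name or "min(" + ", ".join(d.name for d in differences) + ")"
    return ContrastImage(
        values=np.min(np.stack(stack), axis=0),
        affine=ref.affine,
        name=label,
        subject_id=ref.subject_id,
    )


def integration_contrast(fit: GlmFit, bimodal: str = "AV", unimodal: tuple[str, str] = ("A", "V")) -> ContrastImage:
    """The audiovisual integration statistic min(AV-A, AV-V) for one fit."""
    diffs = [
        contrast_image(fit, {bimodal: 1.0, u: -1.0}, name=f"{bimodal}-{u}")
        for u in unimodal
    ]
    return min_difference_contrast(diffs, name=f"{bimodal}-max({','.join(unimodal)})")


def sensitivity_contrast(fit: GlmFit, preferred: str, others: Sequence[str]) -> ContrastImage:
    """Generic sensitivity statistic preferred - max(others)."""
    diffs = [
        contrast_image(fit, {preferred: 1.0, o: -1.0}, name=f"{preferred}-{o}")
        for o in others
    ]
    return min_difference_contrast(diffs, name=f"{preferred}-max({','.join(others)})")
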