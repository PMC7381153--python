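"""Spatial topography of individual integration maxima.

The second analytical arm: locate each subject's maximum of the integration
contrast within a search mask (typically the group-level integration
cluster, per hemisphere), compare the group centroids axis by axis with
two-sample t tests (Bonferroni-corrected across three axes times the number
of hemispheres), and correlate peak coordinates with severity scores.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ContrastImage
from .group import severity_correlation

__all__ = [
    "PeakCoordinate",
    "find_individual_peak",
    "peaks_to_frame",
    "group_centroid",
    "axis_difference_tests",
    "coordinate_severity_correlation",
    "hemisphere_mask",
]

AXES = ("x", "y", "z")


@dataclass
class PeakCoordinate:
    """One subject's within-mask contrast maximum in mm coordinates."""

    subject_id: str
    mni_mm: np.ndarray
    value: float
    mask_name: str = "mask"

    def __post_init__(self) -> None:
        self.mni_mm = np.asarray(self.mni_mm, dtype=float)
        if self.mni_mm.shape != (3,):
            raise ValueError("mni_mm must be a 3-vector")


def find_individual_peak(
    contrast: ContrastImage,
    mask: np.ndarray,
    mask_name: str = "mask",
) -> PeakCoordinate:
    """Voxel with the maximal contrast value inside ``mask``, in mm.

    Ties are broken deterministically by the smallest linear voxel index.
    Raises on an empty mask or a mask with no finite in-mask values.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != contrast.values.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match contrast grid "
            f"{contrast.values.shape}"
        )
    if not mask.any():
        raise ValueError("empty search mask")
    vals = np.where(mask & np.isfinite(contrast.values), contrast.values, -np.inf)
    if not np.isfinite(vals).any():
        raise ValueError("no finite contrast values inside the mask")
    flat = int(np.argmax(vals))  # argmax returns the first (smallest) index on ties
    ijk = np.array(np.unravel_index(flat, vals.shape), dtype=float)
    mm = contrast.affine[:3, :3] @ ijk + contrast.affine[:3, 3]
    return PeakCoordinate(
        subject_id=contrast.subject_id,
        mni_mm=mm,
        value=float(vals.flat[flat]),
        mask_name=mask_name,
    )


def peaks_to_frame(peaks: Sequence[PeakCoordinate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(subject_id=p.subject_id, x=p.mni_mm[0], y=p.mni_mm[1],
                 z=p.mni_mm[2], value=p.value, mask=p.mask_name)
            for p in peaks
        ]
    )


def group_centroid(peaks: Sequence[PeakCoordinate]) -> np.ndarray:
    """Arithmetic mean peak location per spatial axis."""
    if len(peaks) == 0:
        raise ValueError("need at least one peak")
    return np.mean([p.mni_mm for p in peaks], axis=0)


def axis_difference_tests(
    peaks_g1: Sequence[PeakCoordinate],
    peaks_g2: Sequence[PeakCoordinate],
    n_hemispheres: int = 2,
) -> pd.DataFrame:
    """Two-sample t per spatial axis with Bonferroni correction.

    The Bonferroni factor is ``3 * n_hemispheres`` (three axes, tested per
    hemisphere); corrected p-values are capped at 1.  A zero-variance axis
    in both groups yields NaN statistics.
    """
    if len(peaks_g1) < 2 or len(peaks_g2) < 2:
        raise ValueError("need at least two peaks per group")
    a = np.stack([p.mni_mm for p in peaks_g1])
    b = np.stack([p.mni_mm for p in peaks_g2])
    factor = 3 * n_hemispheres
    rows = []
    for i, axis in enumerate(AXES):
        if a[:, i].std() == 0 and b[:, i].std() == 0:
            if np.allclose(a[:, i].mean(), b[:, i].mean()):
                t, p = 0.0, 1.0
            else:
                t, p = np.nan, np.nan
        else:
            t, p = stats.ttest_ind(a[:, i], b[:, i])
        rows.append(
            dict(
                axis=axis,
                t=float(t),
                p_uncorrected=float(p),
                p_bonferroni=float(min(1.0, p * factor)) if np.isfinite(p) else np.nan,
            )
        )
    return pd.DataFrame(rows)


def coordinate_severity_correlation(
    peaks: Sequence[PeakCoordinate],
    scores: Sequence[float],
    axis: str = "y",
) -> tuple[float, float]:
    """Pearson r (and two-sided p) between one peak axis and severity."""
    if axis not in AXES:
        raise ValueError(f"axis must be one of {AXES}")
    coords = [p.mni_mm[AXES.index(axis)] for p in peaks]
    return severity_correlation(coords, scores)


def hemisphere_mask(
    mask: np.ndarray, affine: np.ndarray, hemisphere: str
) -> np.ndarray:
    """Restrict a mask to one hemisphere by the sign of the x coordinate.

    ``x > 0`` is right, ``x < 0`` left; voxels on the midline (x == 0) are
    excluded from both.
    """
    if hemisphere not in ("left", "right"):
        raise ValueError("hemisphere must be 'left' or 'right'")
    mask = np.asarray(mask, dtype=bool)
    ijk = np.stack(np.meshgrid(*[np.arange(s) for s in mask.shape], indexing="ij"), -1)
    x_mm = ijk @ affine[0, :3] + affine[0, 3]
    side = x_mm > 0 if hemisphere == "right" else x_mm < 0
    return mask & side
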