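"""Shared in-memory containers for volumetric data."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .acquisition import AcquisitionSpec

__all__ = ["BoldDataset", "ContrastImage"]


@dataclass
class BoldDataset:
    """One subject's 4D BOLD run.

    ``data`` has shape ``(*grid_shape, n_total)`` straight off the scanner
    (dummy volumes included) or ``(*grid_shape, n_scans)`` after
    :func:`favint.first_level.trim_dummies`.  ``motion`` is a per-volume
    table of the six rigid-body realignment parameters.
    """

    data: np.ndarray
    spec: AcquisitionSpec
    mask: Optional[np.ndarray] = None
    motion: Optional[np.ndarray] = None
    subject_id: str = "sub-00"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D, got shape {self.data.shape}")
        if self.data.shape[:3] != tuple(self.spec.grid_shape):
            raise ValueError(
                f"BOLD grid {self.data.shape[:3]} does not match "
                f"spec grid {tuple(self.spec.grid_shape)}"
            )
        if self.mask is None:
            self.mask = np.ones(self.data.shape[:3], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.data.shape[:3]:
                raise ValueError("mask shape does not match BOLD grid")
        if self.motion is not None:
            self.motion = np.atleast_2d(np.asarray(self.motion, dtype=float))
            if self.motion.shape[0] != self.data.shape[3]:
                raise ValueError(
                    f"motion table has {self.motion.shape[0]} rows for "
                    f"{self.data.shape[3]} volumes"
                )

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    @property
    def affine(self) -> np.ndarray:
        return self.spec.affine


@dataclass
class ContrastImage:
    """A voxelwise contrast-estimate map for one subject.

    Voxels outside the analysis mask are NaN.
    """

    values: np.ndarray
    affine: np.ndarray
    name: str = "contrast"
    subject_id: str = "sub-00"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"contrast map must be 3D, got shape {self.values.shape}")
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def mask(self) -> np.ndarray:
        """Boolean map of defined (non-NaN) voxels."""
        return np.isfinite(self.values)
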