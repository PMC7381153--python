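"""Acquisition geometry and scanner presets.

All analyses run in a common millimetre space defined by a NIfTI affine.  The
default grid is a desk-scale slab (20 x 24 x 20 voxels at 3 mm isotropic)
covering the right temporal lobe, where the superior-temporal-sulcus (STS)
integration effects of interest live; full-brain grids are supported by
passing a different ``grid_shape``/``affine``.

Two scanner-site presets mirror a typical two-site study: a 3T scanner at
site ``G`` (TR = 2.0 s) and one at site ``T`` (TR = 1.7 s), with the series
lengths of the three block-design experiments given per site.  The leading
``n_dummy`` volumes precede T1 saturation equilibrium and are discarded
before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["AcquisitionSpec", "site_preset", "default_affine"]


def default_affine(
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0),
    origin_mm: tuple[float, float, float] = (6.0, -60.0, -21.0),
) -> np.ndarray:
    """Voxel-to-mm affine: axis-aligned scaling plus translation.

    With the defaults, a 20 x 24 x 20 grid spans x in [6, 63] mm,
    y in [-60, 9] mm, z in [-21, 36] mm - the right temporal slab.
    """
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    aff[:3, 3] = origin_mm
    return aff


@dataclass(frozen=True)
class AcquisitionSpec:
    """Scanner/design constants for one functional run.

    Parameters
    ----------
    tr : float
        Repetition time in seconds per volume.
    n_scans : int
        Number of volumes retained for analysis (after dummy removal).
    n_dummy : int
        Leading volumes acquired before T1 equilibrium; simulated with a
        decaying intensity transient and discarded before fitting.
    voxel_size_mm : tuple of float
        Voxel edge lengths in mm (analysis grid, isotropic by default).
    grid_shape : tuple of int
        Number of voxels along x, y, z.
    affine : ndarray, shape (4, 4)
        Voxel-index to mm coordinate map (invertible).
    smooth_fwhm_mm : float
        Width of the Gaussian kernel applied to the simulated signal,
        full width at half maximum in mm.
    """

    tr: float = 2.0
    n_scans: int = 199
    n_dummy: int = 5
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    grid_shape: tuple[int, int, int] = (20, 24, 20)
    affine: np.ndarray = field(default_factory=default_affine)
    smooth_fwhm_mm: float = 8.0

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if self.n_scans <= 0:
            raise ValueError(f"n_scans must be positive, got {self.n_scans}")
        if self.n_dummy < 0:
            raise ValueError(f"n_dummy must be >= 0, got {self.n_dummy}")
        if any(s < 1 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be all >= 1, got {self.grid_shape}")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4) or abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        object.__setattr__(self, "affine", aff)

    @property
    def n_total(self) -> int:
        """Acquired volume count including dummies."""
        return self.n_scans + self.n_dummy

    @property
    def duration(self) -> float:
        """Length of the analyzed series in seconds."""
        return self.n_scans * self.tr

    def with_scans(self, n_scans: int) -> "AcquisitionSpec":
        return replace(self, n_scans=int(n_scans))

    def voxel_to_mm(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (..., 3) to mm coordinates (..., 3)."""
        arr = np.asarray(ijk, dtype=float)
        was_1d = arr.ndim == 1
        out = np.atleast_2d(arr) @ self.affine[:3, :3].T + self.affine[:3, 3]
        return out[0] if was_1d else out


# Acquired series lengths per experiment and site; dummies included.
_SITE_SERIES = {
    "G": {"tr": 2.0, "integration": 204, "face": 302, "voice": 195},
    "T": {"tr": 1.7, "integration": 239, "face": 368, "voice": 232},
}


def site_preset(site: str, experiment: str = "integration", **overrides) -> AcquisitionSpec:
    """Acquisition preset for a study site.

    ``site`` is ``"G"`` (TR 2.0 s) or ``"T"`` (TR 1.7 s); ``experiment`` one
    of ``integration``, ``voice``, ``face``.  The preset's ``n_scans`` is the
    acquired series length minus the five dummy volumes.  Series lengths are
    presets, not constraints: simulated designs may require a different
    ``n_scans`` depending on the inter-block interval (see
    :func:`favint.synth.n_scans_for`).
    """
    try:
        series = _SITE_SERIES[site]
    except KeyError:
        raise ValueError(f"unknown site {site!r}; expected one of {sorted(_SITE_SERIES)}")
    if experiment not in ("integration", "voice", "face"):
        raise ValueError(f"unknown experiment {experiment!r}")
    n_dummy = overrides.pop("n_dummy", 5)
    kwargs = dict(tr=series["tr"], n_scans=series[experiment] - n_dummy, n_dummy=n_dummy)
    kwargs.update(overrides)
    return AcquisitionSpec(**kwargs)
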