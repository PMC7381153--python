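"""Second-level random-effects inference with cluster-level FWE control.

Per-subject contrast images enter a voxelwise linear model (intercept, group
indicator, covariates: mean-centred age plus 0/1 gender and site
indicators).  Significance is assessed at a voxel threshold (p < 0.001 by
default) combined with permutation-based cluster-level family-wise-error
correction (p < 0.05): the FWE p of an observed cluster is the proportion
of permutations whose *maximal* suprathreshold cluster is at least as
large.  One-sample designs use sign flipping, two-sample designs label
permutation; both act on covariate-residualized data (Freedman-Lane).

A closed-form Gaussian-random-field cluster p-value is provided as an
optional cross-check of the permutation result.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .containers import ContrastImage

__all__ = [
    "StatMap",
    "SecondLevelFit",
    "build_group_design",
    "second_level_glm",
    "cluster_fwe",
    "cluster_table_from_map",
    "severity_correlation",
    "grf_cluster_pvalue",
]

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass
class StatMap:
    """A voxelwise t map with its degrees of freedom."""

    t_values: np.ndarray
    dof: int
    contrast_name: str
    direction: str = "greater"
    affine: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.t_values = np.asarray(self.t_values, dtype=float)
        if self.dof <= 0:
            raise ValueError(f"dof must be positive, got {self.dof}")
        if self.direction not in ("greater", "less", "two-sided"):
            raise ValueError(f"invalid direction {self.direction!r}")

    @property
    def mask(self) -> np.ndarray:
        return np.isfinite(self.t_values)

    def z_values(self) -> np.ndarray:
        """Standard-normal-quantile transform of the t map (same tail area)."""
        p = stats.t.sf(self.t_values, self.dof)
        p = np.clip(p, 1e-300, 1 - 1e-16)
        return stats.norm.isf(p)


@dataclass
class SecondLevelFit:
    """Fitted second-level model bundling the resampling inputs.

    ``y`` is subjects x in-mask voxels, ``x`` the design, ``c_index`` the
    tested column; everything :func:`cluster_fwe` needs to rerun the model
    under permutation.
    """

    statmap: StatMap
    y: np.ndarray
    x: np.ndarray
    c_index: int
    mask: np.ndarray
    kind: str  # "one_sample" | "two_sample"
    names: list[str]


def build_group_design(
    groups: Optional[Sequence[str]] = None,
    covariates: Optional[pd.DataFrame] = None,
    n_subjects: Optional[int] = None,
) -> tuple[np.ndarray, list[str], int, str]:
    """Design matrix for the second-level model.

    Returns ``(X, names, tested column index, kind)``.  With ``groups`` the
    tested effect is the SAD-HC difference (group coded 1 for SAD); without,
    it is the intercept (one-sample mean).  Covariate columns: ``age``
    mean-centred, ``gender``/``site`` as 0/1 indicators, any other numeric
    column mean-centred.
    """
    if groups is not None:
        groups = list(groups)
        n_subjects = len(groups)
    if n_subjects is None:
        raise ValueError("provide groups or n_subjects")
    cols = [np.ones(n_subjects)]
    names = ["intercept"]
    if groups is None:
        c_index, kind = 0, "one_sample"
    else:
        labels = sorted(set(groups))
        if len(labels) != 2:
            raise ValueError(f"expected exactly two group labels, got {labels}")
        # SAD (or the lexicographically later label) coded 1
        one = "SAD" if "SAD" in labels else labels[1]
        g = np.array([1.0 if x == one else 0.0 for x in groups])
        c_index, kind = 1, "two_sample"
        cols.append(g)
        names.append(f"group[{one}]")
    if covariates is not None:
        if len(covariates) != n_subjects:
            raise ValueError("covariate rows must align with subjects/maps")
        for col in covariates.columns:
            v = covariates[col]
            if v.dtype == object or isinstance(v.dtype, pd.CategoricalDtype):
                levels = sorted(v.unique())
                if len(levels) < 2:
                    continue
                for lev in levels[1:]:
                    cols.append((v == lev).to_numpy(dtype=float))
                    names.append(f"{col}[{lev}]")
            else:
                x = v.to_numpy(dtype=float)
                cols.append(x - x.mean())
                names.append(col)
    x = np.column_stack(cols)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError(
            "confounded second-level design: group/covariate columns are "
            f"collinear (names: {names})"
        )
    return x, names, c_index, kind


def _t_map(y: np.ndarray, x: np.ndarray, c_index: int) -> tuple[np.ndarray, int]:
    """Voxelwise t for one design column; y is subjects x voxels."""
    n, p = x.shape
    pinv = np.linalg.pinv(x)
    beta = pinv @ y
    resid = y - x @ beta
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    xtx_inv = np.linalg.inv(x.T @ x)
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[c_index, c_index], 1e-300))
    t = beta[c_index] / se
    # zero-residual voxels (e.g. identical maps) are degenerate: report t=0
    scale = np.abs(y).max() if y.size else 1.0
    t[sigma2 <= (1e-10 * max(scale, 1e-30)) ** 2] = 0.0
    return t, dof


def second_level_glm(
    maps: Sequence[ContrastImage],
    groups: Optional[Sequence[str]] = None,
    covariates: Optional[pd.DataFrame] = None,
    contrast_name: Optional[str] = None,
    direction: str = "greater",
) -> SecondLevelFit:
    """Voxelwise random-effects model over subject contrast images.

    One-sample (mean > 0) when ``groups`` is None, otherwise the two-group
    difference (SAD - HC).  Returns a :class:`SecondLevelFit` whose
    ``statmap`` is the t map; pass the fit to :func:`cluster_fwe` for
    cluster-level inference.
    """
    if len(maps) < 3:
        raise ValueError("need at least three subject maps")
    shape = maps[0].values.shape
    stack = np.stack([m.values for m in maps])  # subjects x grid
    mask = np.all(np.isfinite(stack), axis=0)
    y = stack[:, mask]
    x, names, c_index, kind = build_group_design(groups, covariates, len(maps))
    t, dof = _t_map(y, x, c_index)
    t_map = np.full(shape, np.nan)
    t_map[mask] = t
    name = contrast_name or (maps[0].name + (" SAD-HC" if kind == "two_sample" else " mean"))
    statmap = StatMap(
        t_values=t_map, dof=dof, contrast_name=name, direction=direction,
        affine=maps[0].affine,
    )
    return SecondLevelFit(statmap=statmap, y=y, x=x, c_index=c_index, mask=mask,
                          kind=kind, names=names)


def _label_clusters(above: np.ndarray, connectivity: int) -> tuple[np.ndarray, int]:
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[connectivity])
    return ndimage.label(above, structure=structure)


def _threshold_t(statmap_t: np.ndarray, dof: int, voxel_p: float, direction: str) -> np.ndarray:
    if direction == "greater":
        thr = stats.t.isf(voxel_p, dof)
        return np.nan_to_num(statmap_t, nan=-np.inf) > thr
    if direction == "less":
        thr = stats.t.isf(voxel_p, dof)
        return np.nan_to_num(statmap_t, nan=np.inf) < -thr
    thr = stats.t.isf(voxel_p / 2, dof)
    return np.abs(np.nan_to_num(statmap_t, nan=0.0)) > thr


def cluster_table_from_map(
    t_map: np.ndarray,
    dof: int,
    voxel_p: float,
    direction: str,
    connectivity: int,
    affine: Optional[np.ndarray],
) -> pd.DataFrame:
    """Suprathreshold clusters of a t map (no FWE p yet)."""
    above = _threshold_t(t_map, dof, voxel_p, direction)
    labels, n_clusters = _label_clusters(above, connectivity)
    rows = []
    signed = -t_map if direction == "less" else t_map
    for lab in range(1, n_clusters + 1):
        idx = np.nonzero(labels == lab)
        vals = np.abs(signed[idx]) if direction == "two-sided" else signed[idx]
        k = int(np.argmax(vals))
        peak_ijk = np.array([idx[0][k], idx[1][k], idx[2][k]], dtype=float)
        if affine is not None:
            peak = affine[:3, :3] @ peak_ijk + affine[:3, 3]
        else:
            peak = peak_ijk
        t_peak = t_map[idx[0][k], idx[1][k], idx[2][k]]
        p_tail = stats.t.sf(abs(t_peak), dof)
        rows.append(
            dict(
                peak_x=peak[0], peak_y=peak[1], peak_z=peak[2],
                t_peak=t_peak,
                z_peak=stats.norm.isf(np.clip(p_tail, 1e-300, 1.0)) * np.sign(t_peak),
                size_vx=int(len(idx[0])),
                label=lab,
            )
        )
    df = pd.DataFrame(
        rows, columns=["peak_x", "peak_y", "peak_z", "t_peak", "z_peak", "size_vx", "label"]
    )
    return df.sort_values("size_vx", ascending=False, ignore_index=True)


def cluster_fwe(
    fit: SecondLevelFit,
    voxel_p: float = 0.001,
    n_perm: int = 1000,
    seed: int = 0,
    connectivity: int = 18,
    return_labels: bool = False,
):
    """Permutation cluster-level FWE correction for a second-level fit.

    The observed map is thresholded at ``voxel_p`` (one-sided in the fit's
    direction); connected components (18-neighbourhood by default) form
    clusters.  The null distribution of the maximal cluster size is built by
    Freedman-Lane resampling: data are residualized on the nuisance columns,
    then sign-flipped (one-sample) or row-permuted (two-sample), and the
    full-model t map is recomputed.  ``p_fwe = (1 + #{max null size >=
    observed size}) / (1 + n_perm)``.

    Returns a cluster table (columns ``peak_x, peak_y, peak_z, t_peak,
    z_peak, size_vx, p_fwe``), empty when nothing survives the voxel
    threshold.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for a usable null distribution")
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY_RANK)}")
    sm = fit.statmap
    table = cluster_table_from_map(
        sm.t_values, sm.dof, voxel_p, sm.direction, connectivity, sm.affine
    )
    labels_img = None
    if return_labels:
        above = _threshold_t(sm.t_values, sm.dof, voxel_p, sm.direction)
        labels_img, _ = _label_clusters(above, connectivity)
    if table.empty:
        out = table.assign(p_fwe=pd.Series(dtype=float)).drop(columns="label")
        return (out, labels_img) if return_labels else out

    rng = np.random.default_rng(seed)
    nuisance = np.delete(fit.x, fit.c_index, axis=1)
    if nuisance.size:
        resid = fit.y - nuisance @ (np.linalg.pinv(nuisance) @ fit.y)
    else:
        resid = fit.y
    n = fit.y.shape[0]
    shape = sm.t_values.shape
    max_sizes = np.zeros(n_perm, dtype=int)
    for b in range(n_perm):
        if fit.kind == "one_sample":
            signs = rng.choice([-1.0, 1.0], size=n)[:, None]
            y_star = signs * resid
        else:
            y_star = resid[rng.permutation(n)]
        t_star, dof = _t_map(y_star, fit.x, fit.c_index)
        t_vol = np.full(shape, np.nan)
        t_vol[fit.mask] = t_star
        above = _threshold_t(t_vol, dof, voxel_p, sm.direction)
        lab, n_cl = _label_clusters(above, connectivity)
        if n_cl:
            max_sizes[b] = np.bincount(lab.ravel())[1:].max()
    sizes = table["size_vx"].to_numpy()
    p_fwe = (1 + (max_sizes[None, :] >= sizes[:, None]).sum(axis=1)) / (1 + n_perm)
    out = table.assign(p_fwe=p_fwe).drop(columns="label")
    return (out, labels_img) if return_labels else out


def severity_correlation(values: Sequence[float], scores: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation between per-subject effects and severity scores.

    Returns ``(r, two-sided p)``; raises on fewer than three pairs or a
    zero-variance input.
    """
    values = np.asarray(values, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if values.shape != scores.shape or values.ndim != 1:
        raise ValueError("values and scores must be aligned 1D vectors")
    if len(values) < 3:
        raise ValueError("need at least three paired observations")
    if values.std() == 0 or scores.std() == 0:
        raise ValueError("zero variance input; correlation undefined")
    res = stats.pearsonr(values, scores)
    return float(res.statistic), float(res.pvalue)


def grf_cluster_pvalue(
    cluster_size_vx: int,
    t_threshold: float,
    dof: int,
    search_volume_vx: int,
    fwhm_vx: float,
) -> float:
    """Approximate Gaussian-random-field cluster-level FWE p (cross-check).

    Classical closed form for smooth Gaussian fields: the expected number of
    clusters above ``u`` (z-equivalent of the t threshold) times the
    exceedance probability of the cluster extent, Poisson-combined.  Crude
    relative to the permutation test (fixed smoothness ``fwhm_vx`` in
    voxels, Gaussian approximation) - intended as an order-of-magnitude
    sanity check only.
    """
    u = stats.norm.isf(stats.t.sf(t_threshold, dof))
    resels = search_volume_vx / fwhm_vx**3
    # expected Euler characteristic (3D term) and expected suprathreshold volume
    em = resels * (4 * np.log(2)) ** 1.5 / (2 * np.pi) ** 2 * (u**2 - 1) * np.exp(-(u**2) / 2)
    em = max(em, 1e-300)
    en = search_volume_vx * stats.norm.sf(u)
    gamma_5_2 = 1.3293403881791372  # Gamma(5/2)
    beta = (gamma_5_2 * em / en) ** (2.0 / 3.0) if en > 0 else np.inf
    p_extent = np.exp(-beta * cluster_size_vx ** (2.0 / 3.0))
    return float(1.0 - np.exp(-em * p_extent))
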