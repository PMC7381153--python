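"""Post-hoc ROI characterization and demographic/psychometric tests.

Covers extraction of mean contrast estimates from significant clusters,
deconstruction of the integration statistic into its basis contrasts
(AV-A, AV-V), voice-/face-sensitivity tests, inter-ROI comparisons of the
group effect, and the cohort-table statistics (two-sample t tests from
summary statistics, 2x2 chi-square without continuity correction).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ContrastImage

__all__ = [
    "extract_roi_means",
    "basis_deconstruction",
    "sensitivity_tests",
    "roi_effect_comparison",
    "summary_t_test",
    "chi_square_2x2",
    "cohort_table_tests",
]


def extract_roi_means(contrast: ContrastImage, roi: np.ndarray) -> float:
    """Mean of the in-ROI voxel values of one contrast image."""
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != contrast.values.shape:
        raise ValueError(f"ROI shape {roi.shape} != contrast grid {contrast.values.shape}")
    if not roi.any():
        raise ValueError("empty ROI mask")
    vals = contrast.values[roi]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("ROI contains no defined voxels")
    return float(vals.mean())


def _two_sample_t(a: np.ndarray, b: np.ndarray) -> tuple[float, int, float]:
    dof = len(a) + len(b) - 2
    if a.std(ddof=0) == 0 and b.std(ddof=0) == 0:
        # degenerate: no within-group variability
        if a.mean() == b.mean():
            return 0.0, dof, 1.0
        raise ValueError("zero variance with unequal means; t undefined")
    t, p = stats.ttest_ind(a, b)
    return float(t), dof, float(p)


def basis_deconstruction(
    av_a: Sequence[float],
    av_v: Sequence[float],
    groups: Sequence[str],
) -> dict:
    """Deconstruct AV - max(A, V) into its basis contrasts per subject.

    Reports, per group, how many subjects have ``AV-A < AV-V`` (i.e. the
    integration minimum is taken on the auditory difference - the signature
    of a voice-sensitive integration site), plus between-group two-sample t
    tests on each basis contrast.
    """
    av_a = np.asarray(av_a, dtype=float)
    av_v = np.asarray(av_v, dtype=float)
    groups = np.asarray(groups)
    if not (len(av_a) == len(av_v) == len(groups)):
        raise ValueError("av_a, av_v and groups must be aligned")
    indicator = av_a < av_v
    counts = {
        g: (int(indicator[groups == g].sum()), int((groups == g).sum()))
        for g in sorted(set(groups))
    }
    out = {"min_is_av_a_counts": counts, "indicator": indicator}
    labels = sorted(set(groups))
    if len(labels) == 2:
        g1, g2 = ("SAD", "HC") if {"SAD", "HC"} == set(labels) else tuple(labels)
        for name, vals in (("av_a", av_a), ("av_v", av_v)):
            t, dof, p = _two_sample_t(vals[groups == g1], vals[groups == g2])
            out[f"{name}_group_t"] = t
            out[f"{name}_group_dof"] = dof
            out[f"{name}_group_p"] = p
    return out


def sensitivity_tests(
    roi_values: Sequence[float],
    groups: Optional[Sequence[str]] = None,
) -> dict:
    """One-sample (one-tailed, > 0) and group-difference tests of an ROI contrast.

    The one-sample t pools all subjects; the two-sample SAD-vs-HC t is
    two-tailed.  Raises on zero variance.
    """
    vals = np.asarray(roi_values, dtype=float)
    if len(vals) < 2:
        raise ValueError("need at least two subjects")
    if vals.std(ddof=1) == 0:
        if vals.mean() == 0:  # all exactly at the null value
            out = {"one_sample_t": 0.0, "one_sample_dof": len(vals) - 1,
                   "one_sample_p_one_tailed": 0.5}
            if groups is not None:
                out.update(two_sample_t=0.0, two_sample_dof=len(vals) - 2,
                           two_sample_p=1.0)
            return out
        raise ValueError("zero variance in ROI values")
    t1, p1_two = stats.ttest_1samp(vals, 0.0)
    p1 = p1_two / 2 if t1 > 0 else 1 - p1_two / 2  # one-tailed, H1: mean > 0
    out = {
        "one_sample_t": float(t1),
        "one_sample_dof": len(vals) - 1,
        "one_sample_p_one_tailed": float(p1),
    }
    if groups is not None:
        groups = np.asarray(groups)
        labels = sorted(set(groups))
        if len(labels) != 2:
            raise ValueError(f"expected two groups, got {labels}")
        g1, g2 = ("SAD", "HC") if {"SAD", "HC"} == set(labels) else tuple(labels)
        t2, dof, p2 = _two_sample_t(vals[groups == g1], vals[groups == g2])
        out.update(two_sample_t=t2, two_sample_dof=dof, two_sample_p=float(p2))
    return out


def roi_effect_comparison(
    roi_a: Sequence[float],
    roi_b: Sequence[float],
    groups: Sequence[str],
) -> dict:
    """Group-by-ROI interaction via paired differencing.

    Per subject the difference ``roi_a - roi_b`` is formed; the two-sample t
    on these differences tests whether the group effect is stronger in ROI a
    than in ROI b.
    """
    a = np.asarray(roi_a, dtype=float)
    b = np.asarray(roi_b, dtype=float)
    groups = np.asarray(groups)
    if not (len(a) == len(b) == len(groups)):
        raise ValueError("roi_a, roi_b and groups must be aligned")
    d = a - b
    labels = sorted(set(groups))
    if len(labels) != 2:
        raise ValueError(f"expected two groups, got {labels}")
    g1, g2 = ("SAD", "HC") if {"SAD", "HC"} == set(labels) else tuple(labels)
    t, dof, p = _two_sample_t(d[groups == g1], d[groups == g2])
    return {
        "interaction_t": t,
        "interaction_dof": dof,
        "interaction_p": p,
        "mean_diff_g1": float(d[groups == g1].mean()),
        "mean_diff_g2": float(d[groups == g2].mean()),
    }


def summary_t_test(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, int, float]:
    """Pooled-variance two-sample t test from group summary statistics.

    Returns ``(t, dof, two-sided p)`` with ``t`` signed as mean1 - mean2.
    With equal group sizes the pooled and unequal-variance statistics
    coincide.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("SDs must be positive")
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=True)
    return float(res.statistic), n1 + n2 - 2, float(res.pvalue)


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction.

    Cells are row-wise: ``[[a, b], [c, d]]``.  Raises on a zero margin.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise ValueError("cell counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero row or column margin; chi-square undefined")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def cohort_table_tests(cohort: pd.DataFrame) -> pd.DataFrame:
    """Cohort-table group comparisons: t tests on the continuous
    psychometrics and chi-square tests on gender and study site.

    Expects the cohort frame produced by :func:`favint.synth.generate_cohort`.
    Returns one row per variable with the statistic and p value.
    """
    from .synth import CONTINUOUS_VARS

    sad = cohort[cohort["group"] == "SAD"]
    hc = cohort[cohort["group"] == "HC"]
    rows = []
    for cat, first_level in (("gender", "f"), ("site", "T")):
        a = int((sad[cat] == first_level).sum())
        b = int(len(sad) - a)
        c = int((hc[cat] == first_level).sum())
        d = int(len(hc) - c)
        chi2, p = chi_square_2x2(a, b, c, d)
        rows.append(dict(variable=cat, test="chi2", statistic=chi2, dof=1, p=p))
    for var in CONTINUOUS_VARS:
        t, dof, p = summary_t_test(
            sad[var].mean(), sad[var].std(ddof=1), len(sad),
            hc[var].mean(), hc[var].std(ddof=1), len(hc),
        )
        rows.append(dict(variable=var, test="t", statistic=t, dof=dof, p=p))
    return pd.DataFrame(rows)
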