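"""Descriptive statistics: lesion burden, volume normalisation, group tests.

These are the study's scene-setting analyses around the PLS core: the
lesion probability map (per-voxel patient counts), head-size normalisation
of volumes by the volumetric scaling factor v, the non-parametric
Mann-Whitney group comparison of normalised volumes (with a
Kolmogorov-Smirnov normality screen reported alongside), and the
lesion-load vs outcome correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "CorrelationResult",
    "lesion_probability_map",
    "normalize_volume",
    "compare_group_volumes",
    "correlate_lesion_load",
]


@dataclass
class GroupComparison:
    u_statistic: float
    p_value: float
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    ks_p_a: float     # normality screen per group (KS vs fitted normal)
    ks_p_b: float


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int
    method: str


def lesion_probability_map(binary_lesion_masks: np.ndarray) -> np.ndarray:
    """Sum binary per-patient lesion masks into a per-voxel patient count."""
    arr = np.asarray(binary_lesion_masks)
    if arr.ndim != 4:
        raise ValueError("expected shape (n_patients, nx, ny, nz)")
    if arr.dtype != bool:
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("lesion masks must be binary")
        arr = arr.astype(bool)
    return arr.sum(axis=0).astype(np.int64)


def normalize_volume(native_volume: float | np.ndarray, v: float | np.ndarray):
    """Scale a native-space volume (cm^3) to head size: normalized = native * v."""
    v = np.asarray(v, dtype=float)
    if np.any(v <= 0):
        raise ValueError("scaling factor v must be > 0")
    return np.asarray(native_volume, dtype=float) * v


def _ks_normal(x: np.ndarray) -> float:
    sd = x.std(ddof=1)
    if sd == 0:
        return 0.0
    return float(sps.kstest(x, "norm", args=(x.mean(), sd)).pvalue)


def compare_group_volumes(patient_volumes, control_volumes) -> GroupComparison:
    """Two-sided Mann-Whitney U test of the two volume samples.

    Uses scipy's exact method when sample sizes permit and there are no
    ties, the normal approximation with tie correction otherwise.  A KS
    normality screen per group is reported alongside (the rationale for
    preferring the rank test).
    """
    a = np.asarray(patient_volumes, dtype=float)
    b = np.asarray(control_volumes, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    res = sps.mannwhitneyu(a, b, alternative="two-sided")
    return GroupComparison(
        u_statistic=float(res.statistic), p_value=float(res.pvalue),
        n_a=a.size, n_b=b.size,
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        ks_p_a=_ks_normal(a), ks_p_b=_ks_normal(b),
    )


def correlate_lesion_load(
    normalized_lesion_volumes,
    outcome_values,
    method: str = "pearson",
) -> CorrelationResult:
    """Correlation (two-sided p) between lesion load and an outcome."""
    x = np.asarray(normalized_lesion_volumes, dtype=float)
    y = np.asarray(outcome_values, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 paired finite observations")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in one of the variables")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return CorrelationResult(r=float(r), p_value=float(p), n=int(x.size), method=method)
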