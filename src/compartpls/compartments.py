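"""Periventricular / lesion compartmentalisation of the white-matter skeleton.

The periventricular band is the ventricle mask dilated by a fixed number of
voxels (default 3, with a 26-connected 3x3x3 kernel).  Per-patient lesion
maps — continuous in [0,1] after registration-style interpolation — are
thresholded at 0.5, binarised and intersected with the skeleton.  Crossing
the two binary labels partitions each patient's skeleton into four disjoint,
exhaustive compartments; averaging the z-score maps over each compartment
yields the 16-column predictor matrix for the PLS stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .constants import COMPARTMENTS, METRICS, feature_columns
from .zscore import ZScoreStack

__all__ = [
    "CompartmentMasks",
    "dilate_ventricle_mask",
    "project_lesion_to_skeleton",
    "build_compartment_masks",
    "partition_compartments",
    "average_by_compartment",
]


def _check_binary(mask: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.dtype != bool:
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"{name} must be binary, found values {vals[:5]}")
        arr = arr.astype(bool)
    return arr


@dataclass
class CompartmentMasks:
    """Skeleton, periventricular band and per-patient lesioned skeleton."""

    skeleton: np.ndarray                  # boolean grid
    pv_mask: np.ndarray                   # boolean grid (dilated ventricles)
    lesion_skeleton: np.ndarray           # (n_patients, *grid) boolean

    def __post_init__(self) -> None:
        self.skeleton = _check_binary(self.skeleton, "skeleton")
        self.pv_mask = _check_binary(self.pv_mask, "pv_mask")
        self.lesion_skeleton = _check_binary(self.lesion_skeleton, "lesion_skeleton")
        if self.pv_mask.shape != self.skeleton.shape:
            raise ValueError("pv_mask and skeleton grids differ")
        if self.lesion_skeleton.shape[1:] != self.skeleton.shape:
            raise ValueError("lesion_skeleton grid differs from skeleton")
        if (self.lesion_skeleton & ~self.skeleton).any():
            raise ValueError("lesion_skeleton must be a subset of the skeleton")

    @property
    def n_patients(self) -> int:
        return self.lesion_skeleton.shape[0]


def dilate_ventricle_mask(
    ventricle_mask: np.ndarray,
    iterations: int = 3,
    connectivity: int = 26,
) -> np.ndarray:
    """Dilate the ventricle mask to define the periventricular band.

    ``connectivity`` selects the structuring element: 26 (default) is the
    full 3x3x3 box, one iteration growing the mask by one voxel in the
    Chebyshev metric; 6 is the face-connected cross.  The output always
    contains the input; dilation is clipped at the grid boundary.
    """
    mask = _check_binary(ventricle_mask, "ventricle_mask")
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0 or not mask.any():
        return mask.copy()
    if connectivity == 26:
        structure = np.ones((3, 3, 3), dtype=bool)
    elif connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    else:
        raise ValueError("connectivity must be 6 or 26")
    return ndimage.binary_dilation(mask, structure=structure, iterations=iterations)


def project_lesion_to_skeleton(
    lesion_map: np.ndarray,
    skeleton_mask: np.ndarray,
    threshold: float = 0.5,
    tol: float = 1e-6,
) -> np.ndarray:
    """Threshold a continuous lesion map and restrict it to the skeleton.

    Values must lie in [0, 1] (a small tolerance absorbs floating-point
    excursions from interpolation).  The threshold is inclusive: a voxel at
    exactly 0.5 counts as lesioned.
    """
    arr = np.asarray(lesion_map, dtype=float)
    skeleton = _check_binary(skeleton_mask, "skeleton_mask")
    if arr.shape != skeleton.shape:
        raise ValueError("lesion map and skeleton grids differ")
    if arr.min() < -tol or arr.max() > 1 + tol:
        raise ValueError(
            f"lesion map values outside [0, 1]: range [{arr.min():g}, {arr.max():g}]")
    return (arr >= threshold) & skeleton


def build_compartment_masks(
    skeleton_mask: np.ndarray,
    ventricle_mask: np.ndarray,
    lesion_maps: np.ndarray,
    dilation_iterations: int = 3,
    lesion_threshold: float = 0.5,
    connectivity: int = 26,
) -> CompartmentMasks:
    """Convenience constructor: dilate ventricles and project all lesion maps."""
    skeleton = _check_binary(skeleton_mask, "skeleton_mask")
    pv = dilate_ventricle_mask(ventricle_mask, dilation_iterations, connectivity)
    lesions = np.asarray(lesion_maps, dtype=float)
    if lesions.ndim != 4 or lesions.shape[1:] != skeleton.shape:
        raise ValueError("lesion_maps must have shape (n_patients, *grid)")
    proj = np.stack([
        project_lesion_to_skeleton(lesions[j], skeleton, lesion_threshold)
        for j in range(lesions.shape[0])
    ])
    return CompartmentMasks(skeleton=skeleton, pv_mask=pv, lesion_skeleton=proj)


def partition_compartments(masks: CompartmentMasks, patient: int) -> dict[str, np.ndarray]:
    """The four disjoint compartments of one patient's skeleton.

    Returns a mapping over ``COMPARTMENTS``; the four boolean grids are
    pairwise disjoint and their union is the skeleton.
    """
    skel = masks.skeleton
    pv = masks.pv_mask
    les = masks.lesion_skeleton[patient]
    return {
        "pv_lesion": skel & pv & les,
        "nonpv_lesion": skel & ~pv & les,
        "pv_nawm": skel & pv & ~les,
        "nonpv_nawm": skel & ~pv & ~les,
    }


def average_by_compartment(zstack: ZScoreStack, masks: CompartmentMasks) -> pd.DataFrame:
    """Average each patient's z-scores over each (metric, compartment) cell.

    Degenerate (NaN) voxels are excluded from the mean; an empty compartment
    yields NaN for all its cells.  Columns follow ``feature_columns()``
    (metric-major); rows are patients in stack order.
    """
    if zstack.skeleton.shape != masks.skeleton.shape:
        raise ValueError("z-score stack and masks are on different grids")
    if not masks.skeleton.any():
        raise ValueError("skeleton mask is empty")
    n_pat = zstack.n_patients
    if masks.n_patients != n_pat:
        raise ValueError("patient count mismatch between z-scores and lesion masks")
    out = np.full((n_pat, len(feature_columns())), np.nan)
    cols = {name: k for k, name in enumerate(feature_columns())}
    for j in range(n_pat):
        comps = partition_compartments(masks, j)
        for m in METRICS:
            if m not in zstack.z:
                raise ValueError(f"z-score stack lacks metric {m}")
            zmap = zstack.z[m][j]
            for c in COMPARTMENTS:
                vals = zmap[comps[c]]
                vals = vals[np.isfinite(vals)]
                if vals.size:
                    out[j, cols[f"{m}_{c}"]] = vals.mean()
    index = zstack.patient_ids or list(range(n_pat))
    return pd.DataFrame(out, index=index, columns=feature_columns())
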