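"""Voxel-wise z-scoring of patient diffusion maps against a control cohort.

For every skeleton voxel n and metric X, the control cohort of q subjects
defines a reference location X̄_n (arithmetic mean) and dispersion δ_n
(population standard deviation by default, divisor q); each patient j is
then expressed as

    Z_{X,n,j} = (X_{n,j} - X̄_n) / δ_n .

Voxels where the controls show zero dispersion are flagged degenerate and
yield NaN z-scores rather than infinities; downstream compartment averages
skip them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ControlReference", "ZScoreStack", "fit_control_reference", "compute_zscores"]


@dataclass
class ControlReference:
    """Per-voxel control mean and dispersion for each metric, on the skeleton."""

    mean: dict[str, np.ndarray]        # metric -> 3-D grid, NaN off-skeleton
    sd: dict[str, np.ndarray]          # metric -> 3-D grid, NaN off-skeleton
    degenerate: dict[str, np.ndarray]  # metric -> boolean grid (sd == 0 on skeleton)
    skeleton: np.ndarray               # boolean grid
    n_controls: int
    ddof: int = 0

    @property
    def metrics(self) -> list[str]:
        return list(self.mean)


@dataclass
class ZScoreStack:
    """Per-patient, per-metric z-score grids (NaN off-skeleton / degenerate)."""

    z: dict[str, np.ndarray]           # metric -> (n_patients, *grid)
    skeleton: np.ndarray
    patient_ids: list[str] = field(default_factory=list)

    @property
    def n_patients(self) -> int:
        return next(iter(self.z.values())).shape[0]

    @property
    def metrics(self) -> list[str]:
        return list(self.z)


def _as_stack(maps: np.ndarray, name: str, grid: tuple[int, ...]) -> np.ndarray:
    arr = np.asarray(maps, dtype=float)
    if arr.ndim != 4 or arr.shape[1:] != grid:
        raise ValueError(f"{name}: expected shape (n_subjects, {grid}), got {arr.shape}")
    return arr


def fit_control_reference(
    control_maps: dict[str, np.ndarray],
    skeleton_mask: np.ndarray,
    ddof: int = 0,
) -> ControlReference:
    """Fit the per-voxel control mean and dispersion on the skeleton.

    Parameters
    ----------
    control_maps
        Mapping metric -> array of shape (q, nx, ny, nz) with one grid per
        control subject.
    skeleton_mask
        Boolean grid; statistics are defined only where it is True.
    ddof
        0 (default) for the population SD with divisor q; 1 for the sample SD.
    """
    skeleton = np.asarray(skeleton_mask).astype(bool)
    grid = skeleton.shape
    if not control_maps:
        raise ValueError("control_maps is empty")
    mean: dict[str, np.ndarray] = {}
    sd: dict[str, np.ndarray] = {}
    degenerate: dict[str, np.ndarray] = {}
    q = None
    for m, maps in control_maps.items():
        arr = _as_stack(maps, f"control_maps[{m}]", grid)
        if q is None:
            q = arr.shape[0]
        elif arr.shape[0] != q:
            raise ValueError("all metrics must have the same number of controls")
        mu = arr.mean(axis=0)
        dev = arr.std(axis=0, ddof=ddof)
        deg = skeleton & (dev == 0.0)
        mu[~skeleton] = np.nan
        dev[~skeleton] = np.nan
        mean[m], sd[m], degenerate[m] = mu, dev, deg
    assert q is not None
    if q < 2:
        raise ValueError(f"need at least 2 controls, got {q}")
    return ControlReference(mean=mean, sd=sd, degenerate=degenerate,
                            skeleton=skeleton, n_controls=q, ddof=ddof)


def compute_zscores(
    patient_maps: dict[str, np.ndarray],
    reference: ControlReference,
    patient_ids: list[str] | None = None,
) -> ZScoreStack:
    """Z-score each patient map voxel-wise against the control reference.

    Degenerate voxels (control dispersion zero) propagate NaN, never ±inf.
    """
    grid = reference.skeleton.shape
    z: dict[str, np.ndarray] = {}
    for m, maps in patient_maps.items():
        if m not in reference.mean:
            raise ValueError(f"metric {m} missing from the control reference")
        arr = _as_stack(maps, f"patient_maps[{m}]", grid)
        dev = reference.sd[m]
        safe = np.where(dev > 0, dev, np.nan)
        z[m] = (arr - reference.mean[m]) / safe
    n_pat = next(iter(z.values())).shape[0]
    if patient_ids is None:
        patient_ids = [f"P{i:03d}" for i in range(n_pat)]
    if len(patient_ids) != n_pat:
        raise ValueError("patient_ids length does not match the map stack")
    return ZScoreStack(z=z, skeleton=reference.skeleton, patient_ids=list(patient_ids))
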