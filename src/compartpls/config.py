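"""Configuration containers for the synthetic cohort and the study pipeline.

Defaults mirror the study design the package analyses: 52 relapsing-remitting
MS patients and 50 healthy controls, a desk-scale 32x32x32 grid standing in
for the 1 mm skeletonised template space, periventricularly concentrated
lesions, and a demyelination-like group effect (MD/RD up, FA down broadly,
AD up only in a central voxel subset).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np
import yaml

from .constants import COMPARTMENTS, METRICS, N_FEATURES, feature_columns


def _default_control_mean() -> dict[str, float]:
    # typical healthy white-matter skeleton values; diffusivities in mm^2/s
    return {"FA": 0.45, "MD": 8.0e-4, "AD": 1.2e-3, "RD": 6.0e-4}


def _default_control_sd() -> dict[str, float]:
    return {"FA": 0.08, "MD": 6.0e-5, "AD": 9.0e-5, "RD": 6.0e-5}


def _default_effect_z() -> dict[str, dict[str, float]]:
    """Mean patient z-shift per (metric, compartment), demyelination-like.

    RD and MD increase broadly, FA decreases broadly, and AD increases only
    inside the central voxel subset (see ``CohortConfig.ad_central_radius_frac``),
    strongest in lesions and the periventricular compartments.
    """
    return {
        "FA": {"pv_lesion": -0.8, "nonpv_lesion": -0.7, "pv_nawm": -0.5, "nonpv_nawm": -0.3},
        "MD": {"pv_lesion": 1.1, "nonpv_lesion": 1.0, "pv_nawm": 0.8, "nonpv_nawm": 0.3},
        "AD": {"pv_lesion": 0.6, "nonpv_lesion": 0.5, "pv_nawm": 0.3, "nonpv_nawm": 0.0},
        "RD": {"pv_lesion": 1.3, "nonpv_lesion": 1.2, "pv_nawm": 0.9, "nonpv_nawm": 0.4},
    }


def _default_shared_coupling() -> dict[str, dict[str, float]]:
    """Loading of each cell's patient effect on the shared severity factor.

    Cells whose pathology tracks overall demyelination burden (MD/RD of the
    lesioned and periventricular normal-appearing compartments) load strongly;
    the remaining cells vary mostly idiosyncratically.  This reproduces the
    empirical situation in which only those cells are strong outcome
    predictors while the others are weak proxies.
    """
    strong = {"pv_lesion": 0.4, "nonpv_lesion": 0.4, "pv_nawm": 0.4, "nonpv_nawm": 0.08}
    weak = {c: 0.08 for c in COMPARTMENTS}
    return {
        "FA": dict(weak),
        "MD": dict(strong),
        "AD": {c: 0.05 for c in COMPARTMENTS},
        "RD": dict(strong),
    }


def _default_outcome_weights() -> dict[str, float]:
    """Generative weights on the 16 feature cells (unnamed cells are zero).

    Nonzero weights sit on MD and RD of the lesioned compartments and the
    periventricular normal-appearing white matter — the cells the study found
    to drive gray-matter atrophy and disability.
    """
    w: dict[str, float] = {}
    for m in ("MD", "RD"):
        for c in ("pv_lesion", "nonpv_lesion", "pv_nawm"):
            w[f"{m}_{c}"] = 1.0
    return w


def _default_outcome_params() -> dict[str, dict[str, float]]:
    """Baselines / spreads of the outcome variables (volumes in cm^3).

    Volume means match the reported group means; the SDs are the reported
    standard errors scaled by sqrt(n).  ``sign`` is the direction in which
    white-matter damage moves the outcome (-1: atrophy, +1: disability,
    0: no generative coupling).
    """
    return {
        "gm_volume": {
            "baseline": 395.527, "control_baseline": 436.422,
            "sd": 58.05, "control_sd": 84.93, "sign": -1.0,
        },
        "brain_volume": {
            "baseline": 718.764, "control_baseline": 791.772,
            "sd": 107.94, "control_sd": 160.46, "sign": -1.0,
        },
        "wm_volume": {
            "baseline": 323.237, "control_baseline": 355.350,
            "sd": 52.25, "control_sd": 77.28, "sign": 0.0,
        },
        "edss": {"baseline": 1.66, "control_baseline": float("nan"),
                 "sd": 1.44, "control_sd": float("nan"), "sign": 1.0},
    }


@dataclass
class CohortConfig:
    """Full parameterisation of one synthetic study realisation."""

    n_patients: int = 52
    n_controls: int = 50
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    skeleton_fraction: float = 0.10

    # ventricle geometry: Chebyshev balls of radius `ventricle_seed_radius`
    # around each seed voxel; () disables the ventricle mask entirely
    ventricle_seeds: tuple[tuple[int, int, int], ...] = ((12, 16, 16), (20, 16, 16))
    ventricle_seed_radius: int = 2
    pv_dilation_iterations: int = 3

    lesion_rate_pv: float = 0.30
    lesion_rate_nonpv: float = 0.05
    # Gaussian blur of the binary lesion draw, in voxels; emulates the
    # partial-volume smoothing that registration interpolation introduces.
    # Kept below ~0.5 voxel so the 0.5 re-binarisation recovers the drawn
    # lesions (an isolated lesioned voxel stays above threshold).
    lesion_blur_sigma: float = 0.4

    control_mean: dict[str, float] = field(default_factory=_default_control_mean)
    control_sd: dict[str, float] = field(default_factory=_default_control_sd)
    effect_z: dict[str, dict[str, float]] = field(default_factory=_default_effect_z)
    # AD group effects are restricted to the central voxel subset: a Chebyshev
    # ball around the grid centre with radius frac * min(grid_shape)
    ad_central_radius_frac: float = 0.25

    # between-patient severity structure (see docs/methods.md)
    shared_coupling: dict[str, dict[str, float]] = field(default_factory=_default_shared_coupling)
    cell_coupling: float = 0.2

    outcome_weights: dict[str, float] = field(default_factory=_default_outcome_weights)
    outcome_r2: float = 0.5
    outcome_noise_sd: Optional[float] = None  # overrides outcome_r2 when set
    outcome_params: dict[str, dict[str, float]] = field(default_factory=_default_outcome_params)

    voxel_volume_cm3: float = 0.0055  # nominal, sets the lesion-load scale
    v_scaling_mean: float = 1.39
    v_scaling_sd: float = 0.08

    seed: int = 0

    # ------------------------------------------------------------------
    def weight_vector(self) -> np.ndarray:
        """Expand the sparse outcome-weight mapping to the fixed column order."""
        cols = feature_columns()
        unknown = set(self.outcome_weights) - set(cols)
        if unknown:
            raise ValueError(f"unknown feature columns in outcome_weights: {sorted(unknown)}")
        return np.array([self.outcome_weights.get(c, 0.0) for c in cols])

    def generative_columns(self) -> list[str]:
        """Feature columns with a nonzero generative weight."""
        return [c for c in feature_columns() if self.outcome_weights.get(c, 0.0) != 0.0]

    def validate(self) -> None:
        if self.n_patients < 2 or self.n_controls < 2:
            raise ValueError("n_patients and n_controls must both be >= 2")
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise ValueError("grid_shape must be three positive dimensions")
        if not 0.0 < self.skeleton_fraction < 1.0:
            raise ValueError("skeleton_fraction must lie in (0, 1)")
        for rate in (self.lesion_rate_pv, self.lesion_rate_nonpv):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("lesion rates must lie in [0, 1]")
        if self.lesion_rate_pv < self.lesion_rate_nonpv:
            raise ValueError("lesion_rate_pv must be >= lesion_rate_nonpv")
        if self.pv_dilation_iterations < 0 or self.ventricle_seed_radius < 0:
            raise ValueError("dilation iterations and seed radius must be >= 0")
        for m in METRICS:
            if m not in self.control_mean or m not in self.control_sd:
                raise ValueError(f"control_mean/control_sd must define metric {m}")
            if self.control_sd[m] <= 0:
                raise ValueError(f"control_sd[{m}] must be > 0")
            for c in COMPARTMENTS:
                if c not in self.effect_z.get(m, {}):
                    raise ValueError(f"effect_z must define ({m}, {c})")
        for x, y, z in self.ventricle_seeds:
            if not (0 <= x < self.grid_shape[0] and 0 <= y < self.grid_shape[1]
                    and 0 <= z < self.grid_shape[2]):
                raise ValueError(f"ventricle seed {(x, y, z)} outside the grid")
        if self.outcome_r2 is not None and not 0.0 <= self.outcome_r2 < 1.0:
            raise ValueError("outcome_r2 must lie in [0, 1)")
        if self.outcome_noise_sd is not None and self.outcome_noise_sd < 0:
            raise ValueError("outcome_noise_sd must be >= 0")
        self.weight_vector()  # raises on unknown columns

    # ------------------------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["ventricle_seeds"] = [list(s) for s in self.ventricle_seeds]
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "CohortConfig":
        d = dict(d)
        if "grid_shape" in d:
            d["grid_shape"] = tuple(int(v) for v in d["grid_shape"])
        if "ventricle_seeds" in d:
            d["ventricle_seeds"] = tuple(tuple(int(v) for v in s) for s in d["ventricle_seeds"])
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class PLSOptions:
    """Options for the PLS stage of the pipeline."""

    scale: bool = True              # z-score the predictor columns
    n_permutations: int = 5000
    alpha: float = 0.05
    y_variance_threshold: float = 0.05
    max_components: int = 3
    impute: str = "mean"            # "mean" | "drop"

    def validate(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.alpha < 1 or not 0 <= self.y_variance_threshold <= 1:
            raise ValueError("alpha in (0,1); y_variance_threshold in [0,1]")
        if self.max_components < 1:
            raise ValueError("max_components must be >= 1")
        if self.impute not in ("mean", "drop"):
            raise ValueError("impute must be 'mean' or 'drop'")


@dataclass
class StudyConfig:
    """End-to-end pipeline configuration (simulate or ingest)."""

    simulate: Optional[CohortConfig] = field(default_factory=CohortConfig)
    input_dir: Optional[str] = None      # ingest mode: a directory written by save_cohort
    dilation_iterations: int = 3
    lesion_threshold: float = 0.5
    pls: PLSOptions = field(default_factory=PLSOptions)
    outcomes: tuple[str, ...] = ("gm_volume", "brain_volume", "edss")
    seed: int = 0

    def validate(self) -> None:
        if (self.simulate is None) == (self.input_dir is None):
            raise ValueError("exactly one of `simulate` and `input_dir` must be set")
        if self.simulate is not None:
            self.simulate.validate()
        if not 0.0 <= self.lesion_threshold <= 1.0:
            raise ValueError("lesion_threshold must lie in [0, 1]")
        if self.dilation_iterations < 0:
            raise ValueError("dilation_iterations must be >= 0")
        self.pls.validate()
        if not self.outcomes:
            raise ValueError("at least one outcome is required")

    def to_dict(self) -> dict[str, Any]:
        return {
            "simulate": None if self.simulate is None else self.simulate.to_dict(),
            "input_dir": self.input_dir,
            "dilation_iterations": self.dilation_iterations,
            "lesion_threshold": self.lesion_threshold,
            "pls": dataclasses.asdict(self.pls),
            "outcomes": list(self.outcomes),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "StudyConfig":
        d = dict(d)
        sim = d.get("simulate")
        cfg = cls(
            simulate=None if sim is None else CohortConfig.from_dict(sim),
            input_dir=d.get("input_dir"),
            dilation_iterations=int(d.get("dilation_iterations", 3)),
            lesion_threshold=float(d.get("lesion_threshold", 0.5)),
            pls=PLSOptions(**d.get("pls", {})),
            outcomes=tuple(d.get("outcomes", ("gm_volume", "brain_volume", "edss"))),
            seed=int(d.get("seed", 0)),
        )
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
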