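"""Seeded synthetic cohort generator with the study's statistical structure.

Generation happens directly in skeleton space — no diffusion tensors,
registration or skeleton projection are simulated.  One realisation
comprises:

* geometry: a Bernoulli skeleton mask and a ventricle mask grown from seed
  voxels, from which the periventricular band is derived downstream;
* lesion maps: per-patient Bernoulli lesions, denser in the periventricular
  band, optionally blurred to mimic interpolation partial-voluming;
* diffusion maps (FA/MD/AD/RD): controls drawn i.i.d. per voxel from the
  configured metric distribution; patients shifted by a per-compartment
  z-effect (demyelination-like by default: MD/RD up, FA down, AD up only in
  a central voxel subset), modulated per patient by a shared severity factor
  with cell-specific couplings plus idiosyncratic variation;
* outcomes: normalised gray-matter / brain volumes and EDSS generated as a
  noisy linear function of the *actual* compartment-averaged z-scores,
  computed through the real z-score and compartment modules, with the
  generative weights concentrated on MD/RD of the lesioned compartments and
  the periventricular normal-appearing white matter.

The ground truth (weights, severity draws, realised features) is kept on the
cohort for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import ndimage

from .compartments import build_compartment_masks, partition_compartments
from .config import CohortConfig
from .constants import COMPARTMENTS, METRICS, feature_columns
from .zscore import compute_zscores, fit_control_reference

__all__ = [
    "SyntheticCohort",
    "generate_geometry",
    "generate_lesion_maps",
    "generate_diffusion_maps",
    "generate_outcomes",
    "generate_cohort",
]


@dataclass
class SyntheticCohort:
    """One generated study: maps, masks, subject table and ground truth."""

    config: CohortConfig
    skeleton_mask: np.ndarray                 # boolean grid
    ventricle_mask: np.ndarray                # boolean grid (undilated)
    lesion_maps: np.ndarray                   # (n_patients, *grid) in [0, 1]
    metric_maps: dict[str, np.ndarray]        # metric -> (n_subjects, *grid); patients first
    subject_table: pd.DataFrame
    truth: dict[str, Any] = field(default_factory=dict)

    @property
    def patient_ids(self) -> list[str]:
        tab = self.subject_table
        return tab.loc[tab["group"] == "patient", "subject_id"].tolist()

    @property
    def control_ids(self) -> list[str]:
        tab = self.subject_table
        return tab.loc[tab["group"] == "control", "subject_id"].tolist()

    def patient_maps(self) -> dict[str, np.ndarray]:
        n = self.config.n_patients
        return {m: arr[:n] for m, arr in self.metric_maps.items()}

    def control_maps(self) -> dict[str, np.ndarray]:
        n = self.config.n_patients
        return {m: arr[n:] for m, arr in self.metric_maps.items()}


# ----------------------------------------------------------------------
def generate_geometry(
    config: CohortConfig,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the skeleton mask and build the ventricle mask.

    The skeleton is a per-voxel Bernoulli(skeleton_fraction) draw, emulating
    the thin spread-out tract-centre set of a TBSS skeleton at desk scale.
    Ventricles are Chebyshev balls of ``ventricle_seed_radius`` around each
    seed voxel (radius 0 gives single-voxel ventricles).
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    shape = config.grid_shape
    skeleton = rng.random(shape) < config.skeleton_fraction
    if not skeleton.any():
        raise ValueError("degenerate geometry: skeleton mask is empty")

    ventricle = np.zeros(shape, dtype=bool)
    r = config.ventricle_seed_radius
    for x, y, z in config.ventricle_seeds:
        sl = tuple(
            slice(max(0, c - r), min(s, c + r + 1))
            for c, s in zip((x, y, z), shape)
        )
        ventricle[sl] = True

    if config.ventricle_seeds:
        grown = ventricle
        if config.pv_dilation_iterations > 0:
            grown = ndimage.binary_dilation(
                ventricle, structure=np.ones((3, 3, 3), dtype=bool),
                iterations=config.pv_dilation_iterations)
        if grown.all():
            raise ValueError(
                "degenerate geometry: dilated ventricles cover the whole grid")
    return skeleton, ventricle


def generate_lesion_maps(
    config: CohortConfig,
    skeleton_mask: np.ndarray,
    pv_mask: np.ndarray,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-patient continuous lesion maps in [0, 1].

    Lesions are Bernoulli draws with probability ``lesion_rate_pv`` inside
    the periventricular band and ``lesion_rate_nonpv`` elsewhere, then
    blurred with a Gaussian of ``lesion_blur_sigma`` voxels (sigma 0 keeps
    them binary).  Blurring emulates the partial-volume values that
    interpolation during registration would produce; the downstream
    projection re-binarises at 0.5.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    pv = np.asarray(pv_mask, dtype=bool)
    if pv.shape != config.grid_shape:
        raise ValueError("pv_mask grid does not match the configured grid")
    rate = np.where(pv, config.lesion_rate_pv, config.lesion_rate_nonpv)
    maps = np.empty((config.n_patients,) + config.grid_shape)
    for j in range(config.n_patients):
        binary = (rng.random(config.grid_shape) < rate).astype(float)
        if config.lesion_blur_sigma > 0:
            binary = ndimage.gaussian_filter(binary, config.lesion_blur_sigma)
        maps[j] = np.clip(binary, 0.0, 1.0)
    return maps


def _central_mask(config: CohortConfig) -> np.ndarray:
    """Chebyshev ball around the grid centre restricting the AD effect."""
    shape = config.grid_shape
    radius = int(round(config.ad_central_radius_frac * min(shape)))
    centre = [s // 2 for s in shape]
    idx = np.indices(shape)
    cheb = np.max(np.stack([np.abs(idx[d] - centre[d]) for d in range(3)]), axis=0)
    return cheb <= radius


def _severity_multipliers(
    config: CohortConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-patient, per-cell multiplicative severity factors (mean 1).

    multiplier[j, cell] = 1 + lambda_cell * d_j + tau * b_{j,cell}, where d
    is the shared demyelination-severity factor and b are cell-specific
    standard-normal draws.  Couplings come from ``config.shared_coupling``
    and ``config.cell_coupling``.
    """
    cols = feature_columns()
    lam = np.array([
        config.shared_coupling[c.split("_", 1)[0]][c.split("_", 1)[1]] for c in cols
    ])
    d = rng.standard_normal(config.n_patients)
    b = rng.standard_normal((config.n_patients, len(cols)))
    mult = 1.0 + d[:, None] * lam[None, :] + config.cell_coupling * b
    return mult, d, b


def generate_diffusion_maps(
    config: CohortConfig,
    skeleton_mask: np.ndarray,
    pv_mask: np.ndarray,
    lesion_maps: np.ndarray,
    rng: np.random.Generator | None = None,
    severity: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Draw FA/MD/AD/RD maps for all subjects (patients first, then controls).

    Every voxel of every subject starts from the control distribution
    N(control_mean, control_sd) of its metric; patient voxels are then
    shifted by effect_z * severity * control_sd in each compartment they
    belong to (compartments derived with the real projection/partition
    operations).  FA is clipped to [0, 1]; diffusivities are floored at a
    tiny positive value.

    ``severity`` is the (n_patients, 16) multiplier array from the severity
    model; identity multipliers are used when omitted.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    skeleton = np.asarray(skeleton_mask, dtype=bool)
    masks = build_compartment_masks(
        skeleton, np.zeros_like(skeleton), lesion_maps,
        dilation_iterations=0, lesion_threshold=0.5)
    # overwrite the pv part: pv_mask arrives already dilated
    masks.pv_mask = np.asarray(pv_mask, dtype=bool)

    if severity is None:
        severity = np.ones((config.n_patients, len(feature_columns())))
    cols = {name: k for k, name in enumerate(feature_columns())}
    central = _central_mask(config)
    n_sub = config.n_patients + config.n_controls

    out: dict[str, np.ndarray] = {}
    for m in METRICS:
        mu, sd = config.control_mean[m], config.control_sd[m]
        maps = mu + sd * rng.standard_normal((n_sub,) + config.grid_shape)
        for j in range(config.n_patients):
            comps = partition_compartments(masks, j)
            shift = np.zeros(config.grid_shape)
            for c in COMPARTMENTS:
                eff = config.effect_z[m][c]
                if eff == 0.0:
                    continue
                region = comps[c]
                if m == "AD":
                    region = region & central
                shift[region] += eff * severity[j, cols[f"{m}_{c}"]] * sd
            maps[j] += shift
        if m == "FA":
            np.clip(maps, 0.0, 1.0, out=maps)
        else:
            np.maximum(maps, 1e-12, out=maps)
        out[m] = maps
    return out


def generate_outcomes(
    config: CohortConfig,
    features: pd.DataFrame,
    lesion_voxels: np.ndarray,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Build the subject table, outcomes driven by the realised features.

    Patient outcomes are a noisy linear function of the compartmental
    z-score features: the linear predictor s = features @ outcome_weights is
    standardised and injected with variance fraction ``outcome_r2`` of the
    outcome's configured spread (volumes decrease with damage, EDSS
    increases).  When ``outcome_noise_sd`` is set it overrides the R²
    parameterisation: outcome = baseline ± (s - mean(s)) + noise.  EDSS is
    clamped to [0, 10] and rounded to 0.5 steps; controls draw their volumes
    from a higher baseline and carry no EDSS.
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    w = config.weight_vector()
    if features.shape != (config.n_patients, w.size):
        raise ValueError(
            f"features must be ({config.n_patients}, {w.size}), got {features.shape}")
    filled = features.fillna(features.mean(axis=0))
    signal = filled.to_numpy() @ w
    signal_c = signal - signal.mean()
    sd_s = signal_c.std()
    shat = signal_c / sd_s if sd_s > 0 else np.zeros_like(signal_c)

    n_pat, n_ctl = config.n_patients, config.n_controls
    table: dict[str, Any] = {
        "subject_id": [f"P{i:03d}" for i in range(n_pat)] + [f"C{i:03d}" for i in range(n_ctl)],
        "group": ["patient"] * n_pat + ["control"] * n_ctl,
    }

    for name, par in config.outcome_params.items():
        sign, sd_out = par["sign"], par["sd"]
        if config.outcome_noise_sd is not None:
            noise = config.outcome_noise_sd * rng.standard_normal(n_pat)
            pat = par["baseline"] + sign * signal_c + noise
        else:
            r2 = config.outcome_r2 if sign != 0.0 else 0.0
            pat = (par["baseline"]
                   + sign * np.sqrt(r2) * sd_out * shat
                   + np.sqrt(1.0 - r2) * sd_out * rng.standard_normal(n_pat))
        if name == "edss":
            pat = np.clip(pat, 0.0, 10.0)
            pat = np.round(pat * 2.0) / 2.0
            col = np.concatenate([pat, np.full(n_ctl, np.nan)])
        else:
            ctl = par["control_baseline"] + par["control_sd"] * rng.standard_normal(n_ctl)
            col = np.concatenate([pat, ctl])
        table[name] = col

    v = np.clip(config.v_scaling_mean + config.v_scaling_sd * rng.standard_normal(n_pat + n_ctl),
                0.5, None)
    table["v_scaling"] = v
    lesion_vol = np.concatenate([
        np.asarray(lesion_voxels, dtype=float) * config.voxel_volume_cm3,
        np.zeros(n_ctl),
    ])
    table["lesion_volume"] = lesion_vol
    table["norm_lesion_volume"] = lesion_vol * v
    return pd.DataFrame(table)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full, seeded synthetic study.

    Deterministic: identical configs (including seed) give bit-identical
    cohorts.  The outcome features are computed through the real z-score and
    compartment modules, never short-circuited.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    r_geom, r_les, r_sev, r_maps, r_out = (np.random.default_rng(s) for s in ss.spawn(5))

    skeleton, ventricle = generate_geometry(config, r_geom)
    masks = build_compartment_masks(
        skeleton, ventricle, np.zeros((1,) + config.grid_shape),
        dilation_iterations=config.pv_dilation_iterations)
    pv_mask = masks.pv_mask

    lesion_maps = generate_lesion_maps(config, skeleton, pv_mask, r_les)
    severity, d, b = _severity_multipliers(config, r_sev)
    metric_maps = generate_diffusion_maps(
        config, skeleton, pv_mask, lesion_maps, r_maps, severity)

    # features through the real downstream modules
    n_pat = config.n_patients
    control_maps = {m: arr[n_pat:] for m, arr in metric_maps.items()}
    patient_maps = {m: arr[:n_pat] for m, arr in metric_maps.items()}
    reference = fit_control_reference(control_maps, skeleton)
    zstack = compute_zscores(patient_maps, reference)
    cmasks = build_compartment_masks(
        skeleton, ventricle, lesion_maps,
        dilation_iterations=config.pv_dilation_iterations)
    from .compartments import average_by_compartment  # local to avoid cycle confusion
    features = average_by_compartment(zstack, cmasks)

    lesion_voxels = cmasks.lesion_skeleton.reshape(n_pat, -1).sum(axis=1)
    subject_table = generate_outcomes(config, features, lesion_voxels, r_out)

    truth = {
        "outcome_weights": config.weight_vector(),
        "generative_columns": config.generative_columns(),
        "features": features,
        "severity_shared": d,
        "severity_cell": b,
        "compartment_voxels": {
            c: int(partition_compartments(cmasks, 0)[c].sum()) for c in COMPARTMENTS
        },
    }
    return SyntheticCohort(
        config=config,
        skeleton_mask=skeleton,
        ventricle_mask=ventricle,
        lesion_maps=lesion_maps,
        metric_maps=metric_maps,
        subject_table=subject_table,
        truth=truth,
    )
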