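"""End-to-end orchestration: simulate/ingest -> z-score -> compartments ->
PLS per outcome, plus the descriptive stages (lesion probability map, group
volume comparisons, lesion-load correlation).

The report is a plain JSON-serialisable dictionary whose every number comes
from a stage output; provenance records the config hash, seed and library
versions, so two runs with identical configuration are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from .compartments import build_compartment_masks, average_by_compartment
from .config import StudyConfig
from .constants import feature_columns
from .io import save_cohort, save_features, save_nifti, load_cohort
from .pls import (fit_pls, impute_features, permutation_test,
                  select_latent_variables, vip_scores)
from .stats import (compare_group_volumes, correlate_lesion_load,
                    lesion_probability_map)
from .synthetic import generate_cohort
from .zscore import compute_zscores, fit_control_reference

__all__ = ["run_pipeline", "analyse_outcome"]

log = logging.getLogger("compartpls")


def _config_hash(config: StudyConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def analyse_outcome(
    features,
    y,
    options,
    seed: int | None = None,
) -> dict[str, Any]:
    """Fit PLS for one outcome and run the full inference recipe.

    Components are extracted up to ``options.max_components``; each gets a
    permutation p-value on its cross-covariance singular value; the leading
    run of components that are significant (p < alpha) and explain at least
    ``y_variance_threshold`` of Y is retained, and VIP scores are computed
    over the retained components (over the first component when none is
    retained, flagged ``significant: false``).
    """
    X = impute_features(features, options.impute)
    y = np.asarray(y, dtype=float)
    if options.impute == "drop":
        keep = X.index
        y = y[[list(features.index).index(i) for i in keep]]
    n, p = X.shape
    r = min(options.max_components, n - 1, p)
    model = fit_pls(X.to_numpy(), y, n_components=r, scale=options.scale)

    rng = np.random.default_rng(seed)
    perms = [
        permutation_test(X.to_numpy(), y, component=a + 1,
                         n_permutations=options.n_permutations,
                         seed=rng, scale=options.scale)
        for a in range(r)
    ]
    p_values = np.array([pr.p_value for pr in perms])
    retained = select_latent_variables(
        model.explained_y, p_values,
        alpha=options.alpha, y_variance_threshold=options.y_variance_threshold)
    vip_components = retained if retained > 0 else 1
    vip = vip_scores(model, vip_components, columns=list(features.columns))

    cols = list(features.columns)
    return {
        "n_patients": int(n),
        "n_predictors": int(p),
        "components_tested": int(r),
        "retained_components": int(retained),
        "significant": bool(retained > 0),
        "permutation_p": [float(v) for v in p_values],
        "singular_values": [float(v) for v in model.singular_values],
        "explained_y": [float(v) for v in model.explained_y],
        "explained_x": [float(v) for v in model.explained_x],
        "loadings_lv1": dict(zip(cols, map(float, model.x_loadings[:, 0]))),
        "weights_lv1": dict(zip(cols, map(float, model.weights[:, 0]))),
        "vip": dict(zip(cols, map(float, vip.vip))),
        "vip_selected": vip.selected_columns(),
        "n_permutations": int(options.n_permutations),
    }


def run_pipeline(config: StudyConfig, out_dir: str | Path | None = None) -> dict[str, Any]:
    """Execute the whole study and return the JSON-serialisable report.

    When ``out_dir`` is given, all intermediates are persisted there
    (cohort volumes, feature TSV, lesion probability map, report.json).
    """
    config.validate()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    # stage 1: simulate or ingest ------------------------------------
    if config.simulate is not None:
        log.info("stage simulate: generating synthetic cohort (seed=%d)",
                 config.simulate.seed)
        cohort = generate_cohort(config.simulate)
    else:
        log.info("stage ingest: loading cohort from %s", config.input_dir)
        cohort = load_cohort(config.input_dir)
    if out is not None and config.simulate is not None:
        save_cohort(cohort, out / "cohort")

    table = cohort.subject_table
    patients = table[table["group"] == "patient"].reset_index(drop=True)
    controls = table[table["group"] == "control"].reset_index(drop=True)

    # stage 2: z-scores ----------------------------------------------
    log.info("stage zscore: fitting control reference (q=%d)", len(controls))
    reference = fit_control_reference(cohort.control_maps(), cohort.skeleton_mask)
    zstack = compute_zscores(cohort.patient_maps(), reference,
                             patient_ids=cohort.patient_ids)

    # stage 3: compartments ------------------------------------------
    log.info("stage compartments: dilation=%d threshold=%.2f",
             config.dilation_iterations, config.lesion_threshold)
    masks = build_compartment_masks(
        cohort.skeleton_mask, cohort.ventricle_mask, cohort.lesion_maps,
        dilation_iterations=config.dilation_iterations,
        lesion_threshold=config.lesion_threshold)
    features = average_by_compartment(zstack, masks)
    if out is not None:
        save_features(features, out / "features.tsv")

    # stage 4: PLS per outcome ---------------------------------------
    ss = np.random.SeedSequence(config.seed)
    outcome_seeds = ss.generate_state(len(config.outcomes))
    pls_reports: dict[str, Any] = {}
    for name, oseed in zip(config.outcomes, outcome_seeds):
        if name not in patients.columns:
            raise ValueError(f"outcome {name!r} missing from the subject table")
        log.info("stage pls: outcome=%s B=%d", name, config.pls.n_permutations)
        y = patients[name].to_numpy()
        pls_reports[name] = analyse_outcome(features, y, config.pls, seed=int(oseed))

    # stage 5: descriptive stats -------------------------------------
    lesion_binary = masks.lesion_skeleton
    prob_map = lesion_probability_map(lesion_binary)
    if out is not None:
        save_nifti(prob_map.astype(np.int16), out / "lesion_probability_map.nii.gz")

    volumes = {}
    for vol in ("brain_volume", "gm_volume", "wm_volume"):
        cmp = compare_group_volumes(patients[vol], controls[vol])
        volumes[vol] = {
            "patient_mean": cmp.mean_a, "control_mean": cmp.mean_b,
            "u_statistic": cmp.u_statistic, "p_value": cmp.p_value,
            "ks_p_patients": cmp.ks_p_a, "ks_p_controls": cmp.ks_p_b,
        }

    lesion_corr = {}
    for name in ("gm_volume", "brain_volume", "edss"):
        if name not in patients.columns:
            continue
        try:
            res = correlate_lesion_load(patients["norm_lesion_volume"], patients[name])
            lesion_corr[name] = {"r": res.r, "p_value": res.p_value, "n": res.n}
        except ValueError as exc:
            lesion_corr[name] = {"error": str(exc)}

    report = {
        "provenance": {
            "config_hash": _config_hash(config),
            "seed": int(config.seed),
            "compartpls_version": __version__,
            "numpy_version": np.__version__,
        },
        "cohort": {
            "n_patients": int(len(patients)),
            "n_controls": int(len(controls)),
            "grid_shape": list(cohort.skeleton_mask.shape),
            "skeleton_voxels": int(cohort.skeleton_mask.sum()),
            "pv_skeleton_voxels": int((masks.skeleton & masks.pv_mask).sum()),
            "mean_lesion_load": float(patients["lesion_volume"].mean()),
            "mean_norm_lesion_load": float(patients["norm_lesion_volume"].mean()),
        },
        "feature_columns": feature_columns(),
        "pls": pls_reports,
        "group_volumes": volumes,
        "lesion_load_correlation": lesion_corr,
        "lesion_probability_max": int(prob_map.max()),
    }
    if out is not None:
        (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
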