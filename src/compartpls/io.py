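"""NIfTI / TSV / JSON persistence for cohorts and analysis products."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .config import CohortConfig
from .constants import METRICS, column_metadata

__all__ = [
    "save_nifti", "load_nifti",
    "save_cohort", "load_cohort",
    "save_features", "load_features",
]

_AFFINE = np.eye(4)  # voxel-indexed grids, shared identity affine


def save_nifti(array: np.ndarray, path: str | Path) -> None:
    arr = np.asarray(array)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    nib.save(nib.Nifti1Image(arr, _AFFINE), str(path))


def load_nifti(path: str | Path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)


def save_cohort(cohort, out_dir: str | Path) -> None:
    """Write a cohort as NIfTI volumes + TSV subject table + JSON sidecars.

    Layout: ``masks/`` (skeleton, ventricles), ``lesions/<id>_lesion.nii.gz``,
    ``maps/<id>_<metric>.nii.gz``, ``subjects.tsv``, ``cohort.yaml``,
    ``truth.json``.
    """
    out = Path(out_dir)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    (out / "lesions").mkdir(exist_ok=True)
    (out / "maps").mkdir(exist_ok=True)
    save_nifti(cohort.skeleton_mask, out / "masks" / "skeleton.nii.gz")
    save_nifti(cohort.ventricle_mask, out / "masks" / "ventricles.nii.gz")
    pids = cohort.patient_ids
    for j, pid in enumerate(pids):
        save_nifti(cohort.lesion_maps[j].astype(np.float32),
                   out / "lesions" / f"{pid}_lesion.nii.gz")
    ids = list(cohort.subject_table["subject_id"])
    for m in METRICS:
        arr = cohort.metric_maps[m]
        for i, sid in enumerate(ids):
            save_nifti(arr[i].astype(np.float32), out / "maps" / f"{sid}_{m}.nii.gz")
    cohort.subject_table.to_csv(out / "subjects.tsv", sep="\t", index=False)
    cohort.config.to_yaml(out / "cohort.yaml")
    truth = {
        "outcome_weights": list(map(float, cohort.truth["outcome_weights"])),
        "generative_columns": cohort.truth["generative_columns"],
        "compartment_voxels": cohort.truth["compartment_voxels"],
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))


def load_cohort(in_dir: str | Path):
    """Read a cohort directory written by :func:`save_cohort`."""
    from .synthetic import SyntheticCohort  # deferred: io must not depend on rng code

    src = Path(in_dir)
    config = CohortConfig.from_yaml(src / "cohort.yaml")
    table = pd.read_csv(src / "subjects.tsv", sep="\t")
    skeleton = load_nifti(src / "masks" / "skeleton.nii.gz").astype(bool)
    ventricle = load_nifti(src / "masks" / "ventricles.nii.gz").astype(bool)
    ids = list(table["subject_id"])
    pids = list(table.loc[table["group"] == "patient", "subject_id"])
    lesion_maps = np.stack([
        load_nifti(src / "lesions" / f"{pid}_lesion.nii.gz").astype(float) for pid in pids
    ])
    metric_maps = {
        m: np.stack([load_nifti(src / "maps" / f"{sid}_{m}.nii.gz").astype(float)
                     for sid in ids])
        for m in METRICS
    }
    truth = json.loads((src / "truth.json").read_text()) if (src / "truth.json").exists() else {}
    if "outcome_weights" in truth:
        truth["outcome_weights"] = np.asarray(truth["outcome_weights"], dtype=float)
    return SyntheticCohort(
        config=config, skeleton_mask=skeleton, ventricle_mask=ventricle,
        lesion_maps=lesion_maps, metric_maps=metric_maps,
        subject_table=table, truth=truth,
    )


def save_features(features: pd.DataFrame, path: str | Path) -> None:
    """Feature matrix as TSV plus a JSON column-metadata sidecar."""
    path = Path(path)
    features.to_csv(path, sep="\t", index_label="subject_id")
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({"columns": column_metadata()}, indent=2))


def load_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="subject_id")
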