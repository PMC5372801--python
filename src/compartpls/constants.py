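"""Fixed labels and column ordering shared across the package.

The four diffusion metrics are fractional anisotropy (FA, unitless),
mean diffusivity (MD), axial diffusivity (AD) and radial diffusivity
(RD), the diffusivities in mm^2/s.  The white-matter skeleton of each
patient is partitioned into four compartments by crossing the
periventricular mask with the patient's lesion mask:

* ``pv_lesion``     periventricular lesioned white matter
* ``nonpv_lesion``  non-periventricular lesioned white matter
* ``pv_nawm``       periventricular normal-appearing white matter
* ``nonpv_nawm``    non-periventricular normal-appearing white matter

The predictor matrix for the PLS stage has one column per
(metric, compartment) cell.  Column order is metric-major and fixed:
``FA_pv_lesion, FA_nonpv_lesion, ..., RD_nonpv_nawm``.
"""

from __future__ import annotations

METRICS: tuple[str, ...] = ("FA", "MD", "AD", "RD")

COMPARTMENTS: tuple[str, ...] = (
    "pv_lesion",
    "nonpv_lesion",
    "pv_nawm",
    "nonpv_nawm",
)

N_FEATURES = len(METRICS) * len(COMPARTMENTS)


def feature_columns() -> list[str]:
    """Fixed metric-major column order of the compartment feature matrix."""
    return [f"{m}_{c}" for m in METRICS for c in COMPARTMENTS]


def column_metadata() -> list[dict[str, str]]:
    """Per-column (metric, compartment) metadata, aligned with feature_columns()."""
    return [
        {"column": f"{m}_{c}", "metric": m, "compartment": c}
        for m in METRICS
        for c in COMPARTMENTS
    ]
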