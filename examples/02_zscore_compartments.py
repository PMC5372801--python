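"""From metric maps to the 16-column compartment feature matrix.

Fits the per-voxel control reference (mean and population SD over the 16
controls), z-scores every patient map against it, partitions each patient's
skeleton into the four periventricular x lesion compartments, and averages
the z-scores per compartment.  The printed column means show the
demyelination-like group effect: MD/RD z-scores elevated (strongest in
lesions and the periventricular band), FA depressed, AD near zero outside
the central fibres.
"""

from compartpls import (CohortConfig, average_by_compartment,
                        build_compartment_masks, compute_zscores,
                        fit_control_reference, generate_cohort)

cfg = CohortConfig(n_patients=20, n_controls=16, grid_shape=(16, 16, 16),
                   ventricle_seeds=((6, 8, 8), (10, 8, 8)), seed=7)
cohort = generate_cohort(cfg)

reference = fit_control_reference(cohort.control_maps(), cohort.skeleton_mask)
zstack = compute_zscores(cohort.patient_maps(), reference,
                         patient_ids=cohort.patient_ids)
masks = build_compartment_masks(cohort.skeleton_mask, cohort.ventricle_mask,
                                cohort.lesion_maps, dilation_iterations=3)
features = average_by_compartment(zstack, masks)

print("feature matrix:", features.shape)
print("\nmean compartment z-score per cell:")
print(features.mean().round(2).to_string())
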