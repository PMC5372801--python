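# compartpls

Compartmental white-matter analysis for multiple sclerosis imaging studies:
voxel-wise z-scoring of skeleton-space diffusion metrics against a control
cohort, four-way periventricular × lesion compartmentalisation of the
white-matter skeleton, and partial least squares (PLS) regression of atrophy
and disability outcomes with permutation inference and VIP-based variable
selection. A seeded synthetic cohort generator reproduces the statistical
structure the analysis assumes, so the whole pipeline runs and is testable
without any imaging data.

## Who it is for

Neuroimaging groups asking *which* white-matter pathology — focal lesions vs
normal-appearing tissue, periventricular vs deep — best explains gray-matter
atrophy and clinical disability, when the predictors (diffusion metrics per
compartment) are strongly collinear and ordinary regression is unreliable.

## The model

For each diffusion metric X ∈ {FA, MD, AD, RD} and each skeleton voxel *n*,
the q controls define a reference

&nbsp;&nbsp;&nbsp;&nbsp;X̄ₙ = (1/q) Σᵢ Xₙ,ᵢ ,&nbsp;&nbsp;
δₙ = √( (1/q) Σᵢ (X̄ₙ − Xₙ,ᵢ)² ) ,&nbsp;&nbsp;
Z_{X,n,j} = (Xₙ,j − X̄ₙ)/δₙ ,

with *i* indexing controls and *j* patients. The ventricle mask dilated by
three voxels (26-connected kernel) defines the periventricular band; each
patient's lesion map, thresholded at 0.5 and intersected with the skeleton,
splits it further into **periventricular lesioned**, **non-periventricular
lesioned**, **periventricular normal-appearing** and **non-periventricular
normal-appearing** white matter. Averaging Z over each (metric, compartment)
cell gives a patients × 16 predictor matrix **X**.

PLS decomposes predictors and outcome as **X** = T Pᵀ + E, **Y** = U Qᵀ + F,
extracting latent variables whose X-scores maximise covariance with the
outcome (gray-matter volume, brain volume, or EDSS). Each latent variable is
tested by permuting the rows of **Y** (default 5,000 times) and recomputing
the cross-covariance singular value; components are retained while they are
significant and explain ≥ 5 % of the outcome variance. Predictor importance
uses Wold's VIP score, whose squares average to 1, with the conventional
"VIP > 1" selection rule.

## Worked example

`examples/04_full_pipeline.py` simulates the default study (52 patients,
50 controls, 32³ grid) and runs every stage:

```
gm_volume     retained LVs=1 p(LV1)=0.001 explained Y=47.0% X=34.1%
              VIP>1: MD_pv_lesion, MD_nonpv_lesion, MD_pv_nawm, MD_nonpv_nawm,
                     RD_pv_lesion, RD_nonpv_lesion, RD_pv_nawm
...
group volumes (Mann-Whitney):
  brain_volume  patients 710.4 vs controls 776.0 cm^3, p=0.009675
  gm_volume     patients 395.2 vs controls 433.9 cm^3, p=0.02603
  wm_volume     patients 313.3 vs controls 342.5 cm^3, p=0.04427
```

Reading: the first latent variable is significant (permutation p = 0.001)
and explains 47 % of the simulated gray-matter volume; the VIP > 1 set
recovers the generative pattern — mean and radial diffusivity of the
lesioned compartments and the periventricular normal-appearing white matter
drive the atrophy, while FA/AD cells and the deep normal-appearing white
matter stay below threshold. Patients show the configured volume reduction
in all three tissue classes. The other examples walk the individual stages
(simulation, z-scoring + compartments, PLS inference).

A thin CLI wraps the same calls:

```bash
compartpls simulate --out cohort/ --seed 7
compartpls run-all --out results/ --seed 7
compartpls pls --features features.tsv --subjects subjects.tsv \
    --outcome gm_volume --permutations 5000 --seed 7 --out report.json
```

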