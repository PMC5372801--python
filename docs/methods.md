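# Methods

This note documents the statistical model, the synthetic-data generator, the
numerical choices and the known limitations of `compartpls`.

## Analysis model

### Voxel-wise z-scores

Patient maps are standardised voxel-by-voxel against the control cohort:
Z = (X − X̄)/δ, with X̄ the control mean and δ the control **population**
standard deviation (divisor q). A `ddof=1` switch selects the sample SD; the
population convention is the default because the reference is treated as a
fixed normative distribution, not an estimate whose uncertainty is
propagated. Voxels with δ = 0 are flagged degenerate and yield NaN — never
±inf — and are excluded from compartment averages. Z-scores are affine
invariant: rescaling a metric's maps by a > 0 and shifting by b leaves Z
unchanged, so unit conventions (e.g. mm²/s vs µm²/ms) do not matter.

### Compartments

The periventricular band is the ventricle mask dilated `iterations` times
(default 3) with the full 3×3×3 structuring element, i.e. a Chebyshev-ball
growth of 3 voxels; a 6-connected option exists. Lesion maps, continuous in
[0, 1] after interpolation, are re-binarised with an **inclusive** 0.5
threshold (a voxel at exactly 0.5 counts as lesion; the intent of the
threshold is to avoid interpolation-driven mask growth, and the inclusive
convention keeps half-weight voxels rather than discarding them) and
intersected with the skeleton. Crossing the two labels yields four
compartments that are disjoint and exhaustive on the skeleton by
construction. The feature matrix averages **z-scores** (not raw metric
values) per cell; an empty compartment (e.g. a patient without
periventricular lesions) produces a missing cell, which the PLS stage
imputes with the column mean over patients (option: drop the patient).

### PLS, permutation test, VIP

PLS1 components are extracted NIPALS-style with Y-deflation: the weight
vector w (unit norm) is the left singular vector of the cross-covariance
XᵀY — for univariate Y simply Xᵀy normalised — which maximises cov(Xw, Y);
scores t = Xw; loadings by regression of each block on t; both blocks
deflated. Predictor columns are standardised by default (the 16 cells mix
z-score scales across metrics and compartments; a `scale=False` switch
preserves the unscaled variant), Y is centred.

Residual conventions: E = X − TPᵀ exactly. For the Y block the
exact-by-construction decomposition under Y-deflation is the regression
(inner-relation) form Y = TQᵀ + F; the Y-block scores U are retained as
diagnostics of the inner relation rather than entering the residual
definition. Weight-vector signs are fixed so each column's
largest-magnitude element is positive, making loadings reproducible across
runs.

The permutation test permutes the rows of Y uniformly (B = 5,000 by
default) and recomputes the component's cross-covariance singular value;
p = (1 + #{null ≥ observed})/(B + 1). The add-one correction keeps p > 0
and makes the test exact-to-conservative at any B. For the first component
the null is computed vectorised (matrix product over all permuted columns);
higher components re-run the deflation per permutation. Components are
retained while p < α (0.05) **and** explained Y-variance ≥ 5 %, scanning in
order and stopping at the first failure.

VIP_j = √( p · Σₐ SSYₐ w²ⱼₐ / Σₐ SSYₐ ) over the retained components, with
SSYₐ the Y-variance explained by component a. Since the weights have unit
norm, mean(VIP²) = 1 identically, which the test suite asserts on
randomised fits; selection uses the standard VIP > 1 rule.

### Descriptive stages

Lesion probability map = per-voxel sum of binary patient masks. Volume
normalisation multiplies native volumes by the head-size scaling factor v.
Group volume comparisons use the two-sided Mann-Whitney U test (scipy, exact
method where applicable), with a Kolmogorov-Smirnov normality screen per
group reported alongside as the rationale for the rank test. The
lesion-load/outcome correlation defaults to Pearson, Spearman switchable.

## Synthetic cohort generator

The generator's defaults *are* the study conditions: 52 patients, 50
controls, a 32³ grid standing in for the 1 mm template space, 10 % skeleton
fraction, two ventricle seed boxes dilated by 3 voxels into the
periventricular band, lesion rates 0.30 (periventricular) vs 0.05
(elsewhere), and demyelination-like z-effects — MD/RD raised and FA lowered
in all compartments with the largest shifts in lesions and the
periventricular band, AD raised only inside a central Chebyshev ball
(radius 0.25 × grid size), mirroring effects confined to central fibres.
Control metric levels (FA 0.45 ± 0.08; MD 0.8 ± 0.06, AD 1.2 ± 0.09,
RD 0.6 ± 0.06, diffusivities ×10⁻³ mm²/s) are typical healthy skeleton
values; the control variance magnitudes are free parameters of the design,
set once at these values.

Between-patient variation follows a one-factor-plus-idiosyncratic severity
model: the voxel shift of patient j in cell (metric, compartment) c is
effect_z(c) · (1 + λ_c d_j + τ b_{j,c}) · control_sd, with d_j a shared
"demyelination severity" standard normal, b cell-specific standard normals,
τ = 0.2, and λ_c = 0.4 for MD/RD of the lesioned and periventricular
normal-appearing compartments but 0.05–0.08 elsewhere. The asymmetric
couplings are what make the six strongly coupled cells genuinely better
outcome predictors than the remaining proxy cells after column
standardisation — the qualitative separation the real study reports — and
were fixed a priori from this variance arithmetic: a cell's correlation
with the shared factor is λ/√(λ² + τ²), ≈ 0.89 for coupled and ≈ 0.37 for
uncoupled cells, which leaves the uncoupled cells' outcome correlation
(≈ 0.2–0.3) safely below the VIP > 1 boundary at n = 52. The multiplier is
not truncated; negative severities (probability ≈ 1 %) merely flip a
patient's shift and keep the mean effect unbiased, so the compartment-mean
z-score recovers effect_z exactly in expectation.

Outcomes are generated from the **realised** feature matrix, computed
through the real z-score and compartment modules (never short-circuited):
s = features · w with generative weights w = 1 on MD/RD of
{PV-lesioned, non-PV-lesioned, PV-normal-appearing} and 0 elsewhere. With
the R² parameterisation (default 0.5), outcome = baseline ± √R²·σ·ŝ +
√(1−R²)·σ·ε, where ŝ is the standardised linear predictor and σ the
outcome's configured spread; volumes decrease with damage, EDSS increases.
Setting `outcome_noise_sd` (e.g. 0) switches to an additive
baseline − (s − s̄) + noise form for exact-collinearity tests. Volume
baselines and spreads match the reported group means and SE·√n; EDSS is
clamped to [0, 10] and rounded to 0.5 steps; controls draw volumes from the
higher control baselines and have no EDSS. Lesion load converts the lesioned
skeleton voxel count with a nominal voxel volume (0.0055 cm³) chosen to put
the mean native load near the reported ≈ 12 cm³ scale.

Lesion maps are drawn binary and blurred with a Gaussian of σ = 0.4 voxels
to emulate interpolation partial-voluming; σ is kept below ~0.5 voxel so
the inclusive 0.5 re-threshold recovers the drawn lesions (a larger blur
would silently erase isolated deep-white-matter lesions and empty the
non-periventricular lesioned compartment).

### What the generator does not emulate

Control voxel values are independent Gaussians per voxel — no spatial
autocorrelation, no tract geometry, no partial-volume structure in the
metric maps themselves. Downstream statistics operate on compartment
*averages*, which are insensitive to within-compartment correlation for
recovery testing, but passing tests say nothing about spatially structured
noise, registration error, or real lesion morphology. The skeleton is a
Bernoulli voxel set, not a thin connected sheet; the "ventricles" are
boxes. Acquisition, tensor fitting, registration and skeleton projection
are all outside the model: generation happens directly in skeleton space.

## Numerical choices

- Degenerate PLS branches: if the cross-covariance vanishes (Y orthogonal
  to X) extraction stops; trailing components keep zero weights, scores and
  explained variance, and the first singular value is reported as 0.
- Constant Y is rejected by `fit_pls` but handled gracefully by
  `permutation_test` (all null values equal the observed value, p = 1).
- Zero-variance predictor columns receive scale 1 (they are centred to zero
  and contribute nothing).
- Singular-value ties in the permutation null are counted with a 1e-12
  tolerance on the ≥ comparison.
- All randomness flows through `numpy.random.Generator` seeded from a
  single integer via `SeedSequence.spawn`, one child stream per generation
  stage; identical configs give bit-identical cohorts and reports.
- NIfTI volumes are written with an identity affine (voxel-indexed,
  0-based); metric maps round-trip through float32 on disk, so ingest-mode
  results agree with in-memory results to storage precision (~1e-6).

## Test-suite problem sizes

The suite exercises the calibration properties at sizes chosen to keep a
laptop run under a couple of minutes: the null-calibration study uses 200
replicate cohorts on a 16³ grid with the full 52 + 50 subjects and 499
permutations (compartment averages under zero effect are scale-free, so the
grid size only affects Monte-Carlo noise); the parameter-recovery study
uses the full 32³ design across 50 seeds with 999 permutations; smaller
unit fixtures use 12³–16³ grids with 8–30 subjects.

## Known limitations

- Only univariate outcomes are analysed end-to-end; `fit_pls` accepts a
  multivariate Y (SVD-based weights per component) but the pipeline fits
  each outcome separately.
- Reported loadings are on the standardised-predictor scale; they are
  comparable across cells in pattern and sign, not in raw-metric units.
- Mean imputation of empty compartments keeps the design size but shrinks
  that cell's variance for the affected patients; with realistic lesion
  rates empty compartments are rare.
- The permutation test addresses each component's significance
  marginally; no multiplicity correction is applied across the (at most
  three) components or across outcomes, matching common practice for this
  design.
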