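# Methods

This note documents the models and procedures implemented in
`ftdindex`, the defaults chosen where the design was genuinely open, and
the limits of what the synthetic cohorts can demonstrate.

## Normalization chain

Regional volumes are corrected in a fixed order, calibrated on a
reference group (default: all non-FTD subjects of the training data;
configurable, e.g. to SCD only):

1. **Head size.** Proportional scaling `v' = v · T̄/t`, where `t` is the
   subject's total intracranial volume (TIV) and `T̄` the reference-group
   mean TIV. This assumes regional volume scales linearly through the
   origin with cranial capacity — the simplest defensible model, and it
   makes the correction exactly invariant to a common rescaling of a
   subject's volumes and TIV.
2. **Age and sex.** Per-region ordinary least squares of `v'` on
   `(age − ā)` and a male indicator within the reference group
   (`ā` = reference mean age); the fitted slopes are subtracted at
   application time. Because the design matrix is shared across regions,
   all 133 regressions are solved in one `lstsq` call.
3. **Field strength (optional, off by default).** Additive per-region
   offsets of the scanner field (1/1.5/3 T) relative to the most common
   level, fitted jointly with stage 2. Off by default because the
   correction is a second-order effect relative to head size and age.

The order matters (scaling rescales the age slope); it is fixed as
head size first, then residualization, and tested against an
explicit two-step oracle. Corrected volumes are floored at
ε = 0.001 ml so downstream log-ratios stay defined; flooring events are
reported as warnings. Fitting requires at least 10 reference subjects
per fitted coefficient; zero-variance covariates get a zero coefficient
with a warning rather than an error.

## Index construction

**Weights.** For an anterior-side region,
`w = (mean_AD − mean_FTD)/mean_nonFTD`; for a posterior-side region the
difference is reversed. Negative weights are clamped to zero — the
weight map is a one-signed template of "where FTD loses more than AD" —
and the parahippocampal and inferior temporal gyri (both hemispheres)
are excluded from the API map as anatomical outliers (configurable; the
regions are located by name pattern so user atlases work too). No
further thresholding of small weights is applied.

**Ratios and calibration.** API and ASI are natural logarithms of
weighted volume ratios; the log base only rescales (μ, σ) and leaves the
z-score unchanged. μ and σ are the sample mean and SD (n−1) of the raw
value over the non-FTD calibration subjects, so reference z-scores have
mean 0 and SD 1 by construction. TPL is the single normalized left
temporal pole volume passed through the same z-transform.

**ASI weights.** Whether the asymmetry weights should be re-estimated
per hemisphere or inherited from the anterior contrast is open; the
default computes the anterior-contrast weight for every frontotemporal
region and then averages each left/right homologue pair (pairs are
found by stripping hemisphere name markers). Symmetrized weights make
the index exactly mirror-antisymmetric: swapping all left/right volumes
negates the raw value. `asi_weight_mode="independent"` skips the
symmetrization. ASI classification is two-sided on |z| by default,
since right-lateralized cases sit on the opposite tail of the
left-atrophic ones; one-sided classification is available.

**Classification.** Strictly `z < cutoff`, default cutoff −1.65. Under
a normal reference this yields ≈95% specificity
(`Φ(−1.6449) = 0.05`); the parametric cutoff rule returns
`mean + sd · Φ⁻¹(1 − target)` and is the default, with an empirical
order-statistic alternative (largest cutoff keeping the at-or-above
fraction of reference scores ≥ target). For subtype separation, where
high specificity matters less, an optimal cutoff maximizing
(sensitivity+specificity)/2 is provided; candidates are midpoints
between adjacent distinct scores and ties resolve to the more specific
(smaller) cutoff.

## Evaluation

AUC is the trapezoidal area of the empirical ROC (scores negated
internally so that lower = more positive); it equals the pairwise
concordance probability with ties counted half, which the tests verify
against a brute-force oracle to 1e−12. Likelihood ratios are
`LR+ = sens/(1−spec)` and `LR− = (1−sens)/spec`, reported as undefined
(not a number) at the degenerate specificities.

Cross-validation uses stratified k-fold (default k = 10) on the
diagnosis label, so rare groups (e.g. nfvPPA) appear in every training
split. Within each split the normalization model, the region weights
and (μ, σ) are fitted on the training folds only and applied to the
held-out fold; held-out z-scores are pooled across folds and all metrics
computed once on the pool (pooling matches reporting a single AUC per
comparison; per-fold parameters are retained in the report for audit).
The cutoff is fixed at −1.65 from calibration and the *observed*
specificity on held-out data is reported. A leakage test poisons a test
fold and asserts the corresponding training parameters are unchanged.

Age stratification splits at strictly-below-70 vs at-or-above.

## bvFTD subtype clustering

bvFTD subjects are clustered on z-standardized volumes of an 18-ROI
panel spanning frontal, temporal, insular and subcortical territory
(defaults listed in `subtype_clustering.DEFAULT_ROI_SET`; fully
configurable since ROI identity is atlas-dependent). Standardization is
against a reference group (default SCD) or internal. Linkage is Ward on
Euclidean distance (complete/average selectable), the tree is cut at
k = 4 by default, and cluster labels are renumbered by decreasing mean
atrophy so results are reproducible across subject orderings; the last
merge heights are reported for users choosing k. Each cluster is
characterized against reference groups with per-region Welch tests and
Benjamini–Hochberg correction across the ROI set — a region-level
analogue of voxel-based contrast maps, not a reproduction of them.
The cluster-by-API crosstab reports, per cluster, the counts below vs
at-or-above the −1.65 cutoff and each cluster's share of all
above-cutoff cases.

## Synthetic cohorts

The generator emulates the statistical structure the indices assume.
Per subject: sex (group-specific female fraction), age (group normal,
clipped to 40–95), TIV (sex-specific normal: 1420 ± 110 ml female,
1560 ± 120 ml male), then each regional volume = fixed template mean ×
(TIV/1500) × (1 − slope·(age−65)) with slope 0.3%/yr cortical and
0.15%/yr subcortical, × the group's fractional atrophy reductions
(overlapping region sets compound multiplicatively), × lognormal noise
(σ = 0.05 on the log scale). Template means are shipped constants;
their absolute levels cancel in the ratio indices.

Default case mix: 1213 subjects (341 AD, 66 DLB, 40 VaD, 104 other,
229 MCI, 317 SCD, 116 FTD split 64 bvFTD / 30 svPPA / 8 nfvPPA /
10 rtvFTD / 4 +MND); a 200-subject validation preset (110 AD, 20 DLB,
28 VaD, 18 SCD, 24 FTD split 10/12/2) uses a disjoint random stream so
the two cohorts never share subjects. Default atrophy profiles:
bvFTD anterior −15% (with half the bvFTD subjects instead drawn from a
subcortical-predominant profile: subcortical −20%, anterior −5%);
svPPA left temporal pole −30% plus left temporal −15%; nfvPPA left
frontal −15%; rtvFTD right temporal −20%; +MND anterior −10%;
AD temporoparietal and hippocampal −15%; MCI a mild AD pattern;
VaD/DLB/Other mild subcortical or global loss; SCD none. Demographics
follow the published group means (e.g. FTD ≈ 63 ± 7 y, SCD 62 ± 9 y).

**What the simulation does not emulate** — and hence what passing tests
do not show about real data: spatial covariance between neighboring
regions (noise is independent per region), scanner/site batch structure
beyond a global field-strength factor, non-linear aging, disease
heterogeneity beyond the listed archetypes, and diagnostic label noise.
Two consequences are worth knowing. First, independent noise averages
out across the many regions in each weighted sum, so the synthetic API
separates groups more cleanly than any clinical cohort would; its AUC
here characterizes the pipeline, not expected clinical performance.
Second, the synthetic AD profile reduces the *entire* temporal cortex,
which cancels the AD-vs-FTD contrast in temporal regions and clamps
their ASI weights to zero — in real data AD temporal atrophy is
medial-predominant, leaving lateral temporal weights informative — so
ASI discriminates the aphasic variants only weakly on the default
synthetic cohort while TPL (which bypasses the weight map) separates
svPPA essentially perfectly.

A related caveat: because negative weights are clamped, weight learning
selects chance contrasts; on an effect-free cohort the *in-sample* API
AUC is well above 0.5. The chance-level-at-null property therefore
holds — and is tested — on held-out (cross-validated) scores.

## Problem sizes and runtime choices

Tests and the acceptance script run the full pipeline at the default
cohort sizes (1213 training / 200 validation subjects, 133 regions,
10-fold CV). Replicated simulation checks (null-AUC calibration,
effect-size monotonicity, FDR control) use 3–20 replicates at
60-subject-per-group scale and 500 null replicates for the BH check,
with pre-stated 2-SD Monte Carlo allowances on stochastic assertions.
Determinism: every stochastic routine takes an explicit seed; cohort
generation is a pure function of (config, seed).
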