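# Methods

This note documents the models, procedures, parameter choices and known
limitations of `lcnm`. It is written for users who need to judge what the
package computes and what its validation on synthetic phantoms does and
does not establish.

## The measurement model

Neuromelanin-sensitive fast-spin-echo T1 MRI renders the locus coeruleus
(LC), a thin noradrenergic nucleus in the dorsal pons, as a pair of small
hyperintense foci. The package quantifies LC integrity per subject as a
contrast ratio between LC signal and the adjacent pontine tissue,
separately for the rostral, middle and caudal thirds of the nucleus.

**Slice normalization.** 2-D multi-slice FSE acquisitions show
multiplicative slice-to-slice intensity drift. Each axial slice is rescaled
by `global in-mask mean / slice in-mask mean`, with means taken over a
brain mask. The global mean is used as the target so the overall intensity
scale is preserved; the contrast ratio is in any case invariant to a global
scale. Slices with no mask voxels are left unscaled and logged. In the
phantom, the normalization mask excludes the dorsal-pons box containing the
LC tubes, search ROIs and background ROI, so every slice has identical
in-mask composition and per-slice gains cancel exactly; this mirrors the
requirement that scaling must not be driven by the LC hyperintensity
itself.

**Tri-section.** Each LC search ROI is partitioned by axial slice index
into three contiguous blocks; the rostral block is the most superior. When
the slice count is not divisible by three, remainder slices are assigned
rostral-first ((3,3,2) for 8 slices). The standard ROIs divide exactly, so
any consistent rule is admissible; the rule is fixed and shared between the
extractor and the phantom generator.

**Five brightest connected voxels.** Within each sub-ROI the statistic of
interest is the mean of the five brightest *connected* voxels. This is
operationalized as the exact maximizer of the mean over all connected
5-voxel subsets (26-neighborhood by default, configurable to 18 or 6),
found by branch-and-bound: voxels are ordered by decreasing intensity,
subsets are enumerated canonically by their brightest member, a multi-seed
greedy solution provides the incumbent, and two bounds (no root dimmer than
the incumbent mean; partial sums that cannot reach it) prune the search.
Sub-ROIs hold tens of voxels, so the exact search costs milliseconds; ROIs
beyond 4000 voxels fall back to the greedy variant, which is also available
explicitly (`method="greedy"`). The exact implementation is verified in the
test suite against brute-force enumeration of all connected 5-subsets.

**Contrast and background.** The contrast is
`(roi_mean − background_mean) / background_mean`. Following the processing
description this package implements, the background value is obtained with
the *same* five-brightest-connected extraction applied to a background ROI
in the central/median pons, restricted by default to the axial slices of
the sub-ROI being measured (`background_extent="per-subregion"`). This
choice matters for accuracy: the maximum-mean estimator is upward-biased
under noise, and when numerator and denominator are extracted from pools of
matching geometry the bias cancels almost exactly in the ratio (measured
residual bias ≈ −0.003 at the default noise level, versus ≈ −0.008 for a
whole-ROI background and ≈ +0.013 for a plain-mean background). The plain
mean (`background_method="mean"`) and whole-ROI extent remain available.
Left and right contrasts are averaged with an unweighted mean.

## PET SUVR

SUVR images divide voxel-wise uptake by the *median* uptake in a reference
region (occipital in the motivating design, arbitrary mask here); the
median makes the denominator robust to a few extreme voxels and the SUVR
invariant to global uptake rescaling. Smoothing is a separable Gaussian
with per-axis σ = FWHM / √(8 ln 2) / voxel size (8 mm FWHM default) and
reflective boundaries, which preserve total intensity near edges to < 0.1%
for interior-supported images. Partial-volume-effect correction is
deliberately out of scope; statistics run on non-PVE-corrected images.

## Permutation inference

**Omnibus.** Group differences per subregion are tested with an
ANCOVA-type F for the group factor (cell-means design plus covariates,
reduced model intercept + covariates) and a Freedman–Lane permutation null:
the nuisance-only model is fitted, its residuals are permuted and re-added
to the nuisance fit, and F is recomputed. With age as the only covariate
and n = 47 this yields the familiar F(2, 43) layout. Monte-Carlo p-values
use the add-one estimator `(1 + #{F* ≥ F}) / (1 + n_perm)`, which is never
zero and keeps the test level-valid. When no covariates are present and the
number of distinct group relabelings (multinomial coefficient) fits within
the permutation budget, the null is enumerated exhaustively and the p-value
is the exact fraction; the same applies to the regressor relabelings of the
voxel-wise analysis when n! ≤ n_perm.

**Post hocs.** Six one-tailed pairwise contrasts (A>B and A<B per pair)
are evaluated as t statistics on the same Freedman–Lane permutations, with
family-wise error control by Bonferroni: `p_FWER = min(1, 6·p)`,
equivalent to testing at α/6. Post hocs are gated on a significant omnibus
in the pipeline (overridable). The default permutation count is 10,000 with
a mandatory explicit seed; both are recorded in every result.

**Spearman.** rho is the Pearson correlation of mid-ranks (tie-aware). For
n ≤ 10 the two-sided p is exact, enumerating all n! rank permutations; for
larger n the t approximation `t = rho·√((n−2)/(1−rho²))` on n−2 degrees of
freedom is used. Constant inputs yield an undefined rho with an explicit
flag.

**Descriptives.** Levene's test uses the median-centered Brown–Forsythe
variant; age differences use Kruskal–Wallis; sex tables use chi-square
without continuity correction; clinical scores between the two patient
groups use two-sided Mann–Whitney U. Raw MoCA is education-adjusted (+1 if
≤ 12 years of education) before the ceiling cap at 30 — the cap follows the
scale's instructions; the adjustment-then-cap order is a documented choice.

## Voxel-wise cluster inference

Each in-mask voxel receives the t statistic of the slope in a
two-parameter regression (intercept + one scalar regressor) across
subjects, vectorized over voxels; zero-residual voxels are flagged and
carry ±inf. Suprathreshold voxels at a one-tailed parametric
cluster-forming threshold (p < 0.001 primary, p < 0.01 exploratory) are
labeled with 18-connectivity (SPM convention; 6/26 configurable). Cluster
FWE p-values come from the permutation null of the maximum cluster extent
under regressor relabeling (Freedman–Lane with an intercept-only nuisance
model reduces to simple relabeling); random-field theory is intentionally
not used. Peak coordinates are reported in voxel indices and in mm through
the NIfTI affine; no atlas labeling is attempted.

A property worth knowing: at very strict forming thresholds on small
grids, the null max-extent distribution concentrates on a few small tied
integers, and the (exchangeability-exact, valid) discrete p-values become
conservative — the realized family-wise rate falls below the nominal level.
Calibration checks in the test suite therefore run at the exploratory
p < 0.01 threshold, where extents are large enough for the discreteness
loss to be small (measured family-wise rate 0.0375 at nominal 0.05 over
400 null cohorts); recovery checks use the primary p < 0.001 threshold.

## The phantom generator

The generator emulates exactly the data features the pipeline depends on,
in a single common grid (no registration, which is out of scope):

* **Geometry.** Two straight axial cylinders of radius 1 voxel (5-voxel
  cross-section) and 9 slices, placed symmetrically in a dorsal-pons
  position on a 48×48×18 grid at 1 mm isotropic spacing by default;
  curvature of the real nucleus is not modeled because tri-section and
  extraction do not depend on it. Search ROIs are the tubes dilated by
  ~1.5 voxels in-plane; the background ROI is a tube-shaped midline column
  spanning the same slices (matched extraction pools, see above).
* **Intensities.** Uniform pontine background (100 a.u.); each tube third
  is set to `background × (1 + contrast)`. Default group contrasts: HC
  (rostral 0.30, middle 0.25, caudal 0.20); MSA-like (0.30 / 0.175 /
  0.140 — 30% reductions in middle and caudal); PD-like (0.30 / 0.200 /
  0.160). Healthy-control magnitudes of ≈ 0.2–0.3 and 20–40% patient
  reductions are configuration choices representative of the
  neuromelanin-MRI literature, not reported values. Between-subject
  biological spread is Gaussian with sd 0.05, giving the planted HC–MSA
  middle difference an effect size d ≈ 1.5.
* **Noise and artifacts.** Additive Gaussian noise with per-acquisition
  sd 2% of background; the averaging of three repeated acquisitions is
  represented by sd/√3 (rigid co-registration is out of scope). Noise is
  Gaussian, not Rician — at these contrast-to-noise levels the difference
  is immaterial for testing the pipeline. Multiplicative per-slice gains
  are drawn uniformly from (0.9, 1.1).
* **Cognition and PET.** A standard-normal latent score per subject drives
  the raw MoCA (`round(center_group + 2·z)` clipped to 0–30; centers 27.5 /
  25 / 27), the subject's rostral contrast (+0.06·z), and — for the
  MSA-like group — the amplitude of a planted spherical cortical cluster in
  the PET volume: uptake = baseline × (1 + 0.02·z) inside the cluster,
  uniform baseline elsewhere, additive noise sd 1% of baseline (per-voxel
  effect size d ≈ 2 per unit score). The reference region is independent of
  the score by construction. The planted signal is uniform inside the
  cluster, so recovery is assessed by the peak falling within 2 voxels of
  the cluster region, not of a (nonexistent) unique true peak.
* **Scalar cohort simulator.** For statistical calibration and power
  studies, `simulate_contrast_cohort` draws measured-contrast scalars
  directly from the measurement model (group mean + biological spread +
  measurement error ≈ 0.005 from the image-level recovery experiments)
  without rendering images; the image path itself is exercised by the
  recovery and voxel-wise experiments.

**What phantom validation does not show.** The phantoms have no anatomy,
no registration error, no Rician noise floor, no partial-volume gradient at
tube edges, no motion artifacts, and planted effects that exactly match
the model assumptions. Passing tests establish correctness and calibration
of the algorithms under their stated models — not the clinical accuracy of
LC quantification on real scans.

## Problem sizes and numerical choices

Test and acceptance runs use: 50 subjects for contrast recovery; a
study-sized cohort (18/11/18) for the end-to-end analysis; 500 scalar
cohorts × 500 permutations for type-I calibration; 200 cohorts × 1000
permutations for power; 200 null + 100 planted PET cohorts on 32³ grids at
3 mm spacing (n = 12, 150–250 permutations) for voxel-wise calibration and
recovery. Tolerances: exact algebraic identities are asserted at 1e−12,
image-pipeline round trips at 1e−6, Monte-Carlo agreement at 3 binomial
standard errors. Permutation p-values use the add-one estimator; exhaustive
enumerations report exact fractions. Tie-breaks: voxel ordering in the
subset search is by (intensity, index), stable and deterministic; equal-F
permutation comparisons use a relative 1e−12 tolerance so the observed
relabeling always counts itself. Degenerate inputs (constant outcome,
constant regressor, empty ROI, empty suprathreshold set) are either defined
results (F = 0 / p = 1; empty cluster table) or named errors, as documented
per function.
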