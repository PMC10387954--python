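# Methods

## The measurement model

A spoiled gradient-echo (FLASH/SPGR) acquisition at repetition time TR, echo
time TE and flip angle α produces, in steady state, the voxel intensity

    I(α) = M0 · e^(−TE/T2*) · sin α · (1 − E1) / (1 − cos α · E1),   E1 = e^(−TR/T1).

The variable-flip-angle (VFA) method acquires one image per flip angle with
TR and TE fixed — here 3°, 5°, 15° and 30° at TR = 20 ms, TE = 4.15 ms — and
estimates T1 per voxel from the angle dependence.  Because TE is constant
across the series, the factor M0·e^(−TE/T2*) is a single unknown amplitude;
T2\* is never estimated separately.

### The reference-angle normalization and its intrinsic bias

Rather than fitting the amplitude jointly with T1, the workflow treats the
3° image as a direct measurement of the constant c ≈ M0·e^(−TE/T2*)·sin 3°
(the small-angle limit cos α → 1), and predicts the remaining angles as

    Î(α; T1) = c · (sin α / sin 3°) · (1 − E1) / (1 − cos α · E1).

T1 is then the grid candidate (1 ms steps over (0, 4000] ms) minimizing the
sum of squared differences between Î and the measured 5°/15°/30°
intensities.  The 3° image contributes only c; it is not a residual term.
Ties break toward the smaller candidate; argmins at a grid endpoint are
flagged boundary-saturated and excluded from the validity mask, as are
voxels with non-positive or non-finite reference intensity.

The small-angle step is not innocuous at TR = 20 ms.  The measured 3°
intensity equals c · (1 − E1)/(1 − cos 3°·E1), and for tissue-like T1 the
correction factor is far from 1 (≈ 0.92 at T1 = 1300 ms), because 1 − E1
(≈ 0.015) is comparable to 1 − cos 3° (≈ 0.0014).  The least-squares fit
absorbs this amplitude error into T1 and systematically **underestimates**
it: by our own measurement (exhaustive search on noiseless model data,
cross-checked against the exact DESPOT1 linearization) the bias is −3% at
T1 = 300 ms, −9% at 1000 ms, −11% at 1300 ms and −26% at 3500 ms.  This is
a property of the method being reproduced and is deliberately preserved,
not corrected.  Its consequences:

* fitted T1 maps sit below true T1 by a smooth, monotone amount, so group
  *differences* survive (the mapping true→fitted is strictly increasing)
  while absolute values are compressed;
* "parameter recovery" is therefore always assessed against the
  noiseless-fit baseline (true T1 plus the precomputed bias), not against
  true T1 itself.  At SNR 50 (noise SD = 2% of the mean reference-angle
  signal) the median noise-induced error on top of the bias is ≈ 2%,
  bounded in tests at 5%;
* a voxel with true T1 above the 4000 ms grid end does not necessarily
  saturate: the negative bias can pull it back inside the grid.  Boundary
  saturation is exact for self-consistent (prediction-generated) data.

DESPOT1 — regressing I/sin α on I/tan α, slope = E1 — is exact on noiseless
model data and serves purely as the independent oracle in tests; the
production path never uses it.

## Segmentation and CSF removal

A deterministic 1-D k-means (means initialized at the 10th/50th/90th
in-mask percentiles, ≤ 100 iterations, 10⁻⁴ relative tolerance) clusters
the T1-weighted structural volume into three classes mapped by ascending
mean intensity to CSF < GM < WM.  Bias-field estimation is out of scope; a
multiplicative field would degrade this segmentation, which is why the real
workflow bias-corrects first.  Fewer than three separable intensity modes
(adjacent class means closer than twice the summed within-class spreads) is
an error, not a guess.

CSF voxels are removed from the T1 map's validity mask before ROI
averaging.  The pipeline default dilates the CSF mask by one voxel first:
the voxels *adjacent* to ventricles are partial-volume mixtures whose T1 is
pulled toward CSF (~3500 ms) yet whose majority tissue class is GM/WM, so a
hard CSF mask alone does not catch them.  `remove_csf` without dilation
removes exactly the labeled CSF voxels (and is idempotent, never adding
voxels back).

Registration is reduced to "all volumes share a grid"; a nearest-neighbour
resampler under a known affine stands in for the structural→FLASH alignment
only.

## ROI registry and measurement

The packaged registry mirrors a whole-brain macro-label parcellation:
134 measurement regions — 12 subcortical, 72 cortical, 25 cerebellar GM and
25 cerebellar WM (9 bilateral pairs plus 7 unilateral vermis regions per
cerebellar tissue) — plus 72 auxiliary cortical-WM masks for stripping the
WM rim around gyri.  A region's per-subject value is the mean fitted T1
over voxels inside its label ∩ the validity mask (CSF-excluded) ∩ its
admissible tissue class (GM for subcortical/cortical/cerebellar-GM regions,
WM for cerebellar-WM).  Means over fewer than 10 voxels are flagged rather
than dropped; the floor is a package choice for desk-scale phantoms.
Cortical region means are GM-restricted; the cortical-WM masks are kept as
a separate exclusion list.

## Group statistics

Per region, each group's sample is screened with a one-sample
Kolmogorov–Smirnov test against a normal with sample-estimated mean and SD;
if both groups pass at 0.05 an independent-samples t-test (pooled variance)
compares young vs old, otherwise a two-sided Mann–Whitney U (exact below
n = 20 without ties, normal approximation with tie correction otherwise).
The raw p is Bonferroni-corrected with n = 2 for bilateral pairs (the same
structure measured once per hemisphere) and n = 1 for unilateral regions,
thresholded at α = 0.05.  Direction follows the group-mean difference
(t-test) or the rank-sum direction (Mann–Whitney).

Known caveat, documented rather than hidden: KS with *estimated* parameters
is anti-conservative as a normality screen — it passes normal samples
essentially always, but detects even exponential skew at only ~13% for
n = 30.  A Lilliefors-corrected gate (detection ~79% in the same setting)
is available via `method="lilliefors"`.

Two correction families are exposed.  The per-pair default (n = 2) matches
how bilateral measurements are usually handled, but it does **not** control
the family-wise error over a whole region set: with it, a claim of the form
"exactly these k regions differ" carries a substantial false-positive
probability across the remaining regions.  For such exact-subset claims the
`bonferroni="global"` option corrects over the tested family; the
end-to-end effect-detection check uses it for precisely that reason.
Under the null, the per-region rejection rate at α = 0.05 is nominal for
uncorrected (unilateral) regions and ~α/2 for bilateral pairs by
construction of the n = 2 correction; the Monte-Carlo type-I check is
therefore defined over unilateral regions, where [0.03, 0.07] brackets the
nominal level.

## The phantom generator

Geometry is parametric with exact voxel truth: a brain ellipsoid, a WM
core, the GM shell between them, two ventricle ellipsoids, and 12 parcels
mapped onto registry ids (bilateral caudate, thalamus and hippocampus
flanking the ventricles; bilateral pre/postcentral patches in the GM shell;
a bilateral cerebellar pair postero-inferiorly).  Default grid 64×64×16 — a
desk-scale stand-in for 256×256 axial acquisitions chosen so the whole
pipeline runs in seconds per subject.

Default tissue values are literature-typical 3 T numbers, explicitly
package defaults and not measured values: T1 CSF/GM/WM = 3500/1300/850 ms,
M0 1000/850/700, T2\* 200/55/45 ms, structural intensities 300/600/900
(noise SD 20).

Cohort structure (the study conditions):

* n = 30 per group by default;
* old-group T1 prolongation: +150 ms on a designated parcel subset
  (default: bilateral hippocampus and left caudate — three parcels, chosen
  to exercise both a full bilateral pair and a single hemisphere);
* old-group ventricle enlargement: radii × 1.35 (voxel count grows ≈
  1.35³); a one-voxel partial-volume shell around the ventricles carries a
  40% CSF / 60% tissue linear mixture of T1, M0, T2\* and structural
  intensity.  Mixing fitted quantities linearly is a simplification of
  signal-level mixing, adequate for demonstrating the contamination
  mechanism;
* between-subject variability: one additive normal shift (SD 40 ms) per
  parcel and per background tissue, independent across subjects — the
  variance component is a modeling choice, as the emulated study reports
  none;
* acquisition noise: additive Gaussian, SD = 2% of the mean GM
  reference-angle signal (SNR 50); Rician as an option, indistinguishable
  from Gaussian at this SNR (<1% mean-signal difference).

What the phantom does *not* emulate: anatomical folding, bias fields
(optional in principle, absent by default), imperfect spoiling, motion,
spatially varying B1, k-space effects.  Passing tests therefore demonstrate
the pipeline's internal correctness and its statistical behavior under the
assumed noise model — not robustness to real-scanner artifacts.

## Flip-angle (B1) robustness

A uniform B1 error scales every achieved angle by (1 + δ) while the fitter
assumes nominal angles.  The sweep (noiseless, deterministic; δ ∈ {0, ±2%,
±5%, ±10%}, T1 ∈ {500…2500} ms) reports both the error vs true T1 and the
**excess** error vs the δ = 0 fit.  The excess is the meaningful robustness
metric here: it is zero at δ = 0, flips sign with δ (over-flipping raises
the fitted T1 at these settings, under-flipping lowers it) and grows
monotonically with |δ|, whereas the vs-true error is dominated by the
baseline approximation bias and is not monotone in |δ|.  Measured excess at
δ = ±10% is 16–20%; at a 5% excess-error bound the tolerated variability is
|δ| ≤ 2% over the swept grid.  The bound is an explicit user input — the
emulated workflow's own acceptance bound is not public — and the full table
is published rather than a single pass/fail.

## Problem sizes and numerical choices

Grid fits cost one 4000-candidate search per voxel, vectorized as a single
GEMM per voxel chunk with the residual re-evaluated exactly at the argmin
(guaranteeing residual ≥ 0 and exact zero for self-consistent data);
a 64×64×16 subject fits in ~3 s.  The end-to-end effect-detection check
uses n = 15 per group; the Monte-Carlo error-control check uses 500
measurement-level replicates of 20 regions at n = 30 per group; the
noiseless recovery check covers every brain voxel of one subject.  These
sizes were chosen so each check completes in minutes on a single core
while keeping Monte-Carlo error well inside the asserted bands.

Degenerate inputs: identical constant samples short-circuit the group test
(reported as degenerate, never significant); empty masks, absent regions
and sub-floor voxel counts are flagged per row and never abort a batch;
all-zero or non-finite voxels are invalid, not errors.
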