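# Methods

This note documents the models, conventions and numerical choices behind
`focalstage`, and what the synthetic cohorts do and do not establish.

## Regional quantification

Uptake is expressed as SUVR with the whole cerebellum as reference. The
packaged region map carries 42 lateralized AAL-style VOIs grouped into ten
composite regions (frontal, lateral temporal, parietal, cingulate, striatum
x left/right): 9 frontal, 3 lateral-temporal, 5 parietal, 2 cingulate and
2 striatal structures per hemisphere. The map is an editable YAML file; VOI
names and atlas label numbers are whatever the caller's label table says,
nothing is hard-coded. Pooling across a region's VOIs is volume-weighted —
equivalent to averaging over the union of their voxels, and equal to the
unweighted mean when volumes are equal.

The global cortical target is the union of all cortical (non-striatal)
VOIs. This is an approximation: the reference dcCL protocol defines its
cortical target VOI from group-average difference images of anchor cohorts,
which cannot be rebuilt from tabular data. The global VOI list is therefore
configurable.

## Centiloid scaling and global positivity

The dcCL conversion is the affine map anchored at the young-control mean
(0 CL) and the ADCI anchor mean (100 CL). Anchor means are configuration
inputs (per ligand); the synthetic module generates self-consistent anchor
samples. Global positivity uses `CL >= cutoff` with default cutoff
25.11 CL; 20 and 40 CL are the conventional sensitivity settings. The
boundary convention (`>=`, boundary positive) is a choice, exposed as a
parameter, as is the strict `>` used for regional flags — neither
convention is derivable from first principles, and at continuous-valued
boundaries the choice is almost never binding.

`derive_cl_cutoff_roc` maximizes Youden's J (sensitivity + specificity − 1)
over midpoints between consecutive distinct CL values, breaking ties toward
the lower threshold. Youden's J is the documented default criterion; other
ROC optimality criteria exist but are not implemented.

## Regional cutoffs: iterative Tukey fences

Per ligand and per region, the cutoff derivation repeatedly computes Q1,
Q3 and IQR on the retained sample, removes all values outside
`[Q1 − k·IQR, Q3 + k·IQR]` (default k = 1.5; both tails per pass; removed
values never re-enter), and stops when a pass removes nothing. The cutoff
is `(1 + f) · max(retained)` with f = 0.025 — a relative increment ("2.5%
of the highest SUVR in itself"), not an absolute one.

Numerical choices:

* **Quartile convention** — linear interpolation between order statistics
  (the common "type 7" definition) by default; Tukey hinges are available
  via `quartile_method="hinges"`. The choice shifts fences by a fraction of
  one order-statistic gap and rarely changes the retained set.
* **Minimum sample size** — 8. Below that, quartiles of a tiny sample make
  fences meaningless; the derivation refuses rather than guessing.
* **Termination** — the retained set strictly shrinks each pass or the
  loop stops, so at most n passes occur; the retained set cannot empty
  because the quartiles always lie inside the fences.

Known behavior inherited from the method: regions with a large SUVR dynamic
range (the cingulate in practice) bias the cutoff upward, and the cutoff is
an extreme-value statistic — its sampling noise shrinks only slowly with
the reference sample size. No correction is applied for either.

## Staging

Groups: `G−F−` (global-negative, no involved region), `G−F+`
(global-negative, ≥ 1 involved region), `G+` (global-positive). Subtypes:
none (0 regions), focal (1–9), whole-brain (10). All global-positives form
one group regardless of their involvement count; the subtype field
preserves the focal/whole-brain distinction, and a global-positive scan
with zero flags is reported with a `discordant_flag` rather than silently
recoded. Raising the global cutoff can only move scans out of `G+`;
raising regional cutoffs can only lower involvement counts.

## Statistics

* ANOVA/ANCOVA are ordinary least-squares fits (statsmodels) with a
  type-II F test for the group factor; the default ANCOVA adjusts for age
  only, with covariates configurable.
* Tukey post hoc p-values come from the studentized range distribution
  (scipy). Without covariates this is Tukey–Kramer on group means; with
  covariates the comparison is between covariate-adjusted means evaluated
  at the covariate means, with each difference's variance taken from the
  model's coefficient covariance.
* Mann–Whitney uses the exact null distribution for small untied samples
  (both n ≤ 20) and the tie-corrected normal approximation otherwise.
* Jonckheere–Terpstra: JT = sum of pairwise Mann–Whitney counts over
  ordered group pairs (ties count 1/2); p from the tie-corrected normal
  approximation without continuity correction, with an optional seeded
  permutation p. Direction follows the stated group order; one-sided for
  monotone hypotheses, two-sided by default.
* Involvement-frequency bootstrap: restricted to scans with ≥ 1 involved
  region; a lobe counts as involved if either hemisphere's flag is set.
  Participants are resampled with replacement; the two-sided pairwise p is
  `2 · min(P*(f_a ≤ f_b), P*(f_a ≥ f_b))` and the −log10 report floors p at
  1/n_resamples. The ±1-resample floor and the two-sided construction are
  design choices; published reports typically show only a −log10 color
  scale without defining the p construction.
* AIC grouping comparison: Gaussian least-squares fits of
  `outcome ~ grouping (+ age)` for the G/F grouping and for dcCL bands
  (negative < 10 ≤ subthreshold < 25.11 ≤ positive); `AIC = 2k − 2 ln L`,
  lower wins, exact ties go to the G/F grouping. A scan at exactly
  25.11 CL is banded positive, matching the global `>=` convention.
* No multiple-testing correction beyond Tukey is applied.

## The synthetic cohort generator

The generator exists so every stage — cutoff derivation, calibration,
staging, statistics — can be exercised end to end with known ground truth.
Defaults encode the study conditions the pipeline targets: a 900-participant
two-ligand cohort (51.5% FBB), diagnosis mix 23.6 / 41.3 / 35.1%
(CU / aMCI / dementia), global-positivity rates 20.6 / 56.8 / 84.7% by
diagnosis, a focal-positive share of global-negatives rising with
impairment (8.8 / 18.5 / 26.9%), and lobar involvement proportions
38.8 / 32.5 / 32.4 / 26.1 / 13.0% (parietal / frontal / temporal /
cingulate / striatum) among focally involved scans.

Generative model, per participant:

* **One-factor burden.** Global-positives carry a single severity scalar
  that loads onto every lobe (loadings 1.00 / 0.96 / 0.95 / 0.90 / 0.60
  for parietal / frontal / temporal / cingulate / striatum). This
  one-factor spread model reproduces the monotone relation between
  Centiloid level and involvement count with minimal parameters; the true
  inter-regional correlation structure of amyloid accumulation is not
  reported at this granularity, so independence-vs-factor structure is a
  modeling choice.
* **Graded severity by diagnosis.** Impaired positives have established
  burden (severity floors 0.32–0.35 SUVR); CU positives are early
  accumulators drawn from a low graded continuum (floor 0.18). The
  continuum matters: it produces the heavy right tails seen in real CU
  SUVR histograms, and it is what makes iterative fence-trimming behave —
  a detached high-burden cluster at ≥ 25% prevalence would capture Q3 and
  stall the fences, which is a degenerate geometry real reference samples
  do not present.
* **Focal scans** carry 1–2 involved lobes (bilateral with probability
  0.7), with uplift sized so the global burden lands at a subthreshold
  Centiloid target drawn from 8–20 CL. Lobe patterns are allocated by
  largest-remainder rounding of a calibrated pattern distribution —
  independent Bernoulli involvement restricted to 1–2-lobe patterns, with
  rates solved by fixed point so the conditional marginals equal the
  configured proportions — then assigned to subjects in random order. This
  variance-controlled allocation makes a generated cohort *realize* its
  configured involvement frequencies at any seed instead of merely
  matching them in expectation. Striatum-only patterns are excluded:
  striatal amyloid follows cortical involvement.
* **Noise.** Regional SUVR = ligand baseline (FBB 1.20, FMM 1.10) +
  uplift + Gaussian noise split into subject-diffuse, lobe-shared and
  hemisphere components (total SD 0.046); hemispheres of a lobe share
  their loading and differ by the hemisphere component. The global SUVR is
  the volume-weighted mean of the cortical regions (lobe weights
  0.34 / 0.27 / 0.26 / 0.13 frontal / parietal / temporal / cingulate,
  AAL-like volume proportions).
* **Anchors.** Young-control and ADCI anchor samples (n = 20 each, SD 0.03
  and 0.08) are drawn per ligand around the baseline and baseline + 1.0;
  their means define the calibration, so the conversion maps them to 0 and
  100 exactly by construction.
* **Covariates and outcomes.** Age, sex, education, APOE4 and visual-read
  fields are sampled per latent group with the target cohort's per-group
  distributions; MMSE, SVLT delayed recall, hippocampal volume, ICV and
  AD-ROI cortical thickness get planted group means, an age slope centered
  at 71.6 years, Gaussian noise, and truncation to score ranges (MMSE
  0–30, SVLT 0–12). `with_null_effects()` equalizes the group means while
  keeping the age confound, for calibration studies.

Cutoff derivation in the packaged end-to-end path uses a dedicated
445-scan CU reference sample (split across ligands), not the study
cohort's own CU members, mirroring how reference thresholds are derived
from a standalone unimpaired pool. Amyloid-positive CU remain in the
reference; removing them is the outlier step's job.

### What the generator does not emulate

No image-level PET physics, no partial-volume effects, no spatial
correlation beyond the lobe/hemisphere factors, no longitudinal dynamics,
no APOE-burden interaction, and outcome distributions are (truncated)
Gaussian rather than skewed clinical scores. Passing tests therefore show
that the pipeline's logic and statistics behave as specified under the
assumed generative structure — not that the cutoffs or group contrasts
derived from any particular clinical dataset are correct.

## Problem sizes used in validation

The test suite stages a 900-participant cohort end to end, checks
frequency ordering on a 600-scan all-focal cohort (so the five lobar
frequencies are estimated from ~600 eligible scans, the scale at which the
planted ordering is identifiable), verifies the outlier loop against an
independent scalar re-implementation on 100+ random samples, and
calibrates the ANCOVA group test's type-I error over 1,000 null cohorts of
200 participants. These sizes were chosen so each check estimates its
quantity with comfortable margin while the whole suite stays fast.
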