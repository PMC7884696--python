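# Methods

## Overview

`lesiontopo` quantifies *where* an ischemic stroke lesion sits relative to
a brain parcellation, alongside the canonical MRI metrics clinicians
already use, and relates both to longitudinal motor outcomes in a small
cohort. All imaging inputs are assumed co-registered onto one grid
(atlas space); registration, segmentation and tensor fitting are upstream
of this package. The package also contains a synthetic phantom cohort
generator whose outputs carry exact ground truth, which is what the test
suite and acceptance script exercise.

## Lesion-topology scores

For a binary lesion mask and an integer label atlas sharing one grid:

- `PoS(X) = 100 · |lesion ∩ X| / |X|` — the fraction of structure X
  destroyed;
- `PoL(X) = 100 · |lesion ∩ X| / |lesion|` — the fraction of the lesion
  inside X (zero for an empty lesion).

Counts are voxel counts (matching how overlap is scored on registered
images); physical volumes are available through the grid spacing. Because
labels are mutually exclusive, Σ PoL over all structures plus the
unlabeled-lesion fraction is exactly 100 — this conservation identity is
enforced in tests against a literal three-nested-loop voxel counter.

Two modeling choices are deliberately configurable, since field practice
varies:

- **Denominator of PoS**: default is the unilateral label; `merge_pairs`
  pools a structure with its bilateral partner. Lesions are unilateral, so
  the merged denominator roughly halves every PoS.
- **Cohort averaging**: rankings average PoS/PoL across all stroked
  subjects, zeros included; restricting to lesioned subjects only is a
  caller-side filter on the overlap table.

Incidence counts a subject as lesioned in a structure when its overlap is
at least `threshold_voxels` (default 1 — a single "activated" voxel
counts; real data with partial-volume noise may warrant more). Incidence
percents are reported rounded to one decimal, which on a 7-subject cohort
yields the lattice 14.3, 28.6, 42.9, 57.1, 71.4, 85.7, 100.

## Canonical volumetrics

Volumes are voxel counts × voxel volume (in cm³), which on masks is
identical to the manual planimetric sum of per-slice areas × slice
thickness. Hemisphere volumes subtract the lateral ventricle mask of the
same side and exclude the cerebellum entirely. Derived quantities:

- lesion percent of ipsilateral hemisphere: `100 · V_lesion / V_ipsi`;
- hemispheric change: `100 · (V_ipsi / V_contra − 1)`, positive =
  swelling, negative = atrophy;
- midline shift: signed perpendicular distance from the septum-pellucidum
  landmark to the ideal midline plane (a point and unit normal), with the
  normal oriented toward the contralateral hemisphere so that positive
  shift means displacement away from the lesioned side.

Midline shift is computed from explicit landmarks (phantom sidecar, or a
landmarks CSV for real data) rather than detected from image intensities:
the landmark identification step is manual in practice and automating it
is out of scope. Degenerate planes (non-unit normal) are rejected.

## White matter

Mean FA over a manually drawn tract ROI per side, NaN voxels excluded and
counted, and a two-sided paired t-test of ipsi vs contra means across
subjects. The pipeline warns when the two ROI areas differ by more than
10% (the equal-area ROI convention). A zero-variance difference vector
yields a flagged degenerate result rather than p = 0 — with 6–7 subjects,
pretending infinite evidence would be dishonest.

## Statistics

All tests are pure functions and two-sided (printed p-values in this
literature are consistent with two-sidedness; sidedness is never stated).

- `one_sample_t` accepts either raw vectors or printed (mean, SD, n)
  summaries, making published tables first-class inputs. With mean 1.57,
  SD 0.83, n 7 against 0 it returns p = 0.00244; with 115.17 ± 7.89
  against 100, p = 0.00225.
- `paired_t` is the one-sample test on differences; NaN pairs are dropped
  and counted.
- `pearson_r` computes r from centered sums and p from
  `t = r·√((n−2)/(1−r²))` on n−2 df; fewer than 3 complete pairs or zero
  variance is an error/flag, |r| = 1 returns p = 0.
- `sidak_adjust(p, k) = 1 − (1−p)^k`.
- `bh_fdr` is the Benjamini–Hochberg step-up with the running-minimum
  enforcement, NaNs passed through without counting toward m. BH is used
  because the FDR procedure is otherwise unspecified in this literature;
  it is the standard default.
- `rm_anova_sidak` runs a two-way repeated-measures ANOVA (between-subject
  group, within-subject timepoint) delegated to `pingouin.mixed_anova`
  (no sphericity correction by default, matching common practice in prism
  -style analyses), plus Sidak-adjusted pairwise families authored here:
  between groups at each timepoint (pooled-variance two-sample t, k =
  number of timepoints) and within each group against baseline (paired t,
  k = number of post-baseline timepoints). Unbalanced designs are rejected
  with the missing subject × timepoint cells named.

## Correlation pipeline

The feature matrix takes the top `top_n_structures` (default 10)
structures by cohort-mean PoS at the acute imaging session, plus the four
canonical metrics. Outcomes default to the six contralateral-forelimb gait
parameters at days 2 and 8 post-stroke; correlations run within the
stroked group only. A PoS feature with fewer than `min_lesioned`
(default 3) subjects showing any lesion is excluded before FDR, as are
zero-variance cells, so excluded cells never influence the adjustment of
included ones. The FDR family is one heatmap (one feature × outcome table
at one outcome timepoint); a global family is a caller-side concatenation.

## The phantom generator

The generator exists to give every downstream stage a known answer. It
emulates, at porcine scale (≈128 × 128 × 72 mm field of view, default
2 × 2 × 3 mm voxels — 3 mm axial slices as in T2-weighted stroke
protocols):

- a mirrored parcellation: axis-aligned ellipsoid structures packed on a
  jittered lattice in the right (ipsilateral) hemisphere and reflected
  voxel-exactly onto the left, named after MCA-territory structures
  (claustrum, insula, temporal gyri, putamen, pallidum, somatosensory
  cortices, ...), plus paired lateral ventricles and a posterior
  cerebellum compartment, inside a cerebral envelope of ≈35 cm³ net per
  hemisphere;
- MCA-territory lesions: per-structure target coverage fractions realized
  by taking exactly `round(fraction · n_voxels)` voxels nearest the
  structure centroid, plus a free-form territory ellipsoid that claims
  only unlabeled tissue, so per-structure coverage keeps its exact ground
  truth while total lesion volume reaches a realistic ~30% of hemisphere;
- mass effect: the ipsilateral hemisphere envelope is scaled laterally
  and realized as a *count-exact sublevel set* — voxels are sorted by the
  scaled ellipsoid coordinate and exactly `round(V_contra_net · (1 +
  Δ/100))` are kept — so the measured ventricle-subtracted volume ratio
  equals the specified change to within half a voxel, rather than
  drifting by a surface-discretization term;
- a septum landmark displaced by the specified midline shift toward the
  contralateral side, snapped to half-voxel precision in-plane (landmark
  lines are drawn on magnified slices), giving round-trip error of at
  most one in-plane voxel;
- FA maps: mirrored corpus-callosum ROIs beside the midline, contralateral
  baseline FA ≈ 0.45, ipsilateral reduced by a tract decrement (default
  30% acute, 5% chronic, between-subject SD 0.08), voxelwise Gaussian
  noise, clipped to [0, 1];
- outcomes from a linear damage-to-deficit model:

  `value(param, t) = baseline · (1 − Σ_k β[param,k] · PoS_k/100 · 2^(−t/T½)) + ε`

  for post-stroke days t ≥ 0 (pre-stroke rows carry no deficit), with
  recovery half-life T½ = 7 days and noise SD defaulting to 10% of each
  baseline. Healthy baselines use published porcine magnitudes (velocity
  198.78 cm/s, cadence 133.01 strides/min, stride 89.01 cm, step
  44.36 cm, swing 51.93%, stance 48.06%, open-field distance 75.70 m,
  movement duration 230.55 s). mRS is an ordinal 0–6 score produced by
  thresholding the same latent deficit (fixed default thresholds spanning
  0.08–0.85), since no generative model for mRS exists in this
  literature. Deficits load on the motor-coordination structures
  (putamen β = 0.70, globus pallidus 0.68, primary somatosensory cortex
  0.72; stance percent with flipped sign since it rises post-stroke). The
  pallidum and somatosensory coefficients are larger per unit PoS than
  naive realism would suggest because those structures are lesioned in
  only ~71% of subjects: coefficients are sized so that each damaged
  structure's sign is recoverable by the correlation pipeline in ≥95% of
  12-subject cohorts at 10% noise, which is the recovery property the
  package guarantees.

Cohort-level damage is drawn per structure independently (presence ~
Bernoulli at MCA-territory-like probabilities, coverage ~ Beta with
structure-specific means, concentration 4): the true joint distribution of
damage across subjects is not documented anywhere, so independence is the
explicit model choice. All randomness flows through one seeded generator
per subject; identical seeds reproduce cohorts byte for byte.

### What the phantom does *not* emulate

No MR contrast, bias fields, k-space artifacts, partial-volume mixing,
registration error, or deformable biomechanics — swelling is an affine
lateral scale, not tissue mechanics. Structures are convex ellipsoids,
far simpler than cortical ribbon geometry; small-structure registration
error, which dominates real atlas-overlap noise, is absent. Passing tests
therefore demonstrate the *analysis* is correct on its stated inputs, not
that those inputs are attainable from raw scans.

## Numerical choices

- Volumes and overlaps are exact integer counts; no interpolation
  anywhere in the analysis path.
- Count-exact mask construction (sorted sublevel sets, stable ties by
  flat voxel index) makes generator ground truth exact rather than
  discretization-limited.
- Structure ranking breaks mean ties alphabetically for determinism.
- Degenerate inputs (zero variance, empty ROI, zero denominators,
  non-binary masks, unbalanced designs, mismatched grids) raise or flag
  explicitly; nothing silently returns 0 or p = 0.
- Seeds: one `numpy` Generator per subject, spawned from (cohort seed,
  subject index).

## Problem sizes

Default grids are 64 × 64 × 24 voxels; the test suite and acceptance
script use 50 random ≤32³ volumes for loop-oracle equivalence, 200
twelve-subject cohorts for correlation recovery, and 2,000 replicates for
type-I/FDR calibration — sizes chosen so the full suite completes in well
under a minute while keeping Monte-Carlo error (~1%) far below the margins
being tested.

## Known limitations

- The RM-ANOVA requires complete subject × timepoint grids; real cohorts
  with dropout need imputation or mixed models (out of scope).
- PoS denominators (unilateral vs merged bilateral) change rankings; both
  are supported, neither asserted as canonical.
- The midline-shift sign convention (positive toward contralateral)
  follows the acute-swelling geometry; data using the opposite convention
  must be negated on input.
- With 7 subjects, FDR-adjusted correlation p-values are rarely
  significant even for strong true effects — the package reports honest
  adjusted values rather than optimistic ones.
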