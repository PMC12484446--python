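# Methods

This note documents the scientific model behind `oataxia`, the
defaults that matter, the synthetic-data generator's assumptions, and
the numerical choices made where the design was genuinely open.

## Behavioural model

A reach trial is rated 0–5 (fluent, slowed/insecure, corrected during
the reach, corrected after the first reach, corrected after the second
reach, failed).  The per-condition **mean error score** is
`100·Σpoints/(5n)`, a percentage of the worst possible performance.
Error categories partition the trials: fluent {0}, corrected (0, 2],
uncorrected (2, 5] — the half-open intervals matter because two-rater
inputs are averaged per trial before scoring (a 1-vs-2 disagreement
yields 1.5, still "corrected").  Rater disagreements above one point
are logged but still averaged; the study protocol defines no
adjudication rule, and averaging preserves both ratings' information.

The **OA score** of a hand/space combination is the peripheral minus
the foveal mean error score.  Its purpose is deconfounding: a paretic
or tremulous arm degrades reaches regardless of gaze, so a constant
offset on both viewing conditions cancels exactly (this is a unit
test).  What survives the subtraction is the gaze-dependent component
that defines optic ataxia.

Conditions with fewer than `min_valid` valid trials (default 5; the
reference protocol reports 11–16 valid trials per condition but states
no minimum) yield *missing* scores, never zeros — a zero would assert
perfect performance.

## Normative model and single-case inference

Controls have no lesioned side, so ipsi/contra is undefined for them.
Exactly half the controls are assigned left-as-ipsi (the control group
must be even-sized).  Among `n_perm` (default 100 000) random balanced
assignments the pipeline keeps the one minimising

    loss = Σ_measures ( |μ_ipsi − μ_contra| + |σ_ipsi − σ_contra| ) / σ_pooled,

summed over the 8 condition scores and 4 OA scores, with
`σ_pooled = √((σ²_ipsi + σ²_contra)/2)` per measure.  The protocol
this package operationalises states only that the assignment
"balanced mean and SD values"; this loss is the direct scale-free
formalisation of that sentence.  A measure with zero pooled SD
contributes 0 when already balanced and ∞ otherwise.  The search is
exhaustive over the sampled assignments, vectorised, deterministic
given the seed, with ties broken by first occurrence.

A patient is compared to the control norm (μ, σ estimated with
`ddof=1` from n controls) in two ways:

* flipped z-score `z = −(x − μ)/σ`; the sign flip follows
  neuropsychological convention (negative = deficit);
* the Crawford–Howell single-case t, `t = (x − μ)/(σ√(1 + 1/n))`
  with n−1 df, one-tailed in the deficit direction.  This frequentist
  form gives point-identical results to the Bayesian
  Crawford–Garthwaite test in the single-score case while staying
  deterministic; the Monte-Carlo Bayesian variant was deliberately not
  implemented.

The OA flag requires **both** `z < −2` (strict: z = −2 exactly is not
OA) and `p < 0.05`.  With 40 controls the Crawford criterion
(t threshold ≈ 1.68·√(1+1/40)) is slightly more liberal than the z
criterion, so the z cut usually binds; with small control samples the
roles reverse, which is why both are kept.  A patient's overall
classification is the contralesional-hand/contralesional-space flag,
the canonical locus of OA after a unilateral lesion.

Caveat: raw error scores are bounded and right-skewed, so a ±2 SD
normal threshold carries an empirical false-positive rate of roughly
4 % rather than the nominal 2.3 % (measured on simulated
control-identical patients).  This is a property of the published
classification rule, not of its implementation; the single-case test
does not remove it because it corrects for sampling error, not skew.

## Group statistics

* **Mann–Whitney U** (two-sided, U reported for the first group): the
  exact null distribution is used when the pooled data are tie-free
  and n₁·n₂ ≤ 400; otherwise the normal approximation with midranks
  and tie-corrected variance, without continuity correction.  The
  exact branch is validated against a full-enumeration oracle for all
  group sizes up to 5.
* **Pearson χ² on 2×2 tables**, no continuity correction:
  `χ² = n(ad−bc)²/((a+b)(c+d)(a+c)(b+d))`, df = 1.  The
  no-correction choice is validated against the published
  bilateral-lesion table (3/5 vs 3/23 → χ² = 5.38, p = 0.02).  A zero
  marginal raises; the cohort summary layer maps a covariate constant
  in both groups to χ² = 0, p = 1 (no information).
* **Mixed 2×2×2 ANOVA** (between: group; within: viewing, side).
  Because all factors are two-level, each within effect reduces to a
  per-subject contrast: subject mean → GROUP; viewing difference →
  VIEWING, GROUP×VIEWING; side difference → SIDE, GROUP×SIDE; double
  difference → the remaining two effects.  Group comparisons use the
  pooled two-sample t (F = t² exactly); within-factor main effects
  test the unweighted grand mean of the contrast (type-III
  convention, relevant only for unequal group sizes).  All effects
  have df (1, N−2); partial η² = SS_eff/(SS_eff+SS_err).  The
  implementation reproduces R's `aov` with
  `Error(subject/(viewing*side))` to ~10 significant digits on a
  balanced fixture (frozen in `tests/oracles/`).
* **Bonferroni**: α/m; the pipeline applies 0.05/4 to the four
  congruent condition comparisons and 0.05/2 to the two OA-score
  comparisons.

## Lesion cartography

Masks and atlas share one voxel grid; registration is out of scope.
The first voxel axis is assumed to run left→right; hemisphere
operations act on it.  Mirroring reverses that axis about the grid
centre (odd axes reflect about their centre slice, even axes about the
inter-voxel midplane), is an exact involution and conserves volume.
The midline convention is voxel-based, not world-coordinate-based;
masks registered to a symmetric template satisfy both.

Laterality: the predominant side holds more lesion voxels (an exact
50/50 split raises and demands manual assignment); a lesion is
bilateral when both hemispheres carry ≥ `bilateral_min_voxels`
(default 10 — the reference study states no criterion; 10 voxels
suppresses single-voxel segmentation noise at analysis resolution).
A nucleus counts as affected from ≥ `affected_min_voxels` overlap
(default 1, i.e. any involvement; configurable because upsampled
grids inflate voxel counts).  Territory = the group (medial, lateral,
posterior) holding the largest lesioned-voxel share; ties resolve
medial < lateral < posterior with a warning; no nucleus overlap →
"other".  The nucleus→territory table ships as editable YAML
(`src/oataxia/data/territories.yaml`).

Group maps: voxelwise lesion counts and percentages; the subtraction
map is `pct(group A) − pct(group B)`, exactly antisymmetric under
group swap and bounded by ±100.  Display thresholding zeroes
|diff| ≤ 20 % (strictly-exceed convention); the unthresholded map is
always retained.  The paresis, somatosensory and grasping control
analyses reuse this one code path with a different grouping column.

## Synthetic-data generator

The generator emulates the *statistical* structure of a
thalamic-stroke OA study; its defaults are the stated cohort: 28
patients (14 left / 14 right lesions), 40 controls, 5 implanted OA
patients, 11–16 valid trials per condition plus Poisson(1) invalid
trials, two raters with 10 % one-point disagreements.

Raw scores are categorical over {0..5} per cohort × condition:

| distribution | P(0..5) | mean score |
|---|---|---|
| foveal (everyone) | .985 .010 .005 0 0 0 | 0.4 % |
| peripheral (controls, non-OA) | .930 .045 .020 .004 .001 0 | 2.0 % |
| peripheral CH–CS, implanted OA | .35 .38 .20 .05 .02 0 | 20.8 % |

The OA distribution concentrates on corrected errors (points 1–2),
matching the clinical observation that thalamic OA patients mostly
correct in flight; the expected implanted OA score is ≈ 20 percentage
points.  `oa_effect` interpolates between the non-OA and implanted
distributions (0 = null cohort, the default 1 = fully implanted).  An
optional `motor_effect` mixes a motor-error component into the paretic
contralesional hand in both viewing conditions; it cancels in the
expected OA score (tested) but widens the non-OA OA-score
distribution, and it is **off** by default because the stated cohort
model keeps non-OA patients at control level.

Lesions are ellipsoidal blobs (anisotropy ratio 0.75–1.3 per axis,
jittered centre) centred on the voxel centroid of 2–3 target nuclei,
clipped to the atlas-labelled thalamic region, with the radius
iteratively rescaled so the realised volume tracks the request within
a few percent.  Sizes are lognormal (median 1100 mm³, log-SD 0.55)
clipped to the observed range [170.8, 5712.9] mm³.  OA patients draw
targets from the central-thalamus set {CL, CM, VL, VPL, MD} and are
bilateral with rate 0.6 (secondary mirrored blob at 25 % of the
primary volume, preserving the predominant side); non-OA patients
draw from the posterior set {PuA, PuM, PuL, PuI, LP} with bilateral
rate 0.13.  Clinical covariates are Bernoulli draws at the reference
marginal rates and are independent of the behavioural scores (except
through the OA/lesion assignment itself).

The toy atlas tiles an 18×30×18-voxel thalamic box per hemisphere
with 17 cuboid nuclei (dense partition, identical labels left/right,
exactly mirror-symmetric), on a 60×72×60 grid at 1 mm — small enough
for sub-second tests.  Because the tiling is dense, every lesioned
voxel inside the box has a nucleus label, which makes the
subtraction-map containment checks exact.

What a green test does *not* establish: real rating distributions
(between-rater structure, serial dependence of trials), realistic
lesion geometry (vascular-territory shapes rather than ellipsoids),
registration error, or any correlation between covariates and
behaviour beyond the implanted OA effect.

## Degenerate inputs and numerical conventions

Empty trial lists yield NaN scores (missing, never zero); unknown
labels raise naming the offending field.  A control SD of zero flags
the normative model degenerate and refuses z-scores.  Scores are
carried at full precision; reports round to 1 decimal (tables) or 4
(JSON).  All simulation and permutation randomness flows through one
`numpy` Generator seeded from the study/cohort seed; reruns are
byte-identical.

## Known limitations

* No kinematic or video analysis — ratings are the input.
* Registration, segmentation and template choice are upstream of the
  package.
* The ±2 SD rule's skew-driven false-positive excess (above) is
  inherited from the published method.
* Voxelwise lesion-symptom inference (VLBM) is deliberately absent;
  five-patient groups cannot support it.
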