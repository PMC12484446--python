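# oataxia

Optic ataxia (OA) is a visuomotor deficit in which reaching towards
objects breaks down specifically when the target sits in *peripheral*
vision — when gaze and reach goal are dissociated — while reaches to
foveated targets stay largely intact.  Classically attributed to
superior/inferior parietal lesions, OA can also follow circumscribed
thalamic stroke.  `oataxia` is a Python package for detecting and
anatomically localising OA in a thalamic-stroke cohort studied with a
bedside pen-grasping task and lesion masks in a shared reference
space.  It is written for researchers running (or re-analysing)
single-case neuropsychological reach studies with atlas-referenced
lesion mapping.

## What it computes

**Reach-error scoring.** Each videotaped reach is rated 0 (fluent) to 5
(failed).  Per condition (hand × space × viewing; 2 × 2 × 2) the mean
error score is

    score = 100 · Σ points / (5 · n_trials)  ∈ [0, 100],

with trials partitioned into fluent (0), corrected (1–2) and
uncorrected (3–5) categories.  The OA score of a hand/space
combination is `peripheral − foveal`; purely motor factors affect both
viewing conditions alike and cancel.  Patient scores are expressed
relative to the lesion (ipsi-/contralesional hand and space).

**Normative single-case classification.**  Controls have no lesion, so
exactly half are assigned "left as ipsilesional"; among many random
balanced assignments the one that best balances ipsi/contra means and
SDs is kept (default 100 000 permutations, seeded).  A patient's OA
score *x* is judged against the control norm (μ, σ, n) by

* the flipped z-score `z = −(x − μ)/σ` (negative = worse), and
* the Crawford–Howell single-case test
  `t = (x − μ) / (σ √(1 + 1/n))` with n − 1 df (one-tailed).

A combination is flagged as OA when **both** z < −2 and p < 0.05.

**Group statistics.**  Mann–Whitney U (exact when tie-free and
n₁·n₂ ≤ 400), Pearson χ² on 2×2 tables without continuity correction,
Bonferroni-corrected α levels, and a mixed repeated-measures ANOVA
(GROUP × VIEWING × SIDE) with partial η².

**Lesion cartography.**  Lesion volumes, per-nucleus damage against a
labelled atlas (e.g. a digitised Morel thalamus atlas),
medial/lateral/posterior territory classification, hemisphere flipping
to a reference side, voxelwise overlap maps, and percentage
subtraction maps `pct(OA) − pct(non-OA)` with a >20 % display
threshold.  The same subtraction machinery serves the paresis,
somatosensory and grasping control analyses.

**Synthetic cohorts.**  `oataxia.synthdata` generates complete cohorts
with known ground truth — trial ratings, clinical covariates, a
mirror-symmetric 17-nucleus toy atlas and ellipsoidal lesion masks —
so the whole pipeline is testable without patient data.

## Worked example

```python
from oataxia.synthdata import CohortConfig, simulate_cohort
from oataxia.pipeline import StudyConfig, run_study, write_report

bundle = simulate_cohort(CohortConfig(seed=7))     # 28 patients, 40 controls
report = run_study(bundle.ratings, bundle.clinical,
                   masks=bundle.masks, atlas=bundle.atlas,
                   config=StudyConfig(seed=7))
write_report(report, "report/")
print(bundle.truth["oa_subjects"])
```

This cohort implants OA in `['P016', 'P017', 'P018', 'P023', 'P025']`;
the report (`report/report.md`) classifies

```
Patients with contralesional OA: ['P016', 'P017', 'P018', 'P019', 'P023', 'P025']
```

— all five implanted patients plus one false positive (P019), the
expected behaviour of a strict −2 SD threshold on right-skewed scores.
The group statistics show the OA signature: patients differ from
controls for peripheral contralesional reaches (`CH-CS peripheral:
U = 742.5, p = 0.0228`) but not foveally (`CH-CS foveal: U = 592.5,
p = 0.6716`), and the ANOVA GROUP × VIEWING interaction is significant
(`F(1,66) = 6.86, p = 0.0109, partial η² = 0.094`).  The bilateral-lesion
rate separates OA from non-OA patients (`66.7 % vs 18.2 %, χ² = 5.43,
p = 0.020`), and the thresholded subtraction map concentrates on the
implanted central-thalamus nuclei (CL, CM, VL, VPL, MD).

The same run is available from the shell:

```bash
oataxia simulate --seed 7 --out data/
oataxia run --ratings data/ratings.csv --clinical data/clinical.csv \
    --masks-dir data/masks --atlas data/atlas.nii.gz \
    --atlas-labels data/atlas.yaml --seed 7 --out report/
```

## Acceptance script

`scripts/acceptance.py` re-runs the full analysis from scratch on a
freshly simulated default cohort — scoring, the permutation-balanced
normative classification, group statistics and the lesion subtraction
maps — and writes its results as JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/oataxia/scoring.py` — trial validation, error/OA scores, lesion frame
- `src/oataxia/normative.py` — control assignment, z/Crawford–Howell, U/χ²/ANOVA
- `src/oataxia/lesionmap.py` — volumes, atlas damage, overlap/subtraction maps
- `src/oataxia/synthdata.py` — toy atlas, lesion masks, cohort simulation
- `src/oataxia/pipeline.py` — `run_study` orchestration and reports
- `docs/methods.md` — model assumptions, defaults and limitations
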