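"""Synthetic cohorts with known ground truth.

Everything the analysis pipeline consumes can be generated here:
trial-level reach ratings for patients and healthy controls, clinical
covariates, binary lesion masks and a toy thalamic nucleus atlas.  The
generator emulates the statistical structure of a thalamic-stroke
optic-ataxia study:

* controls make almost no reach errors when they look at the target and
  only mild errors in peripheral vision (median peripheral error score
  around 2%);
* non-OA patients score like controls; an optional motor elevation on
  the paretic contralesional hand (``motor_effect``) can be mixed in,
  affecting foveal and peripheral reaches alike so that it cancels in
  the OA difference score (off by default: it is not part of the
  stated cohort model, and it inflates the non-OA score variance);
* a minority of patients (default 5 of 28) are implanted with optic
  ataxia: their peripheral contralesional-hand/contralesional-space
  score distribution shifts strongly towards corrected errors
  (categories 1-2), with uncorrected errors (3-5) remaining rare;
* implanted OA patients receive lesions centred on central-thalamus
  nuclei (CL, CM, VL, VPL, MD) and carry bilateral lesions at a 60%
  rate; the remaining patients receive posterior lesions (pulvinar, LP)
  with a 13% bilateral rate.

The toy atlas tiles a thalamus-shaped box in each hemisphere with 17
disjoint cuboid nuclei, mirror-symmetric about the midsagittal plane,
so that atlas-referenced statements about simulated lesions are exact.

All randomness flows through one seeded generator; the truth labels are
written only to the truth sidecar, never into an analysed column.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .lesionmap import (
    AtlasDefinition,
    VolumeGrid,
    load_territories,
    save_atlas,
    write_volume,
)

log = logging.getLogger(__name__)

# ---------------------------------------------------------------------------
# raw-score distributions (categorical over error points 0..5)
# ---------------------------------------------------------------------------

#: foveal reaches: essentially error-free for everyone
FOVEAL_PROBS = (0.985, 0.010, 0.005, 0.0, 0.0, 0.0)

#: peripheral reaches, unimpaired: mild error rate (mean score ~2%)
PERIPHERAL_PROBS = (0.930, 0.045, 0.020, 0.004, 0.001, 0.0)

#: implanted optic ataxia, peripheral contralesional hand+space: mostly
#: corrected errors (points 1-2), uncorrected (3-5) rare (mean ~21%)
OA_PERIPHERAL_PROBS = (0.35, 0.38, 0.20, 0.05, 0.02, 0.0)

#: motor-elevation mixture component for the paretic contralesional hand
MOTOR_PROBS = (0.0, 0.7, 0.3, 0.0, 0.0, 0.0)


@dataclass
class CohortConfig:
    """Stated world of one simulated cohort.

    Cohort sizes, bilateral-lesion rates and clinical covariate rates
    follow the reference thalamic-stroke study design (28 patients, 40
    age-matched controls, 5 patients with optic ataxia; 60% vs 13%
    bilateral rate in OA vs non-OA patients); trial counts per condition
    are uniform on 11-16 valid trials.
    """

    n_patients: int = 28
    n_controls: int = 40
    n_oa: int = 5
    trials_per_condition: tuple[int, int] = (11, 16)
    invalid_mean: float = 1.0  # Poisson mean of invalid trials per condition
    seed: int = 0

    foveal_probs: tuple = FOVEAL_PROBS
    peripheral_probs: tuple = PERIPHERAL_PROBS
    oa_peripheral_probs: tuple = OA_PERIPHERAL_PROBS
    motor_probs: tuple = MOTOR_PROBS
    #: optional mixture weight of the motor component on the paretic
    #: contralesional hand (both viewing conditions, hence cancelling in
    #: the expected OA score); 0 by default — non-OA patients score like
    #: controls.  ~0.05 instead reproduces the reference patient medians
    #: (~0.9% foveal / ~3.4% peripheral) at the cost of a wider non-OA
    #: OA-score distribution
    motor_effect: float = 0.0
    #: mixture weight moving peripheral CH-CS mass to the OA distribution;
    #: 1.0 = fully implanted, 0.0 = indistinguishable from non-OA
    oa_effect: float = 1.0
    #: fraction of trials on which the second rater deviates by one point
    rater_disagreement_rate: float = 0.10

    bilateral_rate_oa: float = 0.60
    bilateral_rate_nonoa: float = 0.13
    #: secondary (contralateral) blob volume as a fraction of the primary
    bilateral_fraction: float = 0.25
    oa_target_nuclei: tuple = ("CL", "CM", "VL", "VPL", "MD")
    nonoa_target_nuclei: tuple = ("PuA", "PuM", "PuL", "PuI", "LP")
    targets_per_lesion: tuple[int, int] = (2, 3)
    #: lognormal lesion-size model (mm^3), clipped to the observed range
    lesion_size_median_mm3: float = 1100.0
    lesion_size_log_sd: float = 0.55
    lesion_size_range_mm3: tuple[float, float] = (170.8, 5712.9)

    #: clinical covariate marginal rates in the patient group
    clinical_rates: dict = field(
        default_factory=lambda: {
            "somatosensory_upper": 0.393,
            "somatosensory_lower": 0.25,
            "paresis_upper": 0.50,
            "paresis_lower": 0.321,
            "ataxia": 0.143,
            "aphasia": 0.107,
            "neglect": 0.036,
            "grasping_deficit": 0.286,
        }
    )

    grid_shape: tuple[int, int, int] = (60, 72, 60)
    voxel_size_mm: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.n_oa <= self.n_patients:
            raise ValueError("n_oa must lie in [0, n_patients]")
        for name in ("foveal_probs", "peripheral_probs", "oa_peripheral_probs", "motor_probs"):
            p = np.asarray(getattr(self, name), dtype=float)
            if p.size != 6 or p.min() < 0 or not np.isclose(p.sum(), 1.0):
                raise ValueError(f"{name} must be 6 probabilities summing to 1")
        for name in ("motor_effect", "oa_effect", "bilateral_rate_oa", "bilateral_rate_nonoa"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")


# ---------------------------------------------------------------------------
# toy atlas
# ---------------------------------------------------------------------------

# Cuboid nucleus boxes for the right hemisphere, as half-open index
# ranges relative to (midline, y0, z0).  Together they tile the box
# dx 2..19 x dy 0..29 x dz 0..17 without gaps or overlaps; the left
# hemisphere is the mirror image (same labels).
_NUCLEUS_BOXES: dict[str, tuple[int, int, int, int, int, int]] = {
    # medial column (near midline)
    "MD": (2, 10, 0, 10, 9, 18),
    "CeM": (2, 10, 0, 10, 0, 9),
    "CL": (2, 10, 10, 20, 9, 18),
    "CM": (2, 10, 10, 15, 0, 9),
    "Pf": (2, 10, 15, 20, 0, 9),
    # lateral column
    "VA": (10, 20, 0, 5, 0, 18),
    "VL": (10, 20, 5, 15, 9, 18),
    "VM": (10, 20, 5, 15, 0, 9),
    "VPL": (10, 20, 15, 20, 9, 18),
    "VPM": (10, 20, 15, 20, 0, 9),
    # posterior slab
    "LP": (2, 20, 20, 25, 9, 18),
    "PuA": (2, 20, 20, 25, 0, 9),
    "PuM": (2, 11, 25, 30, 0, 18),
    "PuL": (11, 20, 25, 30, 9, 18),
    "PuI": (11, 20, 25, 30, 4, 9),
    "LGN": (11, 16, 25, 30, 0, 4),
    "MGN": (16, 20, 25, 30, 0, 4),
}

NUCLEUS_NAMES = tuple(_NUCLEUS_BOXES)


def make_toy_atlas(
    grid_shape: tuple[int, int, int] = (60, 72, 60), voxel_size: float = 1.0
) -> AtlasDefinition:
    """A mirror-symmetric toy thalamus atlas with 17 cuboid nuclei.

    Each hemisphere hosts the same 17 disjoint nuclei (identical label
    values left and right), densely tiling a thalamus-sized box so that
    every voxel of the box belongs to exactly one nucleus.  The volume
    is exactly invariant under the midsagittal mirror operation.
    """
    nx, ny, nz = grid_shape
    mid = nx // 2
    y0 = ny // 2 - 12
    z0 = nz // 2 - 6
    if mid + 20 > nx or y0 < 0 or y0 + 30 > ny or z0 < 0 or z0 + 18 > nz:
        raise ValueError(f"grid {grid_shape} too small to host the toy atlas")
    vol = np.zeros(grid_shape, dtype=np.int16)
    labels: dict[int, str] = {}
    for value, (name, (x0, x1, ya, yb, za, zb)) in enumerate(_NUCLEUS_BOXES.items(), start=1):
        labels[value] = name
        ys = slice(y0 + ya, y0 + yb)
        zs = slice(z0 + za, z0 + zb)
        # right hemisphere
        vol[mid + x0 : mid + x1, ys, zs] = value
        # mirrored left hemisphere: index i maps to nx-1-i
        vol[nx - mid - x1 : nx - mid - x0, ys, zs] = value
    territories = {n: t for n, t in load_territories().items() if n in NUCLEUS_NAMES}
    grid = VolumeGrid(vol, (voxel_size,) * 3)
    return AtlasDefinition(volume=grid, labels=labels, territories=territories)


# ---------------------------------------------------------------------------
# lesion masks
# ---------------------------------------------------------------------------


def _hemisphere_selector(shape: tuple[int, int, int], side: str) -> np.ndarray:
    nx = shape[0]
    x = np.arange(nx)
    return (x < nx // 2) if side == "left" else (x >= (nx + 1) // 2)


def _ellipsoid_blob(
    region: np.ndarray,
    centre: np.ndarray,
    target_voxels: float,
    radii_ratio: np.ndarray,
) -> np.ndarray:
    """Binary ellipsoid of ~target_voxels voxels clipped to ``region``.

    The radius is rescaled iteratively to compensate for clipping, so
    the realised voxel count tracks the request closely.
    """
    shape = region.shape
    scale = (3.0 * target_voxels / (4.0 * np.pi)) ** (1.0 / 3.0)
    blob = None
    for _ in range(6):
        radii = np.maximum(scale * radii_ratio, 0.6)
        lo = np.maximum(np.floor(centre - radii).astype(int) - 1, 0)
        hi = np.minimum(np.ceil(centre + radii).astype(int) + 2, shape)
        grids = np.meshgrid(*[np.arange(lo[d], hi[d]) for d in range(3)], indexing="ij")
        dist2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, centre, radii))
        local = (dist2 <= 1.0) & region[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        count = int(local.sum())
        blob = np.zeros(shape, dtype=np.uint8)
        blob[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = local
        if count == 0:
            scale *= 1.3
            continue
        if abs(count - target_voxels) / target_voxels < 0.05:
            break
        scale *= (target_voxels / count) ** (1.0 / 3.0)
    return blob


def simulate_lesion_mask(
    atlas: AtlasDefinition,
    target_nuclei,
    size_mm3: float,
    side: str = "right",
    bilateral: bool = False,
    rng: np.random.Generator | None = None,
    bilateral_fraction: float = 0.25,
) -> VolumeGrid:
    """An ellipsoidal lesion blob centred on the chosen nuclei.

    The blob is centred (with a small random jitter) on the voxel
    centroid of the target nuclei in the chosen hemisphere and clipped
    to the atlas-labelled thalamic region, so the realised volume stays
    within a few percent of the request.  A bilateral lesion adds a
    mirrored secondary blob of ``bilateral_fraction`` times the primary
    volume (< 50%, so the predominant side is preserved).
    """
    rng = np.random.default_rng() if rng is None else rng
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    if not 0.0 < bilateral_fraction < 0.5:
        raise ValueError("bilateral_fraction must lie in (0, 0.5)")
    name_to_label = {v: k for k, v in atlas.labels.items()}
    missing = [n for n in target_nuclei if n not in name_to_label]
    if missing:
        raise ValueError(f"target nuclei not in atlas: {missing}")
    label_values = [name_to_label[n] for n in target_nuclei]
    vol = atlas.volume.voxels
    voxvol = atlas.volume.voxel_volume_mm3

    def _blob_on_side(blob_side: str, blob_mm3: float) -> np.ndarray:
        hemi = _hemisphere_selector(vol.shape, blob_side)[:, None, None]
        region = (vol > 0) & hemi
        targets = np.isin(vol, label_values) & hemi
        if not targets.any():
            raise ValueError(f"target nuclei empty in {blob_side} hemisphere")
        centre = np.array(np.nonzero(targets), dtype=float).mean(axis=1)
        centre += rng.uniform(-1.5, 1.5, size=3)
        ratio = rng.uniform(0.75, 1.30, size=3)
        ratio /= ratio.prod() ** (1.0 / 3.0)
        return _ellipsoid_blob(region, centre, blob_mm3 / voxvol, ratio)

    mask = _blob_on_side(side, size_mm3)
    if bilateral:
        other = "left" if side == "right" else "right"
        mask = mask | _blob_on_side(other, bilateral_fraction * size_mm3)
    return atlas.volume.like(mask.astype(np.uint8))


# ---------------------------------------------------------------------------
# trial ratings and clinical covariates
# ---------------------------------------------------------------------------


def condition_probabilities(
    config: CohortConfig,
    is_oa: bool,
    has_paresis: bool,
    lesion_side: str | None,
    hand: str,
    space: str,
    viewing: str,
) -> np.ndarray:
    """Raw-score distribution for one subject in one condition.

    Controls (``lesion_side`` None) use the base distributions.  A
    paretic patient's contralesional hand receives the motor mixture in
    *both* viewing conditions (it cancels in the OA score); an OA
    patient's peripheral contralesional-hand/contralesional-space
    condition is shifted towards the implanted OA distribution by
    ``oa_effect``.
    """
    p = np.asarray(
        config.foveal_probs if viewing == "foveal" else config.peripheral_probs,
        dtype=float,
    )
    if lesion_side is None:
        return p
    contra = "left" if lesion_side == "right" else "right"
    if has_paresis and hand == contra:
        p = (1.0 - config.motor_effect) * p + config.motor_effect * np.asarray(
            config.motor_probs
        )
    if is_oa and viewing == "peripheral" and hand == contra and space == contra:
        p = (1.0 - config.oa_effect) * p + config.oa_effect * np.asarray(
            config.oa_peripheral_probs
        )
    return p


def _simulate_subject_trials(
    rng: np.random.Generator,
    config: CohortConfig,
    subject_id: str,
    is_oa: bool,
    has_paresis: bool,
    lesion_side: str | None,
) -> list[dict]:
    lo, hi = config.trials_per_condition
    rows = []
    for hand in ("left", "right"):
        for space in ("left", "right"):
            for viewing in ("foveal", "peripheral"):
                p = condition_probabilities(
                    config, is_oa, has_paresis, lesion_side, hand, space, viewing
                )
                n_valid = int(rng.integers(lo, hi + 1))
                n_invalid = int(rng.poisson(config.invalid_mean))
                scores = rng.choice(6, size=n_valid + n_invalid, p=p)
                valid = np.ones(n_valid + n_invalid, dtype=bool)
                if n_invalid:
                    valid[rng.choice(n_valid + n_invalid, n_invalid, replace=False)] = False
                for i, (s, v) in enumerate(zip(scores, valid)):
                    rows.append(
                        {
                            "subject_id": subject_id,
                            "trial_id": f"{hand[0]}{space[0]}{viewing[0]}{i:02d}",
                            "hand": hand,
                            "space": space,
                            "viewing": viewing,
                            "raw_score": int(s),
                            "valid": bool(v),
                        }
                    )
    return rows


def _add_second_rater(
    rng: np.random.Generator, trials: pd.DataFrame, disagreement_rate: float
) -> pd.DataFrame:
    """Duplicate the ratings as a second rater with occasional +/-1 shifts."""
    r1 = trials.copy()
    r1["rater_id"] = "R1"
    r2 = trials.copy()
    r2["rater_id"] = "R2"
    flip = rng.random(len(r2)) < disagreement_rate
    delta = rng.choice([-1, 1], size=len(r2))
    shifted = np.clip(r2["raw_score"].to_numpy() + np.where(flip, delta, 0), 0, 5)
    r2["raw_score"] = shifted
    return pd.concat([r1, r2], ignore_index=True)


def simulate_trial_ratings(
    config: CohortConfig,
    subjects: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Two-rater trial table for all subjects of a cohort.

    ``subjects`` needs columns subject_id, is_oa, paresis_upper and
    lesion_side (NaN/None for controls).
    """
    rows: list[dict] = []
    for _, s in subjects.iterrows():
        side = s["lesion_side"] if isinstance(s["lesion_side"], str) else None
        rows.extend(
            _simulate_subject_trials(
                rng,
                config,
                s["subject_id"],
                bool(s["is_oa"]),
                bool(s["paresis_upper"]),
                side,
            )
        )
    trials = pd.DataFrame(rows)
    return _add_second_rater(rng, trials, config.rater_disagreement_rate)


def expected_mean_error_score(probs) -> float:
    """Expected percentage mean error score of a raw-score distribution."""
    p = np.asarray(probs, dtype=float)
    return 100.0 * float((p * np.arange(6)).sum()) / 5.0


def expected_oa_score(config: CohortConfig) -> float:
    """Expected contralesional OA score implanted in an OA patient."""
    peri = condition_probabilities(config, True, False, "left", "right", "right", "peripheral")
    fov = condition_probabilities(config, True, False, "left", "right", "right", "foveal")
    return expected_mean_error_score(peri) - expected_mean_error_score(fov)


# ---------------------------------------------------------------------------
# full cohort bundles
# ---------------------------------------------------------------------------


@dataclass
class CohortBundle:
    """Everything a pipeline run needs, with the generating truth."""

    ratings: pd.DataFrame
    clinical: pd.DataFrame
    masks: dict[str, VolumeGrid]
    atlas: AtlasDefinition
    truth: dict


def simulate_clinical(
    config: CohortConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, dict]:
    """Clinical covariate table plus the hidden truth assignment."""
    n = config.n_patients
    patient_ids = [f"P{i + 1:03d}" for i in range(n)]
    control_ids = [f"C{i + 1:03d}" for i in range(config.n_controls)]
    oa_idx = set(rng.choice(n, size=config.n_oa, replace=False).tolist())
    # balanced left/right lesion sides, randomly permuted
    sides = np.array(["left", "right"])[
        rng.permutation(np.arange(n) % 2)
    ]
    rows = []
    truth_lesions = {}
    for i, sid in enumerate(patient_ids):
        is_oa = i in oa_idx
        rate = config.bilateral_rate_oa if is_oa else config.bilateral_rate_nonoa
        bilateral = bool(rng.random() < rate)
        covs = {k: bool(rng.random() < v) for k, v in config.clinical_rates.items()}
        rows.append(
            {
                "subject_id": sid,
                "cohort": "patient",
                "age": float(np.clip(rng.normal(58.9, 12.6), 24.0, 81.0)),
                "sex": "male" if rng.random() < 0.75 else "female",
                "handedness": "right" if rng.random() < 27 / 28 else "left",
                "aetiology": "infarct" if rng.random() < 26 / 28 else "haemorrhage",
                "lesion_side": sides[i],
                "days_since_stroke": int(rng.integers(2, 10)),
                **covs,
            }
        )
        truth_lesions[sid] = {"is_oa": is_oa, "side": str(sides[i]), "bilateral": bilateral}
    for sid in control_ids:
        rows.append(
            {
                "subject_id": sid,
                "cohort": "control",
                "age": float(np.clip(rng.normal(60.6, 9.1), 40.0, 82.0)),
                "sex": "male" if rng.random() < 0.5 else "female",
                "handedness": "right",
                "aetiology": "",
                "lesion_side": "",
                "days_since_stroke": 0,
                **{k: False for k in config.clinical_rates},
            }
        )
    clinical = pd.DataFrame(rows)
    truth = {
        "oa_subjects": sorted(sid for sid, t in truth_lesions.items() if t["is_oa"]),
        "lesions": truth_lesions,
    }
    return clinical, truth


def simulate_cohort(config: CohortConfig, out_dir=None) -> CohortBundle:
    """Generate a complete, self-consistent synthetic cohort.

    Deterministic given ``config.seed``; rerunning with the same
    configuration reproduces the bundle (and byte-identical CSV files
    when written).  When ``out_dir`` is given, writes ratings.csv,
    clinical.csv, masks/<subject>.nii.gz, atlas.nii.gz, atlas.yaml and
    truth.json.
    """
    rng = np.random.default_rng(config.seed)
    clinical, truth = simulate_clinical(config, rng)
    atlas = make_toy_atlas(config.grid_shape, config.voxel_size_mm)
    lo, hi = config.lesion_size_range_mm3
    t_lo, t_hi = config.targets_per_lesion

    masks: dict[str, VolumeGrid] = {}
    for sid, info in truth["lesions"].items():
        pool = config.oa_target_nuclei if info["is_oa"] else config.nonoa_target_nuclei
        k = int(rng.integers(t_lo, t_hi + 1))
        targets = sorted(rng.choice(list(pool), size=min(k, len(pool)), replace=False).tolist())
        size = float(
            np.clip(
                config.lesion_size_median_mm3
                * np.exp(rng.normal(0.0, config.lesion_size_log_sd)),
                lo,
                hi,
            )
        )
        masks[sid] = simulate_lesion_mask(
            atlas,
            targets,
            size,
            side=info["side"],
            bilateral=info["bilateral"],
            rng=rng,
            bilateral_fraction=config.bilateral_fraction,
        )
        info["targets"] = targets
        info["requested_mm3"] = round(size, 1)

    subjects = clinical[["subject_id", "cohort", "lesion_side", "paresis_upper"]].copy()
    subjects["lesion_side"] = subjects["lesion_side"].where(subjects["lesion_side"] != "", None)
    oa_set = set(truth["oa_subjects"])
    subjects["is_oa"] = subjects["subject_id"].isin(oa_set)
    ratings = simulate_trial_ratings(config, subjects, rng)

    truth["seed"] = config.seed
    truth["config"] = {
        k: (list(v) if isinstance(v, tuple) else v)
        for k, v in dataclasses.asdict(config).items()
    }
    bundle = CohortBundle(ratings=ratings, clinical=clinical, masks=masks, atlas=atlas, truth=truth)
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def write_bundle(bundle: CohortBundle, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.ratings.to_csv(out / "ratings.csv", index=False)
    bundle.clinical.to_csv(out / "clinical.csv", index=False)
    mask_dir = out / "masks"
    mask_dir.mkdir(exist_ok=True)
    for sid, mask in bundle.masks.items():
        write_volume(mask, mask_dir / f"{sid}.nii.gz")
    save_atlas(bundle.atlas, out / "atlas.nii.gz", out / "atlas.yaml")
    (out / "truth.json").write_text(json.dumps(bundle.truth, indent=2, sort_keys=True))
    log.info("wrote synthetic cohort bundle to %s", out)
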