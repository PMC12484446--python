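"""End-to-end study pipeline: scoring -> classification -> lesion maps.

``run_study`` reproduces the full analysis from raw inputs in one call:

1. aggregate the raters, validate trials and compute per-condition
   error scores; patients are scored in the lesion frame (ipsi/contra),
   controls once per candidate framing (left- or right-as-ipsi);
2. pick the balanced control side assignment, build the normative
   model and classify every patient per hand/space combination;
3. group statistics: Mann-Whitney U tests patients vs controls on the
   congruent condition scores (Bonferroni alpha = 0.05/4) and on the OA
   scores (alpha = 0.05/2), plus the 2x2x2 mixed ANOVA;
4. lesion cartography: per-patient volume/laterality/nucleus profile,
   group overlap maps, the OA-vs-non-OA percentage subtraction map and
   the same subtraction applied to the paresis, somatosensory and
   grasping groupings (one code path, the grouping is data);
5. cohort summary tables comparing OA and non-OA patients with
   chi-square or Mann-Whitney tests as appropriate.

Without lesion masks the pipeline degrades to a behaviour-only report
(lesion sides then come from the clinical table).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import lesionmap as lm
from . import normative as nm
from . import scoring as sc

log = logging.getLogger(__name__)

OA_COMBOS = [("contra", "contra"), ("contra", "ipsi"), ("ipsi", "contra"), ("ipsi", "ipsi")]
CONGRUENT_COMBOS = [("contra", "contra"), ("ipsi", "ipsi")]

COMBO_NAMES = {
    ("contra", "contra"): "CH-CS",
    ("contra", "ipsi"): "CH-IS",
    ("ipsi", "contra"): "IH-CS",
    ("ipsi", "ipsi"): "IH-IS",
}

CATEGORICAL_COVARIATES = {
    "handedness": "right",
    "sex": "male",
    "aetiology": "infarct",
    "lesion_side": "left",
    "bilateral": True,
    "somatosensory_upper": True,
    "somatosensory_lower": True,
    "paresis_upper": True,
    "paresis_lower": True,
    "ataxia": True,
    "aphasia": True,
    "neglect": True,
    "grasping_deficit": True,
}

CONTINUOUS_COVARIATES = ["age", "lesion_size_mm3", "days_since_stroke"]

CONTROL_ANALYSES = ["paresis_upper", "somatosensory_upper", "grasping_deficit"]


class StudyError(RuntimeError):
    """A pipeline stage failed; the message carries the stage tag."""


@dataclass
class StudyConfig:
    """All tunable thresholds of a study run."""

    min_valid: int = sc.DEFAULT_MIN_VALID
    n_perm: int = nm.DEFAULT_N_PERM
    seed: int = 0
    z_threshold: float = nm.DEFAULT_Z_THRESHOLD
    alpha: float = nm.DEFAULT_ALPHA
    display_threshold: float = lm.DEFAULT_DISPLAY_THRESHOLD
    affected_min_voxels: int = lm.DEFAULT_AFFECTED_MIN_VOXELS
    bilateral_min_voxels: int = lm.DEFAULT_BILATERAL_MIN_VOXELS
    reference_hemisphere: str = lm.DEFAULT_REFERENCE

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class StudyReport:
    """All pipeline products of one run."""

    condition_scores: pd.DataFrame  # patients, lesion frame
    control_scores: pd.DataFrame  # controls, assigned ipsi/contra frame
    oa_scores: pd.DataFrame  # patients
    classification: pd.DataFrame
    normative: dict  # mu/sigma per measure, assignment metadata
    group_stats: dict
    table1: dict
    table2: pd.DataFrame | None
    lesion_stats: pd.DataFrame | None
    nucleus_frequency: dict | None  # per grouping: DataFrame
    maps: dict | None = field(repr=False, default=None)  # GroupMaps per grouping
    provenance: dict = field(default_factory=dict)


def _stage(name):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StudyError:
                raise
            except Exception as e:  # noqa: BLE001 - tag and re-raise
                raise StudyError(f"[{name}] {e}") from e

        return wrapper

    return deco


# ---------------------------------------------------------------------------
# behavioural stages
# ---------------------------------------------------------------------------


@_stage("scoring")
def score_cohort(
    ratings: pd.DataFrame, lesion_side: dict[str, str], config: StudyConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Patient scores in the lesion frame; control scores per framing.

    Returns ``(patient_scores, patient_oa, controls_left_ipsi,
    controls_right_ipsi)``; the control tables are the condition scores
    under the two candidate side assignments, in ipsi/contra labels.
    """
    trials = sc.aggregate_raters(ratings)
    valid, _counts = sc.validate_trials(trials, config.min_valid)
    patients = valid[valid["subject_id"].isin(lesion_side)]
    controls = valid[~valid["subject_id"].isin(lesion_side)]
    if len(patients) == 0 or len(controls) == 0:
        raise ValueError("need trials for both patients and controls")
    pat_frame = sc.convert_to_lesion_frame(patients, lesion_side)
    pat_scores = sc.condition_scores(pat_frame, config.min_valid)
    pat_oa = sc.oa_scores(pat_scores)
    ctrl_ids = controls["subject_id"].unique()
    ctrl_left = sc.condition_scores(
        sc.convert_to_lesion_frame(controls, {c: "left" for c in ctrl_ids}),
        config.min_valid,
    )
    ctrl_right = sc.condition_scores(
        sc.convert_to_lesion_frame(controls, {c: "right" for c in ctrl_ids}),
        config.min_valid,
    )
    for subj_log in (pat_scores, ctrl_left):
        for sid in subj_log["subject_id"].unique():
            log.info("scored subject %s", sid)
    return pat_scores, pat_oa, ctrl_left, ctrl_right


def _measure_table(scores: pd.DataFrame) -> pd.DataFrame:
    """Controls x measures matrix: 8 condition cells + 4 OA combos."""
    cond = scores.pivot_table(
        index="subject_id",
        columns=["hand", "space", "viewing"],
        values="mean_error_score",
        dropna=False,
    )
    cond.columns = [("cond",) + c for c in cond.columns]
    oa = sc.oa_scores(scores).pivot_table(
        index="subject_id", columns=["hand", "space"], values="oa_score", dropna=False
    )
    oa.columns = [("oa",) + c for c in oa.columns]
    return cond.join(oa).sort_index()


@_stage("normative")
def build_norms(
    ctrl_left: pd.DataFrame, ctrl_right: pd.DataFrame, config: StudyConfig
) -> tuple[nm.NormativeModel, pd.DataFrame]:
    """Balanced control assignment, normative model, assigned-frame scores."""
    left = _measure_table(ctrl_left)
    right = _measure_table(ctrl_right)
    assignment = nm.assign_control_sides(
        left, right, n_perm=config.n_perm, seed=config.seed
    )
    model = nm.build_normative_model(left, right, assignment)
    assigned = pd.DataFrame(
        np.where(assignment.left_as_ipsi[:, None], left.to_numpy(), right.to_numpy()),
        index=left.index,
        columns=left.columns,
    )
    return model, assigned


@_stage("classification")
def classify_patients(
    pat_oa: pd.DataFrame, model: nm.NormativeModel, config: StudyConfig
) -> pd.DataFrame:
    oa_model = nm.NormativeModel(
        measures=[m[1:] for m in model.measures if m[0] == "oa"],
        mu=np.array([model.loc(m)[0] for m in model.measures if m[0] == "oa"]),
        sigma=np.array([model.loc(m)[1] for m in model.measures if m[0] == "oa"]),
        n_controls=model.n_controls,
        assignment=model.assignment,
    )
    out = nm.classify_oa(pat_oa, oa_model, config.z_threshold, config.alpha)
    for sid in out["subject_id"].unique():
        log.info("classified subject %s", sid)
    return out


@_stage("group-stats")
def group_statistics(
    pat_scores: pd.DataFrame,
    pat_oa: pd.DataFrame,
    ctrl_assigned: pd.DataFrame,
    config: StudyConfig,
) -> dict:
    """Patients-vs-controls U tests (Bonferroni-corrected) and the ANOVA."""
    stats: dict = {}
    alpha4 = nm.bonferroni_alpha(config.alpha, 4)
    cond_tests = []
    for hand, space in CONGRUENT_COMBOS:
        for viewing in sc.VIEWINGS:
            pat = pat_scores.query(
                "hand == @hand and space == @space and viewing == @viewing"
            )["mean_error_score"].dropna()
            ctrl = ctrl_assigned[("cond", hand, space, viewing)].dropna()
            res = nm.mann_whitney_u(pat, ctrl)
            cond_tests.append(
                {
                    "measure": f"{COMBO_NAMES[(hand, space)]} {viewing}",
                    "U": res.statistic,
                    "p": res.p,
                    "method": res.method,
                    "alpha_corrected": alpha4,
                    "significant": res.p < alpha4,
                }
            )
    stats["condition_utests"] = cond_tests
    alpha2 = nm.bonferroni_alpha(config.alpha, 2)
    oa_tests = []
    for hand, space in CONGRUENT_COMBOS:
        pat = pat_oa.query("hand == @hand and space == @space")["oa_score"].dropna()
        ctrl = ctrl_assigned[("oa", hand, space)].dropna()
        res = nm.mann_whitney_u(pat, ctrl)
        oa_tests.append(
            {
                "measure": f"OA {COMBO_NAMES[(hand, space)]}",
                "U": res.statistic,
                "p": res.p,
                "method": res.method,
                "alpha_corrected": alpha2,
                "significant": res.p < alpha2,
            }
        )
    stats["oa_utests"] = oa_tests

    congruent = pat_scores[
        [(h, s) in CONGRUENT_COMBOS for h, s in zip(pat_scores["hand"], pat_scores["space"])]
    ].copy()
    congruent["group"] = "patient"
    congruent["side"] = [COMBO_NAMES[(h, s)] for h, s in zip(congruent["hand"], congruent["space"])]
    ctrl_long = []
    for hand, space in CONGRUENT_COMBOS:
        for viewing in sc.VIEWINGS:
            col = ("cond", hand, space, viewing)
            for sid, val in ctrl_assigned[col].items():
                ctrl_long.append(
                    {
                        "subject_id": sid,
                        "group": "control",
                        "side": COMBO_NAMES[(hand, space)],
                        "viewing": viewing,
                        "mean_error_score": val,
                    }
                )
    anova_data = pd.concat(
        [
            congruent[["subject_id", "group", "side", "viewing", "mean_error_score"]],
            pd.DataFrame(ctrl_long),
        ],
        ignore_index=True,
    )
    stats["anova"] = nm.mixed_anova_2x2x2(
        anova_data, group="group", viewing="viewing", side="side", score="mean_error_score"
    )
    return stats


# ---------------------------------------------------------------------------
# lesion stages
# ---------------------------------------------------------------------------


@_stage("lesion-stats")
def lesion_statistics(
    masks: dict[str, lm.VolumeGrid], atlas: lm.AtlasDefinition, config: StudyConfig
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame]]:
    rows = []
    profiles: dict[str, pd.DataFrame] = {}
    for sid in sorted(masks):
        st = lm.lesion_stats(
            sid,
            masks[sid],
            atlas,
            affected_min_voxels=config.affected_min_voxels,
            bilateral_min_voxels=config.bilateral_min_voxels,
        )
        profiles[sid] = st.profile
        rows.append(
            {
                "subject_id": sid,
                "lesion_size_mm3": st.volume_mm3,
                "lesion_side": st.predominant_side,
                "bilateral": st.bilateral,
                "territory": st.territory,
            }
        )
        log.info("lesion stats for subject %s", sid)
    return pd.DataFrame(rows), profiles


@_stage("lesion-maps")
def lesion_maps(
    masks: dict[str, lm.VolumeGrid],
    sides: dict[str, str],
    groupings: dict[str, dict[str, bool]],
    config: StudyConfig,
) -> dict[str, lm.GroupMaps]:
    """Subtraction maps for each grouping (OA and the control analyses).

    Every mask is first mirrored onto the reference hemisphere.  The
    same subtraction machinery serves the OA contrast and the paresis /
    somatosensory / grasping control analyses; only the grouping
    differs.
    """
    flipped = {
        sid: lm.flip_to_reference_hemisphere(m, sides[sid], config.reference_hemisphere)
        for sid, m in masks.items()
    }
    out = {}
    for name, flags in groupings.items():
        in_group = [flipped[s] for s in sorted(flipped) if flags.get(s)]
        out_group = [flipped[s] for s in sorted(flipped) if s in flags and not flags[s]]
        if not in_group or not out_group:
            log.warning("grouping %r has an empty side; skipping its subtraction map", name)
            continue
        out[name] = lm.subtraction_map(in_group, out_group, config.display_threshold)
    return out


# ---------------------------------------------------------------------------
# summary tables
# ---------------------------------------------------------------------------


def _chi2_or_degenerate(a: int, b: int, c: int, d: int) -> nm.TestResult:
    """Pearson chi-square; a constant covariate carries no information."""
    try:
        return nm.chi_square_2x2(a, b, c, d)
    except ValueError:
        return nm.TestResult(statistic=0.0, p=1.0, method="chi-square-degenerate", df=1)


@_stage("table2")
def summarize_group(clinical_patients: pd.DataFrame, oa_flags: pd.Series) -> pd.DataFrame:
    """OA vs non-OA patient comparison per covariate (chi-square / U).

    ``oa_flags`` maps patient id to the contralesional-OA flag.
    Categorical covariates are tested with the Pearson chi-square on
    the 2x2 counts, continuous ones with the Mann-Whitney U.
    """
    df = clinical_patients.set_index("subject_id")
    flags = oa_flags.reindex(df.index)
    grp_oa = df[flags == True]  # noqa: E712 - flags may hold pd.NA
    grp_non = df[flags == False]  # noqa: E712
    if len(grp_oa) == 0 or len(grp_non) == 0:
        log.warning("one classification group is empty; no group comparison table")
        return None
    rows = []
    for cov, positive in CATEGORICAL_COVARIATES.items():
        if cov not in df.columns:
            continue
        a = int((grp_oa[cov] == positive).sum())
        b = len(grp_oa) - a
        c = int((grp_non[cov] == positive).sum())
        d = len(grp_non) - c
        res = _chi2_or_degenerate(a, b, c, d)
        rows.append(
            {
                "covariate": cov,
                "oa_value": 100.0 * a / len(grp_oa),
                "nonoa_value": 100.0 * c / len(grp_non),
                "unit": "%",
                "counts": (a, b, c, d),
                "test": res.method,
                "statistic": res.statistic,
                "p": res.p,
            }
        )
    for cov in CONTINUOUS_COVARIATES:
        if cov not in df.columns:
            continue
        x = grp_oa[cov].dropna()
        y = grp_non[cov].dropna()
        if len(x) == 0 or len(y) == 0:
            continue
        res = nm.mann_whitney_u(x, y)
        rows.append(
            {
                "covariate": cov,
                "oa_value": float(x.median()),
                "nonoa_value": float(y.median()),
                "unit": "median",
                "counts": None,
                "test": res.method,
                "statistic": res.statistic,
                "p": res.p,
            }
        )
    return pd.DataFrame(rows)


@_stage("table1")
def summarize_cohort(
    clinical_patients: pd.DataFrame, lesion_stats_df: pd.DataFrame | None
) -> dict:
    """Demographics, lesion territories and symptom rates of the cohort."""
    df = clinical_patients
    out = {
        "n_patients": int(len(df)),
        "age_mean": float(df["age"].mean()),
        "age_range": [float(df["age"].min()), float(df["age"].max())],
        "n_male": int((df["sex"] == "male").sum()),
        "n_right_handed": int((df["handedness"] == "right").sum()),
        "n_infarct": int((df["aetiology"] == "infarct").sum()),
        "symptom_rates_pct": {
            cov: float(100.0 * df[cov].mean())
            for cov in (
                "somatosensory_upper",
                "somatosensory_lower",
                "paresis_upper",
                "paresis_lower",
                "ataxia",
                "aphasia",
                "neglect",
            )
            if cov in df.columns
        },
    }
    if lesion_stats_df is not None:
        out["lesion_size_median_mm3"] = float(lesion_stats_df["lesion_size_mm3"].median())
        out["lesion_size_range_mm3"] = [
            float(lesion_stats_df["lesion_size_mm3"].min()),
            float(lesion_stats_df["lesion_size_mm3"].max()),
        ]
        out["territory_counts"] = (
            lesion_stats_df["territory"].value_counts().to_dict()
        )
        out["lesion_side_counts"] = (
            lesion_stats_df["lesion_side"].value_counts().to_dict()
        )
        out["n_bilateral"] = int(lesion_stats_df["bilateral"].sum())
    return out


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------


def run_study(
    ratings: pd.DataFrame,
    clinical: pd.DataFrame,
    masks: dict[str, lm.VolumeGrid] | None = None,
    atlas: lm.AtlasDefinition | None = None,
    config: StudyConfig | None = None,
) -> StudyReport:
    """Run the complete analysis; deterministic given the config seed."""
    config = config or StudyConfig()
    patients = clinical[clinical["cohort"] == "patient"]
    lesion_stats_df = None
    profiles = None
    nucleus_freq = None
    maps = None

    if masks:
        if atlas is None:
            raise StudyError("[inputs] lesion masks given without an atlas")
        lesion_stats_df, profiles = lesion_statistics(masks, atlas, config)
        sides = dict(zip(lesion_stats_df["subject_id"], lesion_stats_df["lesion_side"]))
        clin_sides = dict(zip(patients["subject_id"], patients.get("lesion_side", "")))
        for sid, side in sides.items():
            if clin_sides.get(sid) and clin_sides[sid] != side:
                log.warning(
                    "subject %s: clinical lesion side %r disagrees with the mask (%r); using the mask",
                    sid,
                    clin_sides[sid],
                    side,
                )
    else:
        sides = {
            r["subject_id"]: r["lesion_side"]
            for _, r in patients.iterrows()
            if isinstance(r.get("lesion_side"), str) and r["lesion_side"]
        }
        missing = set(patients["subject_id"]) - set(sides)
        if missing:
            raise StudyError(f"[inputs] no lesion side for patient(s) {sorted(missing)}")

    pat_scores, pat_oa, ctrl_left, ctrl_right = score_cohort(ratings, sides, config)
    model, ctrl_assigned = build_norms(ctrl_left, ctrl_right, config)
    classification = classify_patients(pat_oa, model, config)
    group_stats = group_statistics(pat_scores, pat_oa, ctrl_assigned, config)

    oa_flags = (
        classification.drop_duplicates("subject_id")
        .set_index("subject_id")["contralesional_oa"]
    )

    patients_aug = patients.copy()
    if lesion_stats_df is not None:
        patients_aug = patients_aug.drop(
            columns=[c for c in ("lesion_side", "bilateral", "lesion_size_mm3") if c in patients_aug],
            errors="ignore",
        ).merge(lesion_stats_df, on="subject_id", how="left")
        groupings = {"oa": {sid: bool(f) for sid, f in oa_flags.items() if not pd.isna(f)}}
        for cov in CONTROL_ANALYSES:
            if cov in patients_aug.columns:
                groupings[cov] = dict(
                    zip(patients_aug["subject_id"], patients_aug[cov].astype(bool))
                )
        maps = lesion_maps(masks, sides, groupings, config)
        nucleus_freq = {}
        oa_ids = [s for s, f in oa_flags.items() if f is True]
        non_ids = [s for s, f in oa_flags.items() if f is False]
        nucleus_freq["all"] = lm.cohort_nucleus_frequency(profiles.values())
        if oa_ids:
            nucleus_freq["oa"] = lm.cohort_nucleus_frequency(
                [profiles[s] for s in oa_ids if s in profiles]
            )
        if non_ids:
            nucleus_freq["non_oa"] = lm.cohort_nucleus_frequency(
                [profiles[s] for s in non_ids if s in profiles]
            )

    table1 = summarize_cohort(patients, lesion_stats_df)
    table2 = summarize_group(patients_aug, oa_flags)

    from . import __version__

    provenance = {
        "config": config.to_dict(),
        "config_hash": config.config_hash,
        "seed": config.seed,
        "n_perm": config.n_perm,
        "balance_loss": model.assignment.balance_loss,
        "version": __version__,
    }
    return StudyReport(
        condition_scores=pat_scores,
        control_scores=ctrl_assigned,
        oa_scores=pat_oa,
        classification=classification,
        normative={
            "measures": ["/".join(map(str, m)) for m in model.measures],
            "mu": model.mu.tolist(),
            "sigma": model.sigma.tolist(),
            "n_controls": model.n_controls,
            "balance_loss": model.assignment.balance_loss,
        },
        group_stats=group_stats,
        table1=table1,
        table2=table2,
        lesion_stats=lesion_stats_df,
        nucleus_frequency=nucleus_freq,
        maps=maps,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------


def _round_floats(obj, ndigits=4):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def report_dict(report: StudyReport) -> dict:
    """JSON-serialisable summary of a study report.

    Every reported percentage remains recomputable from the included
    per-subject tables.
    """
    def df_records(df):
        if df is None:
            return None
        out = df.copy()
        out.columns = [str(c) for c in out.columns]
        return json.loads(out.to_json(orient="records"))

    anova = report.group_stats["anova"].round(6)
    d = {
        "provenance": report.provenance,
        "classification": df_records(report.classification),
        "oa_patients": sorted(
            report.classification.loc[
                report.classification["contralesional_oa"] == True, "subject_id"  # noqa: E712
            ].unique().tolist()
        ),
        "condition_scores": df_records(report.condition_scores.round(4)),
        "oa_scores": df_records(report.oa_scores.round(4)),
        "normative": _round_floats(report.normative),
        "group_stats": {
            "condition_utests": _round_floats(report.group_stats["condition_utests"]),
            "oa_utests": _round_floats(report.group_stats["oa_utests"]),
            "anova": {
                effect: {k: float(v) for k, v in row.items()}
                for effect, row in anova.iterrows()
            },
        },
        "table1": _round_floats(report.table1),
        "table2": df_records(report.table2.round(4)) if report.table2 is not None else None,
        "lesion_stats": df_records(
            report.lesion_stats.round(2) if report.lesion_stats is not None else None
        ),
        "nucleus_frequency": {
            name: df_records(freq.round(2).reset_index())
            for name, freq in (report.nucleus_frequency or {}).items()
        }
        or None,
    }
    return d


def report_json(report: StudyReport) -> str:
    return json.dumps(report_dict(report), indent=2, sort_keys=True)


def _report_markdown(report: StudyReport) -> str:
    d = report_dict(report)
    lines = ["# Study report", ""]
    lines.append(f"Config hash: `{d['provenance']['config_hash']}`, seed {d['provenance']['seed']}")
    lines.append("")
    lines.append(f"## Classification\n\nPatients with contralesional OA: {d['oa_patients']}")
    lines.append("\n## Group statistics\n")
    for t in d["group_stats"]["condition_utests"] + d["group_stats"]["oa_utests"]:
        star = "*" if t["significant"] else ""
        lines.append(
            f"- {t['measure']}: U = {t['U']}, p = {t['p']}{star} "
            f"(Bonferroni alpha = {t['alpha_corrected']})"
        )
    lines.append("\n### Mixed ANOVA (GROUP x VIEWING x SIDE)\n")
    for effect, row in d["group_stats"]["anova"].items():
        lines.append(
            f"- {effect}: F({int(row['df1'])},{int(row['df2'])}) = {row['F']:.2f}, "
            f"p = {row['p']:.4f}, partial eta2 = {row['eta_p2']:.3f}"
        )
    if d["table2"]:
        lines.append("\n## OA vs non-OA patients\n")
        for r in d["table2"]:
            lines.append(
                f"- {r['covariate']}: OA {r['oa_value']:.1f} vs non-OA "
                f"{r['nonoa_value']:.1f} ({r['unit']}); {r['test']}: "
                f"stat = {r['statistic']:.3f}, p = {r['p']:.3f}"
            )
    if d["nucleus_frequency"]:
        lines.append("\n## Nucleus lesion frequencies (% of group)\n")
        for name, rows in d["nucleus_frequency"].items():
            pct = {r["nucleus"]: r["pct_affected"] for r in rows}
            lines.append(f"- {name}: " + ", ".join(f"{k} {v:.1f}%" for k, v in pct.items()))
    lines.append("")
    return "\n".join(lines)


def write_report(report: StudyReport, out_dir) -> None:
    """Write report.json, report.md, CSV tables and NIfTI maps."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(report_json(report))
    (out / "report.md").write_text(_report_markdown(report))
    report.condition_scores.to_csv(out / "condition_scores.csv", index=False)
    report.oa_scores.to_csv(out / "oa_scores.csv", index=False)
    report.classification.to_csv(out / "classification.csv", index=False)
    if report.lesion_stats is not None:
        report.lesion_stats.to_csv(out / "lesion_stats.csv", index=False)
    if report.maps:
        map_dir = out / "maps"
        map_dir.mkdir(exist_ok=True)
        for name, gm in report.maps.items():
            lm.write_volume(gm.pct_a, map_dir / f"{name}_pct_in.nii.gz")
            lm.write_volume(gm.pct_b, map_dir / f"{name}_pct_out.nii.gz")
            lm.write_volume(gm.diff, map_dir / f"{name}_diff.nii.gz")
            lm.write_volume(gm.diff_display, map_dir / f"{name}_diff_thresh.nii.gz")
    log.info("report written to %s", out)
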