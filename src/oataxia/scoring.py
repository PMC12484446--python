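"""Trial-level reach-error scoring for the bedside optic-ataxia task.

Each reach attempt towards a pen held in the visual periphery is rated
offline from video with integer error points:

====  =============================================
0     fluent reach
1     slowed / insecure
2     corrected during the reach
3     corrected after the first reach
4     corrected after the second reach
5     failed to reach the target
====  =============================================

Trials are organised in a 2 x 2 x 2 design: hand (left/right) x space
(left/right) x viewing condition (foveal: the subject looks at the pen;
peripheral: the subject fixates the camera).  Per condition a percentage
mean error score is computed as

    mean error score = 100 * sum(points) / (5 * n_trials)

ranging from 0 (no error in any trial) to 100.  The optic-ataxia (OA)
score for a hand/space combination is the peripheral minus the foveal
mean error score; purely motor factors (paresis, tremor) affect both
viewing conditions alike and cancel in the difference.

For patients, hand and space labels are re-expressed relative to the
lesioned hemisphere ("ipsi"/"contra"); see :func:`to_lesion_frame`.
"""
from __future__ import annotations

import itertools
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SIDES = ("left", "right")
FRAMES = ("ipsi", "contra")
VIEWINGS = ("foveal", "peripheral")

MAX_RAW_SCORE = 5

#: default minimum number of valid trials for a condition score to be reported
DEFAULT_MIN_VALID = 5

CONDITION_COLS = ["hand", "space", "viewing"]

SCORE_COLUMNS = [
    "n_valid",
    "mean_error_score",
    "pct_fluent",
    "pct_corrected",
    "pct_uncorrected",
]


class LabelError(ValueError):
    """A trial table contains a value outside its closed label set."""


def _check_labels(values: pd.Series, allowed: Iterable[str], field: str) -> None:
    bad = set(values.dropna().unique()) - set(allowed)
    if bad:
        raise LabelError(
            f"unknown value(s) {sorted(bad)} in field {field!r}; "
            f"allowed: {sorted(set(allowed))}"
        )


def mean_error_score(trial_scores: Sequence[float]) -> float:
    """Percentage mean error score of a list of per-trial error points.

    Defined as ``100 * sum(points) / (5 * n)``.  Points may be
    non-integer when two raters were averaged.  An empty list yields
    NaN (a missing score, *not* a perfect one).
    """
    s = np.asarray(trial_scores, dtype=float)
    if s.size == 0:
        return float("nan")
    if not np.all(np.isfinite(s)) or s.min() < 0 or s.max() > MAX_RAW_SCORE:
        raise ValueError(f"trial error points must lie in [0, {MAX_RAW_SCORE}]")
    return 100.0 * float(s.sum()) / (MAX_RAW_SCORE * s.size)


def corrected_uncorrected_rates(
    trial_scores: Sequence[float],
) -> tuple[float, float, float]:
    """Percentages of fluent, corrected and uncorrected reaches.

    Fluent: 0 points; corrected (in flight): points in (0, 2];
    uncorrected (hand stopped at a wrong position): points above 2.
    The three percentages partition the trials and sum to 100.
    """
    s = np.asarray(trial_scores, dtype=float)
    if s.size == 0:
        return (float("nan"),) * 3
    if s.min() < 0 or s.max() > MAX_RAW_SCORE:
        raise ValueError(f"trial error points must lie in [0, {MAX_RAW_SCORE}]")
    fluent = s == 0
    uncorrected = s > 2
    corrected = ~fluent & ~uncorrected
    return tuple(100.0 * float(m.mean()) for m in (fluent, corrected, uncorrected))


def to_lesion_frame(hand: str, space: str, lesion_side: str) -> tuple[str, str]:
    """Re-express left/right hand and space relative to the lesion.

    The side equal to ``lesion_side`` becomes "ipsi", the opposite side
    "contra".  E.g. with a left thalamic lesion, the left hand reaching
    into left space is the ipsilesional hand in ipsilesional space.
    """
    if lesion_side is None or (isinstance(lesion_side, float) and np.isnan(lesion_side)):
        raise ValueError(
            "lesion side is unknown; derive the predominant side from the "
            "lesion mask (oataxia.lesionmap.laterality) or supply it in the "
            "clinical table"
        )
    for name, value in (("hand", hand), ("space", space), ("lesion_side", lesion_side)):
        if value not in SIDES:
            raise LabelError(f"unknown value {value!r} in field {name!r}; allowed: {SIDES}")
    return (
        "ipsi" if hand == lesion_side else "contra",
        "ipsi" if space == lesion_side else "contra",
    )


def aggregate_raters(trials: pd.DataFrame) -> pd.DataFrame:
    """Average the raw error points of independent raters per trial.

    Expects one row per (subject, trial, rater).  Returns one row per
    trial with the mean raw score; the validity flag is the conjunction
    over raters.  Disagreements larger than one point are logged.
    """
    if "rater_id" not in trials.columns or trials["rater_id"].nunique() <= 1:
        return trials.drop(columns=["rater_id"], errors="ignore").copy()
    keys = ["subject_id", "trial_id"] + CONDITION_COLS
    grouped = trials.groupby(keys, sort=False)
    agg = grouped.agg(
        raw_score=("raw_score", "mean"),
        valid=("valid", "all"),
        _spread=("raw_score", lambda s: s.max() - s.min()),
    ).reset_index()
    n_disagree = int((agg["_spread"] > 1).sum())
    if n_disagree:
        log.warning(
            "%d trial(s) with rater disagreement > 1 point (averaged anyway)",
            n_disagree,
        )
    return agg.drop(columns=["_spread"])


def _label_domain(trials: pd.DataFrame) -> tuple[tuple[str, ...], tuple[str, ...]]:
    """Return the (hand/space label set, viewing label set) in use."""
    observed = set(trials["hand"].unique()) | set(trials["space"].unique())
    if observed <= set(SIDES):
        return SIDES, VIEWINGS
    if observed <= set(FRAMES):
        return FRAMES, VIEWINGS
    raise LabelError(
        f"hand/space labels {sorted(observed)} mix or exceed the closed sets "
        f"{SIDES} / {FRAMES}"
    )


def _full_condition_grid(subjects: Iterable, sides: Sequence[str]) -> pd.MultiIndex:
    return pd.MultiIndex.from_tuples(
        [
            (s, h, sp, v)
            for s in subjects
            for h, sp, v in itertools.product(sides, sides, VIEWINGS)
        ],
        names=["subject_id"] + CONDITION_COLS,
    )


def validate_trials(
    trials: pd.DataFrame, min_valid: int = DEFAULT_MIN_VALID
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop invalid trials and count valid trials per condition.

    Returns ``(valid_trials, counts)`` where ``counts`` has one row per
    subject and condition cell (all 8 cells, including empty ones) with
    the number of valid trials and a ``flagged_missing`` column marking
    cells below ``min_valid``.  Flagged cells later yield missing (NaN)
    scores — never zeros, since a zero means a perfect performance.
    """
    if trials is None or len(trials) == 0:
        raise ValueError("trial table is empty")
    if min_valid < 0:
        raise ValueError("min_valid must be >= 0")
    required = {"subject_id", "raw_score", "valid", *CONDITION_COLS}
    missing_cols = required - set(trials.columns)
    if missing_cols:
        raise ValueError(f"trial table lacks column(s): {sorted(missing_cols)}")
    sides, viewings = _label_domain(trials)
    _check_labels(trials["hand"], sides, "hand")
    _check_labels(trials["space"], sides, "space")
    _check_labels(trials["viewing"], viewings, "viewing")
    scores = pd.to_numeric(trials["raw_score"], errors="raise")
    if scores.min() < 0 or scores.max() > MAX_RAW_SCORE:
        raise ValueError(f"raw_score outside [0, {MAX_RAW_SCORE}] in field 'raw_score'")

    valid = trials[trials["valid"].astype(bool)].copy()
    counts = (
        valid.groupby(["subject_id"] + CONDITION_COLS)
        .size()
        .reindex(_full_condition_grid(trials["subject_id"].unique(), sides), fill_value=0)
        .rename("n_valid")
        .reset_index()
    )
    counts["flagged_missing"] = counts["n_valid"] < min_valid
    return valid, counts


def condition_scores(
    valid_trials: pd.DataFrame, min_valid: int = DEFAULT_MIN_VALID
) -> pd.DataFrame:
    """Per-subject, per-condition mean error scores and error-category rates.

    One row per subject x hand x space x viewing cell.  Cells with fewer
    than ``min_valid`` valid trials report their count but NaN scores.
    """
    if len(valid_trials) == 0:
        raise ValueError("no valid trials to score")
    sides, _ = _label_domain(valid_trials)

    def _cell(scores: pd.Series) -> pd.Series:
        pts = scores.to_numpy(dtype=float)
        fl, co, un = corrected_uncorrected_rates(pts)
        return pd.Series(
            [len(pts), mean_error_score(pts), fl, co, un], index=SCORE_COLUMNS
        )

    table = (
        valid_trials.groupby(["subject_id"] + CONDITION_COLS)["raw_score"]
        .apply(_cell)
        .unstack()
        .reindex(_full_condition_grid(valid_trials["subject_id"].unique(), sides))
        .reset_index()
    )
    table["n_valid"] = table["n_valid"].fillna(0).astype(int)
    low = table["n_valid"] < min_valid
    table.loc[low, SCORE_COLUMNS[1:]] = np.nan
    if low.any():
        log.info("%d condition cell(s) below min_valid=%d -> missing score", low.sum(), min_valid)
    return table


def convert_to_lesion_frame(
    table: pd.DataFrame, lesion_side: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """Map left/right hand and space columns to ipsi/contra per subject.

    ``lesion_side`` maps subject id to "left"/"right" (the predominant
    lesion side).  Works on any table with subject_id/hand/space columns
    (trials or score tables).
    """
    sides = dict(lesion_side)
    out = table.copy()
    unknown = set(out["subject_id"].unique()) - set(sides)
    if unknown:
        raise ValueError(
            f"no lesion side for subject(s) {sorted(unknown)}; derive the "
            "predominant side from the lesion mask (oataxia.lesionmap.laterality)"
        )
    frames = [
        to_lesion_frame(h, s, sides[subj])
        for subj, h, s in zip(out["subject_id"], out["hand"], out["space"])
    ]
    out["hand"] = [f[0] for f in frames]
    out["space"] = [f[1] for f in frames]
    return out


def oa_scores(score_table: pd.DataFrame) -> pd.DataFrame:
    """OA difference scores: peripheral minus foveal mean error score.

    One row per subject x hand x space combination, with the two viewing
    scores and their difference ``oa_score`` (percentage points, -100 to
    100).  A missing viewing cell propagates to a missing OA score.
    """
    wide = score_table.pivot_table(
        index=["subject_id", "hand", "space"],
        columns="viewing",
        values="mean_error_score",
        dropna=False,
    )
    for v in VIEWINGS:
        if v not in wide.columns:
            wide[v] = np.nan
    wide = wide[list(VIEWINGS)]
    wide["oa_score"] = wide["peripheral"] - wide["foveal"]
    return wide.reset_index().rename(
        columns={"foveal": "foveal_score", "peripheral": "peripheral_score"}
    )


def read_ratings(path) -> pd.DataFrame:
    """Read a trial-rating CSV (UTF-8, header required)."""
    df = pd.read_csv(path)
    required = {"subject_id", "hand", "space", "viewing", "raw_score", "valid"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ratings file {path} lacks column(s): {sorted(missing)}")
    return df
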