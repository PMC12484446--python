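"""Normative models, single-case classification and group statistics.

Healthy controls have no lesion, so "ipsi"/"contra" is undefined for
them.  To build control norms that are comparable with the patients,
exactly half of the controls are assigned "left as ipsilesional" and
half "right as ipsilesional".  Among a large number of random balanced
assignments the one whose ipsi and contra score distributions are most
similar (in mean and SD) is kept; see :func:`assign_control_sides`.

A patient's OA score is converted to a z-score against the control
norm with the sign flipped so that, following neuropsychological
convention, negative values mean worse performance.  A patient is
classified as having optic ataxia in a hand/space combination when the
flipped z-score falls below -2 *and* the Crawford–Howell single-case
test against the control sample is significant (one-tailed p < 0.05).

The module also provides the group statistics used around the
classification: Mann–Whitney U (exact when feasible), Pearson chi-square
on 2x2 tables without continuity correction, a 2x2x2 mixed
repeated-measures ANOVA with partial eta squared, and Bonferroni alpha
correction.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

DEFAULT_N_PERM = 100_000
DEFAULT_Z_THRESHOLD = -2.0
DEFAULT_ALPHA = 0.05

#: the contralesional hand / contralesional space combination
CONTRA_COMBO = ("contra", "contra")

#: maximum product of group sizes for which the exact Mann-Whitney
#: null distribution is enumerated (tie-free data only)
EXACT_MWU_LIMIT = 400


class DegenerateModelError(ValueError):
    """Raised when a control SD is zero and no z-score can be formed."""


@dataclass
class TestResult:
    """A single statistical test: statistic, p-value and method label."""

    statistic: float
    p: float
    method: str
    df: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0 or math.isnan(self.p)):
            raise ValueError(f"p-value {self.p} outside [0, 1]")


@dataclass
class ControlAssignment:
    """Balanced ipsi-side assignment of the control group."""

    left_as_ipsi: np.ndarray  # boolean, one entry per control
    balance_loss: float
    n_perm: int
    seed: int | None


@dataclass
class NormativeModel:
    """Per-measure control mean and SD under the chosen assignment."""

    measures: list
    mu: np.ndarray
    sigma: np.ndarray
    n_controls: int
    assignment: ControlAssignment
    degenerate: np.ndarray = field(default=None)  # sigma == 0 per measure

    def __post_init__(self) -> None:
        if self.degenerate is None:
            self.degenerate = self.sigma == 0
        if self.degenerate.any():
            log.warning(
                "degenerate normative model (sigma = 0) for measure(s): %s",
                [m for m, d in zip(self.measures, self.degenerate) if d],
            )

    def loc(self, measure) -> tuple[float, float]:
        i = self.measures.index(measure)
        return float(self.mu[i]), float(self.sigma[i])


def _as_matrix(x) -> np.ndarray:
    a = np.asarray(pd.DataFrame(x).to_numpy(dtype=float))
    if a.ndim == 1:
        a = a[:, None]
    return a


def _balanced_assignments(n_perm: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """(n_perm, n) boolean matrix, each row with exactly n/2 True."""
    keys = rng.random((n_perm, n))
    ranks = keys.argsort(axis=1).argsort(axis=1)
    return ranks < n // 2


def _assignment_losses(
    B: np.ndarray, left: np.ndarray, right: np.ndarray
) -> np.ndarray:
    """Balance loss of each candidate assignment (vectorised).

    Loss = sum over measures of (|mean_ipsi - mean_contra| +
    |sd_ipsi - sd_contra|) / pooled SD.  A measure with zero pooled SD
    contributes 0 when its differences are zero, otherwise infinity.
    """
    n = left.shape[0]
    Bf = B.astype(np.float64)
    Cf = 1.0 - Bf
    L2, R2 = left**2, right**2
    m_ipsi = (Bf @ left + Cf @ right) / n
    m_contra = (Bf @ right + Cf @ left) / n
    e2_ipsi = (Bf @ L2 + Cf @ R2) / n
    e2_contra = (Bf @ R2 + Cf @ L2) / n
    bessel = n / (n - 1)
    v_ipsi = np.clip((e2_ipsi - m_ipsi**2) * bessel, 0.0, None)
    v_contra = np.clip((e2_contra - m_contra**2) * bessel, 0.0, None)
    pooled = np.sqrt((v_ipsi + v_contra) / 2.0)
    num = np.abs(m_ipsi - m_contra) + np.abs(np.sqrt(v_ipsi) - np.sqrt(v_contra))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(pooled > 0, num / np.where(pooled > 0, pooled, 1.0), np.where(num > 0, np.inf, 0.0))
    return terms.sum(axis=1)


def assign_control_sides(
    left_scores,
    right_scores,
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = None,
) -> ControlAssignment:
    """Pick the most balanced 50/50 left-as-ipsi control assignment.

    ``left_scores[i, k]`` is control *i*'s value for measure *k* when
    the left side is treated as ipsilesional; ``right_scores`` likewise
    for right-as-ipsi.  Among ``n_perm`` random assignments with exactly
    half of the controls left-as-ipsi, the one minimising the balance
    loss is returned (deterministically, given the seed; ties broken by
    first occurrence).  Measures containing NaN are dropped from the
    loss with a warning.
    """
    left = _as_matrix(left_scores)
    right = _as_matrix(right_scores)
    if left.shape != right.shape:
        raise ValueError("left and right score tables must have the same shape")
    n = left.shape[0]
    if n < 2 or n % 2:
        raise ValueError(f"need an even number of controls >= 2, got {n}")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    keep = ~(np.isnan(left).any(axis=0) | np.isnan(right).any(axis=0))
    if not keep.all():
        log.warning("dropping %d measure(s) with missing control scores from the balance loss", (~keep).sum())
    if not keep.any():
        raise ValueError("no complete measures available to balance on")
    rng = np.random.default_rng(seed)
    best_loss = np.inf
    best_row = None
    # evaluate candidates in chunks to bound memory at large n_perm
    chunk = 20_000
    for start in range(0, n_perm, chunk):
        B = _balanced_assignments(min(chunk, n_perm - start), n, rng)
        losses = _assignment_losses(B, left[:, keep], right[:, keep])
        i = int(np.argmin(losses))
        if losses[i] < best_loss:
            best_loss = float(losses[i])
            best_row = B[i].copy()
    return ControlAssignment(
        left_as_ipsi=best_row, balance_loss=best_loss, n_perm=n_perm, seed=seed
    )


def build_normative_model(
    left_scores, right_scores, assignment: ControlAssignment
) -> NormativeModel:
    """Control mean/SD per measure under a chosen side assignment."""
    left = _as_matrix(left_scores)
    right = _as_matrix(right_scores)
    measures = list(pd.DataFrame(left_scores).columns)
    pick = assignment.left_as_ipsi[:, None]
    X = np.where(pick, left, right)
    return NormativeModel(
        measures=measures,
        mu=np.nanmean(X, axis=0),
        sigma=np.nanstd(X, axis=0, ddof=1),
        n_controls=left.shape[0],
        assignment=assignment,
    )


def z_score_flipped(x, mu, sigma):
    """Sign-flipped z-score: negative values mean worse performance."""
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise DegenerateModelError("control SD must be positive to form a z-score")
    return -(np.asarray(x, dtype=float) - mu) / sigma


def crawford_howell(
    case_score, control_mean, control_sd, n_controls: int
) -> tuple[float, float]:
    """Single-case t-test of one patient against a small control sample.

    t = (case - mean) / (sd * sqrt(1 + 1/n)), referred to Student's t
    with n - 1 degrees of freedom.  The returned p is one-tailed for the
    deficit direction (higher score = worse performance).  For large n
    it converges to the normal tail of the plain z-score.
    """
    if n_controls < 2:
        raise ValueError("need at least 2 controls")
    sd = np.asarray(control_sd, dtype=float)
    if np.any(sd <= 0):
        raise DegenerateModelError("control SD must be positive")
    t = (np.asarray(case_score, float) - control_mean) / (sd * np.sqrt(1.0 + 1.0 / n_controls))
    p = stats.t.sf(t, df=n_controls - 1)
    if np.ndim(t) == 0:
        return float(t), float(p)
    return t, p


def classify_oa(
    oa_table: pd.DataFrame,
    model: NormativeModel,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Classify patients as OA per hand/space combination.

    ``oa_table`` is tidy with columns subject_id, hand, space, oa_score
    in the ipsi/contra frame.  For each combination present in the
    normative model the flipped z-score and the Crawford–Howell test are
    computed; ``oa_flag`` requires *both* z < z_threshold (strict; z
    exactly at the threshold is not OA) and the one-tailed single-case p
    < alpha.  Missing scores yield unclassified rows (flag <NA>).

    The returned frame carries one row per subject x combination plus a
    per-subject ``contralesional_oa`` flag (the contra-hand/contra-space
    combination, the canonical deficit in unilateral lesions).
    """
    rows = []
    for _, r in oa_table.iterrows():
        combo = (r["hand"], r["space"])
        if combo not in model.measures:
            continue
        mu, sigma = model.loc(combo)
        x = r["oa_score"]
        if pd.isna(x):
            log.info("subject %s combo %s: missing OA score, unclassified", r["subject_id"], combo)
            rows.append((r["subject_id"], *combo, np.nan, np.nan, np.nan, np.nan, pd.NA))
            continue
        z = float(z_score_flipped(x, mu, sigma))
        t, p = crawford_howell(x, mu, sigma, model.n_controls)
        flag = bool(z < z_threshold and p < alpha)
        rows.append((r["subject_id"], *combo, x, z, t, p, flag))
    out = pd.DataFrame(
        rows,
        columns=["subject_id", "hand", "space", "oa_score", "z", "cg_t", "cg_p", "oa_flag"],
    )
    contra = (
        out[(out["hand"] == CONTRA_COMBO[0]) & (out["space"] == CONTRA_COMBO[1])]
        .set_index("subject_id")["oa_flag"]
        .rename("contralesional_oa")
    )
    out = out.merge(contra, on="subject_id", how="left")
    return out


def mann_whitney_u(group_a, group_b) -> TestResult:
    """Two-sided Mann–Whitney U test; U is reported for ``group_a``.

    The exact null distribution is enumerated when the data are
    tie-free and n_a * n_b <= 400; otherwise the normal approximation
    with midranks and tie-corrected variance is used.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    if tie_free and a.size * b.size <= EXACT_MWU_LIMIT:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        method = "mann-whitney-exact"
    else:
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        method = "mann-whitney-normal"
    return TestResult(statistic=float(res.statistic), p=float(res.pvalue), method=method)


def chi_square_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Pearson chi-square on a 2x2 table, without continuity correction.

    chi2 = n (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d)), df = 1, two-sided p
    from the upper chi-square tail.  A zero marginal leaves the
    statistic undefined and raises.
    """
    counts = np.array([a, b, c, d], dtype=float)
    if np.any(counts < 0) or counts.sum() == 0:
        raise ValueError("counts must be nonnegative with a positive total")
    n = counts.sum()
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("chi-square undefined: a marginal total is zero")
    chi2 = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    return TestResult(
        statistic=float(chi2), p=float(stats.chi2.sf(chi2, df=1)), method="chi-square", df=1
    )


def bonferroni_alpha(family_alpha: float, m: int) -> float:
    """Bonferroni-corrected per-comparison alpha: family alpha / m."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    if not 0 < family_alpha <= 1:
        raise ValueError("family alpha must lie in (0, 1]")
    return family_alpha / m


ANOVA_EFFECTS = [
    "group",
    "viewing",
    "group:viewing",
    "side",
    "group:side",
    "viewing:side",
    "group:viewing:side",
]


def mixed_anova_2x2x2(
    data: pd.DataFrame,
    subject: str = "subject_id",
    group: str = "group",
    viewing: str = "viewing",
    side: str = "side",
    score: str = "score",
) -> pd.DataFrame:
    """Mixed repeated-measures ANOVA: GROUP x VIEWING x SIDE (2x2x2).

    One between-subject factor (group) and two within-subject factors
    with two levels each.  Because every factor has two levels, each
    within-subject effect reduces to a per-subject contrast score:

    * subject mean          -> GROUP
    * viewing difference    -> VIEWING and GROUP x VIEWING
    * side difference       -> SIDE and GROUP x SIDE
    * double difference     -> VIEWING x SIDE and the three-way term

    Group comparisons on a contrast use the pooled two-sample t (so
    F = t^2 holds exactly); within-factor main effects test the
    unweighted grand mean of the contrast (type-III convention, which
    matters only for unequal group sizes).  All effects have df (1,
    N - 2).  Partial eta squared is SS_effect / (SS_effect + SS_error).

    Subjects with incomplete cells are dropped with a log entry.
    """
    group_of = data.drop_duplicates(subject).set_index(subject)[group]
    if data.groupby(subject)[group].nunique().max() > 1:
        raise ValueError("a subject appears in more than one group")
    wide = data.pivot_table(
        index=subject, columns=[viewing, side], values=score, dropna=False
    )
    if wide.shape[1] != 4:
        raise ValueError(
            f"expected 2 viewing x 2 side = 4 cells, found {wide.shape[1]}"
        )
    incomplete = wide.isna().any(axis=1)
    if incomplete.any():
        log.warning(
            "dropping %d subject(s) with incomplete cells from the ANOVA: %s",
            incomplete.sum(),
            list(wide.index[incomplete]),
        )
        wide = wide[~incomplete]
    v_levels = sorted({c[0] for c in wide.columns})
    s_levels = sorted({c[1] for c in wide.columns})
    groups = group_of.reindex(wide.index)
    g_levels = sorted(pd.unique(groups))
    if len(g_levels) != 2:
        raise ValueError(f"need exactly 2 groups, found {g_levels}")
    y = {
        (v, s): wide[(v, s)].to_numpy(dtype=float)
        for v in v_levels
        for s in s_levels
    }
    m = sum(y.values()) / 4.0
    vdiff = (y[(v_levels[1], s_levels[0])] + y[(v_levels[1], s_levels[1])]) / 2.0 - (
        y[(v_levels[0], s_levels[0])] + y[(v_levels[0], s_levels[1])]
    ) / 2.0
    sdiff = (y[(v_levels[0], s_levels[1])] + y[(v_levels[1], s_levels[1])]) / 2.0 - (
        y[(v_levels[0], s_levels[0])] + y[(v_levels[1], s_levels[0])]
    ) / 2.0
    wdiff = (y[(v_levels[1], s_levels[1])] - y[(v_levels[1], s_levels[0])]) - (
        y[(v_levels[0], s_levels[1])] - y[(v_levels[0], s_levels[0])]
    )
    in_g = [np.asarray(groups == g) for g in g_levels]
    n1, n2 = int(in_g[0].sum()), int(in_g[1].sum())
    if min(n1, n2) < 2:
        raise ValueError("each group needs at least 2 complete subjects")
    N = n1 + n2
    df2 = N - 2
    inv_n = 1.0 / n1 + 1.0 / n2

    def _ss(d: np.ndarray) -> tuple[float, float, float]:
        d1, d2 = d[in_g[0]], d[in_g[1]]
        ss_err = float(((d1 - d1.mean()) ** 2).sum() + ((d2 - d2.mean()) ** 2).sum())
        ss_between = float((d1.mean() - d2.mean()) ** 2 / inv_n)
        grand = (d1.mean() + d2.mean()) / 2.0
        ss_main = float(grand**2 / (inv_n / 4.0))
        return ss_main, ss_between, ss_err

    rows = {}

    def _add(name: str, ss_eff: float, ss_err: float) -> None:
        F = ss_eff / (ss_err / df2) if ss_err > 0 else np.inf
        rows[name] = {
            "F": F,
            "df1": 1,
            "df2": df2,
            "p": float(stats.f.sf(F, 1, df2)),
            "eta_p2": ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0,
        }

    _, ss_grp, ss_err_m = _ss(m)
    _add("group", ss_grp, ss_err_m)
    ss_v, ss_gv, ss_err_v = _ss(vdiff)
    _add("viewing", ss_v, ss_err_v)
    _add("group:viewing", ss_gv, ss_err_v)
    ss_s, ss_gs, ss_err_s = _ss(sdiff)
    _add("side", ss_s, ss_err_s)
    _add("group:side", ss_gs, ss_err_s)
    ss_vs, ss_gvs, ss_err_w = _ss(wdiff)
    _add("viewing:side", ss_vs, ss_err_w)
    _add("group:viewing:side", ss_gvs, ss_err_w)
    return pd.DataFrame.from_dict(rows, orient="index").loc[ANOVA_EFFECTS]
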