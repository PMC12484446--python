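"""Tests for normative models, single-case tests and group statistics."""
import itertools
import json
import math
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from oataxia import normative as nm

ORACLES = Path(__file__).parent / "oracles"


class TestAssignControlSides:
    def test_symmetric_scores_give_zero_loss(self, rng):
        left = rng.normal(5, 2, size=(10, 3))
        a = nm.assign_control_sides(left, left.copy(), n_perm=50, seed=1)
        assert a.balance_loss == pytest.approx(0.0)

    def test_exactly_half_left_as_ipsi(self, rng):
        left = rng.normal(0, 1, size=(12, 2))
        right = rng.normal(1, 2, size=(12, 2))
        a = nm.assign_control_sides(left, right, n_perm=200, seed=3)
        assert a.left_as_ipsi.sum() == 6

    def test_deterministic_given_seed(self, rng):
        left = rng.normal(0, 1, size=(8, 2))
        right = rng.normal(0.5, 1, size=(8, 2))
        a1 = nm.assign_control_sides(left, right, n_perm=100, seed=11)
        a2 = nm.assign_control_sides(left, right, n_perm=100, seed=11)
        assert np.array_equal(a1.left_as_ipsi, a2.left_as_ipsi)
        assert a1.balance_loss == a2.balance_loss

    def test_beats_fresh_random_assignments(self, rng):
        """Returned loss <= loss of 1000 fresh random balanced assignments."""
        left = rng.normal(3, 1.5, size=(10, 4))
        right = rng.normal(4, 2.0, size=(10, 4))
        a = nm.assign_control_sides(left, right, n_perm=5000, seed=2)
        fresh = nm._balanced_assignments(1000, 10, np.random.default_rng(99))
        losses = nm._assignment_losses(fresh, left, right)
        assert a.balance_loss <= losses.min() + 1e-12

    def test_odd_control_count_rejected(self, rng):
        x = rng.normal(size=(7, 2))
        with pytest.raises(ValueError, match="even"):
            nm.assign_control_sides(x, x, n_perm=10, seed=0)


class TestZScoreFlipped:
    def test_mean_gives_zero_and_threshold_boundary(self):
        assert nm.z_score_flipped(10.0, 10.0, 2.0) == 0.0
        assert nm.z_score_flipped(14.0, 10.0, 2.0) == -2.0

    def test_strictly_decreasing_in_score(self, rng):
        x = np.sort(rng.normal(size=20))
        z = nm.z_score_flipped(x, 0.0, 1.0)
        assert (np.diff(z) < 0).all()

    def test_degenerate_sigma_rejected(self):
        with pytest.raises(nm.DegenerateModelError):
            nm.z_score_flipped(1.0, 0.0, 0.0)


class TestCrawfordHowell:
    def test_case_at_control_mean_gives_half(self):
        t, p = nm.crawford_howell(10.0, 10.0, 3.0, 20)
        assert t == 0.0
        assert p == pytest.approx(0.5)

    def test_converges_to_normal_tail_at_large_n(self):
        _, p = nm.crawford_howell(12.0, 10.0, 1.0, 10_000)
        assert p == pytest.approx(stats.norm.sf(2.0), rel=1e-2)

    def test_two_sd_worse_with_forty_controls_significant(self):
        _, p = nm.crawford_howell(16.0, 10.0, 3.0, 40)
        assert p < 0.05

    def test_p_monotone_in_deficit_severity(self):
        ps = [nm.crawford_howell(x, 0.0, 1.0, 30)[1] for x in np.linspace(0, 5, 20)]
        assert all(b < a for a, b in zip(ps, ps[1:]))


def _model(mu, sigma, n=40):
    combos = [("contra", "contra"), ("contra", "ipsi"), ("ipsi", "contra"), ("ipsi", "ipsi")]
    a = nm.ControlAssignment(np.ones(n, bool), 0.0, 1, 0)
    return nm.NormativeModel(
        measures=combos,
        mu=np.full(4, mu),
        sigma=np.full(4, sigma),
        n_controls=n,
        assignment=a,
    )


def _oa_table(scores):
    combos = [("contra", "contra"), ("contra", "ipsi"), ("ipsi", "contra"), ("ipsi", "ipsi")]
    return pd.DataFrame(
        [
            {"subject_id": "p1", "hand": h, "space": s, "oa_score": v}
            for (h, s), v in zip(combos, scores)
        ]
    )


class TestClassifyOA:
    def test_z_minus_1_9_everywhere_is_not_oa(self):
        model = _model(0.0, 1.0)
        out = nm.classify_oa(_oa_table([1.9] * 4), model)
        assert not out["oa_flag"].any()

    def test_boundary_z_exactly_minus_2_is_not_oa(self):
        model = _model(0.0, 1.0)
        out = nm.classify_oa(_oa_table([2.0] * 4), model)
        assert out["z"].tolist() == pytest.approx([-2.0] * 4)
        assert not out["oa_flag"].any()

    def test_contralesional_only_pattern(self):
        """A patient far outside norms only in contra-hand/contra-space."""
        model = _model(0.0, 1.0)
        out = nm.classify_oa(_oa_table([4.6, 0.5, 0.5, 1.32]), model).set_index(
            ["hand", "space"]
        )
        assert out.loc[("contra", "contra"), "oa_flag"]
        assert not out.loc[("ipsi", "ipsi"), "oa_flag"]
        assert out["contralesional_oa"].all()  # broadcast per-subject flag

    def test_missing_score_unclassified(self):
        model = _model(0.0, 1.0)
        out = nm.classify_oa(_oa_table([np.nan, 0.0, 0.0, 0.0]), model)
        flags = out.set_index(["hand", "space"])["oa_flag"]
        assert pd.isna(flags[("contra", "contra")])


def _enumerate_mwu(a, b):
    """Brute-force exact two-sided Mann-Whitney p by full enumeration."""
    pooled = np.concatenate([a, b])
    n = len(pooled)
    na = len(a)
    u_obs = sum(1 for x in a for y in b if x > y) + 0.5 * sum(
        1 for x in a for y in b if x == y
    )
    mean_u = na * len(b) / 2
    count = 0
    total = 0
    for idx in itertools.combinations(range(n), na):
        grp = pooled[list(idx)]
        rest = np.delete(pooled, list(idx))
        u = sum(1 for x in grp for y in rest if x > y)
        total += 1
        if abs(u - mean_u) >= abs(u_obs - mean_u) - 1e-12:
            count += 1
    return count / total


class TestMannWhitney:
    def test_identical_samples_centre_u(self):
        res = nm.mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(4.5)  # n_a*n_b/2

    def test_fully_separated_small_groups(self):
        res = nm.mann_whitney_u([1, 2], [3, 4])
        assert res.statistic == 0.0
        assert res.p == pytest.approx(1 / 3)

    def test_exact_matches_enumeration_oracle(self, rng):
        a = rng.normal(size=5)
        b = rng.normal(0.8, 1, size=5)
        res = nm.mann_whitney_u(a, b)
        assert res.method == "mann-whitney-exact"
        assert res.p == pytest.approx(_enumerate_mwu(a, b))

    def test_ties_fall_back_to_normal_approximation(self):
        res = nm.mann_whitney_u([1, 1, 2, 2] * 6, [1, 2, 2, 3] * 6)
        assert res.method == "mann-whitney-normal"
        assert 0 <= res.p <= 1


class TestChiSquare2x2:
    def test_bilateral_lesion_table(self):
        res = nm.chi_square_2x2(3, 2, 3, 20)
        assert res.statistic == pytest.approx(5.38, abs=0.005)
        assert res.p == pytest.approx(0.02, abs=0.005)

    def test_independence_gives_zero(self):
        res = nm.chi_square_2x2(5, 5, 5, 5)
        assert res.statistic == 0.0
        assert res.p == pytest.approx(1.0)

    def test_closed_form_row(self):
        res = nm.chi_square_2x2(1, 4, 10, 13)
        assert res.statistic == pytest.approx(0.949, abs=0.001)
        assert res.p == pytest.approx(0.33, abs=0.005)

    def test_agrees_with_scipy_contingency(self, rng):
        a, b, c, d = rng.integers(1, 30, size=4)
        res = nm.chi_square_2x2(a, b, c, d)
        chi2, p, _, _ = stats.chi2_contingency([[a, b], [c, d]], correction=False)
        assert res.statistic == pytest.approx(chi2)
        assert res.p == pytest.approx(p)

    @settings(deadline=None)
    @given(st.tuples(*[st.integers(1, 50)] * 4))
    def test_invariant_under_row_and_column_swap(self, counts):
        a, b, c, d = counts
        base = nm.chi_square_2x2(a, b, c, d).statistic
        assert nm.chi_square_2x2(d, c, b, a).statistic == pytest.approx(base)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            nm.chi_square_2x2(0, 0, 3, 4)


class TestBonferroni:
    @pytest.mark.parametrize("m, expected", [(4, 0.0125), (2, 0.025), (1, 0.05)])
    def test_examples(self, m, expected):
        assert nm.bonferroni_alpha(0.05, m) == pytest.approx(expected)


def _anova_fixture():
    return pd.read_csv(ORACLES / "anova_fixture.csv")


class TestMixedAnova:
    # Frozen output of the independent R oracle (tests/oracles/
    # mixed_anova_oracle.R: aov with Error(subject/(viewing*side)) on
    # tests/oracles/anova_fixture.csv, a balanced 6+6-subject design).
    R_ORACLE = {
        "group": (10.2278788303, 0.0095222556701, 0.50563279107),
        "viewing": (107.5940000394, 1.1354346988e-06, 0.91496164773),
        "group:viewing": (25.2655750677, 0.00051678583543, 0.71643734773),
        "side": (24.9555767739, 0.00054086581751, 0.71392261485),
        "group:side": (0.15588505651, 0.70126367941, 0.01534923403),
        "viewing:side": (0.84283045566, 0.38019850683, 0.077731590391),
        "group:viewing:side": (0.70871822, 0.41954681839, 0.066181423905),
    }

    def test_matches_r_aov_oracle(self):
        out = nm.mixed_anova_2x2x2(_anova_fixture(), score="score")
        for effect, (F, p, eta) in self.R_ORACLE.items():
            row = out.loc[effect]
            assert row["F"] == pytest.approx(F, rel=1e-8), effect
            assert row["p"] == pytest.approx(p, rel=1e-8), effect
            assert row["eta_p2"] == pytest.approx(eta, rel=1e-8), effect
            assert (row["df1"], row["df2"]) == (1, 10)

    def test_identical_groups_zero_group_effects(self):
        df = _anova_fixture()
        mirrored = df.copy()
        mirrored["group"] = mirrored["group"].map(
            {"control": "patient", "patient": "control"}
        )
        mirrored["subject_id"] = mirrored["subject_id"] + "_m"
        both = pd.concat([df, mirrored], ignore_index=True)
        out = nm.mixed_anova_2x2x2(both, score="score")
        for effect in ("group", "group:viewing", "group:side", "group:viewing:side"):
            assert out.loc[effect, "F"] == pytest.approx(0.0, abs=1e-20)

    def test_f_equals_t_squared_on_contrasts(self):
        """Between-group within-effects equal the pooled two-sample t^2."""
        df = _anova_fixture()
        out = nm.mixed_anova_2x2x2(df, score="score")
        wide = df.pivot_table(
            index=["subject_id", "group"], columns=["viewing", "side"], values="score"
        )
        vdiff = wide["peripheral"].mean(axis=1) - wide["foveal"].mean(axis=1)
        g = vdiff.index.get_level_values("group")
        t, _ = stats.ttest_ind(vdiff[g == "control"], vdiff[g == "patient"])
        assert out.loc["group:viewing", "F"] == pytest.approx(t**2)

    def test_eta_identity(self):
        out = nm.mixed_anova_2x2x2(_anova_fixture(), score="score")
        recon = out["F"] * out["df1"] / (out["F"] * out["df1"] + out["df2"])
        assert recon.tolist() == pytest.approx(out["eta_p2"].tolist())

    def test_grand_mean_shift_leaves_f_unchanged(self):
        df = _anova_fixture()
        out1 = nm.mixed_anova_2x2x2(df, score="score")
        df2 = df.assign(score=df["score"] + 123.4)
        out2 = nm.mixed_anova_2x2x2(df2, score="score")
        assert out2["F"].tolist() == pytest.approx(out1["F"].tolist())

    def test_incomplete_subject_dropped(self, caplog):
        df = _anova_fixture()
        df = df[~((df["subject_id"] == "c0") & (df["viewing"] == "foveal"))]
        import logging

        with caplog.at_level(logging.WARNING):
            out = nm.mixed_anova_2x2x2(df, score="score")
        assert "c0" in caplog.text
        assert out.loc["group", "df2"] == 9  # 11 subjects - 2
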