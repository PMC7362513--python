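"""Fisher exact, gated comparisons, Spearman, KM/log-rank, Cox, matching."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cafkit import (
    ContingencyTable2x2,
    MatchSpec,
    compare_groups,
    cox_model,
    fisher_exact_2x2,
    km_logrank,
    match_controls,
    simulate_ph_cohort,
    spearman_corr,
)


def fisher_bruteforce(a, b, c, d):
    """Independent enumeration oracle over all margin-fixed tables."""
    row1, row2, col1 = a + b, c + d, a + c
    n = row1 + row2
    denom = comb(n, col1)
    p_obs = comb(row1, a) * comb(row2, c) / denom
    total = 0.0
    for k in range(max(0, col1 - row2), min(row1, col1) + 1):
        p = comb(row1, k) * comb(row2, col1 - k) / denom
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(total, 1.0)


class TestFisher:
    @pytest.mark.parametrize(
        "table,expected",
        [
            (((11, 41), (0, 52)), 5.4163e-4),
            (((3, 49), (0, 52)), 0.2427),
            (((2, 50), (7, 45)), 0.1603),
        ],
    )
    def test_reference_tables(self, table, expected):
        res = fisher_exact_2x2(table)
        assert res.pvalue == pytest.approx(expected, rel=1e-3)

    def test_balanced_diagonal_closed_form(self):
        res = fisher_exact_2x2(((5, 0), (0, 5)))
        assert res.pvalue == pytest.approx(2 / comb(10, 5))

    def test_matches_bruteforce_enumeration(self, rng):
        for _ in range(60):
            a, b, c, d = rng.integers(0, 30, size=4)
            if a + b + c + d == 0:
                continue
            ours = fisher_exact_2x2(((a, b), (c, d))).pvalue
            assert ours == pytest.approx(fisher_bruteforce(a, b, c, d), abs=1e-12)

    def test_matches_scipy(self, rng):
        for _ in range(30):
            a, b, c, d = rng.integers(0, 40, size=4)
            if a + b + c + d == 0:
                continue
            ours = fisher_exact_2x2(((a, b), (c, d)))
            ref = sps.fisher_exact([[a, b], [c, d]])
            assert ours.pvalue == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(0, 0, 0, 0)

    def test_odds_ratio(self):
        assert fisher_exact_2x2(((4, 2), (1, 3))).odds_ratio == pytest.approx(6.0)
        assert np.isinf(fisher_exact_2x2(((5, 0), (2, 3))).odds_ratio)


class TestCompareGroups:
    def test_identical_samples_p_one(self, rng):
        x = rng.normal(size=20)
        res = compare_groups(x, x.copy())
        assert res.pvalue > 0.95

    def test_gate_chooses_t_for_normal_data(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=50), rng.normal(size=50)
        assert compare_groups(x, y).test == "t"

    def test_gate_chooses_wilcoxon_for_skewed_data(self):
        rng = np.random.default_rng(4)
        x, y = rng.lognormal(0, 2.0, 80), rng.lognormal(0, 2.0, 80)
        assert compare_groups(x, y).test == "wilcoxon"

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0], [3.0, 4.0, 5.0])


class TestSpearman:
    def test_monotone_invariance(self):
        x = np.linspace(0, 5, 30)
        rho, _ = spearman_corr(x, np.exp(x))
        assert rho == pytest.approx(1.0)

    def test_antitone(self):
        x = np.linspace(0, 5, 30)
        rho, _ = spearman_corr(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_independent_uniforms_near_zero(self):
        rng = np.random.default_rng(10)
        rho, _ = spearman_corr(rng.random(1000), rng.random(1000))
        assert abs(rho) < 0.1

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            spearman_corr([1.0] * 10, np.arange(10.0))


class TestKaplanMeierLogrank:
    def test_hand_computed_steps_no_censoring(self):
        df = pd.DataFrame({"time": [1, 2, 3, 4], "event": [True] * 4})
        res = km_logrank({"g": df})
        curve = res.curves["g"].set_index("time")["survival"]
        assert curve.loc[0.0] == 1.0
        assert np.allclose(curve.loc[[1, 2, 3, 4]], [0.75, 0.5, 0.25, 0.0])

    def test_no_censoring_equals_empirical_survival(self, rng):
        t = rng.exponential(10, size=40)
        df = pd.DataFrame({"time": t, "event": True})
        curve = km_logrank({"g": df}).curves["g"]
        for time, surv in curve.itertuples(index=False):
            assert surv == pytest.approx(np.mean(t > time), abs=1e-12)

    def test_km_curve_is_nonincreasing(self, rng):
        t = rng.exponential(10, size=50)
        e = rng.random(50) < 0.7
        curve = km_logrank({"g": pd.DataFrame({"time": t, "event": e})}).curves["g"]
        s = curve["survival"].to_numpy()
        assert np.all(np.diff(s) <= 1e-12)

    def test_identical_groups_null(self):
        df = pd.DataFrame({"time": [1, 2, 3, 4, 5], "event": [1, 1, 0, 1, 0]})
        res = km_logrank({"a": df, "b": df.copy()})
        assert res.chi2 == pytest.approx(0.0, abs=1e-9)
        assert res.pvalue == pytest.approx(1.0)

    def test_no_events_rejected(self):
        df = pd.DataFrame({"time": [1.0, 2.0], "event": [False, False]})
        with pytest.raises(ValueError, match="no events"):
            km_logrank({"g": df})

    def test_negative_times_rejected(self):
        df = pd.DataFrame({"time": [-1.0, 2.0], "event": [True, True]})
        with pytest.raises(ValueError, match="negative"):
            km_logrank({"g": df})


class TestCox:
    def test_single_replicate_recovery(self):
        df = simulate_ph_cohort(2000, 5.0, seed=77)
        res = cox_model(df, ["exposed"], mode="univariate")
        row = res.table.iloc[0]
        assert 4.0 < row["hr"] < 6.3
        assert row["ci_low"] <= 5.0 <= row["ci_high"]

    def test_entry_rule_drops_null_covariate(self):
        rng = np.random.default_rng(8)
        df = simulate_ph_cohort(600, 4.0, seed=8)
        df["noise"] = rng.normal(size=len(df))
        res = cox_model(df, ["exposed", "noise"], mode="multivariate")
        tbl = res.table.set_index("covariate")
        assert bool(tbl.loc["exposed", "kept"])
        assert not bool(tbl.loc["noise", "kept"])

    def test_per_decrease_scaling(self):
        df = simulate_ph_cohort(500, 3.0, seed=5)
        df["score"] = 100.0 * df["exposed"] + 50.0
        plain = cox_model(df, ["score"], mode="univariate")
        scaled = cox_model(df, ["score"], mode="univariate", scaling={"score": -50.0})
        b = plain.table.iloc[0]["coef"]
        assert scaled.table.iloc[0]["hr"] == pytest.approx(np.exp(-50.0 * b))
        assert scaled.table.iloc[0]["p"] == pytest.approx(plain.table.iloc[0]["p"])
        lo, hi = scaled.table.iloc[0][["ci_low", "ci_high"]]
        assert lo <= scaled.table.iloc[0]["hr"] <= hi

    def test_constant_covariate_rejected(self):
        df = simulate_ph_cohort(100, 2.0, seed=1)
        df["flat"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            cox_model(df, ["flat"])

    def test_too_few_events_rejected(self):
        df = pd.DataFrame({"time": [1, 2, 3], "event": [True, False, False],
                           "x": [0, 1, 0]})
        with pytest.raises(ValueError, match="events"):
            cox_model(df, ["x"])


def _people(ids, ages, grades, ki67s):
    return pd.DataFrame({"id": ids, "age": ages, "grade": grades, "ki67": ki67s})


class TestMatching:
    def test_exact_copies_matched(self):
        cases = _people(["c1", "c2"], [50, 60], ["II", "III"], [10, 30])
        pool = _people(["p1", "p2", "p3"], [60, 50, 70], ["III", "II", "I"], [30, 10, 5])
        pairs, unmatched = match_controls(cases, pool, seed=0)
        assert unmatched == []
        got = dict(zip(pairs["case_id"], pairs["control_id"]))
        assert got == {"c1": "p2", "c2": "p1"}
        assert (pairs["distance"] == 0).all()

    def test_wrong_grade_never_matches(self):
        cases = _people(["c1"], [50], ["II"], [10])
        pool = _people(["p1", "p2"], [50, 51], ["III", "I"], [10, 11])
        pairs, unmatched = match_controls(cases, pool, seed=0)
        assert len(pairs) == 0 and unmatched == ["c1"]

    def test_caliper_audit_on_synthetic_cohort(self, rng):
        n = 60
        cases = _people(
            [f"c{i}" for i in range(n)],
            rng.uniform(40, 70, n),
            rng.choice(["I", "II", "III"], n),
            rng.uniform(5, 40, n),
        )
        pool = _people(
            [f"p{i}" for i in range(4 * n)],
            rng.uniform(40, 70, 4 * n),
            rng.choice(["I", "II", "III"], 4 * n),
            rng.uniform(5, 40, 4 * n),
        )
        spec = MatchSpec()
        pairs, _ = match_controls(cases, pool, spec=spec, seed=1)
        assert len(pairs) > 0
        merged = pairs.merge(
            cases.add_prefix("case_"), left_on="case_id", right_on="case_id"
        ).merge(pool.add_prefix("control_"), left_on="control_id", right_on="control_id")
        assert (merged["case_grade"] == merged["control_grade"]).all()
        assert ((merged["case_age"] - merged["control_age"]).abs()
                <= spec.age_caliper).all()
        assert ((merged["case_ki67"] - merged["control_ki67"]).abs()
                <= spec.ki67_caliper).all()
        # without replacement: controls used at most once
        assert pairs["control_id"].is_unique

    def test_deterministic_per_seed(self, rng):
        cases = _people(["a", "b", "c"], [50, 52, 54], ["II"] * 3, [10, 12, 14])
        pool = _people(
            [f"p{i}" for i in range(6)],
            [49, 51, 53, 55, 50, 52],
            ["II"] * 6,
            [11, 11, 13, 15, 10, 12],
        )
        p1, _ = match_controls(cases, pool, seed=3)
        p2, _ = match_controls(cases, pool, seed=3)
        assert p1.equals(p2)

    def test_pool_overlap_rejected(self):
        cases = _people(["x"], [50], ["II"], [10])
        with pytest.raises(ValueError, match="overlap"):
            match_controls(cases, cases, seed=0)

    def test_empty_pool_rejected(self):
        cases = _people(["x"], [50], ["II"], [10])
        with pytest.raises(ValueError, match="empty"):
            match_controls(cases, cases.iloc[:0], seed=0)
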