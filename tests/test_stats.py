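import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pancmorph import (
    InputError,
    classify_responder,
    correlate,
    generate_cohort,
    mann_whitney_u,
    paired_t,
    records_to_dataframe,
    summarize_group,
    table1_cohort_spec,
    unpaired_t,
)

finite_floats = st.floats(-1e6, 1e6, allow_nan=False)


def exact_mwu_p(x, y):
    """Brute-force Mann-Whitney: enumerate all group assignments of the
    pooled ranks and count Us at least as extreme (two-sided)."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = pd.Series(pooled).rank().to_numpy()
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    n = len(pooled)
    mu = n1 * (n - n1) / 2
    count = total = 0
    for idx in itertools.combinations(range(n), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total


class TestClassifier:
    def test_strict_boundary(self):
        assert classify_responder(6.9) == "responder"
        assert classify_responder(7.0) == "non_responder"
        assert classify_responder(5.1) == "responder"
        assert classify_responder(8.5) == "non_responder"

    def test_missing_value_unassigned(self):
        assert classify_responder(None) == "unassigned"
        assert classify_responder(float("nan")) == "unassigned"


class TestPairedT:
    def test_hand_computed_example(self):
        res = paired_t([1, 2, 3, 4], [2, 3, 5, 6])
        assert res.statistic == pytest.approx(-5.196, abs=1e-3)
        assert res.p_value == pytest.approx(0.0138, abs=1e-3)
        assert res.n == 4

    def test_swap_negates_t_keeps_p(self):
        a = paired_t([1.0, 2.5, 3.0], [2.0, 2.0, 4.5])
        b = paired_t([2.0, 2.0, 4.5], [1.0, 2.5, 3.0])
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_constant_shift_gives_p_one(self):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        res = paired_t(x + np.array([0.5, -0.5, 0.5, -0.5]), x)
        assert res.p_value == pytest.approx(1.0, abs=1e-12)

    def test_zero_variance_differences_not_computable(self):
        res = paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert res.p_value is None and not res.computable


class TestUnpairedT:
    def test_hand_computed_example(self):
        res = unpaired_t([1, 2, 3], [4, 5, 6])
        assert res.statistic == pytest.approx(-3.674, abs=1e-3)
        assert res.p_value == pytest.approx(0.0213, abs=1e-3)

    @given(
        x=st.lists(finite_floats, min_size=3, max_size=8),
        y=st.lists(finite_floats, min_size=3, max_size=8),
        scale=st.floats(0.1, 100.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scale_invariance(self, x, y, scale):
        a = unpaired_t(x, y)
        b = unpaired_t([scale * v for v in x], [scale * v for v in y])
        if a.computable and b.computable and np.isfinite(a.statistic):
            assert b.statistic == pytest.approx(a.statistic, rel=1e-9, abs=1e-9)

    def test_welch_flag_changes_df(self):
        pooled = unpaired_t([1, 2, 3], [4.0, 8.0, 16.0, 30.0])
        welch = unpaired_t([1, 2, 3], [4.0, 8.0, 16.0, 30.0], welch=True)
        assert pooled.p_value != welch.p_value


class TestMannWhitney:
    def test_small_sample_exact_enumeration(self):
        res = mann_whitney_u([1, 2], [3, 4])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0 / 3.0)
        assert res.note == "exact"

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            x = rng.normal(size=rng.integers(2, 6))
            y = rng.normal(size=rng.integers(2, 6))
            res = mann_whitney_u(x, y)
            assert res.p_value == pytest.approx(exact_mwu_p(x, y), abs=1e-9)

    @given(
        x=st.lists(st.integers(0, 50), min_size=1, max_size=10),
        y=st.lists(st.integers(0, 50), min_size=1, max_size=10),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_rank_sum_identity(self, x, y):
        u1 = mann_whitney_u(x, y).statistic
        u2 = mann_whitney_u(y, x).statistic
        assert u1 + u2 == pytest.approx(len(x) * len(y))

    def test_exact_matches_enumeration_and_tracks_asymptotic_at_n8(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(11)
        asym_gaps = []
        for _ in range(100):
            x = rng.normal(size=8)
            y = rng.normal(size=8) + 0.5
            res = mann_whitney_u(x, y)  # n = 8 -> exact path
            assert res.p_value == pytest.approx(exact_mwu_p(x, y), abs=1e-9)
            p_asym = mannwhitneyu(x, y, method="asymptotic", use_continuity=True).pvalue
            asym_gaps.append(abs(res.p_value - p_asym))
        assert max(asym_gaps) < 0.02


class TestCorrelate:
    def test_perfect_linear_pearson(self):
        x = np.arange(10.0)
        res = correlate(x, 2 * x + 1, "pearson")
        assert res.estimate == pytest.approx(1.0)

    def test_monotone_nonlinear_spearman_vs_pearson(self):
        x = np.arange(1.0, 11.0)
        y = np.exp(x)
        assert correlate(x, y, "spearman").estimate == pytest.approx(1.0)
        assert correlate(x, y, "pearson").estimate < 1.0

    def test_rank_formula_example(self):
        # sum d^2 = 4 -> rho = 1 - 6*4/120 = 0.8 (brute-force rank check)
        x, y = [1, 2, 3, 4, 5], [2, 1, 4, 3, 5]
        rx = pd.Series(x).rank().to_numpy()
        ry = pd.Series(y).rank().to_numpy()
        d2 = ((rx - ry) ** 2).sum()
        expected = 1 - 6 * d2 / (5**3 - 5)
        assert expected == pytest.approx(0.8)
        assert correlate(x, y, "spearman").estimate == pytest.approx(expected)

    def test_zero_variance_not_computable(self):
        assert correlate([1, 1, 1], [1, 2, 3], "pearson").p_value is None


@pytest.fixture(scope="module")
def cohort_df():
    return records_to_dataframe(generate_cohort(table1_cohort_spec(seed=2)))


class TestSummarize:

    def test_cells_match_pandas_group_means(self, cohort_df):
        summary = summarize_group(cohort_df)
        sub = cohort_df.query("group == 'non_responder' and timepoint == 'month6'")["bmi"]
        cell = summary.cell("bmi", "non_responder", "month6")
        assert cell["mean"] == pytest.approx(sub.mean())
        assert cell["sem"] == pytest.approx(sub.std(ddof=1) / np.sqrt(len(sub)))
        assert cell["n"] == len(sub)

    def test_group_swap_keeps_between_group_p(self, cohort_df):
        swapped = cohort_df.copy()
        swapped["group"] = swapped["group"].map(
            {"responder": "non_responder", "non_responder": "responder"}
        )
        a = summarize_group(cohort_df).contrasts
        b = summarize_group(swapped).contrasts
        for contrast in ("between_groups:baseline", "between_groups:month6"):
            pa = a.query("variable == 'weight_kg' and contrast == @contrast")["p_value"].iloc[0]
            pb = b.query("variable == 'weight_kg' and contrast == @contrast")["p_value"].iloc[0]
            assert pa == pytest.approx(pb)

    def test_identical_values_give_not_computable_not_one(self, cohort_df):
        df = cohort_df.copy()
        df["fd"] = 1.2
        contrasts = summarize_group(df).contrasts
        row = contrasts.query("variable == 'fd' and contrast == 'responder:baseline_vs_week8'")
        assert row["p_value"].isna().all()
        assert (row["note"] == "zero-variance differences").all()

    def test_named_tests_used_for_insulin_and_age(self, cohort_df):
        contrasts = summarize_group(cohort_df).contrasts
        ins = contrasts.query("variable == 'insulin_pmol_l' and contrast == 'between_groups:baseline'")
        assert (ins["method"] == "mann_whitney_u").all()
        age = contrasts.query("variable == 'age_years'")
        assert (age["method"] == "unpaired_t").all()

    def test_missing_values_excluded_with_n_reported(self, cohort_df):
        df = cohort_df.copy()
        idx = df.query("group == 'responder' and timepoint == 'baseline'").index[:3]
        df.loc[idx, "fd"] = np.nan
        summary = summarize_group(df)
        assert summary.cell("fd", "responder", "baseline")["n"] == 12 - 3

    def test_input_errors(self):
        with pytest.raises(InputError):
            paired_t([1.0], [2.0])
        with pytest.raises(InputError):
            unpaired_t([1.0], [1.0, 2.0])
        with pytest.raises(InputError):
            correlate([1.0, 2.0], [1.0, 2.0])
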