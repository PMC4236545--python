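import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from villagenet import (
    TownshipConfig,
    anova_oneway,
    build_table,
    default_codebook,
    generate_township,
    group_categories,
    metrics_frame,
    overall_stats,
    tables_to_frame,
)

from conftest import make_person


class TestGroupCategories:
    @pytest.mark.parametrize(
        "age, expected", [(64, "<=64"), (65, "65-74"), (74, "65-74"), (75, ">=75")]
    )
    def test_age_bins(self, codebook, age, expected):
        df = group_categories([make_person(age=age)], codebook)
        assert df.iloc[0]["age_group"] == expected

    def test_srh_three_group_recode(self, codebook):
        df = group_categories([make_person(srh=3)], codebook)
        assert df.iloc[0]["srh_group"] == "good"

    def test_never_married_merges_into_nonspouse_group(self, codebook):
        df = group_categories(
            [
                make_person(marital_status="never_married"),
                make_person(pid="P0001", marital_status="separated_divorced_widowed"),
            ],
            codebook,
        )
        assert set(df["marital_group"]) == {"separated_divorced_widowed"}

    def test_non_respondents_excluded(self, codebook):
        df = group_categories([make_person(is_respondent=False)], codebook)
        assert len(df) == 0


def sums_of_squares_oracle(groups):
    """Textbook SSB/SSW computation, kept deliberately naive."""
    all_vals = [v for g in groups for v in g]
    grand = sum(all_vals) / len(all_vals)
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum((v - sum(g) / len(g)) ** 2 for g in groups for v in g)
    dfb = len(groups) - 1
    dfw = len(all_vals) - len(groups)
    return (ssb / dfb) / (ssw / dfw)


class TestAnova:
    def test_identical_groups_give_f_zero_p_one(self):
        F, p = anova_oneway([[1, 2, 3], [1, 2, 3]])
        assert F == 0.0 and p == 1.0

    def test_perfect_separation_gives_p_zero(self):
        F, p = anova_oneway([[0, 0, 0], [1, 1, 1]])
        assert math.isinf(F) and p == 0.0

    def test_matches_sums_of_squares_oracle(self):
        rng = np.random.default_rng(31)
        groups = [list(rng.normal(m, 1.0, size=10)) for m in (0.0, 0.4, 1.0)]
        F, p = anova_oneway(groups)
        assert F == pytest.approx(sums_of_squares_oracle(groups), abs=1e-10)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(32)
        groups = [rng.normal(m, 1.0, size=n) for m, n in ((0, 8), (0.5, 12), (1, 7))]
        F, p = anova_oneway(groups)
        ref = stats.f_oneway(*groups)
        assert F == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_single_group_undefined(self):
        F, p = anova_oneway([[1, 2, 3]])
        assert math.isnan(F) and math.isnan(p)

    def test_all_constant_undefined(self):
        F, p = anova_oneway([[2, 2], [2, 2]])
        assert math.isnan(F) and math.isnan(p)

    @given(
        shift=st.floats(-50, 50),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_invariant_to_adding_a_constant(self, shift, seed):
        rng = np.random.default_rng(seed)
        groups = [rng.normal(m, 1.0, size=6) for m in (0.0, 1.0)]
        F0, p0 = anova_oneway(groups)
        F1, p1 = anova_oneway([g + shift for g in groups])
        assert F1 == pytest.approx(F0, rel=1e-6, abs=1e-8)
        assert p1 == pytest.approx(p0, rel=1e-6, abs=1e-12)

    def test_invariant_to_group_relabeling(self):
        rng = np.random.default_rng(33)
        groups = [list(rng.normal(m, 1, 8)) for m in (0, 1, 2)]
        F0, _ = anova_oneway(groups)
        F1, _ = anova_oneway(groups[::-1])
        assert F1 == pytest.approx(F0, rel=1e-12)

    def test_p_monotone_decreasing_in_f(self):
        # same dfs, growing separation => larger F, smaller p
        results = [
            anova_oneway([[0, 0.1, -0.1], [d, d + 0.1, d - 0.1]]) for d in (0.2, 0.5, 1.0)
        ]
        Fs = [F for F, _ in results]
        ps = [p for _, p in results]
        assert Fs == sorted(Fs) and ps == sorted(ps, reverse=True)
        assert all(F >= 0 for F in Fs)


class TestOverallStats:
    def test_constant_sample(self):
        mean, sd, skew = overall_stats([2, 2, 2])
        assert mean == 2.0 and sd == 0.0 and math.isnan(skew)

    def test_symmetric_sample_has_zero_skew(self):
        mean, sd, skew = overall_stats([1, 2, 3])
        assert skew == pytest.approx(0.0)

    def test_adjusted_skewness_matches_moment_oracle(self):
        x = [1.0, 1.0, 1.0, 5.0]
        n = len(x)
        mu = sum(x) / n
        m2 = sum((v - mu) ** 2 for v in x) / n
        m3 = sum((v - mu) ** 3 for v in x) / n
        g1 = m3 / m2**1.5
        G1 = g1 * math.sqrt(n * (n - 1)) / (n - 2)
        mean, sd, skew = overall_stats(x)
        assert skew == pytest.approx(G1, abs=1e-12)
        assert skew == pytest.approx(stats.skew(x, bias=False), abs=1e-12)

    def test_plain_moment_ratio_switch(self):
        x = [1.0, 2.0, 2.0, 7.0]
        _, _, g1 = overall_stats(x, skew_estimator="g1")
        assert g1 == pytest.approx(stats.skew(x, bias=True), abs=1e-12)

    def test_missing_values_ignored(self):
        mean, sd, _ = overall_stats([1.0, float("nan"), 3.0])
        assert mean == 2.0

    def test_insufficient_n(self):
        mean, sd, skew = overall_stats([4.0])
        assert mean == 4.0 and math.isnan(sd) and math.isnan(skew)


@pytest.fixture(scope="module")
def township_tables():
    cfg = TownshipConfig(n_population=500, seed=19)
    roster, surveys, _ = generate_township(cfg)
    codebook = default_codebook()
    metrics = metrics_frame(surveys, codebook)
    tables = build_table(metrics, ["age_group", "srh_group"], roster, codebook)
    return roster, metrics, tables


class TestBuildTable:

    def test_shape_three_age_rows_plus_footer(self, township_tables):
        _, _, tables = township_tables
        t = next(t for t in tables if t.measure == "size" and t.grouping == "age_group")
        assert t.categories == ["<=64", "65-74", ">=75"]
        frame = tables_to_frame([t])
        assert len(frame) == 4  # 3 categories + overall footer

    def test_category_ns_sum_and_proportions(self, township_tables):
        _, metrics, tables = township_tables
        for t in tables:
            assert sum(t.n.values()) == metrics[t.measure].notna().sum()
            assert sum(t.proportion.values()) == pytest.approx(1.0, abs=1e-9)

    def test_grand_mean_is_weighted_category_mean(self, township_tables):
        _, _, tables = township_tables
        for t in tables:
            total = sum(t.n.values())
            weighted = sum(t.n[c] * t.mean[c] for c in t.categories) / total
            assert t.overall_mean == pytest.approx(weighted, rel=1e-12)

    def test_all_missing_measure_yields_undefined_cells(self, township_tables):
        roster, metrics, _ = township_tables
        codebook = default_codebook()
        empty = pd.DataFrame(
            {"void": [float("nan")] * len(metrics)}, index=metrics.index
        )
        tables = build_table(empty, ["age_group"], roster, codebook)
        t = tables[0]
        assert t.categories == [] and math.isnan(t.overall_mean)

    def test_planted_size_srh_association_is_monotone(self, township_tables):
        """The generator links self-rated health to network size, so mean size
        must increase across the three srh groups."""
        _, _, tables = township_tables
        t = next(t for t in tables if t.measure == "size" and t.grouping == "srh_group")
        means = [t.mean[c] for c in ["poor_somewhat_poor", "good", "very_good_excellent"]]
        assert means[0] < means[1] < means[2]
        assert t.anova_p < 0.05
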