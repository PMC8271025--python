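import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy import stats

from radstab import (
    StabilityAnalysis,
    concordance_cc,
    corrected_ccc,
    dynamic_range,
    load_printed_fixture,
    robustness_table,
    stratify,
)

paired = st.integers(2, 30).flatmap(
    lambda n: st.tuples(
        arrays(float, n, elements=st.floats(-50, 50, width=32)),
        arrays(float, n, elements=st.floats(-50, 50, width=32)),
    )
)


class TestConcordance:
    def test_perfect_agreement(self):
        assert concordance_cc([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        assert concordance_cc([-1, 0, 1], [1, 0, -1]) == pytest.approx(-1.0)

    def test_shifted_sequence(self):
        # 2 * s_xy / (s_x^2 + s_y^2 + shift^2) = 2*1.25 / (1.25+1.25+1)
        assert concordance_cc([1, 2, 3, 4], [2, 3, 4, 5]) == pytest.approx(2.5 / 3.5)

    def test_degenerate_pair_is_nan(self):
        assert np.isnan(concordance_cc([2, 2, 2], [2, 2, 2]))

    def test_sample_moment_variant_differs_only_via_shift_term(self):
        x, y = [1.0, 2, 3, 4], [2.0, 3, 4, 5]
        pop = concordance_cc(x, y, moment="population")
        samp = concordance_cc(x, y, moment="sample")
        assert samp != pop
        assert samp == pytest.approx(2 * (5 / 3) / (2 * (5 / 3) + 1))

    def test_rejects_short_or_mismatched(self):
        with pytest.raises(ValueError):
            concordance_cc([1], [1])
        with pytest.raises(ValueError):
            concordance_cc([1, 2], [1, 2, 3])

    @settings(max_examples=150, deadline=None)
    @given(paired)
    def test_bounded_by_pearson_and_symmetric(self, xy):
        x, y = xy
        ccc = concordance_cc(x, y)
        if np.isnan(ccc):
            return
        assert -1 - 1e-12 <= ccc <= 1 + 1e-12
        assert ccc == pytest.approx(concordance_cc(y, x), abs=1e-12)
        if np.std(x) > 1e-9 and np.std(y) > 1e-9:
            r = stats.pearsonr(x, y).statistic
            assert abs(ccc) <= abs(r) + 1e-9

    @settings(max_examples=150, deadline=None)
    @given(paired)
    def test_moment_formula_matches_mean_square_definition(self, xy):
        # 1 - E[(X-Y)^2] / (s_x^2 + s_y^2 + (mx-my)^2) with expectation over
        # the empirical joint of independently-recentred samples
        x, y = xy
        ccc = concordance_cc(x, y)
        if np.isnan(ccc):
            return
        msd = np.mean(((x - x.mean()) - (y - y.mean())) ** 2) + (x.mean() - y.mean()) ** 2
        denom = x.var() + y.var() + (x.mean() - y.mean()) ** 2
        assert ccc == pytest.approx(1 - msd / denom, abs=1e-12)


class TestDynamicRange:
    def test_distinct_constant_samples_give_zero(self):
        assert dynamic_range([3, 3, 3], [5, 5, 5]) == pytest.approx(0.0)

    def test_identity_gives_one(self):
        assert dynamic_range([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_worked_example(self):
        assert dynamic_range([0, 10], [0, 8]) == pytest.approx(0.9)

    def test_constant_everywhere_is_nan(self):
        assert np.isnan(dynamic_range([1, 1], [1, 1]))

    @settings(max_examples=150, deadline=None)
    @given(paired)
    def test_bounded_and_symmetric(self, xy):
        x, y = xy
        dr = dynamic_range(x, y)
        if np.isnan(dr):
            return
        assert -1e-12 <= dr <= 1 + 1e-12
        assert dr == pytest.approx(dynamic_range(y, x), abs=1e-12)


class TestCorrectedCcc:
    @pytest.mark.parametrize(
        "ccc, icc, expected",
        [(0.88, 0.95, 0.93), (0.5, 1.0, 0.5), (0.99, 0.90, 1.09)],
    )
    def test_exact_arithmetic_not_clipped(self, ccc, icc, expected):
        assert corrected_ccc(ccc, icc) == pytest.approx(expected)


class TestRobustnessTable:
    def test_noiseless_matrix_all_one(self, noiseless_phantom):
        tab = robustness_table(noiseless_phantom)
        assert np.allclose(tab["ccc"], 1.0)
        assert np.allclose(tab["dr"], 1.0)
        assert (tab["n"] == 16).all()

    def test_constant_feature_flagged_undefined(self, catalog, default_phantom):
        data = default_phantom[
            default_phantom["sequence"].eq("T2 map")
            & default_phantom["feature_name"].isin(["ngtdm_Busyness", "ngtdm_Contrast"])
        ].copy()
        data.loc[data["feature_name"] == "ngtdm_Busyness", "value"] = 7.0
        tab = robustness_table(data).set_index("feature_name")
        assert np.isnan(tab.loc["ngtdm_Busyness", "ccc"])
        assert np.isnan(tab.loc["ngtdm_Busyness", "dr"])
        assert np.isfinite(tab.loc["ngtdm_Contrast", "ccc"])
        strat = stratify(tab.reset_index(), catalog)
        assert strat.n_undefined == 1

    def test_missing_scan_flagged_incomplete(self, default_phantom):
        data = default_phantom[
            default_phantom["sequence"].eq("T2 map")
            & default_phantom["feature_name"].eq("glcm_Contrast")
        ]
        drop = data[(data["object_id"] == "apple1") & (data["scan"] == 2)].index
        tab = robustness_table(data.drop(index=drop))
        assert tab["incomplete"].all()
        assert (tab["n"] == 15).all()


class TestStratify:
    def test_inclusive_conjunction_at_cutoff(self, catalog):
        import pandas as pd

        table = pd.DataFrame(
            {
                "feature_name": ["glcm_Contrast", "glcm_Idm"],
                "sequence": ["T2 map", "T2 map"],
                "ccc": [0.90, 0.91],
                "dr": [0.90, 0.89],
            }
        )
        strat = stratify(table, catalog)
        flags = strat.flags.set_index("feature_name")
        assert bool(flags.loc["glcm_Contrast", "pass_090"])  # 0.90 passes: inclusive
        assert not bool(flags.loc["glcm_Idm", "pass_090"])  # needs both statistics

    def test_table1_fixture_all_pass_at_090(self, catalog):
        t1 = load_printed_fixture("table1")
        strat = stratify(t1, catalog)
        assert strat.flags["pass_090"].all()
        assert len(strat.flags) == 84

    def test_nested_cutoff_monotonicity(self, catalog, default_phantom):
        res = StabilityAnalysis(default_phantom, catalog).fit()
        strat = res.stratify()
        for frame in (strat.by_sequence, strat.by_class_sequence, strat.by_class):
            assert (frame["frac_095"] <= frame["frac_090"] + 1e-12).all()
            assert (frame["frac_090"] <= frame["frac_085"] + 1e-12).all()

    def test_flags_are_nested(self, catalog, default_phantom):
        res = StabilityAnalysis(default_phantom, catalog).fit()
        flags = res.stratify().flags
        assert (~flags["pass_095"] | flags["pass_090"]).all()
        assert (~flags["pass_090"] | flags["pass_085"]).all()

    def test_shape_class_is_most_robust(self, catalog, default_phantom):
        res = StabilityAnalysis(default_phantom, catalog).fit()
        by_class = res.stratify().by_class
        assert by_class["frac_095"].idxmax() == "shape"

    def test_combine_mean_averages_per_sequence_fractions(self, catalog, default_phantom):
        res = StabilityAnalysis(default_phantom, catalog).fit()
        mean = res.stratify(combine="mean").by_class
        pooled = res.stratify(combine="pool").by_class
        manual = (
            res.stratify(combine="mean")
            .by_class_sequence.groupby(level="feature_class")["frac_090"]
            .mean()
        )
        assert np.allclose(mean["frac_090"], manual)
        assert set(pooled.index) == set(mean.index)
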