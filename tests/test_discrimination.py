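from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from radstab import (
    DiscriminationAnalysis,
    PhantomConfig,
    all_pairs_bound,
    generate_phantom_dataset,
    gini_score,
    group_fdr,
    mann_whitney_auc,
    null_model,
    perfect_separation_pvalue,
    success_counts,
)
from radstab.catalog import FeatureCatalog, build_feature_catalog

groups = st.tuples(
    st.lists(st.integers(-20, 20), min_size=1, max_size=8),
    st.lists(st.integers(-20, 20), min_size=1, max_size=8),
)


def brute_force_u(a, b):
    """Definitional U: count (a_i, b_j) pairs with b_j above, ties half."""
    u = 0.0
    for ai in a:
        for bj in b:
            if bj > ai:
                u += 1.0
            elif bj == ai:
                u += 0.5
    return u


class TestMannWhitneyAuc:
    def test_complete_separation(self):
        u, auc = mann_whitney_auc([1, 2, 3], [4, 5, 6])
        assert (u, auc) == (9.0, 1.0)

    def test_identical_groups_tie_to_half(self):
        _, auc = mann_whitney_auc([1, 2, 3], [1, 2, 3])
        assert auc == pytest.approx(0.5)

    def test_near_perfect_worked_example(self):
        u, auc = mann_whitney_auc([1, 2, 3, 4, 5, 7], [6, 8, 9, 10, 11, 12])
        assert u == 35.0
        assert auc == pytest.approx(35 / 36)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_auc([], [1])

    @settings(max_examples=200, deadline=None)
    @given(groups)
    def test_matches_brute_force_and_complements(self, ab):
        a, b = ab
        u, auc = mann_whitney_auc(a, b)
        assert u == brute_force_u(a, b)
        _, auc_rev = mann_whitney_auc(b, a)
        assert auc + auc_rev == pytest.approx(1.0)

    @settings(max_examples=100, deadline=None)
    @given(groups)
    def test_matches_scipy_midrank_statistic(self, ab):
        a, b = ab
        u, _ = mann_whitney_auc(a, b)
        ref = stats.mannwhitneyu(b, a, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(ref.statistic)


class TestGiniScore:
    @pytest.mark.parametrize(
        "auc, gini", [(1.0, 1.0), (0.5, 0.0), (35 / 36, 34 / 36), (0.0, -1.0)]
    )
    def test_rescaling(self, auc, gini):
        assert gini_score(auc) == pytest.approx(gini)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            gini_score(1.5)


@pytest.fixture(scope="module")
def grid(default_phantom, catalog):
    return DiscriminationAnalysis(default_phantom, catalog).fit().grid


class TestPairwiseGrid:
    def test_default_design_grid_size(self, grid):
        # 120 unordered pairs of 16 objects x 106 features x 5 sequences
        assert len(grid) == 63_600
        pairs = grid.groupby(["object_a", "object_b"]).ngroups
        assert pairs == 120
        assert (grid["n1"] == 6).all() and (grid["n2"] == 6).all()

    def test_replicates_per_group_are_six(self, grid):
        assert grid["u"].notna().all()
        assert grid["u"].between(0, 36).all()

    def test_gini_consistent_with_auc(self, grid):
        assert np.allclose(grid["gini"], 2 * grid["auc"] - 1)
        perfect = grid["perfect"]
        assert (grid.loc[perfect, "auc"].isin([0.0, 1.0])).all()

    def test_minimal_design_single_entry(self, catalog):
        sub = FeatureCatalog(
            entries=tuple(e for e in catalog if e.feature_name == "ngtdm_Busyness")
        )
        cfg = PhantomConfig(
            n_types=2, n_objects_per_type=1, sequences=("T2 map",), seed=0
        )
        data = generate_phantom_dataset(cfg, sub)
        grid = DiscriminationAnalysis(data, sub).fit().grid
        assert len(grid) == 1

    def test_incomplete_replicates_flagged_and_excluded(self, catalog, default_phantom):
        data = default_phantom[
            default_phantom["sequence"].eq("T2 map")
            & default_phantom["feature_name"].isin(["glcm_Idm", "glcm_Idn"])
        ]
        drop = data[
            (data["object_id"] == "apple1")
            & (data["scan"] == 2)
            & (data["feature_name"] == "glcm_Idm")
            & (data["session"] == "R2")
        ].index
        grid = DiscriminationAnalysis(data.drop(index=drop), catalog).fit().grid
        bad = grid[grid["incomplete"]]
        assert len(bad) == 15  # apple1 pairs for the one damaged feature
        assert (bad["feature_name"] == "glcm_Idm").all()
        assert bad["u"].isna().all() and not bad["perfect"].any()

    def test_success_counts_monotone_in_group_size(self, grid, catalog):
        per_class = success_counts(grid, catalog, "class")
        per_seq = success_counts(grid, catalog, "sequence")
        merged = per_class.merge(per_seq, on="sequence", suffixes=("_class", "_seq"))
        assert (merged["n_successes_class"] <= merged["n_successes_seq"]).all()

    def test_strong_separation_gives_full_success(self, grid):
        assert (success_counts(grid, build_feature_catalog())["n_successes"] == 120).all()

    def test_cross_type_pairs_all_separated(self, catalog, default_phantom):
        # type spread >> object spread >> noise: every cross-type pair must
        # be perfectly separated by at least one feature
        grid = DiscriminationAnalysis(default_phantom, catalog).fit().grid
        types = default_phantom.drop_duplicates("object_id").set_index("object_id")[
            "object_type"
        ]
        g = grid.copy()
        cross = g["object_a"].map(types) != g["object_b"].map(types)
        ok = g[cross].groupby(["object_a", "object_b"])["perfect"].any()
        assert ok.all()

    def test_relabeling_objects_preserves_success_counts(self, catalog, default_phantom):
        data = default_phantom[default_phantom["sequence"] == "T2 map"]
        objects = sorted(data["object_id"].unique())
        rng = np.random.default_rng(4)
        perm = dict(zip(objects, rng.permutation(objects)))
        relabeled = data.assign(object_id=data["object_id"].map(perm))
        c1 = success_counts(
            DiscriminationAnalysis(data, catalog).fit().grid, catalog
        )
        c2 = success_counts(
            DiscriminationAnalysis(relabeled, catalog).fit().grid, catalog
        )
        assert c1["n_successes"].tolist() == c2["n_successes"].tolist()


class TestRanking:
    def test_competition_ranking_with_shared_ranks(self, catalog, default_phantom):
        res = DiscriminationAnalysis(default_phantom, catalog).fit()
        rank = res.ranking()
        assert rank["rank"].iloc[0] == 1
        # descending successes; ties share a rank, next rank skips
        counts = rank["n_successes"].to_numpy()
        assert (np.diff(counts) <= 0).all()
        expected_rank = (
            rank["n_successes"].rank(method="min", ascending=False).astype(int)
        )
        assert (rank["rank"] == expected_rank).all()


class TestNullModel:
    def test_six_vs_six_exact(self):
        assert perfect_separation_pvalue(6, 6) == pytest.approx(1 / 924)

    def test_tiny_cases(self):
        assert perfect_separation_pvalue(1, 1) == pytest.approx(0.5)
        assert perfect_separation_pvalue(2, 2) == pytest.approx(1 / 6)

    def test_two_sided_doubles(self):
        assert perfect_separation_pvalue(6, 6, two_sided=True) == pytest.approx(2 / 924)
        assert perfect_separation_pvalue(1, 1, two_sided=True) == 1.0

    @pytest.mark.parametrize("n1, n2", [(2, 2), (3, 2), (3, 3), (4, 3)])
    def test_matches_exhaustive_rank_enumeration(self, n1, n2):
        total = 0
        hits = 0
        for b_ranks in combinations(range(n1 + n2), n2):
            a_ranks = [r for r in range(n1 + n2) if r not in b_ranks]
            _, auc = mann_whitney_auc(a_ranks, list(b_ranks))
            total += 1
            hits += auc == 1.0
        assert total == comb(n1 + n2, n1)
        assert Fraction(hits, total) == Fraction(
            perfect_separation_pvalue(n1, n2)
        ).limit_denominator(total)

    def test_group_fdr_and_bound(self):
        fdr = group_fdr(1 / 924, 106)
        assert fdr == pytest.approx(0.1084, abs=5e-4)
        assert group_fdr(0.3, 1) == pytest.approx(0.3)
        assert all_pairs_bound(fdr, 120) < 1e-58
        assert all_pairs_bound(0.5, 1) == 0.5

    def test_null_model_assembly(self):
        nm = null_model()
        assert nm.p_perfect == pytest.approx(1 / 924)
        assert nm.fdr_single == pytest.approx(1 - (1 - 1 / 924) ** 106)
        assert nm.p_all_pairs == pytest.approx(nm.fdr_single**120)
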