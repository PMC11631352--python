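import itertools

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix, TreeNode
from scipy.spatial.distance import pdist, squareform

from organaudit.diversity import (TestResult, alpha_diversity, beta_diversity,
                                  clr_transform, compare_conditions,
                                  kruskal_wallis, permanova, rarefy)
from tests.conftest import random_feature_table


@pytest.fixture
def four_tip_tree():
    return TreeNode.read(["((f1:0.1,f2:0.2):0.3,(f3:0.4,f4:0.5):0.6)root;"])


class TestRarefy:
    def test_columns_sum_to_depth(self):
        rng = np.random.default_rng(0)
        t = random_feature_table(rng, n_features=20, max_count=200)
        out = rarefy(t, depth=100, seed=1)
        assert (out.sum(axis=0) == 100).all()

    def test_shallow_samples_dropped(self):
        t = pd.DataFrame({"deep": [600, 600], "shallow": [400, 599]},
                         index=["f1", "f2"])
        out = rarefy(t, depth=1000, seed=0)
        assert list(out.columns) == ["deep"]

    def test_seed_reproducible(self):
        rng = np.random.default_rng(1)
        t = random_feature_table(rng, max_count=100)
        pd.testing.assert_frame_equal(rarefy(t, 50, seed=9), rarefy(t, 50, seed=9))

    def test_never_inflates_counts(self):
        rng = np.random.default_rng(2)
        for seed in range(10):
            t = random_feature_table(rng, max_count=100)
            out = rarefy(t, depth=40, seed=seed)
            assert (out.to_numpy() <= t[out.columns].to_numpy()).all()

    def test_all_samples_too_shallow_errors(self):
        t = pd.DataFrame({"s1": [3]}, index=["f1"])
        with pytest.raises(ValueError):
            rarefy(t, depth=10, seed=0)


class TestAlpha:
    def test_shannon_four_equal_features_is_two_bits(self):
        t = pd.DataFrame({"s": [25, 25, 25, 25]},
                         index=["f1", "f2", "f3", "f4"])
        assert alpha_diversity(t, "shannon")["s"] == pytest.approx(2.0)

    def test_simpson_evenness_uniform_is_one(self):
        t = pd.DataFrame({"s": [10, 10, 10, 10, 10]},
                         index=[f"f{i}" for i in range(5)])
        assert alpha_diversity(t, "simpson_e")["s"] == pytest.approx(1.0)

    def test_observed_features(self):
        t = pd.DataFrame({"s": [5, 0, 1]}, index=["f1", "f2", "f3"])
        assert alpha_diversity(t, "observed_features")["s"] == 2

    def test_faith_single_tip_is_root_path(self, four_tip_tree):
        t = pd.DataFrame({"s": [3, 0, 0, 0]}, index=["f1", "f2", "f3", "f4"])
        got = alpha_diversity(t, "faith_pd", tree=four_tip_tree)["s"]
        assert got == pytest.approx(0.1 + 0.3)

    def test_faith_missing_tip_listed(self, four_tip_tree):
        t = pd.DataFrame({"s": [3, 1]}, index=["f1", "not_in_tree"])
        with pytest.raises(ValueError, match="not_in_tree"):
            alpha_diversity(t, "faith_pd", tree=four_tip_tree)


class TestBeta:
    @pytest.mark.parametrize("metric", ["jaccard", "bray_curtis", "aitchison"])
    def test_identical_columns_distance_zero(self, metric):
        t = pd.DataFrame({"s1": [3, 4, 0], "s2": [3, 4, 0]},
                         index=["f1", "f2", "f3"])
        dm = beta_diversity(t, metric)
        assert dm["s1", "s2"] == pytest.approx(0.0)

    @pytest.mark.parametrize("metric", ["unweighted_unifrac", "weighted_unifrac"])
    def test_unifrac_identical_columns(self, metric, four_tip_tree):
        t = pd.DataFrame({"s1": [3, 4, 0, 1], "s2": [3, 4, 0, 1]},
                         index=["f1", "f2", "f3", "f4"])
        dm = beta_diversity(t, metric, tree=four_tip_tree)
        assert dm["s1", "s2"] == pytest.approx(0.0)

    def test_disjoint_presence_jaccard_one(self):
        t = pd.DataFrame({"s1": [5, 0], "s2": [0, 9]}, index=["f1", "f2"])
        assert beta_diversity(t, "jaccard")["s1", "s2"] == pytest.approx(1.0)

    def test_bray_curtis_closed_form(self):
        t = pd.DataFrame({"s1": [2, 0], "s2": [0, 2]}, index=["f1", "f2"])
        assert beta_diversity(t, "bray_curtis")["s1", "s2"] == pytest.approx(1.0)

    def test_aitchison_is_euclidean_of_clr(self):
        rng = np.random.default_rng(3)
        t = random_feature_table(rng, n_features=5)
        dm = beta_diversity(t, "aitchison", pseudocount=1)
        clr = clr_transform(t, 1).to_numpy().T
        manual = np.linalg.norm(clr[0] - clr[1])
        assert dm[t.columns[0], t.columns[1]] == pytest.approx(manual)

    def test_matrices_symmetric_zero_diagonal_bounded(self):
        rng = np.random.default_rng(4)
        t = random_feature_table(rng) + 1
        for metric in ("jaccard", "bray_curtis"):
            dm = beta_diversity(t, metric)
            data = dm.data
            assert np.allclose(data, data.T, atol=1e-12)
            assert (np.diag(data) == 0).all()
            assert data.min() >= 0 and data.max() <= 1


class TestKruskalWallis:
    def _series(self, values, groups):
        idx = [f"s{i}" for i in range(len(values))]
        return pd.Series(values, index=idx), pd.Series(groups, index=idx)

    def test_identical_multisets_h_zero(self):
        v, g = self._series([1, 2, 3, 1, 2, 3], list("aaabbb"))
        assert kruskal_wallis(v, g).statistic == pytest.approx(0.0)

    def test_separated_groups_oracle_value(self):
        # hand evaluation of the rank-sum formula:
        # H = 12/(6*7) * (6^2/3 + 15^2/3) - 3*7 = 3.857142...
        v, g = self._series([1, 2, 3, 4, 5, 6], list("aaabbb"))
        assert kruskal_wallis(v, g).statistic == pytest.approx(3.857, abs=5e-4)

    def test_shift_invariance(self):
        v, g = self._series([1.0, 5.0, 2.0, 8.0, 3.0, 9.0], list("ababab"))
        h1 = kruskal_wallis(v, g).statistic
        h2 = kruskal_wallis(v + 100.0, g).statistic
        assert h1 == pytest.approx(h2)

    def test_empty_group_rejected(self):
        v = pd.Series([1.0, 2.0], index=["s0", "s1"])
        g = pd.Series(["a", None], index=["s0", "s1"])
        with pytest.raises(ValueError):
            kruskal_wallis(v, g)


def _pseudo_f(dm, labels):
    """Independent one-way PERMANOVA pseudo-F (textbook sums of squares)."""
    d2 = dm.data ** 2
    n = len(labels)
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in set(labels):
        idx = [i for i, l in enumerate(labels) if l == g]
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    a = len(set(labels))
    return (ss_among / (a - 1)) / (ss_within / (n - a))


class TestPermanova:
    def _clustered_dm(self, per_group, sep, seed=0):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(0, 0.01, (per_group, 3)),
                       rng.normal(sep, 0.01, (per_group, 3))])
        ids = [f"s{i}" for i in range(2 * per_group)]
        groups = pd.Series(["a"] * per_group + ["b"] * per_group, index=ids)
        return DistanceMatrix(squareform(pdist(X)), ids), groups

    def test_p_at_least_formula_floor(self):
        dm, groups = self._clustered_dm(4, sep=0.0, seed=1)
        r = permanova(dm, groups, n_permutations=99, seed=0)
        assert r.p_value >= 1 / 100

    def test_separated_clusters_reach_floor_p(self):
        dm, groups = self._clustered_dm(12, sep=100.0, seed=2)
        r = permanova(dm, groups, n_permutations=999, seed=0)
        assert r.p_value == pytest.approx(1 / 1000)

    def test_enumeration_oracle_n6(self):
        """Exact null at n=6: enumerate all 20 labelings; only the true
        partition (and its mirror) achieves F >= F_obs, so the exact
        permutation p is 2/20 and the sampled p approaches it."""
        dm, groups = self._clustered_dm(3, sep=100.0, seed=3)
        labels = list(groups)
        f_obs = _pseudo_f(dm, labels)
        count = sum(
            _pseudo_f(dm, perm) >= f_obs - 1e-12
            for perm in set(itertools.permutations(labels)))
        assert count == 2  # identity + group swap
        r = permanova(dm, groups, n_permutations=1999, seed=0)
        assert r.p_value == pytest.approx(2 / 20, abs=0.04)

    def test_statistic_matches_independent_formula(self):
        dm, groups = self._clustered_dm(5, sep=2.0, seed=4)
        r = permanova(dm, groups, n_permutations=99, seed=0)
        assert r.statistic == pytest.approx(_pseudo_f(dm, list(groups)))

    def test_uncovered_sample_rejected(self):
        dm, groups = self._clustered_dm(3, sep=1.0)
        with pytest.raises(ValueError):
            permanova(dm, groups.drop(groups.index[0]), n_permutations=9)


class TestCompareConditions:
    def _result(self, stat, p, method="permanova:bray_curtis", grouping="g"):
        return TestResult(statistic=stat, p_value=p, n_permutations=999,
                          method=method, grouping=grouping)

    def test_identical_lists_no_change(self):
        res = [self._result(2.0, 0.01), self._result(1.0, 0.50, "kw:shannon")]
        out = compare_conditions(res, res)
        assert (out["effect_fold_change"] == 1.0).all()
        assert (out["p_shift"] == 0.0).all()
        assert (~out["crossed_alpha"]).all()

    def test_significance_crossing_flagged(self):
        out = compare_conditions([self._result(2.0, 0.04)],
                                 [self._result(2.0, 0.06)])
        assert bool(out.loc[0, "crossed_alpha"])

    def test_effect_fold(self):
        out = compare_conditions([self._result(2.0, 0.5)],
                                 [self._result(1.0, 0.5)])
        assert out.loc[0, "effect_fold_change"] == pytest.approx(0.5)

    def test_unpaired_entry_named(self):
        with pytest.raises(ValueError, match="kw:shannon"):
            compare_conditions([self._result(1.0, 0.5)],
                               [self._result(1.0, 0.5, "kw:shannon")])
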