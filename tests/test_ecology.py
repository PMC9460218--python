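import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from metabologenome.ecology import (
    classical_mds,
    correlation_distance_matrix,
    permanova,
    unifrac_matrix,
    unweighted_unifrac,
    weighted_unifrac,
)
from oracles import (
    random_tree_dict,
    unweighted_unifrac_bruteforce,
    weighted_unifrac_bruteforce,
)

PAIRED_TREE = "((A:1,B:1):1,(C:1,D:1):1);"
STAR4 = "(A:1,B:1,C:1,D:1);"


class TestUnweightedUniFrac:
    def test_identical_presence_sets_distance_zero(self):
        a = {"A": 0.5, "C": 0.5}
        assert unweighted_unifrac(a, dict(a), PAIRED_TREE) == 0.0

    def test_sister_taxa_worked_example(self):
        # unique branches A,B (length 2); shared internal branch above {A,B}
        assert unweighted_unifrac({"A": 1.0}, {"B": 1.0}, PAIRED_TREE) == pytest.approx(2 / 3)

    def test_disjoint_star_samples_distance_one(self):
        assert unweighted_unifrac({"A": 1.0}, {"B": 1.0}, STAR4) == 1.0

    def test_unknown_taxon_named_in_error(self):
        with pytest.raises(KeyError, match="Zeta"):
            unweighted_unifrac({"Zeta": 1.0}, {"A": 1.0}, PAIRED_TREE)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            unweighted_unifrac({"A": 0.0}, {"B": 1.0}, PAIRED_TREE)

    def test_matches_bruteforce_oracle_on_random_trees(self):
        rng = np.random.default_rng(2024)
        worst = 0.0
        for _ in range(100):
            n = int(rng.integers(2, 9))
            newick, a, b = random_tree_dict(rng, n)
            if not any(v > 0 for v in a.values()) or not any(v > 0 for v in b.values()):
                continue
            mine = unweighted_unifrac(a, b, newick)
            oracle = unweighted_unifrac_bruteforce(a, b, newick)
            worst = max(worst, abs(mine - oracle))
        assert worst < 1e-12

    def test_triangle_inequality_on_random_triples(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = int(rng.integers(3, 9))
            newick, a, b = random_tree_dict(rng, n)
            _, c, _ = random_tree_dict(rng, n)
            # reuse the same tree for c by regenerating abundances only
            c = {k: v for k, v in zip(a.keys(), rng.random(len(a)))}
            dab = unweighted_unifrac(a, b, newick)
            dac = unweighted_unifrac(a, c, newick)
            dcb = unweighted_unifrac(c, b, newick)
            assert dab <= dac + dcb + 1e-12


class TestWeightedUniFrac:
    def test_identical_abundances_distance_zero(self):
        a = {"A": 0.25, "B": 0.25, "C": 0.5}
        assert weighted_unifrac(a, dict(a), PAIRED_TREE) == pytest.approx(0.0)

    def test_star_tree_disjoint_normalized_is_one(self):
        # raw = 1*1 + 1*1 = 2; normalizer = 2
        assert weighted_unifrac({"A": 1.0}, {"B": 1.0}, STAR4, normalized=True) == pytest.approx(1.0)
        assert weighted_unifrac({"A": 1.0}, {"B": 1.0}, STAR4) == pytest.approx(2.0)

    def test_scale_invariance_of_fractions(self):
        a = {"A": 0.2, "B": 0.8}
        a_half = {"A": 0.1, "B": 0.4}
        b = {"C": 0.5, "D": 0.5}
        assert weighted_unifrac(a, b, PAIRED_TREE) == pytest.approx(
            weighted_unifrac(a_half, b, PAIRED_TREE)
        )

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            n = int(rng.integers(2, 9))
            newick, a, b = random_tree_dict(rng, n)
            for normalized in (False, True):
                mine = weighted_unifrac(a, b, newick, normalized=normalized)
                oracle = weighted_unifrac_bruteforce(a, b, newick, normalized=normalized)
                assert mine == pytest.approx(oracle, abs=1e-12)

    def test_matrix_agrees_with_pairwise_and_skbio(self, default_cohort):
        from skbio.diversity import beta_diversity
        from metabologenome.ecology import TreeIndex

        table = default_cohort.abundance.iloc[:8]
        idx = TreeIndex(default_cohort.tree)
        mat = unifrac_matrix(table, idx, weighted=False)
        # pairwise calls agree with the matrix path
        s0, s3 = table.index[0], table.index[3]
        assert mat.loc[s0, s3] == pytest.approx(
            unweighted_unifrac(table.loc[s0], table.loc[s3], idx)
        )
        # independent cross-check against scikit-bio
        sk = beta_diversity(
            "unweighted_unifrac",
            (table.to_numpy() > 0).astype(int),
            ids=list(table.index),
            taxa=list(table.columns),
            tree=idx.tree,
        )
        np.testing.assert_allclose(mat.to_numpy(), sk.data, atol=1e-10)


class TestCorrelationDistance:
    def test_self_distance_zero_and_reversed_ranks_two(self):
        table = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [8.0, 6.0, 4.0, 2.0]], index=["s1", "s2"]
        )
        d = correlation_distance_matrix(table)
        assert d.loc["s1", "s1"] == 0.0
        assert d.loc["s1", "s2"] == pytest.approx(2.0)

    def test_monotone_transform_leaves_distance_unchanged(self):
        base = pd.DataFrame(
            [[1.0, 5.0, 2.0, 9.0], [3.0, 1.0, 8.0, 2.0]], index=["s1", "s2"]
        )
        transformed = base.copy()
        transformed.loc["s1"] = np.exp(base.loc["s1"])
        d1 = correlation_distance_matrix(base)
        d2 = correlation_distance_matrix(transformed)
        assert d1.loc["s1", "s2"] == pytest.approx(d2.loc["s1", "s2"])

    def test_missing_values_use_shared_features_only(self):
        table = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0, np.nan], [2.0, 4.0, 6.0, 8.0, 1.0]],
            index=["s1", "s2"],
        )
        d = correlation_distance_matrix(table)
        assert d.loc["s1", "s2"] == pytest.approx(0.0)  # rho=1 on 4 shared features

    def test_too_few_shared_features_flagged_nan(self):
        table = pd.DataFrame(
            [[1.0, 2.0, np.nan, np.nan], [np.nan, np.nan, 1.0, 2.0]],
            index=["s1", "s2"],
        )
        d = correlation_distance_matrix(table)
        assert np.isnan(d.loc["s1", "s2"])


class TestClassicalMDS:
    def test_line_configuration_reconstructed_exactly(self):
        # points at 0, 3, 5 on a line
        d = pd.DataFrame(
            [[0.0, 3.0, 5.0], [3.0, 0.0, 2.0], [5.0, 2.0, 0.0]],
            index=list("abc"), columns=list("abc"),
        )
        coords, eigvals = classical_mds(d, k=2)
        embedded = squareform(pdist(coords.to_numpy()))
        np.testing.assert_allclose(embedded, d.to_numpy(), atol=1e-9)
        assert eigvals[0] > 0

    def test_all_zero_distances_give_zero_coordinates(self):
        d = pd.DataFrame(np.zeros((4, 4)), index=list("abcd"), columns=list("abcd"))
        with pytest.warns(UserWarning):
            coords, _ = classical_mds(d, k=2)
        assert np.allclose(coords.to_numpy(), 0.0)

    def test_embedding_invariant_to_sample_order(self, rng):
        pts = rng.normal(size=(6, 3))
        d = pd.DataFrame(squareform(pdist(pts)), index=range(6), columns=range(6))
        perm = rng.permutation(6)
        d_perm = d.iloc[perm, perm]
        c1, _ = classical_mds(d, k=3)
        c2, _ = classical_mds(d_perm, k=3)
        e1 = squareform(pdist(c1.loc[d.index].to_numpy()))
        e2 = squareform(pdist(c2.loc[d.index].to_numpy()))
        np.testing.assert_allclose(e1, e2, atol=1e-9)

    def test_k_must_be_smaller_than_n(self):
        d = pd.DataFrame(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            classical_mds(d, k=3)


def _separated_matrix(n_per_group=12):
    n = 2 * n_per_group
    d = np.ones((n, n))
    d[:n_per_group, :n_per_group] = 0.0
    d[n_per_group:, n_per_group:] = 0.0
    np.fill_diagonal(d, 0.0)
    labels = ["g1"] * n_per_group + ["g2"] * n_per_group
    return pd.DataFrame(d, index=range(n), columns=range(n)), labels


class TestPermanova:
    def test_fully_separated_groups_hit_permutation_floor(self):
        d, labels = _separated_matrix()
        res = permanova(d, labels, n_permutations=999, seed=0)
        assert res.p == pytest.approx(1 / 1000)

    def test_pseudo_f_exceeds_one_when_between_exceeds_within(self, rng):
        pts = np.vstack([rng.normal(0, 1, (6, 2)), rng.normal(5, 1, (6, 2))])
        d = pd.DataFrame(squareform(pdist(pts)))
        labels = ["a"] * 6 + ["b"] * 6
        res = permanova(d, labels, n_permutations=99, seed=1)
        assert res.pseudo_F > 1

    def test_relabelling_invariance(self, rng):
        pts = rng.normal(size=(12, 2))
        d = pd.DataFrame(squareform(pdist(pts)))
        labels = np.array(["a", "b", "c"] * 4)
        perm = rng.permutation(12)
        d_perm = d.iloc[perm, perm].reset_index(drop=True)
        d_perm.columns = range(12)
        f1 = permanova(d, labels, n_permutations=9, seed=0).pseudo_F
        f2 = permanova(d_perm, labels[perm], n_permutations=9, seed=0).pseudo_F
        assert f1 == pytest.approx(f2)

    def test_matches_skbio_pseudo_f(self, rng):
        from skbio.stats.distance import DistanceMatrix
        from skbio.stats.distance import permanova as skbio_permanova

        pts = rng.normal(size=(10, 2))
        d = squareform(pdist(pts))
        labels = ["a"] * 5 + ["b"] * 5
        mine = permanova(pd.DataFrame(d), labels, n_permutations=99, seed=0)
        theirs = skbio_permanova(DistanceMatrix(d), grouping=labels, permutations=99)
        assert mine.pseudo_F == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_group_of_one_rejected(self):
        d = pd.DataFrame(np.ones((3, 3)) - np.eye(3))
        with pytest.raises(ValueError):
            permanova(d, ["a", "a", "b"], n_permutations=99)
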