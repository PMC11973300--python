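import io

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix, TreeNode
from skbio.stats.distance import permanova as skbio_permanova

from qmp.stats import (
    bh_adjust, filter_taxa, fisher_exact, fold_change, generalized_unifrac,
    pairwise_permanova, paired_taxon_tests, permanova, richness,
    shannon_effective, unifrac_distance_matrix, wilcoxon_signed_rank,
)
from qmp.tables_io import ValidationError
from tests._oracles import (
    bh_stepup, fisher_exact_p, permanova_exhaustive_p, wilcoxon_exact_p,
)


def _tree(newick: str) -> TreeNode:
    return TreeNode.read(io.StringIO(newick), convert_underscores=False)


class TestFilterTaxa:
    def test_clause_enumeration(self):
        # 6 taxa on 2 groups x 4 samples, constructed so that one taxon
        # fails the prevalence clause, one the abundance clause: 4 remain
        samples = [f"g1s{i}" for i in range(4)] + [f"g2s{i}" for i in range(4)]
        groups = {"g1": samples[:4], "g2": samples[4:]}
        rel = pd.DataFrame(0.0, index=samples, columns=list("ABCDEF"))
        rel.loc[samples[:2], "A"] = 0.01          # 50% in g1, abundant -> kept
        rel.loc[["g1s0", "g2s0"], "B"] = 0.01     # 25% in each group -> out
        rel.loc[samples[:4], "C"] = 0.001         # prevalent, never >=0.25% -> out
        rel.loc[samples, "D"] = 0.30              # everywhere -> kept
        rel.loc[samples[4:], "E"] = 0.0025        # boundary abundance -> kept
        rel.loc[samples[:2] + samples[4:6], "F"] = 0.05   # 50% both groups -> kept
        assert filter_taxa(rel, groups) == ["A", "D", "E", "F"]

    def test_boundary_prevalence_retained(self):
        samples = [f"s{i}" for i in range(10)]
        rel = pd.DataFrame(0.0, index=samples, columns=["t"])
        rel.loc[samples[:3], "t"] = 0.01          # exactly 30%
        assert filter_taxa(rel, {"g": samples}) == ["t"]

    def test_empty_group_rejected(self):
        rel = pd.DataFrame({"t": [0.1]}, index=["s"])
        with pytest.raises(ValidationError, match="empty"):
            filter_taxa(rel, {"g": []})


class TestWilcoxon:
    def test_all_same_sign_five_pairs(self):
        # exact two-sided p over all 2^5 sign assignments
        _, p = wilcoxon_signed_rank([5, 7, 9, 12, 14], [1, 2, 3, 4, 5])
        assert p == pytest.approx(0.0625)

    def test_identical_vectors_degenerate(self, caplog):
        with caplog.at_level("WARNING", logger="qmp"):
            _, p = wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_sign_flip_symmetry(self, rng):
        x, y = rng.random(8), rng.random(8)
        assert wilcoxon_signed_rank(x, y)[1] == pytest.approx(
            wilcoxon_signed_rank(y, x)[1])

    @pytest.mark.parametrize("n", [3, 4, 5, 6, 7, 8])
    def test_matches_enumeration_oracle(self, n):
        rng = np.random.default_rng(100 + n)
        for _ in range(5):
            d = rng.standard_normal(n) + 0.5
            _, p = wilcoxon_signed_rank(d, np.zeros(n))
            assert p == pytest.approx(wilcoxon_exact_p(d), abs=1e-12)


class TestFisher:
    def test_perfect_separation(self):
        _, p = fisher_exact([[6, 0], [0, 6]])
        assert p == pytest.approx(2 / 924)

    def test_balanced_table_is_one(self):
        assert fisher_exact([[3, 3], [3, 3]])[1] == 1.0

    def test_transpose_invariance(self, rng):
        t = rng.integers(0, 9, (2, 2))
        assert fisher_exact(t)[1] == pytest.approx(fisher_exact(t.T)[1])

    def test_zero_margin_is_one(self):
        assert fisher_exact([[0, 0], [3, 5]])[1] == 1.0

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(30):
            t = rng.integers(0, 9, (2, 2))
            assert fisher_exact(t)[1] == pytest.approx(fisher_exact_p(t), abs=1e-10)


class TestBH:
    def test_stepup_minima(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_all_ones(self):
        assert (bh_adjust([1.0, 1.0, 1.0]) == 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    def test_matches_definition_on_random_vectors(self, rng):
        for m in (1, 2, 5, 20, 100):
            p = rng.random(m)
            q = bh_adjust(p)
            assert q == pytest.approx(bh_stepup(p), abs=1e-12)
            # order-preserving and bounded
            assert (np.argsort(q) == np.argsort(q[np.argsort(p)][np.argsort(np.argsort(p))])).all
            assert (q >= p - 1e-15).all() and (q <= 1.0).all()


class TestFoldChangeAndDiversity:
    @pytest.mark.parametrize("before, after, expected", [
        (4.8e7, 1.9e7, 0.40),   # phylum-level cells/g drop after treatment
        (7.0, 7.0, 1.00),
        (2.0, 1.3, 0.65),       # relative-percent drop of a family
    ])
    def test_fold_change_two_decimals(self, before, after, expected):
        assert round(fold_change(before, after), 2) == expected

    def test_zero_baseline_undefined(self):
        assert np.isnan(fold_change(0.0, 5.0))

    def test_equipartition(self):
        f = np.full(8, 1 / 8)
        assert richness(f) == 8
        assert shannon_effective(f) == pytest.approx(8.0)

    def test_single_taxon(self):
        assert shannon_effective([1.0]) == pytest.approx(1.0)

    def test_uneven_three_taxa(self):
        # exp(H) for (1/2, 1/4, 1/4) is 2^(3/2)
        assert shannon_effective([0.5, 0.25, 0.25]) == pytest.approx(2 ** 1.5)

    def test_detection_threshold(self):
        assert richness([0.5, 0.3, 0.15, 0.05], detection_min=0.1) == 3


class TestGeneralizedUnifrac:
    def test_identical_samples_zero(self):
        tree = _tree("((A:1,B:2):1,C:1);")
        p = pd.Series({"A": 0.2, "B": 0.3, "C": 0.5})
        assert generalized_unifrac(tree, p, p) == pytest.approx(0.0)

    def test_disjoint_on_star_tree_one(self):
        tree = _tree("(A:1,B:1,C:1,D:1);")
        p = pd.Series({"A": 0.6, "B": 0.4, "C": 0.0, "D": 0.0})
        q = pd.Series({"A": 0.0, "B": 0.0, "C": 0.5, "D": 0.5})
        assert generalized_unifrac(tree, p, q) == pytest.approx(1.0)

    def test_two_leaf_hand_value(self):
        # branch sums: num = 1*1.5*(0.5/1.5) + 1*0.5*(0.5/0.5) = 1.0,
        # denom = 1.5 + 0.5 = 2.0 -> d = 0.5 at alpha = 1
        tree = _tree("(A:1,B:1);")
        p = pd.Series({"A": 0.5, "B": 0.5})
        q = pd.Series({"A": 1.0, "B": 0.0})
        assert generalized_unifrac(tree, p, q, alpha=1.0) == pytest.approx(0.5)

    def test_symmetry_and_range(self, rng):
        tree = _tree("((A:1,B:0.5):0.7,(C:2,D:1):0.3);")
        for _ in range(10):
            p = pd.Series(rng.dirichlet(np.ones(4)), index=list("ABCD"))
            q = pd.Series(rng.dirichlet(np.ones(4)), index=list("ABCD"))
            d = generalized_unifrac(tree, p, q)
            assert d == pytest.approx(generalized_unifrac(tree, q, p))
            assert 0.0 <= d <= 1.0

    def test_missing_abundant_taxon_rejected(self):
        tree = _tree("(A:1,B:1);")
        p = pd.Series({"A": 0.5, "B": 0.3, "Z": 0.2})
        with pytest.raises(ValidationError, match="Z"):
            generalized_unifrac(tree, p, p)

    def test_matrix_matches_pairwise(self, rng):
        tree = _tree("((A:1,B:0.5):0.7,(C:2,D:1):0.3);")
        abund = pd.DataFrame(rng.dirichlet(np.ones(4), 3),
                             index=list("xyz"), columns=list("ABCD"))
        dm = unifrac_distance_matrix(tree, abund, alpha=0.5)
        for i in "xyz":
            for j in "xyz":
                expected = generalized_unifrac(
                    tree, abund.loc[i], abund.loc[j], alpha=0.5)
                assert dm.at[i, j] == pytest.approx(expected)


def _random_distance_matrix(rng, n):
    pts = rng.standard_normal((n, 3))
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    labels = [f"s{i}" for i in range(n)]
    return pd.DataFrame(d, index=labels, columns=labels)


class TestPermanova:
    def test_constant_distances_analytic_r2(self):
        # with all pairwise distances equal, R^2 = (k-1)/(n-1) and F = 1
        n, c = 8, 0.7
        d = pd.DataFrame(c * (1 - np.eye(n)),
                         index=[f"s{i}" for i in range(n)],
                         columns=[f"s{i}" for i in range(n)])
        groups = pd.Series(["a"] * 4 + ["b"] * 4, index=d.index)
        res = permanova(d, groups, n_perm=99, seed=1)
        assert res.r_squared == pytest.approx(1 / 7)
        assert res.pseudo_f == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self, rng):
        d = _random_distance_matrix(rng, 6)
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=d.index)
        exact = permanova_exhaustive_p(d.values ** 2, 3)
        res = permanova(d, groups, n_perm=4999, seed=0)
        assert res.p_value == pytest.approx(exact, abs=0.03)

    def test_matches_skbio_pseudo_f(self, rng):
        d = _random_distance_matrix(rng, 10)
        groups = pd.Series(["a"] * 5 + ["b"] * 5, index=d.index)
        ours = permanova(d, groups, n_perm=9, seed=0)
        theirs = skbio_permanova(DistanceMatrix(d.values, ids=list(d.index)),
                                 grouping=groups.values, permutations=9)
        assert ours.pseudo_f == pytest.approx(theirs["test statistic"])

    def test_singleton_group_rejected(self, rng):
        d = _random_distance_matrix(rng, 5)
        groups = pd.Series(["a"] * 4 + ["b"], index=d.index)
        with pytest.raises(ValidationError, match="fewer than 2"):
            permanova(d, groups)

    def test_seed_reproducibility(self, rng):
        d = _random_distance_matrix(rng, 10)
        groups = pd.Series(["a"] * 5 + ["b"] * 5, index=d.index)
        p1 = permanova(d, groups, n_perm=199, seed=42).p_value
        p2 = permanova(d, groups, n_perm=199, seed=42).p_value
        assert p1 == p2

    def test_pairwise_mode_covers_all_pairs(self, rng):
        d = _random_distance_matrix(rng, 9)
        groups = pd.Series(["a"] * 3 + ["b"] * 3 + ["c"] * 3, index=d.index)
        out = pairwise_permanova(d, groups, n_perm=99, seed=0)
        assert len(out) == 3
        assert (out["q"] >= out["p"] - 1e-12).all()


class TestPairedTaxonTests:
    def test_fold_change_and_flags(self):
        pairs = pd.DataFrame(
            {"sample_t0": [f"p{i}_d0" for i in range(6)],
             "sample_t1": [f"p{i}_d1" for i in range(6)]},
            index=[f"p{i}" for i in range(6)])
        before = np.array([10.0, 11, 9, 10.5, 9.7, 12])
        after = before * 0.4
        abund = pd.DataFrame(
            {"down": np.concatenate([before, after]),
             "flat": np.concatenate([before, before + 1e-6])},
            index=list(pairs["sample_t0"]) + list(pairs["sample_t1"]))
        res = paired_taxon_tests(abund, pairs, "d0_vs_d1", "facs")
        down = res.set_index("taxon").loc["down"]
        assert down["fold_change"] == pytest.approx(0.4)
        assert down["p"] == pytest.approx(2 / 64)
        assert bool(down["significant_p"])
        assert (res["q"] >= res["p"] - 1e-12).all()
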