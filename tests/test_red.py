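"""Relative evolutionary divergence: recursion, MRCA, per-taxon minima."""

from __future__ import annotations

import itertools
import logging

import pytest

from ribobound import (
    IdentityMatrix,
    RedTree,
    compute_reds,
    find_mrca,
    identity_red_pairs,
    min_red_within_taxon,
    taxonomy_concordance_filter,
)
from ribobound.simulate import SimulationConfig, simulate_tree

from conftest import make_taxonomy
from oracles import mrca_by_ancestor_sets

TOY = "((A:1,B:1):1,C:2);"


def toy_tree() -> RedTree:
    return compute_reds(RedTree.from_newick_string(TOY))


class TestComputeReds:
    def test_toy_tree_hand_computed_value(self):
        """Cherry ancestor: p=0, d=1, u=mean(2,2)=2 -> red = 0 + (1/2)(1-0)."""
        t = toy_tree()
        mrca = find_mrca(t, "A", "B")
        assert t.red_of(mrca) == pytest.approx(0.5, abs=1e-12)

    def test_root_zero_leaves_one(self):
        t = toy_tree()
        assert t.red_of(t.root) == 0.0
        for lab in "ABC":
            assert t.red_of(lab) == 1.0

    @pytest.mark.parametrize("seed", [1, 2, 3])
    @pytest.mark.parametrize("n", [8, 33, 64])
    def test_random_trees_endpoints_and_monotonicity(self, seed, n):
        t = compute_reds(simulate_tree(SimulationConfig(n_leaves=n, seed=seed)))
        assert t.red_of(t.root) == 0.0
        for node in t.tree.preorder_node_iter():
            assert 0.0 <= node.red <= 1.0 + 1e-12
            if node.parent_node is not None:
                assert node.red >= node.parent_node.red - 1e-12
            if node.is_leaf():
                assert node.red == 1.0

    def test_uniform_ultrametric_closed_form(self):
        """With all branch lengths equal on a balanced tree, red(node) is its
        normalized depth (edges from root / tree height in edges)."""
        # complete binary tree of height 4, every branch length 1
        def build(depth):
            if depth == 0:
                return "L"
            left, right = build(depth - 1), build(depth - 1)
            return f"({left}:1,{right}:1)"

        newick = build(4) + ";"
        # give leaves unique labels
        count = itertools.count(1)
        newick = "".join(
            f"L{next(count)}" if c == "L" else c for c in newick
        )
        t = compute_reds(RedTree.from_newick_string(newick))
        for node in t.tree.preorder_node_iter():
            depth_edges = 0
            p = node
            while p.parent_node is not None:
                depth_edges += 1
                p = p.parent_node
            assert node.red == pytest.approx(depth_edges / 4, abs=1e-9)

    def test_child_order_permutation_invariance(self):
        t1 = toy_tree()
        t2 = compute_reds(RedTree.from_newick_string("(C:2,(B:1,A:1):1);"))
        for a, b in [("A", "B"), ("A", "C"), ("B", "C")]:
            assert t1.red_of(find_mrca(t1, a, b)) == pytest.approx(
                t2.red_of(find_mrca(t2, a, b)), abs=1e-12
            )

    def test_zero_length_subtree_takes_parent_red(self, caplog):
        t = RedTree.from_newick_string("((A:0,B:0):0,C:2);")
        with caplog.at_level(logging.WARNING):
            compute_reds(t)
        mrca = find_mrca(t, "A", "B")
        # u = 0 below the cherry: limit of the recursion is the parent's value
        assert t.red_of(mrca) == 0.0
        assert any("zero-length" in r.message for r in caplog.records)

    def test_negative_branch_length_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            RedTree.from_newick_string("((A:1,B:-1):1,C:2);")


class TestFindMrca:
    def test_cherry_and_root(self):
        t = toy_tree()
        assert find_mrca(t, "A", "B") is not t.root
        assert find_mrca(t, "A", "C") is t.root

    def test_polytomy_mrca_is_root(self):
        t = RedTree.from_newick_string("(A:1,B:1,C:1);")
        assert find_mrca(t, "A", "B") is t.root

    def test_unknown_label_and_self_pair_rejected(self):
        t = toy_tree()
        with pytest.raises(KeyError):
            find_mrca(t, "A", "Z")
        with pytest.raises(ValueError):
            find_mrca(t, "A", "A")

    @pytest.mark.parametrize("seed", [4, 9])
    def test_agrees_with_ancestor_set_oracle(self, seed):
        t = simulate_tree(SimulationConfig(n_leaves=40, seed=seed))
        labels = t.leaf_labels()
        import random

        rng = random.Random(seed)
        for _ in range(60):
            a, b = rng.sample(labels, 2)
            assert find_mrca(t, a, b) is mrca_by_ancestor_sets(t.tree, a, b)


class TestConcordance:
    def test_identical_records_retained(self):
        a = [make_taxonomy("x")]
        b = [make_taxonomy("x")]
        assert taxonomy_concordance_filter(a, b) == ["x"]

    def test_genus_mismatch_dropped(self):
        a = [make_taxonomy("x", genus="g1")]
        b = [make_taxonomy("x", genus="g2")]
        assert taxonomy_concordance_filter(a, b) == []

    def test_one_sided_id_dropped(self):
        assert taxonomy_concordance_filter([make_taxonomy("x")], []) == []

    def test_whitespace_trimmed_before_compare(self):
        a = [make_taxonomy("x", genus="g1 ")]
        b = [make_taxonomy("x", genus="g1")]
        assert taxonomy_concordance_filter(a, b) == ["x"]


class TestMinRedWithinTaxon:
    def test_cherry_genus(self):
        t = toy_tree()
        taxa = [make_taxonomy(s, genus="gAB") for s in "AB"]
        (tm,) = min_red_within_taxon(t, taxa, "genus")
        assert tm.min_red == pytest.approx(0.5)
        assert set(tm.argmin_pair) == {"A", "B"}

    def test_spanning_pair_hits_root(self):
        t = toy_tree()
        taxa = [make_taxonomy(s, genus="gAC") for s in "AC"]
        (tm,) = min_red_within_taxon(t, taxa, "genus")
        assert tm.min_red == 0.0

    def test_singleton_omitted(self):
        t = toy_tree()
        taxa = [make_taxonomy("A", genus="g1"), make_taxonomy("B", genus="g2"),
                make_taxonomy("C", genus="g2")]
        out = min_red_within_taxon(t, taxa, "genus")
        assert [tm.taxon_name for tm in out] == ["g2"]

    def test_member_missing_from_tree_is_an_error(self):
        t = toy_tree()
        with pytest.raises(KeyError, match="Z"):
            min_red_within_taxon(t, [make_taxonomy("Z")], "genus")

    @pytest.mark.parametrize("seed", [3, 8])
    def test_matches_explicit_pairwise_minimum(self, seed):
        """The reported minimum equals a brute-force min over all pairs."""
        from ribobound.simulate import assign_ranks_from_depths

        cfg = SimulationConfig(n_leaves=30, seed=seed)
        t = compute_reds(simulate_tree(cfg))
        taxa = assign_ranks_from_depths(t, cfg.rank_depth_thresholds)
        for rank in ("genus", "family", "order"):
            groups: dict[str, list[str]] = {}
            for rec in taxa:
                groups.setdefault(rec.rank_value(rank), []).append(rec.strain_id)
            expected = {
                name: min(
                    t.red_of(find_mrca(t, a, b))
                    for a, b in itertools.combinations(members, 2)
                )
                for name, members in groups.items()
                if len(members) >= 2
            }
            got = {
                tm.taxon_name: tm.min_red
                for tm in min_red_within_taxon(t, taxa, rank)
            }
            assert got.keys() == expected.keys()
            for name in expected:
                assert got[name] == pytest.approx(expected[name], abs=1e-12)


class TestIdentityRedPairs:
    def matrix(self):
        return IdentityMatrix.from_pairs(
            [("A", "B", 98.0), ("A", "C", 80.0), ("B", "C", 81.0)]
        )

    def test_three_strains_three_records(self):
        df = identity_red_pairs(self.matrix(), toy_tree(), ["A", "B", "C"])
        assert len(df) == 3
        row = df[(df.id_a == "A") & (df.id_b == "B")].iloc[0]
        assert row.mrca_red == pytest.approx(0.5)
        assert row.identity_pct == 98.0

    def test_empty_id_list(self):
        df = identity_red_pairs(self.matrix(), toy_tree(), [])
        assert len(df) == 0

    def test_positive_rank_correlation_on_benchmark(self, pipeline60):
        import pandas as pd
        from scipy.stats import spearmanr

        df = pd.read_csv(pipeline60.out_dir / "identity_red_pairs.tsv", sep="\t")
        rho = spearmanr(df.identity_pct, df.mrca_red).statistic
        assert rho > 0.5
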