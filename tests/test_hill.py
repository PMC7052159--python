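import math

import dendropy
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nichebreadth import (
    dietary_breadth,
    evenness_factor,
    hill_number,
    levins_index,
    phylo_hill_number,
    species_profile,
    trait_breadth,
)
from nichebreadth.simulate import perturb_tree_set, simulate_prey_tree

from conftest import make_tree, profile


def hill_oracle(p, q):
    """Direct plain-Python evaluation of the defining formulas."""
    p = [x / sum(p) for x in p if x > 0]
    if q == 1:
        return math.exp(-sum(x * math.log(x) for x in p))
    return sum(x**q for x in p) ** (1.0 / (1.0 - q)) if q != 0 else float(len(p))


def phylo_oracle(p: dict, tree: dendropy.Tree, q: float) -> float:
    """Naive branch walk on an explicitly pruned clone of the tree.

    For every edge of the pruned tree the abundance is accumulated by
    enumerating its descendant leaves; edges above the MRCA of the support
    (descendant set == full support) are excluded, matching the
    pruned-to-support definition.
    """
    support = {k for k, v in p.items() if v > 0}
    pruned = dendropy.Tree(tree)
    pruned.retain_taxa_with_labels(sorted(support))
    total = sum(v for v in p.values() if v > 0)
    terms = []
    for edge in pruned.preorder_edge_iter():
        if edge.length is None or edge.head_node is None:
            continue
        leaves = {
            lf.taxon.label for lf in edge.head_node.leaf_iter() if lf.taxon
        }
        a = sum(p.get(lb, 0.0) for lb in leaves & support) / total
        if 0 < a < 1 - 1e-12 and edge.length > 0:
            terms.append((edge.length, a))
    tbar = sum(length * a for length, a in terms)
    if q == 1:
        return math.exp(-sum((length / tbar) * a * math.log(a) for length, a in terms))
    return sum((length / tbar) * a**q for length, a in terms) ** (1 / (1 - q))


class TestNeutralHill:
    def test_matches_direct_formula_on_random_profiles(self, random_profiles):
        for p in random_profiles:
            for q in (0, 0.5, 1, 2, 3):
                assert hill_number(p, q) == pytest.approx(
                    hill_oracle(list(p), q), abs=1e-10
                )

    @pytest.mark.parametrize(
        "p, q, expected",
        [
            ([0.5, 0.5], 1, 2.0),
            ([1.0], 0, 1.0),
            ([1.0], 2, 1.0),
            ([0.8, 0.1, 0.1], 1, 1.8946457081379977),
        ],
    )
    def test_frozen_values(self, p, q, expected):
        assert hill_number(p, q) == pytest.approx(expected, abs=1e-12)

    def test_uniform_profile_gives_richness_at_every_q(self):
        for s in (1, 4, 17):
            for q in (0, 0.5, 1, 2, 5):
                assert hill_number(np.full(s, 1.0 / s), q) == pytest.approx(s)

    def test_monotone_non_increasing_in_q(self, random_profiles):
        qs = np.linspace(0, 4, 17)
        for p in random_profiles[:30]:
            values = [hill_number(p, q) for q in qs]
            assert all(a >= b - 1e-9 for a, b in zip(values, values[1:]))

    def test_replication_principle_doubling(self, rng):
        """Pooling two equally diverse, fully distinct profiles doubles qD."""
        base = rng.dirichlet(np.ones(6))
        pooled = np.concatenate([base / 2, base / 2])
        for q in (0, 0.5, 1, 2):
            assert hill_number(pooled, q) == pytest.approx(
                2 * hill_number(base, q), rel=1e-10
            )

    def test_negative_q_rejected(self):
        with pytest.raises(ValueError):
            hill_number([0.5, 0.5], -1)


class TestDerivedMetrics:
    def test_evenness_uniform_and_single(self):
        assert evenness_factor(np.full(8, 0.125)) == pytest.approx(1.0)
        assert evenness_factor([1.0]) == pytest.approx(1.0)

    def test_evenness_concentrated_frozen(self):
        # exp(-sum p ln p)/4 computed directly
        p = [0.97, 0.01, 0.01, 0.01]
        expected = hill_oracle(p, 1) / 4
        assert expected == pytest.approx(0.2957, abs=2e-4)
        assert evenness_factor(p) == pytest.approx(expected, abs=1e-12)

    def test_levins_frozen_and_identity(self, random_profiles):
        assert levins_index([0.5, 0.3, 0.2]) == pytest.approx(1 / 0.38, abs=1e-12)
        assert levins_index(np.full(7, 1 / 7)) == pytest.approx(7.0)
        for p in random_profiles:
            assert levins_index(p) == pytest.approx(
                hill_number(p, 2), abs=1e-12
            )

    def test_trait_breadth(self):
        assert trait_breadth([1.0]) == pytest.approx(1.0)
        assert trait_breadth([1 / 3] * 3) == pytest.approx(3.0)
        # exp(Shannon) of (0.6, 0.3, 0.1), frozen from the direct formula
        assert trait_breadth([0.6, 0.3, 0.1]) == pytest.approx(
            math.exp(-(0.6 * math.log(0.6) + 0.3 * math.log(0.3)
                       + 0.1 * math.log(0.1))),
            abs=1e-12,
        )


class TestPhyloHill:
    def test_star_tree_reduces_to_neutral(self, star_tree):
        p = {"A": 0.4, "B": 0.3, "C": 0.2, "D": 0.05, "E": 0.05}
        for q in (0, 0.5, 1, 2, 3):
            assert phylo_hill_number(p, star_tree, q) == pytest.approx(
                hill_number(list(p.values()), q), rel=1e-10
            )

    def test_two_leaf_even(self):
        tree = make_tree("(A:1,B:1):0;")
        assert phylo_hill_number({"A": 0.5, "B": 0.5}, tree, 1) == pytest.approx(2.0)

    def test_single_otu_is_one_lineage(self):
        tree = make_tree("((A:1,B:1):1,C:2):0;")
        for q in (0, 1, 2):
            assert phylo_hill_number({"A": 1.0}, tree, q) == pytest.approx(1.0)

    def test_matches_naive_pruning_oracle_on_random_trees(self, rng):
        for i in range(25):
            tree = simulate_prey_tree(8, seed=int(rng.integers(2**31 - 1)))
            labels = [f"OTU_{j + 1}" for j in range(8)]
            support = rng.choice(labels, size=int(rng.integers(2, 9)), replace=False)
            p = dict(zip(support, rng.dirichlet(np.ones(len(support)))))
            for q in (0, 0.5, 1, 2):
                assert phylo_hill_number(p, tree, q) == pytest.approx(
                    phylo_oracle(p, tree, q), abs=1e-10
                )

    def test_branch_length_scale_invariance(self, rng):
        tree = simulate_prey_tree(10, seed=11)
        p = dict(
            zip([f"OTU_{i + 1}" for i in range(10)], rng.dirichlet(np.ones(10)))
        )
        reference = {q: phylo_hill_number(p, tree, q) for q in (0, 1, 2)}
        scaled = dendropy.Tree(tree)
        for edge in scaled.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= 13.7
        for q, expected in reference.items():
            assert phylo_hill_number(p, scaled, q) == pytest.approx(
                expected, rel=1e-10
            )

    def test_missing_leaf_reported(self, star_tree):
        with pytest.raises(ValueError, match="OTU_X"):
            phylo_hill_number({"A": 0.5, "OTU_X": 0.5}, star_tree, 1)


class TestDietaryBreadth:
    def test_single_otu_individual_gives_unit_breadth(self, star_tree):
        pr = profile([1.0], index=["A"], species="sp1")
        for metric in ("dR", "dRE"):
            assert dietary_breadth([pr], metric).mean == pytest.approx(1.0)
        est = dietary_breadth([pr], "dRER", trees=[star_tree, star_tree])
        assert est.mean == pytest.approx(1.0)
        assert est.se == 0.0

    def test_identical_individuals_pool_to_same_profile(self):
        pr = profile([0.7, 0.3], species="sp1")
        pooled = species_profile([pr, pr, pr])
        pd.testing.assert_series_equal(pooled.values, pr.values)

    def test_read_pooling_weights_by_depth(self):
        a = profile([1.0, 0.0])
        a.depth = 9000
        b = profile([0.0, 1.0])
        b.depth = 1000
        pooled = species_profile([a, b], pool="reads")
        assert pooled.values.tolist() == pytest.approx([0.9, 0.1])

    def test_drer_dispersion_zero_for_identical_trees(self, rng):
        tree = simulate_prey_tree(12, seed=5)
        trees = perturb_tree_set(tree, n_trees=10, sd=0.0, seed=1)
        labels = [f"OTU_{i + 1}" for i in range(12)]
        profs = [
            profile(rng.dirichlet(np.ones(12)), index=labels, species="sp")
            for _ in range(4)
        ]
        est = dietary_breadth(profs, "dRER", trees=trees)
        assert est.se == pytest.approx(0.0, abs=1e-12)
        assert est.n_draws == 10

    def test_drer_mean_matches_per_tree_oracle(self, rng):
        """Mean across draws equals independently recomputed per-tree values."""
        tree = simulate_prey_tree(12, seed=9)
        trees = perturb_tree_set(tree, n_trees=8, sd=0.2, seed=2)
        labels = [f"OTU_{i + 1}" for i in range(12)]
        profs = [
            profile(rng.dirichlet(np.full(12, 0.5)), index=labels, species="sp")
            for _ in range(10)
        ]
        est = dietary_breadth(profs, "dRER", trees=trees)
        pooled = species_profile(profs)
        oracle = [
            phylo_oracle(pooled.values.to_dict(), t, 1) for t in trees
        ]
        assert est.mean == pytest.approx(np.mean(oracle), rel=1e-9)
        assert est.se == pytest.approx(
            np.std(oracle, ddof=1) / math.sqrt(len(oracle)), rel=1e-6
        )

    def test_drer_requires_trees(self):
        with pytest.raises(ValueError):
            dietary_breadth([profile([0.5, 0.5])], "dRER")


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    st.lists(st.floats(min_value=1e-3, max_value=1.0), min_size=2, max_size=20),
    st.floats(min_value=0, max_value=4),
)
def test_hill_bounds_property(raw, q):
    """1 <= qD <= S for any profile, any q >= 0."""
    value = hill_number(raw, q)
    assert 1.0 - 1e-9 <= value <= len(raw) + 1e-9
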