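"""Beta-diversity partitions, hull geometry, transect summaries, beta SES."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

import commphylo as cp
from commphylo.containers import DistanceMatrix
from commphylo.traitspace import TraitSpace


def star_tree(labels):
    return cp.tree_from_newick("(" + ",".join(f"{l}:1" for l in labels) + ");")


def _space(points, ids=None):
    pts = np.asarray(points, dtype=float)
    ids = ids or [f"s{i}" for i in range(len(pts))]
    lam = np.ones(pts.shape[1])
    return TraitSpace(list(ids), pts, lam, lam / lam.sum())


SQUARE = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float)


class TestChooseDimensions:
    @pytest.mark.parametrize("ra,rb,expected", [
        (10, 12, 4),   # algebraic cap
        (3, 9, 2),     # richness - 1 rule
        (2, 2, 1),     # interval hulls
        (5, 40, 4),
        (6, 6, 4),
    ])
    def test_rule(self, ra, rb, expected):
        assert cp.choose_dimensions(ra, rb) == expected

    def test_richness_below_two_rejected(self):
        with pytest.raises(cp.ValidationError):
            cp.choose_dimensions(1, 5)


class TestTaxonomic:
    def test_identical_sets_zero(self):
        p = cp.sorensen_partition({"A", "B"}, {"A", "B"})
        assert p.as_tuple() == (0.0, 0.0, 0.0)

    def test_disjoint_sets_pure_turnover(self):
        p = cp.sorensen_partition({"A", "B"}, {"C", "D"})
        assert p.beta_sor == 1.0 and p.beta_sim == 1.0 and p.beta_sne == 0.0

    def test_nested_sets_pure_nestedness(self):
        p = cp.sorensen_partition({"A", "B", "C"}, {"A", "B"})
        assert p.beta_sim == 0.0
        assert p.beta_sor == pytest.approx(0.2)
        assert p.beta_sne == pytest.approx(0.2)


class TestPhylo:
    def test_identical_sets_zero(self, three_tip_tree):
        p = cp.phylo_beta_pair(three_tip_tree, {"A", "B"}, {"A", "B"})
        assert p.as_tuple() == (0.0, 0.0, 0.0)

    def test_star_tree_disjoint(self):
        tree = star_tree("ABCD")
        p = cp.phylo_beta_pair(tree, {"A", "B"}, {"C", "D"})
        assert p.beta_sor == 1.0 and p.beta_sim == 1.0 and p.beta_sne == 0.0

    def test_star_tree_nested(self):
        tree = star_tree("ABCD")
        p = cp.phylo_beta_pair(tree, {"A", "B", "C"}, {"A", "B"})
        assert p.beta_sim == 0.0
        assert p.beta_sor == pytest.approx(0.2)
        assert p.beta_sne == pytest.approx(0.2)

    def test_star_tree_reduces_to_taxonomic_sorensen(self):
        rng = np.random.default_rng(3)
        labels = list("ABCDEFGH")
        tree = star_tree(labels)
        for _ in range(50):
            sa = {l for l in labels if rng.random() < 0.5} or {"A"}
            sb = {l for l in labels if rng.random() < 0.5} or {"B"}
            pt = cp.phylo_beta_pair(tree, sa, sb)
            ps = cp.sorensen_partition(sa, sb)
            assert pt.beta_sor == pytest.approx(ps.beta_sor)
            assert pt.beta_sim == pytest.approx(ps.beta_sim)

    def test_symmetry(self, rng):
        tree = cp.simulate_tree(12, rng)
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        a, b = set(labels[:7]), set(labels[4:])
        p1 = cp.phylo_beta_pair(tree, a, b)
        p2 = cp.phylo_beta_pair(tree, b, a)
        assert p1.beta_sor == pytest.approx(p2.beta_sor)
        assert p1.beta_sim == pytest.approx(p2.beta_sim)

    def test_branches_counted_from_union_mrca(self):
        # deep root branches shared by neither site must not count:
        # within one basal clade the other clade's stem is irrelevant
        tree = cp.tree_from_newick("(((A:1,B:1):1,C:2):3,D:5);")
        p = cp.phylo_beta_pair(tree, {"A", "B"}, {"C"})
        # from the ABC ancestor: shared 0, unique {A:1,B:1,AB:1}=3, {C:2}=2
        assert p.beta_sor == pytest.approx(1.0)
        assert p.beta_sim == pytest.approx(1.0)


class TestHulls:
    def test_unit_square_volume(self):
        assert cp.hull_volume(SQUARE) == pytest.approx(1.0)

    def test_identical_hulls_intersection_is_own_volume(self):
        v, se = cp.hull_intersection_volume(SQUARE, SQUARE.copy())
        assert v == pytest.approx(1.0, abs=1e-9)

    def test_half_overlapping_squares(self):
        v, _ = cp.hull_intersection_volume(SQUARE, SQUARE + [0.5, 0.0])
        assert v == pytest.approx(0.5, abs=1e-9)

    def test_disjoint_hulls(self):
        v, _ = cp.hull_intersection_volume(SQUARE, SQUARE + [5.0, 0.0])
        assert v == 0.0

    def test_interval_hulls_k1(self):
        a = np.array([[0.0], [1.0]])
        b = np.array([[0.4], [2.0]])
        v, _ = cp.hull_intersection_volume(a, b)
        assert v == pytest.approx(0.6)

    def test_degenerate_vertices_flagged(self):
        line = np.array([[0, 0], [1, 1], [2, 2], [3, 3]], dtype=float)
        with pytest.raises(cp.DegenerateHullError):
            cp.hull_volume(line)

    def test_exact_vs_monte_carlo_on_random_polytopes(self):
        rng = np.random.default_rng(9)
        for k in (2, 3, 4):
            for _ in range(5):
                pa = rng.normal(size=(k + 4, k))
                pb = rng.normal(size=(k + 4, k)) + 0.3
                exact, _ = cp.hull_intersection_volume(pa, pb)
                mc, se = cp.monte_carlo_intersection_volume(pa, pb, rng,
                                                            n_mc=40_000)
                assert abs(exact - mc) <= max(3 * se, 1e-9)


class TestFunctional:
    def test_identical_sets_zero(self):
        sp = _space(SQUARE, list("abcd"))
        p = cp.functional_beta_pair(sp, {"a", "b", "c"}, {"a", "b", "c"}, k=2)
        assert p.as_tuple() == (0.0, 0.0, 0.0)

    def test_half_overlapping_squares_partition(self):
        pts = np.vstack([SQUARE, SQUARE + [0.5, 0.0]])
        ids = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        sp = _space(pts, ids)
        p = cp.functional_beta_pair(sp, {f"a{i}" for i in range(4)},
                                    {f"b{i}" for i in range(4)}, k=2)
        assert p.beta_sor == pytest.approx(0.5)
        assert p.beta_sim == pytest.approx(0.5)
        assert p.beta_sne == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_squares_full_turnover(self):
        pts = np.vstack([SQUARE, SQUARE + [5.0, 0.0]])
        ids = [f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)]
        sp = _space(pts, ids)
        p = cp.functional_beta_pair(sp, {f"a{i}" for i in range(4)},
                                    {f"b{i}" for i in range(4)}, k=2)
        assert p.beta_sor == 1.0 and p.beta_sim == 1.0

    def test_too_few_species_for_dimension_rejected(self):
        sp = _space(SQUARE, list("abcd"))
        with pytest.raises(cp.ValidationError):
            cp.functional_beta_pair(sp, {"a", "b"}, {"c", "d"}, k=2)

    def test_degenerate_site_flagged(self):
        pts = np.array([[0, 0], [1, 1], [2, 2],
                        [0, 1], [1, 0], [0.5, 0.6]], dtype=float)
        sp = _space(pts, list("abcdef"))
        with pytest.raises(cp.DegenerateHullError):
            cp.functional_beta_pair(sp, {"a", "b", "c"}, {"d", "e", "f"}, k=2)


class TestAdditivityProperty:
    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=60, deadline=None)
    def test_taxonomic_partition_additivity_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        labels = list("ABCDEFGHIJ")
        sa = {l for l in labels if rng.random() < 0.5} or {"A"}
        sb = {l for l in labels if rng.random() < 0.5} or {"B"}
        p = cp.sorensen_partition(sa, sb)
        assert p.beta_sim + p.beta_sne == pytest.approx(p.beta_sor, abs=1e-12)
        assert 0.0 <= p.beta_sim <= p.beta_sor <= 1.0


class TestSummaries:
    def test_three_site_hand_example(self):
        parts = {("A", "B"): cp.sorensen_partition({"x"}, {"x"}),
                 ("A", "C"): cp.sorensen_partition({"x"}, {"x"}),
                 ("B", "C"): cp.sorensen_partition({"x"}, {"x"})}
        parts[("A", "B")].beta_sor = 0.2
        parts[("A", "C")].beta_sor = 0.4
        parts[("B", "C")].beta_sor = 0.6
        means, consec = cp.pairwise_beta_summaries(parts, ["A", "B", "C"])
        assert means.beta_sor.tolist() == pytest.approx([0.3, 0.4, 0.5])
        assert consec.beta_sor.tolist() == pytest.approx([0.2, 0.6])

    def test_counts_follow_transect_length(self, rng):
        tree = cp.simulate_tree(30, rng)
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        sites = [f"s{i}" for i in range(10)]
        present = {s: set(rng.choice(labels, size=12, replace=False))
                   for s in sites}
        parts = cp.pairwise_beta_matrix(
            lambda a, b: cp.phylo_beta_pair(tree, present[a], present[b]),
            sites)
        means, consec = cp.pairwise_beta_summaries(parts, sites)
        assert len(means) == 10 and len(consec) == 9

    def test_missing_pair_is_error(self):
        parts = {("A", "B"): cp.sorensen_partition({"x"}, {"y"})}
        with pytest.raises(cp.ValidationError):
            cp.pairwise_beta_summaries(parts, ["A", "B", "C"])


class TestBetaSes:
    def test_null_equal_to_observed_gives_zero_ses(self, rng):
        tree = cp.simulate_tree(10, rng)
        labels = [l.taxon.label for l in tree.leaf_node_iter()]
        a, b = set(labels[:6]), set(labels[4:])
        obs = lambda: cp.phylo_beta_pair(tree, a, b)
        out = cp.beta_ses(obs, lambda r: obs(), n_null=20, rng=rng)
        assert all(res.ses == 0.0 and res.degenerate
                   for res in out.values())

    def test_identical_sites_ses_nonpositive(self, rng):
        tree = cp.simulate_tree(10, rng)
        labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
        a = set(labels[:6])
        obs = lambda: cp.phylo_beta_pair(tree, a, a)
        null = lambda r: cp.phylo_beta_pair(
            cp.shuffle_tip_labels(tree, labels, r), a, set(labels[3:9]))
        out = cp.beta_ses(obs, null, n_null=30, rng=rng)
        assert out["beta_sor"].observed == 0.0
        assert out["beta_sor"].ses <= 0.0
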