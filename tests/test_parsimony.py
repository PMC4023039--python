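"""Wagner length, searches, homoplasy statistics, node distances."""

import itertools

import numpy as np
import pytest

from conftest import random_matrix
from retrodict.coding import ANCESTOR_LABEL, CharacterMatrix, attach_ancestor
from retrodict.parsimony import (
    FitStats,
    ParsimonyError,
    all_rooted_trees,
    branch_and_bound,
    exhaustive_search,
    fit_stats,
    g1_statistic,
    heuristic_search,
    leaves,
    node_distances,
    random_rooted_tree,
    reroot_at_leaf,
    robinson_foulds,
    sankoff_length,
    strict_consensus,
    to_newick,
    tree_length_distribution,
    wagner_length,
)


def brute_force_length(tree, m: CharacterMatrix) -> int:
    """Oracle: minimize over all explicit internal-node labelings."""
    rows = {t: m.states[i] for i, t in enumerate(m.taxa)}

    def internals(t):
        return 0 if isinstance(t, str) else 1 + internals(t[0]) + internals(t[1])

    ni = internals(tree)
    total = 0
    for c in range(m.states.shape[1]):
        col = {t: int(rows[t][c]) for t in m.taxa}
        best = None
        for lab in itertools.product(range(m.k), repeat=ni):
            it = iter(lab)

            def cost(t):
                if isinstance(t, str):
                    return col[t], 0
                s1, c1 = cost(t[0])
                s2, c2 = cost(t[1])
                mine = next(it)
                return mine, c1 + c2 + abs(mine - s1) + abs(mine - s2)

            _, steps = cost(tree)
            best = steps if best is None else min(best, steps)
        total += best
    return total


class TestWagnerLength:
    def test_two_taxa_ordered_cost(self):
        m = CharacterMatrix(
            taxa=("A", "B"), characters=("c",), states=np.array([[0], [2]]), k=3
        )
        assert wagner_length(("A", "B"), m) == 2

    def test_clean_split_costs_one_step(self):
        m = CharacterMatrix(
            taxa=("A", "B", "C", "D"),
            characters=("c",),
            states=np.array([[0], [0], [2], [2]]),
            k=3,
        )
        assert wagner_length((("A", "B"), ("C", "D")), m) == 2
        assert brute_force_length((("A", "B"), ("C", "D")), m) == 2

    def test_identical_rows_zero_length(self):
        m = CharacterMatrix(
            taxa=("A", "B", "C"),
            characters=("c1", "c2"),
            states=np.array([[1, 3], [1, 3], [1, 3]]),
            k=5,
        )
        assert wagner_length((("A", "B"), "C"), m) == 0

    def test_taxon_mismatch_rejected(self):
        m = CharacterMatrix(
            taxa=("A", "B"), characters=("c",), states=np.array([[0], [1]]), k=2
        )
        with pytest.raises(ParsimonyError):
            wagner_length(("A", "X"), m)

    def test_matches_brute_force_and_sankoff(self, rng):
        # the core oracle-equivalence sweep: random trees and small matrices
        for _ in range(200):
            nt = int(rng.integers(2, 7))
            k = int(rng.integers(2, 5))
            nc = int(rng.integers(1, 4))
            m = random_matrix(rng, nt, nc, k)
            tree = random_rooted_tree(list(m.taxa), rng)
            w = wagner_length(tree, m)
            assert w == sankoff_length(tree, m)
            assert w == brute_force_length(tree, m)

    def test_relabeling_preserves_length(self, rng):
        m = random_matrix(rng, 6, 5, 4)
        tree = random_rooted_tree(list(m.taxa), rng)
        perm = list(rng.permutation(m.taxa))
        relabel = dict(zip(m.taxa, perm))

        def rl(t):
            return relabel[t] if isinstance(t, str) else (rl(t[0]), rl(t[1]))

        rows = {relabel[t]: m.states[i] for i, t in enumerate(m.taxa)}
        m2 = CharacterMatrix(
            taxa=m.taxa,
            characters=m.characters,
            states=np.array([rows[t] for t in m.taxa]),
            k=m.k,
        )
        assert wagner_length(tree, m) == wagner_length(rl(tree), m2)


class TestSearches:
    def test_exhaustive_finds_perfect_tree(self):
        # perfectly nested additive matrix: unique optimum with CI = 1
        states = np.array(
            [[0, 0, 0], [1, 0, 0], [1, 1, 0], [1, 1, 1], [1, 1, 2]]
        )
        m = CharacterMatrix(
            taxa=("A", "B", "C", "D", "E"),
            characters=("c1", "c2", "c3"),
            states=states,
            k=3,
        )
        res = exhaustive_search(m)
        st = fit_stats(res.best, m, compute_g1=False)
        assert st.CI == 1.0 and st.RI == 1.0 and st.RC == 1.0
        assert res.length == 4  # sum of character ranges: 1 + 1 + 2

    def test_two_taxa_single_topology(self):
        m = CharacterMatrix(
            taxa=("A", "B"), characters=("c",), states=np.array([[0], [3]]), k=4
        )
        res = exhaustive_search(m)
        assert res.length == 3 and len(res.trees) == 1

    def test_exhaustive_refuses_large(self, rng):
        m = random_matrix(rng, 10, 2, 3)
        with pytest.raises(ParsimonyError, match="branch_and_bound"):
            exhaustive_search(m)

    def test_branch_and_bound_equals_exhaustive(self, rng):
        for _ in range(15):
            m = random_matrix(rng, 7, int(rng.integers(3, 10)), int(rng.integers(2, 7)))
            assert branch_and_bound(m).length == exhaustive_search(m).length

    def test_branch_and_bound_with_ancestor(self, rng):
        m = attach_ancestor(
            random_matrix(rng, 6, 6, 4), polarity={f"c{j}": 0 for j in range(6)}
        )
        bb, ex = branch_and_bound(m), exhaustive_search(m)
        assert bb.length == ex.length
        assert all(t[0] == ANCESTOR_LABEL for t in bb.trees)

    def test_heuristic_deterministic_and_bounded(self, rng):
        m = random_matrix(rng, 9, 8, 5)
        a = heuristic_search(m, seed=42, restarts=5)
        b = heuristic_search(m, seed=42, restarts=5)
        assert a.length == b.length
        assert [to_newick(t) for t in a.trees] == [to_newick(t) for t in b.trees]
        assert a.length >= branch_and_bound(m).length

    def test_heuristic_finds_optimum_usually(self, rng):
        hits = 0
        trials = 25
        for i in range(trials):
            m = random_matrix(rng, 7, 8, 5)
            ex = exhaustive_search(m)
            h = heuristic_search(m, seed=i, restarts=10)
            hits += h.length == ex.length
        assert hits >= 0.9 * trials

    def test_single_taxon_plus_ancestor(self):
        m = CharacterMatrix(
            taxa=("A", ANCESTOR_LABEL),
            characters=("c1", "c2"),
            states=np.array([[3, 1], [0, 0]]),
            k=4,
        )
        res = heuristic_search(m, seed=0)
        assert res.length == 4


class TestFitStats:
    def test_rc_is_product_of_ci_and_ri(self, rng):
        m = random_matrix(rng, 6, 6, 5)
        tree = random_rooted_tree(list(m.taxa), rng)
        st = fit_stats(tree, m, compute_g1=False)
        assert st.RC == pytest.approx(st.CI * st.RI, abs=1e-15)
        assert 0 < st.CI <= 1

    def test_g1_matches_full_enumeration_skewness(self):
        from scipy import stats as sps

        m = CharacterMatrix(
            taxa=("A", "B", "C", "D", "E"),
            characters=("c",),
            states=np.array([[0], [0], [1], [1], [1]]),
            k=2,
        )
        lengths = tree_length_distribution(m)
        assert len(lengths) == 105  # all rooted topologies on 5 taxa
        rows = {t: m.states[i] for i, t in enumerate(m.taxa)}
        expect = sps.skew(
            [wagner_length(t, m) for t in all_rooted_trees(sorted(m.taxa))], bias=False
        )
        assert g1_statistic(lengths) == pytest.approx(expect)

    def test_g1_zero_for_symmetric_distribution(self):
        assert g1_statistic(np.array([1.0, 2.0, 3.0, 3.0, 2.0, 1.0, 2.0, 2.0])) == 0.0

    def test_g1_undefined_for_flat_distribution(self):
        assert g1_statistic(np.array([4.0, 4.0, 4.0, 4.0])) is None

    def test_g1_sampled_symmetric_near_zero(self, rng):
        # two-taxon matrices have a single topology per shape; engineer a
        # symmetric length distribution via balanced binary characters
        m = CharacterMatrix(
            taxa=("A", "B", "C", "D"),
            characters=("c1", "c2", "c3"),
            states=np.array([[0, 0, 1], [1, 1, 0], [0, 1, 0], [1, 0, 1]]),
            k=2,
        )
        lengths = tree_length_distribution(m)
        g1 = g1_statistic(lengths)
        assert abs(g1) < 0.5  # near-symmetric by construction


class TestNodeDistances:
    def test_root_cherry(self):
        nd = node_distances(("A", "B"), exclude=())
        assert nd["nd"] == {"A": 1, "B": 1}
        assert nd["relative_age"] == {"A": 0.0, "B": 0.0}

    def test_caterpillar(self):
        nd = node_distances(((("A", "B"), "C"), "D"), exclude=())
        assert nd["nd"] == {"A": 3, "B": 3, "C": 2, "D": 1}
        assert nd["relative_age"]["D"] == pytest.approx(2 / 3)
        assert nd["relative_age"]["C"] == pytest.approx(1 / 3)

    def test_ancestor_excluded_from_nd_max(self):
        t = (ANCESTOR_LABEL, (("A", "B"), "C"))
        nd = node_distances(t)
        assert ANCESTOR_LABEL not in nd["nd"]
        assert nd["nd_max"] == 3  # A and B, not ANC

    def test_unrooted_leaf_input_rejected(self):
        with pytest.raises(ParsimonyError):
            node_distances("A")


class TestTreeUtils:
    def test_rooted_tree_count(self):
        assert sum(1 for _ in all_rooted_trees(list("ABCD"))) == 15
        assert sum(1 for _ in all_rooted_trees(list("ABCDE"))) == 105

    def test_rf_matches_dendropy(self, rng):
        import dendropy

        for _ in range(10):
            taxa = [f"t{i}" for i in range(8)]
            t1 = random_rooted_tree(taxa, rng)
            t2 = random_rooted_tree(taxa, rng)
            tns = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(data=to_newick(t1), schema="newick", taxon_namespace=tns)
            d2 = dendropy.Tree.get(data=to_newick(t2), schema="newick", taxon_namespace=tns)
            d1.encode_bipartitions()
            d2.encode_bipartitions()
            rf = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
            assert robinson_foulds(t1, t2, normalized=False) == rf

    def test_reroot_preserves_unrooted_topology(self, rng):
        taxa = [f"t{i}" for i in range(7)]
        t = random_rooted_tree(taxa, rng)
        for leaf in taxa:
            r = reroot_at_leaf(t, leaf)
            assert r[0] == leaf
            assert robinson_foulds(t, r) == 0.0

    def test_strict_consensus_collapses_conflicts(self):
        t1 = ((("A", "B"), "C"), "D")
        t2 = ((("A", "C"), "B"), "D")
        cons = strict_consensus([t1, t2])
        assert sorted(leaves(cons)) == ["A", "B", "C", "D"]
        assert to_newick(cons) == "((A,B,C),D);"
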