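"""Determinism and ground-truth fidelity of the synthetic generators."""

import numpy as np
import pytest

from retrodict.coding import attach_ancestor
from retrodict.parsimony import (
    branch_and_bound,
    heuristic_search,
    leaves,
    node_distances,
    robinson_foulds,
    to_newick,
)
from retrodict.structure import decompose_cloverleaf, parse_dotbracket
from retrodict.synthetic import (
    SCAFFOLD_STRUCTURE,
    SimulationConfig,
    evolve_trna_family,
    scaffold_structure,
    simulate_character_drift,
    simulate_domain_census,
    simulate_reference_tree,
)


class TestReferenceTree:
    def test_two_taxa_single_cherry(self):
        assert to_newick(simulate_reference_tree(2, seed=0)) == "(T001,T002);"

    def test_deterministic_per_seed(self):
        a = to_newick(simulate_reference_tree(30, seed=7))
        b = to_newick(simulate_reference_tree(30, seed=7))
        c = to_newick(simulate_reference_tree(30, seed=8))
        assert a == b and a != c

    def test_internal_node_count(self):
        def internals(t):
            return 0 if isinstance(t, str) else 1 + sum(internals(c) for c in t)

        t = simulate_reference_tree(571, seed=1)
        assert len(leaves(t)) == 571
        assert internals(t) == 570

    def test_too_few_taxa_rejected(self):
        with pytest.raises(ValueError):
            simulate_reference_tree(1, seed=0)


class TestFamilyEvolution:
    def test_zero_mutation_rate_returns_scaffold_everywhere(self):
        tree = simulate_reference_tree(6, seed=3)
        cfg = SimulationConfig(n_taxa=6, seed=3, substitution_prob=0.0)
        seqs = evolve_trna_family(tree, cfg)
        assert set(seqs.values()) == {scaffold_structure().sequence}

    def test_fully_compensatory_leaves_keep_all_arms(self):
        tree = simulate_reference_tree(8, seed=4)
        cfg = SimulationConfig(
            n_taxa=8, seed=4, substitution_prob=0.15, compensatory_prob=1.0
        )
        for name, seq in evolve_trna_family(tree, cfg).items():
            s = parse_dotbracket(seq, SCAFFOLD_STRUCTURE, name=name)
            sub = decompose_cloverleaf(s)
            assert all(
                sub.present[r] for r in ("acceptor", "d_arm", "anticodon_arm", "t_arm")
            )

    def test_deterministic_given_seed(self):
        tree = simulate_reference_tree(5, seed=9)
        cfg = SimulationConfig(n_taxa=5, seed=9)
        assert evolve_trna_family(tree, cfg) == evolve_trna_family(tree, cfg)


class TestCharacterDrift:
    def test_states_bounded_and_polarized(self):
        tree = simulate_reference_tree(8, seed=5)
        m = simulate_character_drift(tree, SimulationConfig(n_taxa=8, seed=5))
        assert m.states.min() >= 0 and m.states.max() <= m.k - 1
        assert set(m.polarity.values()) == {0}

    def test_recovery_of_known_topology_and_root(self):
        # the headline recovery experiment: low-noise accretion-drift
        # characters must let parsimony re-derive tree and root
        rfs, roots = [], 0
        n_rep = 10
        for seed in range(n_rep):
            tree = simulate_reference_tree(8, seed=seed)
            cfg = SimulationConfig(n_taxa=8, seed=seed + 1000)
            m = attach_ancestor(simulate_character_drift(tree, cfg))
            res = branch_and_bound(m, seed=seed)
            ingroup = res.best[1]
            rfs.append(robinson_foulds(ingroup, tree))
            rs = lambda t: frozenset(frozenset(leaves(c)) for c in t)
            roots += rs(ingroup) == rs(tree)
        assert np.mean(rfs) <= 0.2
        assert roots >= 0.8 * n_rep


class TestDomainCensus:
    def test_root_birth_present_everywhere(self):
        tree = simulate_reference_tree(12, seed=6)
        cfg = SimulationConfig(n_taxa=12, seed=6, birth_prob=0.0)
        truth = simulate_domain_census(tree, cfg)
        # birth only at the (forced) root: no zeros anywhere
        assert truth.census.shape[0] == 1
        assert (truth.census.to_numpy() > 0).all()

    def test_growth_factor_one_no_noise_constant_abundance(self):
        tree = simulate_reference_tree(10, seed=7)
        cfg = SimulationConfig(
            n_taxa=10, seed=7, birth_prob=0.0, growth_factor=1.0, noise_sigma=0.0
        )
        truth = simulate_domain_census(tree, cfg)
        assert set(truth.census.to_numpy().ravel()) == {1}

    def test_true_ages_decrease_with_birth_order(self):
        tree = simulate_reference_tree(15, seed=8)
        truth = simulate_domain_census(tree, SimulationConfig(n_taxa=15, seed=8))
        ordered = sorted(truth.birth_order, key=truth.birth_order.get)
        ages = [truth.ages[d] for d in ordered]
        assert ages[0] == max(ages)  # root-born domain oldest

    def test_root_domain_most_basal_in_reconstructed_tod(self):
        from retrodict.coding import code_abundance

        hits = 0
        n_rep = 10
        for seed in range(n_rep):
            tree = simulate_reference_tree(20, seed=seed)
            cfg = SimulationConfig(n_taxa=20, seed=seed + 2000)
            truth = simulate_domain_census(tree, cfg)
            if truth.census.shape[0] < 4:
                hits += 1  # degenerate census: nothing to rank
                continue
            m = attach_ancestor(code_abundance(truth.census, k=24))
            res = heuristic_search(m, seed=seed, restarts=5)
            nd = node_distances(res.best)["nd"]
            root_domain = next(
                d for d, o in truth.birth_order.items() if o == 0
            )
            hits += nd[root_domain] == min(nd.values())
        assert hits >= 0.8 * n_rep

    def test_faithful_interaction_map_resolves(self):
        tree = simulate_reference_tree(10, seed=11)
        truth = simulate_domain_census(tree, SimulationConfig(n_taxa=10, seed=11))
        for rec in truth.interactions:
            assert rec.domain in truth.ages

    def test_byte_identical_reruns(self):
        tree = simulate_reference_tree(10, seed=12)
        cfg = SimulationConfig(n_taxa=10, seed=12)
        a = simulate_domain_census(tree, cfg)
        b = simulate_domain_census(tree, cfg)
        assert a.census.equals(b.census) and a.ages == b.ages
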