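"""The species-mapping DP against brute force and its structural invariants."""

import random

import pytest

from dtlor import EventCosts, parse_newick
from dtlor.oracle import enumerate_valid_species_maps
from dtlor.species_dp import INF, compute_species_tables, species_opt
from dtlor.exceptions import NotBinaryError
from dtlor.model import Reconciliation, score_reconciliation
from dtlor.synthgen import GeneratorConfig, random_instance
from conftest import make_instance


def dtl_only_opt(instance, g):
    """Brute-force min cost of a species map of G(g), all vertices inside S.

    Scores through the event-inference path with a uniform synteny labeling
    and subtracts nothing: origins/rearrangements are excluded by scoring
    with O=R=0 and a single region.
    """
    G, S = instance.gene_tree, instance.species_tree
    sub_vertices = set(G.subtree(g))
    best = None
    costs = EventCosts(
        instance.costs.duplication,
        instance.costs.transfer,
        instance.costs.loss,
        0,
        0,
    )
    for Phi in enumerate_valid_species_maps(G, S, instance.assoc.phi):
        if any(Phi[v] is None for v in sub_vertices):
            continue
        # restrict to the subtree: treat g as its own root
        total = 0
        from dtlor.model import classify_vertex_event, infer_losses

        for v in sub_vertices:
            s = Phi[v]
            if not G.is_leaf(v):
                kind = classify_vertex_event(S, G, v, Phi)
                if kind == "duplication":
                    total += costs.duplication
                elif kind == "transfer":
                    total += costs.transfer
            if v != g:
                total += costs.loss * len(infer_losses(S, G, v, Phi))
        if best is None or total < best:
            best = total
    return best


class TestBaseCases:
    def test_leaf_on_matching_species_leaf_is_free(self, three_leaf_iso):
        t = compute_species_tables(three_leaf_iso)
        assert t.C("ga", "a") == 0
        assert t.terminate_cost("ga", "a") == 0

    def test_leaf_on_other_species_leaf_impossible(self, three_leaf_iso):
        t = compute_species_tables(three_leaf_iso)
        assert t.C("ga", "b") == INF

    def test_isomorphic_instance_costs_nothing(self, three_leaf_iso):
        t = compute_species_tables(three_leaf_iso)
        assert species_opt(t, "v") == 0
        assert t.C("v", "r") == 0

    def test_multifurcation_redirected(self, trifurcation):
        with pytest.raises(NotBinaryError):
            compute_species_tables(trifurcation)


class TestDerivedExamples:
    def test_two_leaf_gene_tree_speciation_with_loss_or_transfer(self):
        inst = make_instance(
            "((a,b)x,c)r;",
            "(ga,gc)u;",
            {"ga": "a", "gc": "c"},
            {"ga": 1, "gc": 1},
            EventCosts(1, 1, 1, 2, 2),
        )
        t = compute_species_tables(inst)
        assert species_opt(t, "u") == 1
        assert dtl_only_opt(inst, "u") == 1

    def test_cherry_duplication_on_one_leaf(self, cherry_duplication):
        t = compute_species_tables(cherry_duplication)
        assert species_opt(t, "u") == 1  # one duplication at a
        assert dtl_only_opt(cherry_duplication, "u") == 1


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(40))
    def test_root_value_matches_brute_force(self, seed):
        rng = random.Random(seed)
        cfg = GeneratorConfig(
            seed=seed,
            species_leaves=rng.randint(2, 4),
            gene_leaves=rng.randint(2, 4),
            synteny_labels=1,
            costs=EventCosts(
                rng.randint(0, 3), rng.randint(0, 3), rng.randint(0, 3), 1, 1
            ),
        )
        inst = random_instance(cfg)
        t = compute_species_tables(inst)
        assert species_opt(t, inst.gene_tree.root) == dtl_only_opt(
            inst, inst.gene_tree.root
        )


class TestInvariants:
    def instance(self, seed):
        return random_instance(GeneratorConfig(seed=seed, species_leaves=4,
                                               gene_leaves=4, synteny_labels=1))

    @pytest.mark.parametrize("seed", range(10))
    def test_best_entry_and_transfer_structure(self, seed):
        inst = self.instance(seed)
        t = compute_species_tables(inst)
        S = inst.species_tree
        for g in inst.gene_tree.postorder:
            for s in S.postorder:
                assert t.BestEntry(g, s) <= t.C(g, s)
                if S.is_leaf(s):
                    assert t.BestEntry(g, s) == t.C(g, s)
                assert species_opt(t, g) <= t.C(g, s)
            # nothing is incomparable to the handle
            assert t.BestTransfer(g, S.root) == INF
            for s in S.postorder:
                p = S.parent(s)
                if p is not None:
                    assert t.BestTransfer(g, s) <= t.BestTransfer(g, p)

    @pytest.mark.parametrize("seed", range(10))
    def test_best_transfer_is_min_over_incomparable(self, seed):
        inst = self.instance(seed)
        t = compute_species_tables(inst)
        S = inst.species_tree
        for g in inst.gene_tree.postorder:
            for s in S.postorder:
                incomp = [
                    t.C(g, u) for u in S.postorder if not S.are_comparable(s, u)
                ]
                expected = min(incomp) if incomp else INF
                assert t.BestTransfer(g, s) == expected

    def test_opt_monotone_in_costs(self):
        base = GeneratorConfig(seed=5, species_leaves=4, gene_leaves=5,
                               synteny_labels=1)
        inst = random_instance(base)
        ref = species_opt(compute_species_tables(inst), inst.gene_tree.root)
        for bump in [EventCosts(3, 1, 1, 2, 2), EventCosts(1, 3, 1, 2, 2),
                     EventCosts(1, 1, 3, 2, 2)]:
            inst2 = make_instance(
                inst.species_tree.to_newick(), inst.gene_tree.to_newick(),
                inst.assoc.phi, inst.assoc.gamma, bump,
            )
            assert species_opt(compute_species_tables(inst2),
                               inst2.gene_tree.root) >= ref
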