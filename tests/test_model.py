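"""Event semantics: classification, loss inference, origins/rearrangements,
scoring and constraint validation."""

import random

import pytest

from dtlor import (
    EventCosts,
    Instance,
    LeafAssociation,
    Reconciliation,
    parse_newick,
    score_reconciliation,
    validate_reconciliation,
)
from dtlor.model import (
    DUPLICATION,
    SPECIATION,
    TRANSFER,
    classify_vertex_event,
    event_counts,
    infer_losses,
    infer_or_events,
)
from dtlor.oracle import brute_force_opt, enumerate_valid_species_maps
from conftest import make_instance

S3 = "((a,b)x,c)r;"


def cherry(phi_a, phi_b, phi_root):
    """A two-leaf gene tree with an explicit species map."""
    G = parse_newick("(g1,g2)u;")
    S = parse_newick(S3)
    Phi = {"g1": phi_a, "g2": phi_b, "u": phi_root}
    return S, G, Phi


class TestClassification:
    @pytest.mark.parametrize(
        "images,expected",
        [
            (("a", "b", "x"), SPECIATION),
            (("a", "a", "a"), DUPLICATION),
            (("a", "x", "x"), DUPLICATION),  # child at the vertex itself
            (("a", "c", "x"), TRANSFER),
            (("a", "c", "a"), TRANSFER),
            (("x", "c", "r"), SPECIATION),
            (("a", "b", "r"), DUPLICATION),  # both in the left subtree of r
        ],
    )
    def test_kinds(self, images, expected):
        S, G, Phi = cherry(*images)
        assert classify_vertex_event(S, G, "u", Phi) == expected

    def test_outside_vertex_induces_nothing(self):
        S, G, Phi = cherry("a", "b", None)
        assert classify_vertex_event(S, G, "u", Phi) is None

    def test_exactly_one_kind_on_random_valid_maps(self):
        """Speciation/duplication/transfer are exhaustive and exclusive."""
        rng = random.Random(7)
        S = parse_newick("(((a,b)x,c)y,d)r;")
        G = parse_newick("((g1,g2)u,(g3,g4)w)v;")
        phi = {g: rng.choice(list(S.leaves)) for g in G.leaves}
        maps = enumerate_valid_species_maps(G, S, phi)
        assert maps
        for Phi in maps:
            for g in ("u", "w", "v"):
                if Phi[g] is not None:
                    kind = classify_vertex_event(S, G, g, Phi)
                    assert kind in (SPECIATION, DUPLICATION, TRANSFER)


class TestLosses:
    def test_speciating_parent_excludes_top_vertex(self):
        S, G, Phi = cherry("a", "c", "r")  # speciation at r
        assert infer_losses(S, G, "g1", Phi) == ["x"]
        assert infer_losses(S, G, "g2", Phi) == []

    def test_duplicating_parent_loses_at_top_vertex(self):
        S, G, Phi = cherry("a", "a", "r")  # duplication at r
        assert infer_losses(S, G, "g1", Phi) == ["r", "x"]

    def test_entry_from_outside_has_no_path(self):
        S, G, Phi = cherry("a", "b", None)
        assert infer_losses(S, G, "g1", Phi) == []

    def test_transfer_recipient_has_no_losses(self):
        S, G, Phi = cherry("a", "c", "a")  # g2 lands incomparably on c
        assert infer_losses(S, G, "g2", Phi) == []
        assert infer_losses(S, G, "g1", Phi) == []


class TestOriginRearrangement:
    G = parse_newick("((ga,gb)u,gc)v;")

    def events(self, Gamma):
        return infer_or_events(self.G, Gamma)

    def test_uniform_labels_one_root_origin(self):
        evs = self.events(dict.fromkeys(["ga", "gb", "gc", "u", "v"], 1))
        assert [e.kind for e in evs].count("origin") == 1
        assert all(e.kind == "origin" for e in evs)

    def test_star_root_two_origins(self):
        Gamma = {"v": None, "u": 1, "ga": 1, "gb": 1, "gc": 2}
        evs = self.events(Gamma)
        kinds = sorted(e.kind for e in evs)
        assert kinds == ["origin", "origin"]

    def test_label_change_is_rearrangement(self):
        Gamma = {"v": 1, "u": 1, "ga": 1, "gb": 1, "gc": 2}
        evs = self.events(Gamma)
        kinds = sorted(e.kind for e in evs)
        assert kinds == ["origin", "rearrangement"]
        rearr = next(e for e in evs if e.kind == "rearrangement")
        assert rearr.synteny == (1, 2)


class TestScoreAndValidate:
    def test_isomorphic_case_scores_one_origin(self, three_leaf_iso):
        inst = three_leaf_iso
        rec = Reconciliation(
            inst.gene_tree,
            inst.species_tree,
            {"ga": "a", "gb": "b", "gc": "c", "u": "x", "v": "r"},
            dict.fromkeys(["ga", "gb", "gc", "u", "v"], 1),
        )
        assert validate_reconciliation(rec, inst) == []
        assert score_reconciliation(rec, inst.costs) == 2
        assert brute_force_opt(inst).cost == 2

    def test_cherry_duplication_scores_origin_plus_dup(self, cherry_duplication):
        inst = cherry_duplication
        rec = Reconciliation(
            inst.gene_tree,
            inst.species_tree,
            {"g1": "a", "g2": "a", "u": "a"},
            dict.fromkeys(["g1", "g2", "u"], 1),
        )
        assert validate_reconciliation(rec, inst) == []
        assert score_reconciliation(rec, inst.costs) == 3  # O + D
        assert brute_force_opt(inst).cost == 3

    def test_scoring_is_linear_in_each_cost(self, cherry_duplication):
        inst = cherry_duplication
        rec = Reconciliation(
            inst.gene_tree,
            inst.species_tree,
            {"g1": "a", "g2": "a", "u": "r"},
            dict.fromkeys(["g1", "g2", "u"], 1),
        )
        # duplication at r, both children pass r and x: 4 losses, 1 origin
        base = score_reconciliation(rec, EventCosts(1, 1, 1, 2, 2))
        double_d = score_reconciliation(rec, EventCosts(2, 1, 1, 2, 2))
        double_l = score_reconciliation(rec, EventCosts(1, 1, 2, 2, 2))
        counts = event_counts(rec.events())
        assert double_d - base == counts["duplication"]
        assert double_l - base == counts["loss"]

    def test_child_mapped_to_ancestor_reported(self, three_leaf_iso):
        inst = three_leaf_iso
        rec = Reconciliation(
            inst.gene_tree,
            inst.species_tree,
            {"ga": "a", "gb": "b", "gc": "c", "u": "a", "v": "r"},
            dict.fromkeys(["ga", "gb", "gc", "u", "v"], 1),
        )
        # u's child gb maps to b, incomparable with a: transfer is fine;
        # break it harder: map u below its own child image's ancestor
        rec.species_map["u"] = "b"
        rec.species_map["ga"] = "a"
        # ga's image a is incomparable to b: still a transfer; force 2b:
        rec.species_map["v"] = "a"
        out = validate_reconciliation(rec, inst)
        assert any("2" in msg for msg in out)

    def test_all_outside_invalid_when_leaves_exist(self, three_leaf_iso):
        inst = three_leaf_iso
        rec = Reconciliation(
            inst.gene_tree,
            inst.species_tree,
            dict.fromkeys(["ga", "gb", "gc", "u", "v"]),
            dict.fromkeys(["ga", "gb", "gc", "u", "v"]),
        )
        out = validate_reconciliation(rec, inst)
        assert out  # leaves must follow phi/gamma

    def test_actual_parent_with_star_child_reported(self, three_leaf_iso):
        inst = three_leaf_iso
        rec = Reconciliation(
            inst.gene_tree,
            inst.species_tree,
            {"ga": "a", "gb": "b", "gc": "c", "u": None, "v": "r"},
            {"ga": 1, "gb": 1, "gc": 1, "u": None, "v": 1},
        )
        out = validate_reconciliation(rec, inst)
        assert any("child" in msg and "*" in msg for msg in out) or any(
            "2a" in msg for msg in out
        )

    def test_negative_costs_rejected(self):
        with pytest.raises(Exception):
            EventCosts(-1, 1, 1, 2, 2)
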