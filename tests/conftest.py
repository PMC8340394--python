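"""Shared fixtures: tiny hand-built instances used throughout the suite."""

import pytest

from dtlor import EventCosts, Instance, LeafAssociation, parse_newick

DEFAULT_COSTS = EventCosts(1, 1, 1, 2, 2)


def make_instance(s_nwk, g_nwk, phi, gamma, costs=DEFAULT_COSTS):
    S = parse_newick(s_nwk)
    G = parse_newick(g_nwk)
    return Instance(S, G, LeafAssociation(phi=phi, gamma=gamma), costs)


@pytest.fixture
def three_leaf_iso():
    """Gene tree congruent with the species tree, uniform synteny: Opt = O."""
    return make_instance(
        "((a,b)x,c)r;",
        "((ga,gb)u,gc)v;",
        {"ga": "a", "gb": "b", "gc": "c"},
        {"ga": 1, "gb": 1, "gc": 1},
    )


@pytest.fixture
def three_leaf_split_synteny():
    """Same trees, one gene leaf in a second region: origin/rearrangement tension."""
    return make_instance(
        "((a,b)x,c)r;",
        "((ga,gb)u,gc)v;",
        {"ga": "a", "gb": "b", "gc": "c"},
        {"ga": 1, "gb": 1, "gc": 2},
    )


@pytest.fixture
def cherry_duplication():
    """Both gene leaves on one species leaf: one duplication under one origin."""
    return make_instance(
        "((a,b)x,c)r;",
        "(g1,g2)u;",
        {"g1": "a", "g2": "a"},
        {"g1": 1, "g2": 1},
    )


@pytest.fixture
def trifurcation():
    """Soft polytomy whose best resolution mirrors the species tree."""
    return make_instance(
        "((s1,s2)x,s3)r;",
        "(g1,g2,g3)v;",
        {"g1": "s1", "g2": "s2", "g3": "s3"},
        {"g1": 1, "g2": 1, "g3": 1},
    )
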