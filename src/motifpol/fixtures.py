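"""Small reconstructed example systems used in docs and tests.

These fixtures are synthetic reconstructions: the worked examples they
emulate are described at caption level (species counts, qualitative
topology, printed distances or outcomes), not as full edge tables, so the
topologies here are rebuilt to satisfy exactly those described properties.
Asserted expectations are limited to the printed quantities.
"""

from __future__ import annotations

import pandas as pd

from .logic import LogicRule, SimplifiedModel
from .network import InteractionNetwork, SpeciesNode, PLANT, POLLINATOR


def _or_rule(target: str, positives: list[str]) -> LogicRule:
    return LogicRule(target, frozenset(
        frozenset([(p, True)]) for p in positives))


def _model_from_positive_rules(positives: dict[str, list[str]]) -> SimplifiedModel:
    """Simplified model whose ON rules are plain ORs of benefactors.

    The companion interaction network carries the reciprocal edge pairs
    implied by the rules (a direction is positive iff the source appears
    among the target's benefactors); trait lengths are nominal since the
    rules, not the traits, are the object of interest here.
    """
    net = InteractionNetwork()
    for s in positives:
        guild = PLANT if s.startswith("pl_") else POLLINATOR
        net.add_species(SpeciesNode(s, guild, 1.0))
    pairs = set()
    for tgt, srcs in positives.items():
        for src in srcs:
            pl, po = (tgt, src) if tgt.startswith("pl_") else (src, tgt)
            pairs.add((pl, po))
    for pl, po in sorted(pairs):
        sign_pair = (1 if po in positives[pl] else -1,
                     1 if pl in positives[po] else -1)
        net.add_interaction(pl, po, sign_pair)
    rules = {s: _or_rule(s, srcs) for s, srcs in positives.items()}
    return SimplifiedModel(network=net, rules=rules, stats={})


def mutual_pair_model() -> SimplifiedModel:
    """One mutualistic plant-pollinator pair; two attractors (both on/off)."""
    return _model_from_positive_rules({"pl_1": ["po_1"], "po_1": ["pl_1"]})


def expanded_example_model() -> SimplifiedModel:
    """Six-species simplified community for expanded-network walk-throughs.

    Reconstructed so that its expanded network has twelve virtual nodes and
    four composite nodes, an all-inactive stable motif spanning the whole
    community with {~po_1, ~po_2, ~po_3} among its driver sets, and a
    two-species sub-community motif {pl_2, po_2} driven by either member.
    """
    return _model_from_positive_rules({
        "pl_1": ["po_1"],
        "pl_2": ["po_1", "po_2"],
        "pl_3": ["po_2", "po_3"],
        "po_1": ["pl_1", "pl_3"],
        "po_2": ["pl_2"],
        "po_3": ["pl_2", "pl_3"],
    })


def generalist_collapse_model() -> SimplifiedModel:
    """Six-species community whose generalist plant is a one-node driver.

    pl_2 survives on either of two pollinators; its extinction drives the
    all-inactive motif and the whole community collapses.
    """
    return _model_from_positive_rules({
        "pl_1": ["po_1"],
        "pl_2": ["po_1", "po_2"],
        "pl_3": ["po_2"],
        "po_1": ["pl_2"],
        "po_2": ["pl_2"],
    })


def restoration_cascade_model() -> SimplifiedModel:
    """Six-species community where restoring pl_2 rebuilds everything.

    Extinction of po_1 and po_2 cascades to full collapse; re-introducing
    the generalist plant pl_2 re-activates every species.
    """
    return _model_from_positive_rules({
        "pl_1": ["po_1"],
        "pl_2": ["po_1", "po_2", "po_3"],
        "pl_3": ["po_2"],
        "po_1": ["pl_1", "pl_2"],
        "po_2": ["pl_2", "pl_3"],
        "po_3": ["pl_3"],
    })


def ldoi_bfs_network() -> InteractionNetwork:
    """Five-plant / three-pollinator threshold network for the LDOI search.

    Reconstructed so that the breadth-first worst-case propagation from
    {~pl_1} fixes exactly seven further states:
    {~po_3, ~pl_2, ~pl_3, ~pl_4, ~pl_5, ~po_1, ~po_2}.
    """
    net = InteractionNetwork()
    traits = {"pl_1": 10.0, "pl_2": 12.0, "pl_3": 12.0, "pl_4": 12.0,
              "pl_5": 12.0, "po_1": 15.0, "po_2": 15.0, "po_3": 10.0}
    for s, t in traits.items():
        net.add_species(SpeciesNode(s, PLANT if s.startswith("pl_") else POLLINATOR, t))
    for pl, po in [("pl_1", "po_1"), ("pl_1", "po_3"), ("pl_2", "po_1"),
                   ("pl_2", "po_3"), ("pl_3", "po_2"), ("pl_3", "po_3"),
                   ("pl_4", "po_3"), ("pl_5", "po_3")]:
        net.add_interaction(pl, po)  # signs follow from the traits
    net.validate()
    return net


def fd_worked_profiles() -> pd.DataFrame:
    """Incidence block for the functional-diversity worked example.

    Four plants as rows, three pollinators as columns; the pairwise
    Euclidean column distances are d(po_1, po_2) = sqrt(3) ~ 1.73,
    d(po_1, po_3) = 1 and d(po_2, po_3) = 2, so the total single-linkage
    dendrogram branch length is ~4.46 and the po_3 root path is ~1.73.
    """
    return pd.DataFrame(
        {"po_1": [1, 1, 0, 0], "po_2": [1, 0, 1, 1], "po_3": [0, 1, 0, 0]},
        index=["pl_1", "pl_2", "pl_3", "pl_4"],
    )
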