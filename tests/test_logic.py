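"""Threshold-to-logic conversion: prime implicants, pruning, simplification."""

import itertools

import numpy as np
import pytest

from motifpol.logic import (LogicRule, activation_probability,
                            choose_retained_negative_count,
                            complete_sum_from_function,
                            drop_nonfunctional_negative_edges,
                            negated_rule, parse_expression,
                            prune_nonestablishable, read_rules, simplify_rule,
                            threshold_to_prime_implicants, write_rules)
from motifpol.network import InteractionNetwork, SpeciesNode
from motifpol.threshold import ThresholdRule


def _rule(n_pos, n_neg, target="x"):
    return ThresholdRule(target, tuple((f"p{i}", 4) for i in range(n_pos))
                         + tuple((f"n{i}", -1) for i in range(n_neg)))


def _threshold_fn(rule):
    def fn(state):
        return sum(w * state[r] for r, w in rule.regulators) > 0
    return fn


@pytest.mark.parametrize(
    "n_pos, n_neg, expected",
    [
        (3, 5, 33),  # the canonical combinatorial-explosion example
        (1, 0, 1),
        (2, 3, 2),   # up to three inhibitors never matter
        (1, 4, 4),   # each implicant silences one of the four inhibitors
    ],
)
def test_prime_implicant_counts(n_pos, n_neg, expected):
    assert len(threshold_to_prime_implicants(_rule(n_pos, n_neg)).implicants) == expected


@pytest.mark.parametrize("n_pos, n_neg", [(1, 1), (2, 4), (3, 5), (2, 6), (4, 2)])
def test_prime_implicants_match_truth_table_oracle(n_pos, n_neg):
    rule = _rule(n_pos, n_neg)
    variables = [r for r, _ in rule.regulators]
    oracle = complete_sum_from_function(variables, _threshold_fn(rule))
    assert threshold_to_prime_implicants(rule).implicants == oracle


def test_no_positive_regulator_is_constant_zero():
    assert threshold_to_prime_implicants(_rule(0, 3)).is_constant_zero


def _net(edges):
    """Build a network from (plant, pollinator, sign_to_plant, sign_to_po)."""
    net = InteractionNetwork()
    species = {s for e in edges for s in e[:2]}
    for s in sorted(species):
        guild = "plant" if s.startswith("pl_") else "pollinator"
        net.add_species(SpeciesNode(s, guild, 1.0))
    for pl, po, s_pl, s_po in edges:
        net.add_interaction(pl, po, (s_pl, s_po))
    return net


def test_prune_removes_negative_only_species():
    net = _net([("pl_1", "po_1", 1, -1)])  # pollinator never benefits
    pruned = prune_nonestablishable(net)
    # the pollinator goes, stripping the plant's only benefactor: all gone
    assert pruned.species == []


def test_prune_cascades_along_benefit_chains():
    # pl_1 receives no benefit; po_1 relies on pl_1; pl_2 relies on po_1
    net = _net([("pl_1", "po_1", -1, 1), ("pl_2", "po_1", 1, -1),
                ("pl_2", "po_2", 1, 1)])
    pruned = prune_nonestablishable(net)
    assert pruned.species == ["pl_2", "po_2"]


def test_prune_keeps_fully_benefited_network():
    net = _net([("pl_1", "po_1", 1, 1), ("pl_2", "po_1", 1, 1)])
    assert prune_nonestablishable(net).species == ["pl_1", "pl_2", "po_1"]


def test_nonfunctional_negative_edges_are_dropped():
    rules = {
        "x": threshold_to_prime_implicants(_rule(1, 3, "x")),
        "y": threshold_to_prime_implicants(_rule(1, 4, "y")),
    }
    assert rules["x"].negative_literals() == set()          # all three dropped
    assert rules["y"].negative_literals() == {f"n{i}" for i in range(4)}


def test_drop_nonfunctional_edges_keeps_reciprocal_positives():
    # po_1 benefits pl_1 but robs po-side value from three plants
    net = _net([("pl_1", "po_1", 1, 1), ("pl_2", "po_1", 1, -1),
                ("pl_3", "po_1", 1, -1), ("pl_4", "po_1", 1, -1)])
    rules = {s: threshold_to_prime_implicants(
        ThresholdRule(s, tuple(net.in_edges(s)))) for s in net.species}
    reduced = drop_nonfunctional_negative_edges(net, rules)
    # po_1 had one positive (pl_1) and three negatives: negatives all dropped
    assert all(w > 0 for _, w in reduced.in_edges("po_1"))
    # the positive partner edges po_1 -> pl_k survive
    for pl in ("pl_1", "pl_2", "pl_3", "pl_4"):
        assert reduced.graph.has_edge("po_1", pl)


def test_simplification_conserves_activation_probability():
    rule = _rule(3, 5)
    # exhaustive check of the probability the example rule activates
    states = itertools.product([0, 1], repeat=8)
    names = [r for r, _ in rule.regulators]
    p_exact = sum(_threshold_fn(rule)(dict(zip(names, bits)))
                  for bits in states) / 2 ** 8
    assert activation_probability(rule) == pytest.approx(p_exact)
    assert p_exact == pytest.approx(103 / 128)
    assert choose_retained_negative_count(rule) == 0  # (1 - 2^-3) is closest
    simplified = simplify_rule(rule, np.random.default_rng(0))
    assert len(simplified.implicants) == 3


def test_simplification_without_negatives_is_or_of_positives():
    simplified = simplify_rule(_rule(2, 0), np.random.default_rng(0))
    assert simplified.implicants == frozenset(
        [frozenset([("p0", True)]), frozenset([("p1", True)])])


def test_retained_negative_choice_is_reproducible_and_best():
    rule = _rule(1, 6)
    x = choose_retained_negative_count(rule)
    p_thr = activation_probability(rule)
    gaps = [abs(0.5 * 2.0 ** -k - p_thr) for k in range(7)]
    assert gaps[x] == min(gaps)
    a = simplify_rule(rule, np.random.default_rng(11))
    b = simplify_rule(rule, np.random.default_rng(11))
    assert a.implicants == b.implicants


def test_negation_de_morgan_and_involution():
    f = LogicRule("x", frozenset([frozenset([("p1", True)]),
                                  frozenset([("p2", True)])]))
    assert negated_rule(f).implicants == frozenset(
        [frozenset([("p1", False), ("p2", False)])])
    g = LogicRule("x", frozenset([frozenset([("p1", True), ("n1", False)]),
                                  frozenset([("p2", True), ("n1", False)])]))
    ng = negated_rule(g)
    assert ng.implicants == frozenset([
        frozenset([("p1", False), ("p2", False)]), frozenset([("n1", True)])])
    assert negated_rule(ng).implicants == g.implicants


def test_negation_matches_truth_table_oracle():
    rng = np.random.default_rng(2)
    variables = ["a", "b", "c", "d"]
    for _ in range(20):
        rule = simplify_rule(
            ThresholdRule("x", tuple((v, 4 if rng.random() < 0.6 else -1)
                                     for v in variables)),
            rng)
        if rule.is_constant_zero:
            continue
        expected = complete_sum_from_function(
            sorted(rule.variables()), lambda st: not rule.evaluate(st))
        assert negated_rule(rule).implicants == expected


def test_bnet_round_trip(tmp_path):
    rules = {
        "pl_1": LogicRule("pl_1", frozenset([
            frozenset([("po_1", True), ("po_2", False)]),
            frozenset([("po_3", True), ("po_2", False)])])),
        "po_1": LogicRule("po_1", frozenset([frozenset([("pl_1", True)])])),
        "po_2": LogicRule("po_2", frozenset()),  # constant 0: cannot establish
    }
    path = write_rules(rules, tmp_path / "rules.bnet")
    assert read_rules(path) == rules


def test_parser_matches_independent_evaluation():
    rule = parse_expression("x", "(a | b) & !c | d & !a")
    for bits in itertools.product([False, True], repeat=4):
        a, b, c, d = bits
        assert rule.evaluate({"a": a, "b": b, "c": c, "d": d}) == \
            ((a or b) and not c or (d and not a))


def test_parser_rejects_unknown_tokens(tmp_path):
    path = tmp_path / "bad.bnet"
    path.write_text("x, a % b\n")
    with pytest.raises(ValueError):
        read_rules(path)
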