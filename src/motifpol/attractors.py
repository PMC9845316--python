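"""Attractor identification and control via motif combinations.

Every autonomous trajectory of the model stabilizes a combination of stable
motifs and motif groups; each *maximal consistent combination* (no two
members sharing a species with opposite states) percolates to one minimal
trap space.  In this model class every minimal trap space fixes all
species, i.e. is a point attractor, so "attractor" and "minimal trap
space" are used interchangeably.

The attractor in which the most species establish is the *maximal richness
community*; every other attractor's established set is a subset of its
established set.  A *control set* of an attractor is a union of driver
sets, one per member of its defining combination — stabilizing it steers
the community into that attractor from any initial composition.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx

from .expanded import (ConditionallyStableMotif, ExpandedNetwork, MotifGroup,
                       StableMotif, build_expanded_network, build_motif_groups,
                       find_conditionally_stable_motifs, find_driver_sets,
                       find_stable_motifs, ldoi_expanded, vlabel)
from .logic import LogicRule, SimplifiedModel

MUTUALLY_EXCLUSIVE = "mutually_exclusive"
LDOI_CONTAINS = "ldoi_contains"


class PercolationContradictionError(RuntimeError):
    """Constant propagation derived both states for one species."""


def percolate(on_rules: Mapping[str, LogicRule],
              pinned: Mapping[str, bool]) -> dict[str, bool]:
    """Propagate fixed states through the logical rules to a fixpoint.

    A species fixes to 1 when one implicant of its ON rule is fully
    satisfied, and to 0 when every implicant is falsified.  Deriving the
    opposite of an already-fixed state raises
    :class:`PercolationContradictionError`.
    """
    assign: dict[str, bool] = dict(pinned)
    changed = True
    while changed:
        changed = False
        for s, rule in on_rules.items():
            satisfied = any(
                all(assign.get(n) == v for n, v in imp) for imp in rule.implicants)
            falsified = rule.is_constant_zero or all(
                any(n in assign and assign[n] != v for n, v in imp)
                for imp in rule.implicants)
            forced = True if satisfied else (False if falsified else None)
            if forced is None:
                continue
            if s in assign:
                if assign[s] != forced:
                    raise PercolationContradictionError(
                        f"{s} forced to {forced} against pinned {assign[s]}")
            else:
                assign[s] = forced
                changed = True
    return assign


@dataclass(frozen=True)
class Attractor:
    """A minimal trap space plus the combination that produced it.

    In the common case (no negative feedback loop) every species is fixed
    and the trap space is a point attractor.  A retained inhibitor on a
    feedback loop can leave species oscillating; those appear in ``free``
    and are recorded as not stably established in ``states``.
    """

    states: tuple[tuple[str, bool], ...]  # sorted (species, state)
    combination: tuple = ()
    free: tuple[str, ...] = ()

    @property
    def state_dict(self) -> dict[str, bool]:
        return dict(self.states)

    @property
    def active(self) -> frozenset:
        return frozenset(s for s, v in self.states if v)

    @property
    def richness(self) -> int:
        return len(self.active)

    def __repr__(self) -> str:
        return f"Attractor(active={sorted(self.active)})"


def functional_relation_graph(
    motifs: Sequence[StableMotif],
    groups: Sequence[MotifGroup],
    expnet: ExpandedNetwork,
) -> nx.DiGraph:
    """Labeled relations among stable motifs and motif groups.

    Two vertices are ``mutually_exclusive`` (symmetric) when they share a
    species with opposite states; ``ldoi_contains`` points from a vertex
    whose LDOI covers all of another's virtual nodes.
    """
    vertices = list(motifs) + list(groups)
    g = nx.DiGraph()
    g.add_nodes_from(vertices)
    ldois = {v: ldoi_expanded(expnet, v.states) for v in vertices}
    for a, b in itertools.combinations(vertices, 2):
        shared_opposite = any(((n, not v) in b.states) for n, v in a.states)
        if shared_opposite:
            g.add_edge(a, b, label=MUTUALLY_EXCLUSIVE)
            g.add_edge(b, a, label=MUTUALLY_EXCLUSIVE)
            continue
        if set(b.states) <= ldois[a]:
            g.add_edge(a, b, label=LDOI_CONTAINS)
        if set(a.states) <= ldois[b]:
            g.add_edge(b, a, label=LDOI_CONTAINS)
    return g


def maximal_consistent_combinations(relation_graph: nx.DiGraph) -> list[tuple]:
    """Maximal vertex sets free of internal mutual-exclusivity edges."""
    compat = nx.Graph()
    vertices = list(relation_graph.nodes)
    compat.add_nodes_from(vertices)
    for a, b in itertools.combinations(vertices, 2):
        d = relation_graph.get_edge_data(a, b)
        if d is None or d["label"] != MUTUALLY_EXCLUSIVE:
            compat.add_edge(a, b)
    if not vertices:
        return [()]
    return [tuple(sorted(c, key=lambda m: m.key)) for c in nx.find_cliques(compat)]


def trap_space_of_combination(
    combination: Sequence[StableMotif | MotifGroup],
    on_rules: Mapping[str, LogicRule],
) -> Attractor:
    """Percolate a consistent combination to its minimal trap space.

    In this model class the trap space fixes every species.  Species left
    untouched by the percolation can only belong to benefit cycles none of
    whose polarities was selected; the only state consistent with no
    stabilized support is extinction, and the result is verified to be a
    fixed point.
    """
    pinned: dict[str, bool] = {}
    for member in combination:
        for n, v in member.states:
            if pinned.setdefault(n, v) != v:
                raise PercolationContradictionError(f"combination conflicts on {n}")
    assign = percolate(on_rules, pinned)
    full = {s: assign.get(s, False) for s in on_rules}
    if is_fixed_point(on_rules, full):
        return Attractor(states=tuple(sorted(full.items())),
                         combination=tuple(combination))
    # species the percolation leaves undetermined sit on a negative feedback
    # loop (retained inhibitor) and oscillate: the minimal trap space leaves
    # them free and they do not count as stably established
    free = tuple(sorted(set(on_rules) - set(assign)))
    if not free:
        raise PercolationContradictionError(
            "combination did not percolate to a fixed point")
    return Attractor(states=tuple(sorted(full.items())),
                     combination=tuple(combination), free=free)


def is_fixed_point(on_rules: Mapping[str, LogicRule],
                   state: Mapping[str, bool]) -> bool:
    return all(rule.evaluate(state) == state[s] for s, rule in on_rules.items())


@dataclass
class ModelAnalysis:
    """Full motif/attractor analysis of one simplified model."""

    model: SimplifiedModel
    expnet: ExpandedNetwork
    stable_motifs: list[StableMotif]
    csms: list[ConditionallyStableMotif]
    groups: list[MotifGroup]
    relation_graph: nx.DiGraph
    attractors: list[Attractor]

    @property
    def maximal_richness(self) -> Attractor:
        return maximal_richness_attractor(self.attractors)


def analyze(model: SimplifiedModel) -> ModelAnalysis:
    """Run the whole pipeline: expanded net, motifs, groups, attractors."""
    expnet = build_expanded_network(model.rules)
    sms = find_stable_motifs(expnet, model.rules)
    csms = find_conditionally_stable_motifs(expnet, model.rules, sms)
    groups = build_motif_groups(sms, csms, expnet)
    relg = functional_relation_graph(sms, groups, expnet)
    combos = maximal_consistent_combinations(relg)
    attractors: dict[tuple, Attractor] = {}
    for combo in combos:
        att = trap_space_of_combination(combo, model.rules)
        attractors.setdefault((att.states, att.free), att)  # collapse duplicates
    atts = sorted(attractors.values(), key=lambda a: a.states)
    return ModelAnalysis(model=model, expnet=expnet, stable_motifs=sms,
                         csms=csms, groups=groups, relation_graph=relg,
                         attractors=atts)


def maximal_richness_attractor(attractors: Sequence[Attractor]) -> Attractor:
    """The attractor with the most established species.

    Every other attractor's established set is expected to be a subset of
    the winner's; ties (not observed in this model class) break by
    canonical state order.
    """
    if not attractors:
        raise ValueError("need at least one attractor")
    best = sorted(attractors, key=lambda a: (-a.richness, a.states))[0]
    return best


def reduce_combination(members: Sequence, expnet: ExpandedNetwork) -> list:
    """Drop combination members implied by the others' joint LDOI.

    A member whose virtual nodes lie in the LDOI of the remaining members
    stabilizes automatically and needs no driver set of its own; removing
    such members (in canonical order, iterated to a fixpoint) leaves the
    combination that actually has to be controlled.
    """
    members = sorted(members, key=lambda m: m.key)
    changed = True
    while changed and len(members) > 1:
        changed = False
        for i, m in enumerate(members):
            rest = members[:i] + members[i + 1:]
            joint = frozenset().union(*(set(r.states) for r in rest))
            if set(m.states) <= ldoi_expanded(expnet, joint):
                members = rest
                changed = True
                break
    return members


def control_sets_of_attractor(
    attractor: Attractor,
    driver_sets_by_member: Mapping[object, Sequence[frozenset]],
    on_rules: Mapping[str, LogicRule],
    max_candidates: int = 10_000,
    expnet: ExpandedNetwork | None = None,
) -> tuple[list[frozenset], bool]:
    """Minimum-cardinality unions of one driver set per combination member.

    When *expnet* is given, the combination is first reduced: members whose
    stabilization is already implied by the rest (an LDOI containment) need
    no driver set of their own.  Returns ``(control_sets, complete)``;
    *complete* is False when a member lacks any driver set (within the
    caller's size cap) or when the enumeration hit *max_candidates*.  Every
    returned set is verified by percolation to reproduce the attractor's
    full state assignment.
    """
    members = list(attractor.combination)
    if not members:
        return [frozenset()], True
    if expnet is not None:
        members = reduce_combination(members, expnet)
    complete = True
    choice_lists = []
    for m in members:
        ds = list(driver_sets_by_member.get(m, ()))
        if not ds:
            return [], False
        choice_lists.append(ds)

    best: list[frozenset] = []
    best_size = None
    n_seen = 0
    for choice in itertools.product(*choice_lists):
        n_seen += 1
        if n_seen > max_candidates:
            complete = False
            break
        union = frozenset().union(*choice)
        if best_size is None or len(union) < best_size:
            best, best_size = [union], len(union)
        elif len(union) == best_size and union not in best:
            best.append(union)

    target = attractor.state_dict
    verified = []
    for cs in best:
        assign = percolate(on_rules, {n: v for n, v in cs})
        full = {s: assign.get(s, False) for s in on_rules}
        if full == target:
            verified.append(cs)
    return sorted(verified, key=lambda s: sorted(vlabel(v) for v in s)), complete


def attractor_control_report(
    analysis: ModelAnalysis,
    max_driver_size: int = 4,
    max_candidates: int = 10_000,
) -> dict[Attractor, tuple[list[frozenset], bool]]:
    """Control sets for every attractor of an analyzed model."""
    driver_cache: dict[object, list[frozenset]] = {}
    out = {}
    for att in analysis.attractors:
        for m in att.combination:
            if m not in driver_cache:
                driver_cache[m] = find_driver_sets(
                    m, analysis.expnet, max_size=max_driver_size)
        out[att] = control_sets_of_attractor(
            att, driver_cache, analysis.model.rules, max_candidates,
            expnet=analysis.expnet)
    return out
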