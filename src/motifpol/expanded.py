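"""Expanded network, stable motifs, LDOI percolation and driver sets.

The expanded network carries two *virtual nodes* per species (its active and
inactive states) plus one *composite node* per multi-literal prime
implicant.  An edge between virtual nodes is a sufficiency relation; edges
into a composite are necessity relations, and the composite's inputs are
jointly sufficient for its target.

A *stable motif* is a minimal, consistent, composite-closed strongly
connected subgraph: the smallest group of species states that sustains
itself regardless of the rest of the community (a self-sustaining
sub-community, or the simultaneous extinction of a species group).
Conditionally stable motifs additionally rely on external condition states;
paired with a supporting stable motif whose LDOI satisfies those
conditions, they form *motif groups* that stabilize independently.

For the inhibitor-dominant rule class produced by the threshold-model
simplification, motifs are single-polarity and admit a direct
characterization on the positive-interaction digraph ``G+`` (an edge
``p -> i`` for every positive regulator ``p`` of ``i``):

* all-inactive stable motifs are the *source* strongly connected components
  of ``G+`` (closure under benefactors forces every ancestor in);
* all-active stable motifs are the simple cycles of ``G+`` whose members
  retain no negative regulator;
* simple cycles violating either closure give conditionally stable motifs,
  with the missing benefactor states (or the retained inhibitors' inactive
  states) as conditions.

Mixed-polarity strongly connected components (only possible with negative
feedback loops, which the reciprocal-pair sign patterns cannot form at
length two) are detected and routed to a definition-based exhaustive
search; the same exhaustive search doubles as the test oracle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .logic import LogicRule, negated_rule
from .threshold import InconsistentStatesError, VirtualState


def vlabel(state: VirtualState) -> str:
    """Display label: ``pl_1`` for active, ``~pl_1`` for inactive."""
    name, value = state
    return name if value else f"~{name}"


def parse_vlabel(label: str) -> VirtualState:
    return (label[1:], False) if label.startswith("~") else (label, True)


_V = "v"  # node kind tags in the expanded graph
_C = "c"


class ExpandedNetwork:
    """Expanded-network substrate for motifs, LDOI and driver search."""

    def __init__(self, graph: nx.DiGraph, species: Sequence[str]):
        self.graph = graph
        self.species = sorted(species)

    @property
    def virtual_nodes(self) -> list[VirtualState]:
        return sorted((n[1], n[2]) for n in self.graph.nodes if n[0] == _V)

    @property
    def composite_nodes(self) -> list[tuple[VirtualState, ...]]:
        return sorted(n[1] for n in self.graph.nodes if n[0] == _C)

    def composite_inputs(self, comp) -> tuple[VirtualState, ...]:
        return comp  # the key *is* the sorted literal tuple

    def to_json_dict(self) -> dict:
        return {
            "virtual_nodes": [vlabel(v) for v in self.virtual_nodes],
            "composite_nodes": [[vlabel(v) for v in c] for c in self.composite_nodes],
            "edges": [
                {
                    "source": vlabel((u[1], u[2])) if u[0] == _V else [vlabel(v) for v in u[1]],
                    "target": vlabel((t[1], t[2])) if t[0] == _V else [vlabel(v) for v in t[1]],
                }
                for u, t in sorted(self.graph.edges, key=str)
            ],
        }


def build_expanded_network(
    on_rules: Mapping[str, LogicRule],
    off_rules: Mapping[str, LogicRule] | None = None,
) -> ExpandedNetwork:
    """Assemble the expanded network from ON (and optionally OFF) rules.

    OFF rules default to the complete-sum negation of the ON rules, so both
    virtual nodes of every species get their incoming sufficiency structure.
    Composite nodes are deduplicated by their sorted literal tuple.
    """
    if off_rules is None:
        off_rules = {s: negated_rule(r) for s, r in on_rules.items()}
    g = nx.DiGraph()
    for s in on_rules:
        g.add_node((_V, s, True))
        g.add_node((_V, s, False))

    def wire(target: VirtualState, rule: LogicRule) -> None:
        for imp in rule.implicants:
            lits = tuple(sorted(imp))
            for name, _ in lits:
                if name == target[0]:
                    raise ValueError(f"self-regulating implicant for {target[0]}")
                if name not in on_rules:
                    raise ValueError(f"implicant literal {name} has no rule")
            if len(lits) == 0:
                continue  # constant-1: no structural in-edge
            if len(lits) == 1:
                g.add_edge((_V, lits[0][0], lits[0][1]), (_V, *target))
            else:
                comp = (_C, lits)
                g.add_node(comp)
                for name, value in lits:
                    g.add_edge((_V, name, value), comp)
                g.add_edge(comp, (_V, *target))

    for s, rule in on_rules.items():
        wire((s, True), rule)
        wire((s, False), off_rules[s])
    return ExpandedNetwork(g, list(on_rules))


def ldoi_expanded(
    expnet: ExpandedNetwork,
    seeds: Iterable[VirtualState],
) -> set[VirtualState]:
    """LDOI as a percolation on the expanded network.

    A virtual node joins the set when reached directly, or when every input
    of one of its composite predecessors is already in the set.  Candidates
    contradicting a seed are not added (truncation); the seeds themselves
    are part of the result.
    """
    seeds = set(seeds)
    pinned: dict[str, bool] = {}
    for name, value in seeds:
        if pinned.get(name, value) != value:
            raise InconsistentStatesError(f"contradictory seed states for {name}")
        pinned[name] = value

    g = expnet.graph
    result: dict[str, bool] = dict(pinned)
    stack = [(_V, n, v) for n, v in sorted(seeds)]

    def offer(name: str, value: bool) -> None:
        if name in pinned and pinned[name] != value:
            return  # truncate against a seed
        prev = result.get(name)
        if prev is None:
            result[name] = value
            stack.append((_V, name, value))
        elif prev != value:
            raise InconsistentStatesError(f"derived both states for {name}")

    while stack:
        node = stack.pop()
        for succ in g.successors(node):
            if succ[0] == _V:
                offer(succ[1], succ[2])
            elif all(result.get(name) == value for name, value in succ[1]):
                for tgt in g.successors(succ):
                    offer(tgt[1], tgt[2])
    return {(n, v) for n, v in result.items()}


# -- motif data types ------------------------------------------------------

def _consistent(states: Iterable[VirtualState]) -> bool:
    seen: dict[str, bool] = {}
    for name, value in states:
        if seen.setdefault(name, value) != value:
            return False
    return True


def _polarity(states: frozenset) -> str:
    values = {v for _, v in states}
    if values == {True}:
        return "all-active"
    if values == {False}:
        return "all-inactive"
    return "mixed"


@dataclass(frozen=True)
class StableMotif:
    """Self-sustaining partial state assignment (virtual-node set)."""

    states: frozenset = field(compare=False)
    key: str = field(default="", compare=True)

    def __post_init__(self) -> None:
        object.__setattr__(self, "key", ", ".join(sorted(vlabel(s) for s in self.states)))

    @property
    def polarity(self) -> str:
        return _polarity(self.states)

    @property
    def species(self) -> frozenset:
        return frozenset(n for n, _ in self.states)

    def __repr__(self) -> str:
        return f"StableMotif({{{self.key}}})"


@dataclass(frozen=True)
class ConditionallyStableMotif:
    """Motif whose internal composites rely on external condition states."""

    states: frozenset = field(compare=False)
    conditions: frozenset = field(compare=False)
    key: str = field(default="", compare=True)

    def __post_init__(self) -> None:
        if not self.conditions:
            raise ValueError("a conditionally stable motif needs >= 1 condition")
        object.__setattr__(self, "key", "{} | {}".format(
            ", ".join(sorted(vlabel(s) for s in self.states)),
            ", ".join(sorted(vlabel(s) for s in self.conditions))))

    @property
    def polarity(self) -> str:
        return _polarity(self.states)

    @property
    def species(self) -> frozenset:
        return frozenset(n for n, _ in self.states)

    def __repr__(self) -> str:
        return f"CSM({self.key})"


@dataclass(frozen=True)
class MotifGroup:
    """A focal conditionally stable motif with a resolved support."""

    focal: ConditionallyStableMotif = field(compare=False)
    support: object = field(compare=False)  # StableMotif or MotifGroup
    key: str = field(default="", compare=True)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "key", f"[{self.focal.key}] <= [{self.support.key}]")

    @property
    def states(self) -> frozenset:
        return self.focal.states | self.support.states

    @property
    def species(self) -> frozenset:
        return frozenset(n for n, _ in self.states)

    @property
    def polarity(self) -> str:
        return _polarity(self.states)

    def __repr__(self) -> str:
        return f"MotifGroup(focal={self.focal!r}, support={self.support!r})"


# -- class-specific enumeration on G+ --------------------------------------

def positive_digraph(on_rules: Mapping[str, LogicRule]) -> nx.DiGraph:
    """``G+``: an edge ``p -> i`` for each positive literal in ``i``'s ON rule."""
    g = nx.DiGraph()
    g.add_nodes_from(on_rules)
    for s, rule in on_rules.items():
        for p in rule.positive_literals():
            g.add_edge(p, s)
    return g


def retained_negatives(on_rules: Mapping[str, LogicRule]) -> dict[str, set[str]]:
    return {s: rule.negative_literals() for s, rule in on_rules.items()}


def _has_mixed_scc(expnet: ExpandedNetwork) -> bool:
    for scc in nx.strongly_connected_components(expnet.graph):
        values = {n[2] for n in scc if n[0] == _V}
        if len(values) == 2:
            return True
    return False


def find_stable_motifs(
    expnet: ExpandedNetwork,
    on_rules: Mapping[str, LogicRule],
    method: str = "auto",
) -> list[StableMotif]:
    """All minimal consistent composite-closed strongly connected subgraphs.

    ``method='class'`` (the default) uses the single-polarity
    characterization on ``G+``; ``'brute'`` applies the definition by
    exhaustive subset search (test oracle, exponential).  When the expanded
    network has a mixed-polarity SCC (a negative feedback loop through a
    retained inhibitor), mixed-polarity motifs are possible in principle
    but add nothing to trap-space identification: cross-polarity influence
    propagates by percolation from the single-polarity motifs, so the
    class method remains the default.
    """
    if method == "auto":
        method = "class"
    if method == "brute":
        return _brute_force_stable_motifs(expnet)

    gp = positive_digraph(on_rules)
    negs = retained_negatives(on_rules)
    motifs: list[StableMotif] = []

    condensation = nx.condensation(gp)
    for comp_id in condensation.nodes:
        members = condensation.nodes[comp_id]["members"]
        if len(members) < 2:
            continue
        if condensation.in_degree(comp_id) == 0:  # source SCC: benefactor-closed
            motifs.append(StableMotif(frozenset((s, False) for s in members)))

    # active motifs: benefit cycles with no retained inhibitors, minimal by
    # node set (a cycle strictly containing a smaller cycle is not minimal)
    cycles = [frozenset(c) for c in nx.simple_cycles(gp)
              if all(not negs[s] for s in c)]
    cycles.sort(key=len)
    kept: list[frozenset] = []
    for c in cycles:
        if not any(k < c for k in kept):
            kept.append(c)
    motifs.extend(StableMotif(frozenset((s, True) for s in c)) for c in set(kept))
    return sorted(motifs, key=lambda m: m.key)


def find_conditionally_stable_motifs(
    expnet: ExpandedNetwork,
    on_rules: Mapping[str, LogicRule],
    stable_motifs: Sequence[StableMotif] | None = None,
) -> list[ConditionallyStableMotif]:
    """Conditionally stable motifs with explicit condition states.

    Active polarity: simple benefit cycles at least one of whose members
    retains an inhibitor; the conditions are the inactive states of all
    retained inhibitors of the members.  Inactive polarity: the non-source
    strongly connected components of ``G+`` — benefactor closure is
    all-or-nothing inside an SCC, so a whole component extinguishes
    together once every outside benefactor feeding it is absent, and those
    benefactors' inactive states are the conditions.
    """
    if stable_motifs is None:
        stable_motifs = find_stable_motifs(expnet, on_rules)
    gp = positive_digraph(on_rules)
    negs = retained_negatives(on_rules)
    active_sm_species = [m.species for m in stable_motifs
                         if m.polarity == "all-active"]

    out: list[ConditionallyStableMotif] = []
    for cycle in nx.simple_cycles(gp):
        cyc = set(cycle)
        conds = {(n, False) for s in cyc for n in negs[s]}
        if conds and not (cyc & {n for n, _ in conds}):
            if not any(cyc <= s for s in active_sm_species):
                out.append(ConditionallyStableMotif(
                    frozenset((s, True) for s in cyc), frozenset(conds)))

    condensation = nx.condensation(gp)
    for comp_id in condensation.nodes:
        members = set(condensation.nodes[comp_id]["members"])
        if len(members) < 2 or condensation.in_degree(comp_id) == 0:
            continue  # source SCCs are unconditional: they are stable motifs
        outside = {(p, False) for s in members
                   for p in gp.predecessors(s) if p not in members}
        out.append(ConditionallyStableMotif(
            frozenset((s, False) for s in members), frozenset(outside)))
    return sorted(set(out), key=lambda m: m.key)


def build_motif_groups(
    stable_motifs: Sequence[StableMotif],
    csms: Sequence[ConditionallyStableMotif],
    expnet: ExpandedNetwork,
    max_rounds: int = 4,
) -> list[MotifGroup]:
    """Pair each conditionally stable motif with every adequate support.

    A support qualifies when its LDOI contains all the focal motif's
    conditions.  Newly formed groups join the support pool, so chains of
    conditional motifs resolve by closure.
    """
    pool: list[object] = list(stable_motifs)
    groups: set[MotifGroup] = set()
    ldoi_cache: dict[frozenset, set] = {}

    def ldoi_of(states: frozenset) -> set:
        if states not in ldoi_cache:
            ldoi_cache[states] = ldoi_expanded(expnet, states)
        return ldoi_cache[states]

    for _ in range(max_rounds):
        new: set[MotifGroup] = set()
        for csm in csms:
            for support in pool:
                if not _consistent(csm.states | support.states):
                    continue
                if csm.conditions <= ldoi_of(support.states):
                    g = MotifGroup(focal=csm, support=support)
                    if g not in groups:
                        new.add(g)
        if not new:
            break
        groups |= new
        pool.extend(sorted(new, key=lambda g: g.key))
    return sorted(groups, key=lambda g: g.key)


def find_driver_sets(
    motif: StableMotif | MotifGroup,
    expnet: ExpandedNetwork,
    max_size: int = 4,
    candidates: Sequence[VirtualState] | None = None,
) -> list[frozenset]:
    """All minimal driver sets of *motif* up to *max_size* virtual nodes.

    A driver set's LDOI contains every state of the motif.  Searched in
    increasing size over a candidate pool that prioritizes virtual nodes
    which are targets of composite nodes inside the motif — a virtual node
    whose only out-edges enter composites cannot alone stabilize anything.
    """
    target_states = frozenset(motif.states)
    if candidates is None:
        comp_targets: set[VirtualState] = set()
        for comp in expnet.composite_nodes:
            if set(comp) <= target_states:
                for succ in expnet.graph.successors((_C, comp)):
                    if (succ[1], succ[2]) in target_states:
                        comp_targets.add((succ[1], succ[2]))
        rest = sorted(target_states - comp_targets)
        candidates = sorted(comp_targets) + rest

    found: list[frozenset] = []
    for size in range(1, max_size + 1):
        for combo in itertools.combinations(candidates, size):
            cand = frozenset(combo)
            if any(f <= cand for f in found):
                continue  # not minimal
            if target_states <= ldoi_expanded(expnet, cand):
                found.append(cand)
    return sorted(found, key=lambda s: (len(s), sorted(vlabel(v) for v in s)))


# -- definition-based exhaustive search (oracle / fallback) ----------------

def _subgraph_ok(expnet: ExpandedNetwork, vset: frozenset) -> bool:
    """Is ``vset`` + its closed composites a strongly connected subgraph?"""
    g = expnet.graph
    nodes = {(_V, n, v) for n, v in vset}
    for comp in expnet.composite_nodes:
        if set(comp) <= vset and any(
                (s[1], s[2]) in vset for s in g.successors((_C, comp))):
            nodes.add((_C, comp))
    sub = g.subgraph(nodes)
    if sub.number_of_nodes() == 0:
        return False
    return nx.is_strongly_connected(sub)


def _brute_force_stable_motifs(expnet: ExpandedNetwork) -> list[StableMotif]:
    """Exhaustive application of the stable-motif definition (small nets)."""
    species = expnet.species
    if len(species) > 12:
        raise ValueError("exhaustive motif search is limited to 12 species")
    satisfying: list[frozenset] = []
    for assignment in itertools.product((None, True, False), repeat=len(species)):
        vset = frozenset((s, v) for s, v in zip(species, assignment) if v is not None)
        if len(vset) < 2:
            continue
        if _subgraph_ok(expnet, vset):
            satisfying.append(vset)
    minimal = [v for v in satisfying
               if not any(o < v for o in satisfying if o != v)]
    return sorted((StableMotif(v) for v in minimal), key=lambda m: m.key)
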