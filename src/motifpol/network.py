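"""Signed, weighted, directed bipartite plant-pollinator networks.

The regional species pool is a bipartite graph of plant and pollinator
species.  A habitual visitation of a plant by a pollinator is encoded as a
*reciprocal pair* of directed edges between the two species, one in each
direction.  The sign of each direction depends on the morphological match
between the plant's corolla depth and the pollinator's proboscis length:

* corolla much deeper than the proboscis -- the pollinator contacts the
  flower (pollination happens, ``+`` toward the plant) but cannot reach the
  nectar (``-`` toward the pollinator);
* proboscis much longer than the corolla -- the pollinator robs nectar
  without touching the reproductive parts (``-`` toward the plant, ``+``
  toward the pollinator);
* otherwise the lengths match and both species benefit (``+``, ``+``).

Positive interactions carry weight ``+4`` and negative ones ``-1``, so a
single benefit outweighs up to three costs in the threshold dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx
import pandas as pd

PLANT = "plant"
POLLINATOR = "pollinator"

#: default interaction weights
W_POS = 4
W_NEG = -1

#: default trait-ratio thresholds separating mismatch from match
MATCH_LO = 0.9
MATCH_HI = 1.1


def guild_of(species: str) -> str:
    """Guild implied by the species label prefix (``pl_*`` or ``po_*``)."""
    if species.startswith("pl_"):
        return PLANT
    if species.startswith("po_"):
        return POLLINATOR
    raise ValueError(f"species id {species!r} must start with 'pl_' or 'po_'")


def classify_interaction(
    l_pl: float,
    l_po: float,
    match_lo: float = MATCH_LO,
    match_hi: float = MATCH_HI,
) -> tuple[int, int]:
    """Sign pair ``(sign toward plant, sign toward pollinator)`` for a visit.

    Signs are ``+1``/``-1``.  Boundary ratios (``l_pl == match_hi * l_po``
    or ``l_pl == match_lo * l_po``) count as a match, since the mismatch
    conditions are strict inequalities.
    """
    if l_pl <= 0 or l_po <= 0:
        raise ValueError("trait lengths must be positive")
    if l_pl > match_hi * l_po:
        return (1, -1)
    if l_pl < match_lo * l_po:
        return (-1, 1)
    return (1, 1)


@dataclass(frozen=True)
class SpeciesNode:
    """A species of the regional pool with its morphological trait length."""

    id: str
    guild: str
    trait_length: float

    def __post_init__(self) -> None:
        if self.trait_length <= 0:
            raise ValueError("trait_length must be positive")
        if guild_of(self.id) != self.guild:
            raise ValueError(f"guild {self.guild!r} contradicts id {self.id!r}")


class InteractionNetwork:
    """Bipartite species-pool network with reciprocal signed edge pairs.

    Thin wrapper around a :class:`networkx.DiGraph`; node attributes are
    ``guild`` and ``trait_length``, edge attribute ``weight`` is ``+4`` or
    ``-1``.  Every interacting pair has exactly two opposite directed edges.
    """

    def __init__(self) -> None:
        self.graph = nx.DiGraph()

    # -- construction ------------------------------------------------------

    def add_species(self, node: SpeciesNode) -> None:
        self.graph.add_node(node.id, guild=node.guild, trait_length=node.trait_length)

    def add_interaction(self, plant: str, pollinator: str,
                        sign_pair: tuple[int, int] | None = None,
                        w_pos: int = W_POS, w_neg: int = W_NEG) -> None:
        """Add the reciprocal edge pair for one plant-pollinator visit.

        If *sign_pair* is omitted it is recomputed from the stored traits.
        """
        if guild_of(plant) != PLANT or guild_of(pollinator) != POLLINATOR:
            raise ValueError("interaction must connect a plant and a pollinator")
        if sign_pair is None:
            sign_pair = classify_interaction(
                self.graph.nodes[plant]["trait_length"],
                self.graph.nodes[pollinator]["trait_length"],
            )
        s_pl, s_po = sign_pair
        if (s_pl, s_po) == (-1, -1):
            raise ValueError("a (-,-) interaction pair cannot occur")
        self.graph.add_edge(pollinator, plant, weight=w_pos if s_pl > 0 else w_neg)
        self.graph.add_edge(plant, pollinator, weight=w_pos if s_po > 0 else w_neg)

    # -- queries -----------------------------------------------------------

    @property
    def species(self) -> list[str]:
        return sorted(self.graph.nodes)

    @property
    def plants(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["guild"] == PLANT)

    @property
    def pollinators(self) -> list[str]:
        return sorted(n for n, d in self.graph.nodes(data=True) if d["guild"] == POLLINATOR)

    def trait_length(self, species: str) -> float:
        return self.graph.nodes[species]["trait_length"]

    def interacting_pairs(self) -> Iterator[tuple[str, str]]:
        """Yield each ``(plant, pollinator)`` pair exactly once.

        A pair interacts when either directed edge is present: conversion
        and simplification may delete one direction's superfluous negative
        edge while the beneficial partner edge keeps the species connected.
        """
        seen = set()
        for u, v in self.graph.edges:
            pair = (v, u) if guild_of(u) == POLLINATOR else (u, v)
            if pair not in seen:
                seen.add(pair)
                yield pair

    def sign_pair(self, plant: str, pollinator: str) -> tuple[int, int]:
        """Directed signs ``(toward plant, toward pollinator)``; 0 = deleted."""
        def sign(u: str, v: str) -> int:
            data = self.graph.get_edge_data(u, v)
            if data is None:
                return 0
            return 1 if data["weight"] > 0 else -1
        return (sign(pollinator, plant), sign(plant, pollinator))

    def in_edges(self, species: str) -> list[tuple[str, int]]:
        """Regulators of *species* as ``(source, weight)`` pairs."""
        return sorted((u, d["weight"]) for u, _, d in self.graph.in_edges(species, data=True))

    def copy(self) -> "InteractionNetwork":
        out = InteractionNetwork()
        out.graph = self.graph.copy()
        return out

    def subnetwork(self, keep: Iterable[str]) -> "InteractionNetwork":
        """Induced subnetwork on *keep*; reciprocal pairs stay intact."""
        out = InteractionNetwork()
        out.graph = self.graph.subgraph(set(keep)).copy()
        return out

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionNetwork):
            return NotImplemented
        return nx.utils.graphs_equal(self.graph, other.graph)

    # -- invariants --------------------------------------------------------

    def validate(self) -> None:
        """Raise if any type invariant is violated."""
        for n, d in self.graph.nodes(data=True):
            if d["guild"] != guild_of(n):
                raise ValueError(f"guild mismatch at {n}")
            if d["trait_length"] <= 0:
                raise ValueError(f"non-positive trait length at {n}")
        for u, v, d in self.graph.edges(data=True):
            if u == v:
                raise ValueError(f"self-edge at {u}")
            if {guild_of(u), guild_of(v)} != {PLANT, POLLINATOR}:
                raise ValueError(f"non-bipartite edge {u}->{v}")
            if d["weight"] not in (W_POS, W_NEG):
                raise ValueError(f"illegal weight on {u}->{v}: {d['weight']}")
            if not self.graph.has_edge(v, u):
                raise ValueError(f"missing reciprocal edge for {u}->{v}")
        for pl, po in self.interacting_pairs():
            if self.sign_pair(pl, po) == (-1, -1):
                raise ValueError(f"(-,-) pair {pl}/{po}")


def interaction_class_fractions(net: InteractionNetwork) -> tuple[float, float, float]:
    """Fractions of (mutual, plant-only-benefit, pollinator-only-benefit) pairs.

    A direction whose superfluous negative edge was deleted counts the same
    as a present negative edge: the benefit flows one way only.
    """
    counts = {"mutual": 0, "plant": 0, "pollinator": 0}
    total = 0
    for pl, po in net.interacting_pairs():
        s_pl, s_po = net.sign_pair(pl, po)
        if s_pl > 0 and s_po > 0:
            counts["mutual"] += 1
        elif s_pl > 0:
            counts["plant"] += 1
        elif s_po > 0:
            counts["pollinator"] += 1
        else:  # pragma: no cover - excluded by the network invariants
            raise ValueError(f"pair {pl}/{po} benefits neither species")
        total += 1
    if total == 0:
        raise ValueError("network has no interactions")
    return (counts["mutual"] / total, counts["plant"] / total,
            counts["pollinator"] / total)


# -- plain-text round trip -------------------------------------------------

def write_network(net: InteractionNetwork, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.nodes.tsv`` and ``<prefix>.edges.tsv``."""
    prefix = Path(prefix)
    nodes = pd.DataFrame(
        [(n, d["guild"], d["trait_length"]) for n, d in sorted(net.graph.nodes(data=True))],
        columns=["id", "guild", "trait_length"],
    )
    edges = pd.DataFrame(
        [(u, v, d["weight"]) for u, v, d in sorted(net.graph.edges(data=True))],
        columns=["source", "target", "weight"],
    )
    node_path = prefix.with_suffix(".nodes.tsv")
    edge_path = prefix.with_suffix(".edges.tsv")
    nodes.to_csv(node_path, sep="\t", index=False)
    edges.to_csv(edge_path, sep="\t", index=False)
    return node_path, edge_path


def read_network(prefix: str | Path) -> InteractionNetwork:
    """Read a network written by :func:`write_network` (lossless round trip)."""
    prefix = Path(prefix)
    nodes = pd.read_csv(prefix.with_suffix(".nodes.tsv"), sep="\t")
    edges = pd.read_csv(prefix.with_suffix(".edges.tsv"), sep="\t")
    net = InteractionNetwork()
    for row in nodes.itertuples(index=False):
        net.add_species(SpeciesNode(str(row.id), str(row.guild), float(row.trait_length)))
    for i, row in enumerate(edges.itertuples(index=False), start=2):
        w = int(row.weight)
        if w not in (W_POS, W_NEG):
            raise ValueError(f"line {i}: weight {w} outside {{{W_POS}, {W_NEG}}}")
        net.graph.add_edge(str(row.source), str(row.target), weight=w)
    net.validate()
    return net
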