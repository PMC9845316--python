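"""Structural keystone-species measures and functional diversity.

Baselines against which motif-driver analysis is compared:

* directed betweenness centrality (connector species);
* node contribution to nestedness, adapted to directed networks:
  ``eta_i = (1/N) * sum_{j != i} n_ij / (k_in_i * k_in_j)`` where ``n_ij``
  counts the benefactors/inhibitors two species share (common
  in-neighbours) — species with few interactions that are shared with
  other low-degree species contribute most, and are the most vulnerable;
* MusRank, the iterative importance/vulnerability ranking for mutualistic
  bipartite networks; it deliberately binarizes and symmetrizes the
  incidence, which is exactly the property that can make it miss
  direction-dependent keystone species;
* functional diversity: total branch length of a single-linkage dendrogram
  built from Euclidean distances between interaction profiles, with one
  dendrogram per guild because the networks are directed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist

from .network import InteractionNetwork, PLANT, POLLINATOR, guild_of


def betweenness_ranking(net: InteractionNetwork) -> pd.Series:
    """Shortest-path betweenness on the directed, unweighted graph."""
    bc = nx.betweenness_centrality(net.graph, normalized=False)
    return pd.Series(bc, name="betweenness").sort_index()


def nestedness_contribution(net: InteractionNetwork) -> pd.Series:
    """Per-species nestedness contribution from shared in-neighbours.

    Species with zero in-degree are excluded (with a warning); after
    pruning every species has at least one benefactor so this is only
    relevant for raw pools.
    """
    species = net.species
    n_total = len(species)
    idx = {s: i for i, s in enumerate(species)}
    m = np.zeros((n_total, n_total))
    for u, v in net.graph.edges:
        m[idx[v], idx[u]] = 1.0  # row = target: row lists in-neighbours
    k_in = m.sum(axis=1)
    scored = [s for s in species if k_in[idx[s]] > 0]
    dropped = [s for s in species if k_in[idx[s]] == 0]
    if dropped:
        warnings.warn(f"excluding zero-in-degree species from nestedness: {dropped}")
    shared = m @ m.T  # (i, j) -> number of common in-neighbours
    eta = {}
    for s in scored:
        i = idx[s]
        total = sum(shared[i, idx[j]] / (k_in[i] * k_in[idx[j]])
                    for j in scored if j != s)
        eta[s] = total / n_total
    return pd.Series(eta, name="nestedness_contribution").sort_index()


def musrank(
    net: InteractionNetwork,
    tol: float = 1e-9,
    max_iter: int = 200_000,
) -> tuple[pd.Series, pd.Series]:
    """Fixed point of the MusRank iteration: ``(importance, vulnerability)``.

    Pollinators are the active species (importance ``I_A``), plants the
    passive ones (vulnerability ``V_P``).  The incidence is binarized and
    symmetrized (any interacting pair counts, whatever the edge signs).
    Both score vectors start at 1 and are renormalized to mean 1 every
    iteration; the fixed point does not depend on the start.  On nested
    networks the scores of strict specialists decay toward zero only
    algebraically, hence the generous default iteration cap.
    """
    plants, pollinators = net.plants, net.pollinators
    if not plants or not pollinators:
        raise ValueError("need both guilds for MusRank")
    m = np.zeros((len(pollinators), len(plants)))
    for pl, po in net.interacting_pairs():
        m[pollinators.index(po), plants.index(pl)] = 1.0
    if (m.sum(axis=0) == 0).any() or (m.sum(axis=1) == 0).any():
        raise ValueError("every species must have at least one interaction")
    floor = 1e-12  # specialist scores decay to zero; flooring keeps 1/I finite
    imp = np.ones(len(pollinators))
    vul = np.ones(len(plants))
    for _ in range(max_iter):
        # sequential update: vulnerabilities see the freshly renormalized
        # importances, which is what actually reaches a fixed point (the
        # simultaneous variant can settle into a two-cycle instead)
        imp_new = m @ vul
        imp_new /= imp_new.mean()
        imp_new = np.maximum(imp_new, floor)
        vul_new = 1.0 / (m.T @ (1.0 / imp_new))
        vul_new /= vul_new.mean()
        vul_new = np.maximum(vul_new, floor)
        delta = max(np.abs(imp_new - imp).max(), np.abs(vul_new - vul).max())
        imp, vul = imp_new, vul_new
        if delta < tol:
            return (pd.Series(imp, index=pollinators, name="importance"),
                    pd.Series(vul, index=plants, name="vulnerability"))
    raise RuntimeError(
        f"MusRank did not converge in {max_iter} iterations (last delta {delta:.2e})")


# -- functional diversity ---------------------------------------------------

@dataclass(frozen=True)
class Dendrogram:
    """Single-linkage merge tree over species interaction profiles.

    ``heights[k]`` is the merge height of internal node ``n + k`` (leaves
    are ``0..n-1`` at height 0) and ``parent[v]`` the merge node above
    ``v``; the root has parent -1.  The branch segment above node ``v`` has
    length ``heights[parent[v]] - height(v)``.
    """

    leaves: tuple[str, ...]
    merge_children: tuple[tuple[int, int], ...]
    heights: tuple[float, ...]
    parent: tuple[int, ...]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def node_height(self, v: int) -> float:
        return 0.0 if v < self.n_leaves else self.heights[v - self.n_leaves]

    def segment_length(self, v: int) -> float:
        p = self.parent[v]
        if p < 0:
            return 0.0
        return self.node_height(p) - self.node_height(v)

    def to_newick(self) -> str:
        def rec(v: int) -> str:
            length = self.segment_length(v)
            if v < self.n_leaves:
                return f"{self.leaves[v]}:{length:g}"
            a, b = self.merge_children[v - self.n_leaves]
            return f"({rec(a)},{rec(b)}):{length:g}"
        root = 2 * self.n_leaves - 2 if self.n_leaves > 1 else 0
        return rec(root) + ";"


def fd_dendrogram(profiles: pd.DataFrame) -> Dendrogram:
    """Cluster one guild by its incidence columns (nearest-point linkage).

    *profiles* has one column per scored species and one row per species of
    the opposite guild; entries are 0/1.  Distances are Euclidean between
    columns.
    """
    leaves = tuple(profiles.columns)
    if len(leaves) < 2:
        return Dendrogram(leaves=leaves, merge_children=(), heights=(), parent=(-1,) * len(leaves))
    x = profiles.to_numpy(dtype=float).T
    # condensed distances keep scipy from guessing whether a square 0/1
    # profile matrix is itself a distance matrix
    z = linkage(pdist(x, metric="euclidean"), method="single")
    n = len(leaves)
    parent = [-1] * (2 * n - 1)
    children = []
    heights = []
    for k, row in enumerate(z):
        a, b = int(row[0]), int(row[1])
        children.append((a, b))
        heights.append(float(row[2]))
        parent[a] = n + k
        parent[b] = n + k
    return Dendrogram(leaves=leaves, merge_children=tuple(children),
                      heights=tuple(heights), parent=tuple(parent))


def functional_diversity(dendro: Dendrogram, survivors: Iterable[str]) -> float:
    """Total length of the branch segments linking *survivors* to the root.

    ``FD`` of the full leaf set is the total branch length of the
    dendrogram; ``FD`` of the empty set is 0; a single survivor contributes
    its root path.  Monotone under set inclusion by construction.
    """
    survivors = set(survivors)
    unknown = survivors - set(dendro.leaves)
    if unknown:
        raise KeyError(f"unknown leaves: {sorted(unknown)}")
    if not survivors or dendro.n_leaves < 2:
        return 0.0
    used: set[int] = set()
    index = {s: i for i, s in enumerate(dendro.leaves)}
    for s in survivors:
        v = index[s]
        while v >= 0 and v not in used:
            used.add(v)
            v = dendro.parent[v]
    return float(sum(dendro.segment_length(v) for v in used))


def fd_restoration_ranking(
    dendro: Dendrogram,
    extinct: Sequence[str],
    survivors: Sequence[str],
) -> pd.Series:
    """Extinct species ranked by the branch length their return would add."""
    extinct = list(extinct)
    if set(extinct) & set(survivors):
        raise ValueError("extinct and surviving sets overlap")
    base = functional_diversity(dendro, survivors)
    gains = {s: functional_diversity(dendro, set(survivors) | {s}) - base
             for s in extinct}
    series = pd.Series(gains, name="fd_gain")
    return series.sort_values(ascending=False, kind="stable").reindex(
        sorted(gains, key=lambda s: (-gains[s], s)))


def guild_profiles(net: InteractionNetwork, guild: str) -> pd.DataFrame:
    """Incidence block whose columns are the *guild*'s species.

    Rows are the opposite guild; an entry is 1 when the row species has an
    edge toward the column species' guild member -- i.e. the matrix of
    edges incoming to the opposite guild is transposed so that each scored
    species is one column, mirroring the trait-matrix construction.
    """
    if guild == POLLINATOR:
        rows, cols = net.plants, net.pollinators
    elif guild == PLANT:
        rows, cols = net.pollinators, net.plants
    else:
        raise ValueError(f"unknown guild {guild!r}")
    m = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for u, v in net.graph.edges:
        if guild_of(u) == guild and v in m.index:
            m.loc[v, u] = 1
    return m
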