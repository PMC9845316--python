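"""Synthetic regional species-pool generator.

Ensembles of prototypical bipartite plant-pollinator networks: degree
sequences follow an exponentially cut-off power law
``P(k) ~ k**(-gamma) * exp(-k / kappa)``, and species trait lengths
(corolla depth, proboscis length) are drawn from right-skewed skew-normal
distributions.  Interaction signs then follow deterministically from the
trait match (see :mod:`motifpol.network`).

The default distribution parameters are documented choices, not fitted
values: gamma=2.5 / kappa=20 is typical of empirical pollination webs, and
the mm-scale skew-normal triples are chosen so that roughly 7.7% of the
regional-pool interactions are mutually beneficial, the hallmark proportion
of this model family (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .network import (InteractionNetwork, SpeciesNode, PLANT, POLLINATOR,
                      classify_interaction, MATCH_LO, MATCH_HI, W_POS, W_NEG)


@dataclass(frozen=True)
class DegreeDist:
    """Exponentially cut-off power law ``P(k) ~ k**-gamma * exp(-k/kappa)``."""

    gamma: float = 1.8
    kappa: float = 20.0

    def pmf(self, k_max: int) -> np.ndarray:
        if self.gamma <= 1 or self.kappa <= 0:
            raise ValueError("need gamma > 1 and kappa > 0")
        k = np.arange(1, k_max + 1, dtype=float)
        w = k ** (-self.gamma) * np.exp(-k / self.kappa)
        return w / w.sum()


@dataclass(frozen=True)
class TraitDist:
    """Skew-normal trait-length distribution (location/scale in length units)."""

    location: float
    scale: float
    shape: float

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.scale <= 0:
            raise ValueError("scale must be positive")
        dist = stats.skewnorm(self.shape, loc=self.location, scale=self.scale)
        out = dist.rvs(size=n, random_state=rng)
        bad = out <= 0  # lengths must be positive: resample the offenders
        while bad.any():
            out[bad] = dist.rvs(size=int(bad.sum()), random_state=rng)
            bad = out <= 0
        return out


class UnrealizableDegreeSequenceError(RuntimeError):
    """Sampled degree sequence admits no simple bipartite realization."""


#: defaults chosen so the regional pool shows ~7.7% mutual interactions
DEFAULT_PLANT_TRAITS = TraitDist(location=1.0, scale=8.0, shape=4.0)
DEFAULT_POLLINATOR_TRAITS = TraitDist(location=1.0, scale=6.0, shape=4.0)


@dataclass(frozen=True)
class EnsembleConfig:
    """Everything needed to generate one network of the ensemble."""

    n_plants: int = 25
    n_pollinators: int = 25
    degree_dist: DegreeDist = field(default_factory=DegreeDist)
    plant_traits: TraitDist = field(default_factory=lambda: DEFAULT_PLANT_TRAITS)
    pollinator_traits: TraitDist = field(default_factory=lambda: DEFAULT_POLLINATOR_TRAITS)
    match_lo: float = MATCH_LO
    match_hi: float = MATCH_HI
    w_pos: int = W_POS
    w_neg: int = W_NEG
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plants < 1 or self.n_pollinators < 1:
            raise ValueError("guild sizes must be >= 1")
        if not (0 < self.match_lo < 1 < self.match_hi):
            raise ValueError("need 0 < match_lo < 1 < match_hi")
        if not (self.w_pos > abs(self.w_neg) > 0):
            raise ValueError("need w_pos > |w_neg| > 0")


def sample_bipartite_degrees(
    n_plants: int,
    n_pollinators: int,
    degree_dist: DegreeDist,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired degree sequences with equal totals.

    Each side is sampled independently from the cut-off power law (degrees
    capped at the opposite guild size), then the smaller-total side is
    repaired by incrementing/decrementing randomly chosen degrees until the
    stub counts match.
    """
    if n_plants < 1 or n_pollinators < 1:
        raise ValueError("guild sizes must be >= 1")
    k_pl = rng.choice(np.arange(1, n_pollinators + 1), size=n_plants,
                      p=degree_dist.pmf(n_pollinators))
    k_po = rng.choice(np.arange(1, n_plants + 1), size=n_pollinators,
                      p=degree_dist.pmf(n_plants))
    k_pl = k_pl.astype(int)
    k_po = k_po.astype(int)

    target = (k_pl.sum() + k_po.sum()) // 2
    target = max(target, n_plants, n_pollinators)  # every species keeps degree >= 1
    if target > n_plants * n_pollinators:
        raise ValueError("required stub total exceeds the bipartite capacity")

    def repair(seq: np.ndarray, cap: int) -> np.ndarray:
        while seq.sum() != target:
            i = rng.integers(len(seq))
            if seq.sum() < target and seq[i] < cap:
                seq[i] += 1
            elif seq.sum() > target and seq[i] > 1:
                seq[i] -= 1
        return seq

    k_pl = repair(k_pl, n_pollinators)
    k_po = repair(k_po, n_plants)
    return k_pl, k_po


def assign_trait_lengths(n: int, trait_dist: TraitDist, rng: np.random.Generator) -> np.ndarray:
    """*n* positive trait lengths (non-positive draws are resampled)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return trait_dist.sample(n, rng)


def _match_stubs(k_pl: np.ndarray, k_po: np.ndarray,
                 rng: np.random.Generator, max_rounds: int = 200) -> set[tuple[int, int]]:
    """Configuration-model stub matching without multi-edges.

    Pollinator stubs are shuffled against plant stubs; colliding pairings
    are re-drawn by random pairwise swaps.
    """
    from collections import Counter

    pl_stubs = np.repeat(np.arange(len(k_pl)), k_pl)
    po_stubs = np.repeat(np.arange(len(k_po)), k_po)
    assert len(pl_stubs) == len(po_stubs)
    for _ in range(max_rounds):
        rng.shuffle(po_stubs)
        pairs = list(zip(pl_stubs.tolist(), po_stubs.tolist()))
        counts = Counter(pairs)
        for _ in range(50 * len(pairs)):
            dup = next((i for i, p in enumerate(pairs) if counts[p] > 1), None)
            if dup is None:
                return set(pairs)
            j = int(rng.integers(len(pairs)))
            a, b = pairs[dup], pairs[j]
            na, nb = (a[0], b[1]), (b[0], a[1])
            if j != dup and counts[na] == 0 and counts[nb] == 0 and na != nb:
                counts[a] -= 1
                counts[b] -= 1
                counts[na] += 1
                counts[nb] += 1
                pairs[dup], pairs[j] = na, nb
        if max(counts.values()) == 1:
            return set(pairs)

    # fallback: greedy largest-first realization, randomized by edge swaps
    remaining = list(enumerate(k_pl.tolist()))
    edges: set[tuple[int, int]] = set()
    for j in sorted(range(len(k_po)), key=lambda j: -k_po[j]):
        remaining.sort(key=lambda t: -t[1])
        if k_po[j] > sum(1 for _, c in remaining if c > 0):
            raise UnrealizableDegreeSequenceError(
                "degree sequence is not bipartite-realizable")
        for idx in range(int(k_po[j])):
            i, c = remaining[idx]
            edges.add((i, j))
            remaining[idx] = (i, c - 1)
    edge_list = sorted(edges)
    for _ in range(10 * len(edge_list)):
        a, b = (edge_list[int(rng.integers(len(edge_list)))] for _ in range(2))
        if a[0] != b[0] and a[1] != b[1]:
            na, nb = (a[0], b[1]), (b[0], a[1])
            if na not in edges and nb not in edges:
                edges.discard(a)
                edges.discard(b)
                edges.add(na)
                edges.add(nb)
                edge_list = sorted(edges)
    return edges


def generate_network(config: EnsembleConfig) -> InteractionNetwork:
    """One regional species-pool network, deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    for _ in range(20):  # resample on (rare) unrealizable degree sequences
        k_pl, k_po = sample_bipartite_degrees(
            config.n_plants, config.n_pollinators, config.degree_dist, rng)
        try:
            pairs = _match_stubs(k_pl, k_po, rng)
            break
        except UnrealizableDegreeSequenceError:
            continue
    else:
        raise UnrealizableDegreeSequenceError(
            "no realizable degree sequence after 20 attempts")
    l_pl = assign_trait_lengths(config.n_plants, config.plant_traits, rng)
    l_po = assign_trait_lengths(config.n_pollinators, config.pollinator_traits, rng)

    net = InteractionNetwork()
    for i in range(config.n_plants):
        net.add_species(SpeciesNode(f"pl_{i + 1}", PLANT, float(l_pl[i])))
    for i in range(config.n_pollinators):
        net.add_species(SpeciesNode(f"po_{i + 1}", POLLINATOR, float(l_po[i])))

    for i, j in sorted(pairs):
        plant, pollinator = f"pl_{i + 1}", f"po_{j + 1}"
        sign_pair = classify_interaction(
            float(l_pl[i]), float(l_po[j]), config.match_lo, config.match_hi)
        net.add_interaction(plant, pollinator, sign_pair,
                            w_pos=config.w_pos, w_neg=config.w_neg)
    net.validate()
    return net


def generate_ensemble(config: EnsembleConfig, n_networks: int) -> list[InteractionNetwork]:
    """Independent networks with per-network child seeds spawned from ``config.seed``."""
    seeds = np.random.SeedSequence(config.seed).spawn(n_networks)
    out = []
    for ss in seeds:
        child = int(ss.generate_state(1)[0] % (2 ** 31))
        cfg = EnsembleConfig(
            n_plants=config.n_plants, n_pollinators=config.n_pollinators,
            degree_dist=config.degree_dist, plant_traits=config.plant_traits,
            pollinator_traits=config.pollinator_traits, match_lo=config.match_lo,
            match_hi=config.match_hi, w_pos=config.w_pos, w_neg=config.w_neg,
            seed=child)
        out.append(generate_network(cfg))
    return out
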