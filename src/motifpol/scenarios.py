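"""Extinction, blocking and restoration experiment pipelines.

Every experiment starts from the *maximal richness community* (the
attractor with the most established species) and perturbs it:

* **extinction**: fix a species set to the inactive state, percolate the
  cascade, and measure the *damage percentage* -- the share of the other
  established species that are lost.  Driver sets of inactive stable
  motifs/motif groups are compared with equally sized non-driver sets,
  partial driver sets, and candidates picked by structural measures;
* **blocking**: protect the driver species of the largest inactive motif
  (they are pinned present and excluded from extinction choices) and
  compare the damage with the unprotected arm;
* **restoration**: starting from the worst same-size driver-set damage,
  re-introduce species chosen either as driver sets of active stable
  motifs or from the top functional-diversity contributors, and measure
  the share of extinct species recovered; chosen sets are optionally
  re-verified on the original threshold rules, where the simplified model
  may overestimate the reach of an active state;
* **attractor control**: for every attractor holding at least a given
  fraction of the maximal richness, report the minimal control-set size.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .attractors import Attractor, ModelAnalysis, percolate
from .expanded import StableMotif, find_driver_sets
from .logic import SimplifiedModel
from .measures import (betweenness_ranking, fd_restoration_ranking,
                       fd_dendrogram, guild_profiles, musrank,
                       nestedness_contribution)
from .network import PLANT, POLLINATOR
from .threshold import rules_from_network, pinned_attractor


@dataclass
class DamageReport:
    network_id: str
    extinct: frozenset
    pre: Attractor
    post: Attractor
    damage_pct: float


@dataclass
class RestorationReport:
    network_id: str
    damaged: Attractor
    restored: frozenset
    post: Attractor
    restoration_pct: float
    restoration_pct_excl: float
    flavor: str = "simplified"  # or "threshold"


# -- single perturbations --------------------------------------------------

def synchronous_closure(model: SimplifiedModel, initial: Mapping[str, bool],
                        pins: Mapping[str, bool]) -> tuple[dict[str, bool], tuple[str, ...]]:
    """Deterministic synchronous closure of the pinned simplified dynamics.

    Returns the node-wise stable state of the reached attractor and the
    species oscillating within it (counted as not stably established).
    """
    state = {s: bool(initial[s]) for s in model.rules}
    state.update(pins)
    order = sorted(model.rules)
    seen: dict[tuple, int] = {}
    trace = []
    for i in range(2 ** 14):
        key = tuple(state[s] for s in order)
        if key in seen:
            cycle = trace[seen[key]:]
            stable = {s: all(st[s] for st in cycle) for s in order}
            free = tuple(s for s in order
                         if any(st[s] for st in cycle) and not stable[s])
            return stable, free
        seen[key] = i
        trace.append(dict(state))
        state = {s: rule.evaluate(state) for s, rule in model.rules.items()}
        state.update(pins)
    raise RuntimeError("synchronous closure did not repeat")


def _pinned_trap_state(model: SimplifiedModel, attractor: Attractor,
                       pins: dict[str, bool]) -> Attractor:
    """Percolate pins; untouched species keep their pre-perturbation state.

    When the overlay is a fixed point of the pinned dynamics it is returned
    directly (the usual case: the perturbed model reached from an attractor
    has a single attractor).  A retained inhibitor on a feedback loop can
    instead leave species oscillating; then the synchronous closure decides
    their stable status.
    """
    pre = attractor.state_dict
    assign = percolate(model.rules, pins)
    full = {s: assign.get(s, pre[s]) for s in model.rules}
    if all(s in pins or rule.evaluate(full) == full[s]
           for s, rule in model.rules.items()):
        return Attractor(states=tuple(sorted(full.items())))
    stable, free = synchronous_closure(model, full, pins)
    return Attractor(states=tuple(sorted(stable.items())), free=free)


def apply_extinction(model: SimplifiedModel, attractor: Attractor,
                     extinct: Iterable[str]) -> Attractor:
    """Attractor after pinning *extinct* inactive and percolating the cascade."""
    extinct = frozenset(extinct)
    pre = attractor.state_dict
    not_active = [e for e in extinct if not pre.get(e, False)]
    if not_active:
        raise ValueError(f"already-extinct species are not candidates: {not_active}")
    return _pinned_trap_state(model, attractor, {e: False for e in extinct})


def damage_percentage(pre: Attractor, post: Attractor,
                      extinct: Iterable[str]) -> float:
    """Percent of the other established species lost to the cascade.

    The initially extinguished species are excluded from both the numerator
    and the denominator.
    """
    extinct = frozenset(extinct)
    denom = pre.richness - len(extinct)
    if denom <= 0:
        raise ZeroDivisionError("no species left to measure damage on")
    lost = (pre.active - post.active) - extinct
    return 100.0 * len(lost) / denom


def apply_restoration(model: SimplifiedModel, damaged: Attractor,
                      restored: Iterable[str]) -> Attractor:
    """Attractor after pinning *restored* active and percolating."""
    return _pinned_trap_state(model, damaged, {r: True for r in frozenset(restored)})


def restoration_percentages(extinct: frozenset, post: Attractor,
                            restored: frozenset) -> tuple[float, float]:
    """(inclusive, exclusive) share of extinct species that are back.

    The inclusive tally counts the re-introduced species themselves (they
    are present post-restoration); the exclusive tally drops them from
    numerator and denominator.
    """
    recovered = extinct & post.active
    inclusive = 100.0 * len(recovered) / len(extinct) if extinct else 0.0
    rest = extinct - restored
    exclusive = 100.0 * len(recovered - restored) / len(rest) if rest else 0.0
    return inclusive, exclusive


# -- candidate machinery ---------------------------------------------------

def inactive_vertices(analysis: ModelAnalysis) -> list:
    return [m for m in list(analysis.stable_motifs) + list(analysis.groups)
            if m.polarity == "all-inactive"]


def active_stable_motifs(analysis: ModelAnalysis) -> list[StableMotif]:
    return [m for m in analysis.stable_motifs if m.polarity == "all-active"]


def inactive_driver_sets(
    analysis: ModelAnalysis,
    size: int,
    active_pool: frozenset,
    max_size: int | None = None,
) -> list[frozenset]:
    """Driver sets (of inactive motifs/groups) of exactly *size* species.

    Only sets whose species are all established in the reference community
    qualify -- already-absent species cannot go extinct.
    """
    max_size = size if max_size is None else max_size
    out: set[frozenset] = set()
    for m in inactive_vertices(analysis):
        for ds in find_driver_sets(m, analysis.expnet, max_size=max_size):
            if len(ds) == size and all(n in active_pool for n, _ in ds):
                out.add(frozenset(n for n, _ in ds))
    return sorted(out, key=sorted)


def _subsample(pool: list, k: int, cap: int, rng: np.random.Generator) -> list:
    """All k-subsets of *pool*, or a seeded subsample of *cap* of them."""
    n_total = math.comb(len(pool), k)
    if n_total <= cap:
        return [frozenset(c) for c in itertools.combinations(pool, k)]
    picks = set()
    pool = list(pool)
    while len(picks) < cap:
        picks.add(frozenset(rng.choice(pool, size=k, replace=False).tolist()))
    return sorted(picks, key=sorted)


def _structural_pool(analysis: ModelAnalysis, measure: str) -> list[str]:
    """Top/bottom-10% candidate pool for a structural measure."""
    net = analysis.model.network
    n = len(net.species)
    k = math.ceil(0.1 * n)
    if measure == "betweenness":
        scores = betweenness_ranking(net)
        ranked = scores.sort_values(ascending=False, kind="stable")
    elif measure == "nestedness":
        scores = nestedness_contribution(net)
        ranked = scores.sort_values(ascending=True, kind="stable")  # lowest first
    elif measure in ("musrank_plant", "musrank_pollinator"):
        importance, vulnerability = musrank(net)
        guild = POLLINATOR if measure.endswith("pollinator") else PLANT
        scores = importance if guild == POLLINATOR else vulnerability
        k = math.ceil(0.1 * len(scores))
        ranked = scores.sort_values(ascending=False, kind="stable")
    else:
        raise ValueError(f"unknown structural measure {measure!r}")
    ranked = ranked.reindex(sorted(ranked.index, key=lambda s: (-ranked[s], s)))
    return list(ranked.index[:k])


def extinction_experiment(
    analyses: Sequence[tuple[str, ModelAnalysis]],
    mode: str,
    size: int,
    rng: np.random.Generator,
    set_cap: int = 1000,
) -> pd.DataFrame:
    """Per-network average damage for one extinction mode and set size.

    Modes: ``driver`` (driver sets of inactive motifs/groups),
    ``nondriver`` (same-size sets avoiding every driver-set member of the
    examined size), ``partial_driver`` (half of a 4-node driver set plus
    random non-drivers), and ``structural:<measure>`` with measure one of
    betweenness / nestedness / musrank_plant / musrank_pollinator.
    Networks with no qualifying sets are skipped (reported with NaN).
    """
    rows = []
    for net_id, analysis in analyses:
        maxrich = analysis.maximal_richness
        active = frozenset(maxrich.active)
        if not active:
            rows.append((net_id, mode, size, float("nan"), 0))
            continue
        driver_sets = inactive_driver_sets(analysis, size, active)

        if mode == "driver":
            sets = driver_sets
        elif mode == "nondriver":
            # non-drivers must not drive any inactive motif at any size up
            # to the examined one, else pairs containing a singleton driver
            # would masquerade as non-driver extinctions
            members: set[str] = set()
            for k in range(1, size + 1):
                for ds in inactive_driver_sets(analysis, k, active):
                    members |= ds
            pool = sorted(active - members)
            sets = _subsample(pool, size, set_cap, rng) if len(pool) >= size else []
        elif mode == "partial_driver":
            if size != 4:
                raise ValueError("the partial-driver comparison uses size 4")
            full_sets = inactive_driver_sets(analysis, 4, active)
            members = set()
            for k in range(1, 5):
                for ds in inactive_driver_sets(analysis, k, active):
                    members |= ds
            pool = sorted(active - members) if full_sets else []
            sets = []
            for ds in full_sets:
                if len(pool) < 2:
                    continue
                part = rng.choice(sorted(ds), size=2, replace=False).tolist()
                filler = rng.choice(pool, size=2, replace=False).tolist()
                sets.append(frozenset(part + filler))
        elif mode.startswith("structural:"):
            pool = [s for s in _structural_pool(analysis, mode.split(":", 1)[1])
                    if s in active]
            sets = _subsample(pool, size, set_cap, rng) if len(pool) >= size else []
        else:
            raise ValueError(f"unknown mode {mode!r}")

        damages = []
        for ext in sets:
            if maxrich.richness - len(ext) <= 0:
                continue
            post = apply_extinction(analysis.model, maxrich, ext)
            damages.append(damage_percentage(maxrich, post, ext))
        rows.append((net_id, mode, size,
                     float(np.mean(damages)) if damages else float("nan"),
                     len(damages)))
    return pd.DataFrame(rows, columns=["network_id", "mode", "size",
                                       "mean_damage_pct", "n_sets"])


# -- blocking --------------------------------------------------------------

def largest_inactive_vertex(analysis: ModelAnalysis):
    """Largest inactive stable motif or motif group.

    Size is the virtual-node count; ties break by larger LDOI, then by
    canonical label order.
    """
    from .expanded import ldoi_expanded

    candidates = inactive_vertices(analysis)
    if not candidates:
        return None
    return sorted(
        candidates,
        key=lambda m: (-len(m.states),
                       -len(ldoi_expanded(analysis.expnet, m.states)),
                       m.key))[0]


def blocking_experiment(
    net_id: str,
    analysis: ModelAnalysis,
    rng: np.random.Generator,
    max_driver_size: int = 4,
    set_cap: int = 200,
) -> dict | None:
    """Mean damage with vs without protecting the largest inactive motif.

    All driver sets of the largest inactive stable motif or motif group are
    identified; in the blocked arm those driver species are pinned present
    (excluded from extinction choices), so no complete driver set can be
    extinguished.  Both arms draw extinction sets of the same size (the
    motif's minimal driver-set size).
    """
    maxrich = analysis.maximal_richness
    active = frozenset(maxrich.active)
    target = largest_inactive_vertex(analysis)
    if target is None:
        return None
    driver_sets = [frozenset(n for n, _ in ds)
                   for ds in find_driver_sets(target, analysis.expnet,
                                              max_size=max_driver_size)]
    driver_sets = [ds for ds in driver_sets if ds <= active]
    if not driver_sets:
        return None
    size = min(len(ds) for ds in driver_sets)
    protected = frozenset().union(*driver_sets)

    def arm(pool: Iterable[str]) -> float | None:
        pool = sorted(pool)
        if len(pool) < size:
            return None
        damages = []
        for ext in _subsample(pool, size, set_cap, rng):
            if maxrich.richness - len(ext) <= 0:
                continue
            post = apply_extinction(analysis.model, maxrich, ext)
            damages.append(damage_percentage(maxrich, post, ext))
        return float(np.mean(damages)) if damages else None

    blocked = arm(active - protected)
    unblocked = arm(active)
    if blocked is None or unblocked is None:
        return None
    return {"network_id": net_id, "size": size,
            "blocked_mean_damage": blocked, "unblocked_mean_damage": unblocked,
            "protected": sorted(protected)}


# -- restoration -----------------------------------------------------------

def worst_driver_damage(analysis: ModelAnalysis, size: int) -> tuple[Attractor, frozenset] | None:
    """Most-damaged community reachable by one size-*size* driver extinction."""
    maxrich = analysis.maximal_richness
    active = frozenset(maxrich.active)
    best: tuple[int, tuple, Attractor, frozenset] | None = None
    for ext in inactive_driver_sets(analysis, size, active):
        if maxrich.richness - len(ext) <= 0:
            continue
        post = apply_extinction(analysis.model, maxrich, ext)
        extinct = maxrich.active - post.active
        key = (-len(extinct), post.states)
        if best is None or key < (best[0], best[1]):
            best = (key[0], key[1], post, frozenset(extinct))
    if best is None:
        return None
    return best[2], best[3]


def restoration_by_motif_drivers(
    net_id: str,
    analysis: ModelAnalysis,
    damaged: Attractor,
    size: int,
) -> list[RestorationReport]:
    """Restore via driver sets (size <= *size*) of active stable motifs.

    Each qualifying driver set whose species are all currently extinct is
    one data point: its species are pinned present, the benefit cascade is
    percolated, and the share of extinct species recovered is recorded.
    """
    maxrich = analysis.maximal_richness
    extinct = maxrich.active - damaged.active
    reports = []
    for motif in active_stable_motifs(analysis):
        for ds in find_driver_sets(motif, analysis.expnet, max_size=size):
            species = frozenset(n for n, _ in ds)
            if not species <= extinct:
                continue
            post = apply_restoration(analysis.model, damaged, species)
            inc, exc = restoration_percentages(frozenset(extinct), post, species)
            reports.append(RestorationReport(
                network_id=net_id, damaged=damaged, restored=species,
                post=post, restoration_pct=inc, restoration_pct_excl=exc))
    return reports


def fd_candidate_pool(analysis: ModelAnalysis, damaged: Attractor) -> list[str]:
    """Top-10% extinct species by added functional-diversity branch length.

    One dendrogram per guild (the incidence is directed); extinct species
    are scored by the branch length their return adds over the survivors
    of their own guild, then pooled and cut at the top 10% of the
    community size (ties resolved canonically).
    """
    model = analysis.model
    maxrich = analysis.maximal_richness
    extinct = sorted(maxrich.active - damaged.active)
    survivors = damaged.active
    gains: dict[str, float] = {}
    for guild in (PLANT, POLLINATOR):
        profiles = guild_profiles(model.network, guild)
        members = [s for s in profiles.columns]
        dendro = fd_dendrogram(profiles)
        guild_ext = [s for s in extinct if s in members]
        guild_sur = [s for s in members if s in survivors]
        if not guild_ext:
            continue
        ranking = fd_restoration_ranking(dendro, guild_ext, guild_sur)
        gains.update(ranking.to_dict())
    k = math.ceil(0.1 * len(model.network.species))
    ranked = sorted(gains, key=lambda s: (-gains[s], s))
    return ranked[:k]


def restoration_by_functional_diversity(
    net_id: str,
    analysis: ModelAnalysis,
    damaged: Attractor,
    size: int,
    rng: np.random.Generator,
    set_cap: int = 200,
) -> list[RestorationReport]:
    """Restore *size* species drawn from the top functional-diversity pool."""
    maxrich = analysis.maximal_richness
    extinct = maxrich.active - damaged.active
    pool = [s for s in fd_candidate_pool(analysis, damaged) if s in extinct]
    if len(pool) < size:
        return []
    reports = []
    for chosen in _subsample(pool, size, set_cap, rng):
        post = apply_restoration(analysis.model, damaged, chosen)
        inc, exc = restoration_percentages(frozenset(extinct), post, chosen)
        reports.append(RestorationReport(
            network_id=net_id, damaged=damaged, restored=frozenset(chosen),
            post=post, restoration_pct=inc, restoration_pct_excl=exc))
    return reports


def verify_restoration_on_threshold(
    analysis: ModelAnalysis,
    damaged: Attractor,
    restored: frozenset,
    net_id: str = "",
) -> RestorationReport:
    """Re-check a chosen restoration set on the original threshold rules.

    The restored species are pinned present in the threshold model of the
    pruned network and the synchronous dynamics are closed from the damaged
    state; species oscillating in a limit cycle do not count as stably
    re-established.  The simplified model can only overestimate the reach
    of active states, so the threshold percentage is at most the
    simplified one (discrepancies are flagged by the caller).
    """
    thr_rules = rules_from_network(analysis.model.pruned_network)
    initial = {s: int(v) for s, v in damaged.states}
    stable = pinned_attractor(thr_rules, initial, {r: 1 for r in restored})
    post = Attractor(states=tuple(sorted((s, bool(v)) for s, v in stable.items())))
    maxrich = analysis.maximal_richness
    extinct = maxrich.active - damaged.active
    inc, exc = restoration_percentages(frozenset(extinct), post, restored)
    return RestorationReport(network_id=net_id, damaged=damaged,
                             restored=restored, post=post,
                             restoration_pct=inc, restoration_pct_excl=exc,
                             flavor="threshold")


# -- attractor-control restoration ----------------------------------------

def restoration_control_experiment(
    analysis: ModelAnalysis,
    richness_fraction: float = 0.7,
    max_driver_size: int = 4,
    max_candidates: int = 10_000,
) -> pd.DataFrame:
    """Minimal control-set sizes for the high-richness attractors.

    Every attractor holding at least ``richness_fraction`` of the maximal
    richness is a target; its control set is the union of one driver set
    per member of its defining combination, and the minimum union size is
    bucketed by richness band (70-80 / 80-90 / 90-100%).
    """
    from .attractors import control_sets_of_attractor

    maxrich = analysis.maximal_richness
    if maxrich.richness == 0:
        return pd.DataFrame(columns=["richness_pct", "band", "min_control_size",
                                     "complete"])
    driver_cache: dict[object, list[frozenset]] = {}
    rows = []
    for att in analysis.attractors:
        pct = 100.0 * att.richness / maxrich.richness
        if pct < 100.0 * richness_fraction:
            continue
        for m in att.combination:
            if m not in driver_cache:
                driver_cache[m] = find_driver_sets(
                    m, analysis.expnet, max_size=max_driver_size)
        sets, complete = control_sets_of_attractor(
            att, driver_cache, analysis.model.rules, max_candidates,
            expnet=analysis.expnet)
        band = ("90-100" if pct >= 90 else "80-90" if pct >= 80 else "70-80")
        rows.append((pct, band,
                     min((len(s) for s in sets), default=float("nan")),
                     complete))
    return pd.DataFrame(rows, columns=["richness_pct", "band",
                                       "min_control_size", "complete"])
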