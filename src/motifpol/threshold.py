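"""Boolean threshold dynamics and the worst-case LDOI search.

Each species ``i`` updates synchronously via a threshold rule

    sigma_i(t+1) = H( sum_j E(j, i) * sigma_j(t) ),

with ``H(x) = 1`` iff ``x > 0``.  A species is present when its population
is above a persistence threshold; it needs net positive support from its
interaction partners to establish or persist.

The logical domain of influence (LDOI) of a set of pinned node states is
computed directly on the threshold rules by breadth-first propagation over
out-neighbours, deciding sufficiency under a worst-case assumption about
every regulator whose state is still unknown:

* to conclude a node is forced *active*, unknown positive regulators are
  assumed inactive and unknown negative regulators active (minimal sum);
* to conclude it is forced *inactive*, unknown positive regulators are
  assumed active and unknown negatives inactive (maximal sum).

Nodes failing every sufficiency check are revisited whenever one of their
regulators acquires a state.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .network import InteractionNetwork

#: a virtual state: (species id, state); True = active / present
VirtualState = tuple[str, bool]


class InconsistentStatesError(ValueError):
    """A species was asked to hold both states at once."""


@dataclass(frozen=True)
class ThresholdRule:
    """Weighted-sum-threshold update function of one species."""

    target: str
    regulators: tuple[tuple[str, int], ...]  # (regulator id, weight)

    def __post_init__(self) -> None:
        names = [r for r, _ in self.regulators]
        if len(names) != len(set(names)):
            raise ValueError(f"duplicate regulator in rule for {self.target}")

    @property
    def positives(self) -> tuple[str, ...]:
        return tuple(r for r, w in self.regulators if w > 0)

    @property
    def negatives(self) -> tuple[str, ...]:
        return tuple(r for r, w in self.regulators if w < 0)


def rules_from_network(net: InteractionNetwork) -> dict[str, ThresholdRule]:
    """One threshold rule per species, read off the in-edges."""
    return {s: ThresholdRule(s, tuple(net.in_edges(s))) for s in net.species}


def synchronous_step(rules: Mapping[str, ThresholdRule],
                     state: Mapping[str, int]) -> dict[str, int]:
    """One synchronous update of a full state assignment."""
    missing = set(state) - set(rules)
    if missing:
        raise KeyError(f"no rule for species: {sorted(missing)}")
    nxt = {}
    for s, rule in rules.items():
        total = sum(w * state[r] for r, w in rule.regulators)
        nxt[s] = 1 if total > 0 else 0
    return nxt


def find_attractor_synchronous(
    rules: Mapping[str, ThresholdRule],
    initial: Mapping[str, int],
    max_steps: int = 10000,
) -> list[dict[str, int]]:
    """Attractor reached from *initial*: the repeating state sequence.

    Fixed points come back as length-1 cycles.  Deterministic finite
    dynamics must repeat within ``2**n`` steps; *max_steps* is a guard.
    """
    if set(initial) != set(rules):
        raise ValueError("initial assignment must cover every species")
    order = sorted(rules)
    seen: dict[tuple[int, ...], int] = {}
    trace: list[dict[str, int]] = []
    state = dict(initial)
    for step in range(max_steps + 1):
        key = tuple(state[s] for s in order)
        if key in seen:
            return trace[seen[key]:]
        seen[key] = step
        trace.append(dict(state))
        state = synchronous_step(rules, state)
    raise RuntimeError("no repetition within max_steps")


def _check_seed_consistency(seeds: Iterable[VirtualState]) -> dict[str, bool]:
    pinned: dict[str, bool] = {}
    for name, value in seeds:
        if pinned.get(name, value) != value:
            raise InconsistentStatesError(f"contradictory seed states for {name}")
        pinned[name] = value
    return pinned


def ldoi_threshold(
    rules: Mapping[str, ThresholdRule],
    seeds: Sequence[VirtualState],
) -> set[VirtualState]:
    """Logical domain of influence of pinned states under threshold rules.

    Returns the seed states together with every node state forced by them
    under the worst-case sufficiency checks.  A derived state that would
    contradict a seed is never added (the percolation truncates there); a
    contradiction between two *derived* states raises
    :class:`InconsistentStatesError`.
    """
    pinned = _check_seed_consistency(seeds)
    known: dict[str, bool] = dict(pinned)

    # out-neighbour map: species -> set of targets it regulates
    targets: dict[str, set[str]] = {}
    for rule in rules.values():
        for r, _ in rule.regulators:
            targets.setdefault(r, set()).add(rule.target)

    queue: deque[str] = deque()
    queued: set[str] = set()

    def enqueue_targets(source: str) -> None:
        for t in sorted(targets.get(source, ())):
            if t not in known and t not in queued:
                queue.append(t)
                queued.add(t)

    for name in sorted(known):
        enqueue_targets(name)

    while queue:
        node = queue.popleft()
        queued.discard(node)
        if node in known:
            continue
        rule = rules[node]
        base = sum(w * (1 if known[r] else 0)
                   for r, w in rule.regulators if r in known)
        unknown_pos = sum(w for r, w in rule.regulators if r not in known and w > 0)
        unknown_neg = sum(w for r, w in rule.regulators if r not in known and w < 0)
        forced: bool | None = None
        if base + unknown_neg > 0:          # even maximal opposition stays positive
            forced = True
        elif base + unknown_pos <= 0:       # even maximal support stays non-positive
            forced = False
        if forced is None:
            continue  # revisited when a regulator acquires a state
        if node in pinned and pinned[node] != forced:
            continue  # truncate: never override a seed
        if node in known and known[node] != forced:
            raise InconsistentStatesError(f"derived both states for {node}")
        known[node] = forced
        enqueue_targets(node)

    return {(n, v) for n, v in known.items()}


def write_threshold_rules(rules: Mapping[str, "ThresholdRule"], path) -> None:
    """TSV serialization: one ``target<TAB>regulator<TAB>weight`` row per edge.

    Species without regulators are written with an empty regulator column
    so the round trip preserves them.
    """
    from pathlib import Path

    lines = ["target\tregulator\tweight"]
    for target, rule in sorted(rules.items()):
        if not rule.regulators:
            lines.append(f"{target}\t\t")
        for reg, w in rule.regulators:
            lines.append(f"{target}\t{reg}\t{w}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_threshold_rules(path) -> dict[str, "ThresholdRule"]:
    from pathlib import Path

    regs: dict[str, list[tuple[str, int]]] = {}
    lines = Path(path).read_text().splitlines()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ValueError(f"line {lineno}: expected 3 tab-separated fields")
        target, reg, w = parts
        regs.setdefault(target, [])
        if reg:
            regs[target].append((reg, int(w)))
    return {t: ThresholdRule(t, tuple(r)) for t, r in regs.items()}


def parse_seed_tokens(text: str) -> list[VirtualState]:
    """Parse pinned-state tokens like ``pl_3=0,po_1=1``."""
    seeds = []
    for token in text.split(","):
        token = token.strip()
        if not token:
            continue
        name, _, value = token.partition("=")
        if value not in ("0", "1"):
            raise ValueError(f"bad seed token {token!r} (want name=0 or name=1)")
        seeds.append((name.strip(), value == "1"))
    return seeds


def pinned_attractor(
    rules: Mapping[str, ThresholdRule],
    initial: Mapping[str, int],
    pins: Mapping[str, int],
) -> dict[str, int]:
    """Stationary state with some species pinned, from synchronous closure.

    Pins the given species, runs the synchronous dynamics from *initial*
    until the trajectory repeats, and returns the cycle's node-wise state
    (a node oscillating within the cycle counts as not stably active).
    """
    pinned_rules = dict(rules)
    state = dict(initial)
    for s, v in pins.items():
        pinned_rules[s] = ThresholdRule(s, ())
        state[s] = v

    def step(st: Mapping[str, int]) -> dict[str, int]:
        out = synchronous_step(pinned_rules, st)
        for s, v in pins.items():
            out[s] = v
        return out

    order = sorted(rules)
    seen: dict[tuple[int, ...], int] = {}
    trace = []
    for i in range(2 ** 14):
        key = tuple(state[s] for s in order)
        if key in seen:
            cycle = trace[seen[key]:]
            return {s: 1 if all(st[s] for st in cycle) else 0 for s in order}
        seen[key] = i
        trace.append(dict(state))
        state = step(state)
    raise RuntimeError("no repetition while closing pinned dynamics")
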