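"""Conversion of threshold rules to logical (disjunctive prime form) rules.

A threshold rule with positive weight ``+4`` and negative weight ``-1`` is a
unate Boolean function, so its complete sum of prime implicants (Blake
canonical form) can be enumerated in closed form: an implicant picks ``a``
positive regulators to be active and, if necessary, ``b`` negative
regulators to be inactive, with ``4a - (N_n - b) > 0`` and ``b`` minimal.

Conversion reveals structure the raw weights hide:

* species with no positive in-edge can never establish and are pruned
  (iterated to a fixpoint, since a removal may strip another species' only
  benefactor);
* a negative edge that appears in no prime implicant of its target has no
  functional consequence and is deleted (with one positive regulator and at
  most three negatives, the rule is equivalent to the positive regulator
  alone);
* the probability-conserving simplification replaces the full rule by the
  inhibitor-dominant form ``(P_1 | ... | P_Np) & !N_1 & ... & !N_x``, with
  ``x`` randomly retained negatives chosen so that the probability of
  activation under independent fair-coin regulators is conserved as closely
  as possible.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .network import InteractionNetwork
from .threshold import ThresholdRule, VirtualState

Implicant = frozenset  # of VirtualState literals


@dataclass(frozen=True)
class LogicRule:
    """A species' update function as a complete sum of prime implicants.

    ``implicants`` empty means the constant-0 function (the species can
    never establish); the single empty implicant means constant 1.
    """

    target: str
    implicants: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for imp in self.implicants:
            names = [n for n, _ in imp]
            if len(names) != len(set(names)):
                raise ValueError(f"implicant with contradictory literals in {self.target}")
        if len(self.implicants) <= 64:  # the quadratic audit stays cheap
            for a, b in itertools.combinations(self.implicants, 2):
                if a < b or b < a:
                    raise ValueError(f"non-prime implicant cover in {self.target}")

    @property
    def is_constant_zero(self) -> bool:
        return not self.implicants

    def variables(self) -> set[str]:
        return {n for imp in self.implicants for n, _ in imp}

    def evaluate(self, state: Mapping[str, bool]) -> bool:
        return any(all(state[n] == v for n, v in imp) for imp in self.implicants)

    def positive_literals(self) -> set[str]:
        return {n for imp in self.implicants for n, v in imp if v}

    def negative_literals(self) -> set[str]:
        return {n for imp in self.implicants for n, v in imp if not v}


# -- complete sum oracles --------------------------------------------------

def complete_sum_from_function(
    variables: Sequence[str],
    func: Callable[[Mapping[str, bool]], bool],
    max_vars: int = 16,
) -> frozenset:
    """Blake canonical form of an arbitrary Boolean function by truth table.

    Quine-McCluskey-style merging over all minterms; exponential, intended
    for small rules and as the independent oracle for the closed-form path.
    """
    n = len(variables)
    if n > max_vars:
        raise ValueError(f"truth-table enumeration capped at {max_vars} variables")
    minterms = []
    for bits in itertools.product((False, True), repeat=n):
        assign = dict(zip(variables, bits))
        if func(assign):
            minterms.append(frozenset(zip(variables, bits)))
    if not minterms:
        return frozenset()
    current = set(minterms)
    primes: set[frozenset] = set()
    while current:
        merged_away: set[frozenset] = set()
        nxt: set[frozenset] = set()
        cur = sorted(current, key=sorted)
        for a, b in itertools.combinations(cur, 2):
            diff = a ^ b
            if len(diff) == 2 and len({x for x, _ in diff}) == 1:
                nxt.add(a & b)
                merged_away.add(a)
                merged_away.add(b)
        primes |= current - merged_away
        current = nxt
    # drop non-minimal terms (supersets of other primes)
    return frozenset(p for p in primes
                     if not any(q < p for q in primes if q != p))


def threshold_to_prime_implicants(rule: ThresholdRule) -> LogicRule:
    """Complete sum of prime implicants of a +4/-1 threshold rule.

    Uses the unate coalition enumeration: implicants with ``a`` active
    positives need ``b = max(0, N_n - 4a + 1)`` inactive negatives; once
    ``b`` reaches 0, adding further positives is superfluous.
    """
    for _, w in rule.regulators:
        if w not in (4, -1):
            raise ValueError("closed form requires weights +4 / -1")
    pos, neg = sorted(rule.positives), sorted(rule.negatives)
    if not pos:
        return LogicRule(rule.target, frozenset())  # constant 0: cannot establish
    n_n = len(neg)
    implicants = []
    for a in range(1, len(pos) + 1):
        b = max(0, n_n - 4 * a + 1)
        for chosen_p in itertools.combinations(pos, a):
            p_lits = tuple((p, True) for p in chosen_p)
            for chosen_n in itertools.combinations(neg, b):
                implicants.append(frozenset(p_lits + tuple((n, False) for n in chosen_n)))
        if b == 0:
            break
    return LogicRule(rule.target, frozenset(implicants))


def functional_negatives(rule: ThresholdRule) -> set[str]:
    """Negative regulators that appear in at least one prime implicant.

    Closed form for the +4/-1 class: with at least one positive regulator,
    up to three negatives never flip the outcome (4 - 3 > 0) and all are
    superfluous; from four negatives on, every implicant with a single
    active positive must silence some of them, and by symmetry every
    negative regulator then appears in some implicant.
    """
    for _, w in rule.regulators:
        if w not in (4, -1):
            raise ValueError("closed form requires weights +4 / -1")
    if not rule.positives or len(rule.negatives) <= 3:
        return set()
    return set(rule.negatives)


def prune_nonestablishable(net: InteractionNetwork) -> InteractionNetwork:
    """Iteratively remove species lacking any positive in-edge.

    Removal strips the reciprocal partner edges too; iterates to a fixpoint
    because a removal can take away another species' only benefactor.
    """
    out = net.copy()
    while True:
        doomed = [s for s in out.species
                  if not any(w > 0 for _, w in out.in_edges(s))]
        if not doomed:
            return out
        out.graph.remove_nodes_from(doomed)


def drop_nonfunctional_negative_edges(
    net: InteractionNetwork,
    rules: Mapping[str, LogicRule],
) -> InteractionNetwork:
    """Delete negative edges absent from every prime implicant of their target.

    The reciprocal (positive) partner edge of each deleted negative edge is
    retained, so interacting species stay connected.
    """
    out = net.copy()
    for s in out.species:
        functional = rules[s].negative_literals()
        for src, w in out.in_edges(s):
            if w < 0 and src not in functional:
                out.graph.remove_edge(src, s)
    return out


def activation_probability(rule: ThresholdRule) -> float:
    """P(H > 0) with each regulator an independent fair coin (exact)."""
    n_p, n_n = len(rule.positives), len(rule.negatives)
    total = 0
    for a in range(n_p + 1):
        for n_act in range(n_n + 1):
            if 4 * a - n_act > 0:
                total += math.comb(n_p, a) * math.comb(n_n, n_act)
    return total / 2 ** (n_p + n_n)


def choose_retained_negative_count(rule: ThresholdRule) -> int:
    """The ``x`` that best conserves the activation probability.

    Candidates are ``(1 - 2**-N_p) * 2**-x`` for ``x`` in ``0..N_n``; ties
    break toward smaller ``x`` (fewer retained inhibitors).
    """
    n_p, n_n = len(rule.positives), len(rule.negatives)
    if n_p == 0:
        return 0
    p_thr = activation_probability(rule)
    best_x, best_gap = 0, float("inf")
    for x in range(n_n + 1):
        gap = abs((1 - 2.0 ** -n_p) * 2.0 ** -x - p_thr)
        if gap < best_gap - 1e-15:
            best_x, best_gap = x, gap
    return best_x


def simplify_rule(rule: ThresholdRule, rng: np.random.Generator) -> LogicRule:
    """Inhibitor-dominant simplified rule ``(OR of positives) & !N_1..!N_x``.

    The ``x`` retained negative regulators are sampled uniformly without
    replacement; every retained inhibitor can single-handedly overcome all
    positive support, standing in for the collective cost of the dropped
    negative interactions.
    """
    pos = sorted(rule.positives)
    if not pos:
        return LogicRule(rule.target, frozenset())
    neg = sorted(rule.negatives)
    x = choose_retained_negative_count(rule)
    kept = sorted(rng.choice(neg, size=x, replace=False).tolist()) if x else []
    neg_lits = tuple((n, False) for n in kept)
    return LogicRule(rule.target, frozenset(
        frozenset(((p, True),) + neg_lits) for p in pos))


def negated_rule(rule: LogicRule) -> LogicRule:
    """Complete sum of prime implicants of ``NOT f`` (for the inactive state).

    Inhibitor-dominant rules negate in closed form by De Morgan:
    ``(P_1 | .. | P_k) & !N_1 .. & !N_x`` becomes
    ``(!P_1 & .. & !P_k) | N_1 | .. | N_x``.  Other shapes fall back to the
    truth-table oracle.
    """
    if rule.is_constant_zero:
        return LogicRule(rule.target, frozenset([frozenset()]))  # constant 1
    if rule.implicants == frozenset([frozenset()]):
        return LogicRule(rule.target, frozenset())
    shared_negs = None
    positives = []
    eq2_shape = True
    for imp in rule.implicants:
        ps = [n for n, v in imp if v]
        ns = frozenset((n, v) for n, v in imp if not v)
        if len(ps) != 1:
            eq2_shape = False
            break
        if shared_negs is None:
            shared_negs = ns
        elif shared_negs != ns:
            eq2_shape = False
            break
        positives.append(ps[0])
    if eq2_shape and len(set(positives)) == len(positives):
        off_all_pos = frozenset((p, False) for p in positives)
        implicants = {off_all_pos} | {frozenset(((n, True),)) for n, _ in shared_negs}
        return LogicRule(rule.target, frozenset(implicants))
    variables = sorted(rule.variables())
    return LogicRule(rule.target, complete_sum_from_function(
        variables, lambda st: not rule.evaluate(st)))


# -- whole-network conversion pipeline ------------------------------------

@dataclass
class SimplifiedModel:
    """Simplified logical model of a pruned species pool."""

    network: InteractionNetwork            # pruned, functional edges only
    rules: dict[str, LogicRule]            # ON rules, inhibitor-dominant
    stats: dict[str, float]
    #: pruned network with its full threshold weights (pre-conversion);
    #: defaults to `network` for hand-built models
    pruned_network: InteractionNetwork | None = None

    def __post_init__(self) -> None:
        if self.pruned_network is None:
            self.pruned_network = self.network

    def off_rules(self) -> dict[str, LogicRule]:
        return {s: negated_rule(r) for s, r in self.rules.items()}


def simplify_network(net: InteractionNetwork, rng: np.random.Generator) -> SimplifiedModel:
    """Prune, convert to prime form, drop superfluous negatives, simplify."""
    pruned = prune_nonestablishable(net)
    thr_rules = {s: ThresholdRule(s, tuple(pruned.in_edges(s))) for s in pruned.species}
    # which negatives survive conversion follows in closed form; enumerating
    # the full prime-implicant sets of hub species would explode
    functional = {s: functional_negatives(r) for s, r in thr_rules.items()}
    functional_net = pruned.copy()
    for s in functional_net.species:
        for src, w in functional_net.in_edges(s):
            if w < 0 and src not in functional[s]:
                functional_net.graph.remove_edge(src, s)

    neg_edges_total = sum(1 for _, _, d in net.graph.edges(data=True) if d["weight"] < 0)
    neg_after_pruning = sum(1 for _, _, d in pruned.graph.edges(data=True) if d["weight"] < 0)
    neg_after_conversion = sum(
        1 for _, _, d in functional_net.graph.edges(data=True) if d["weight"] < 0)

    simplified: dict[str, LogicRule] = {}
    kept_neg = 0
    for s in sorted(functional_net.species):
        rule = thr_rules[s]
        simplified[s] = simplify_rule(rule, rng)
        kept_neg += len(simplified[s].negative_literals())

    final_net = functional_net.copy()
    for s in final_net.species:
        retained = simplified[s].negative_literals()
        for src, w in final_net.in_edges(s):
            if w < 0 and src not in retained:
                final_net.graph.remove_edge(src, s)

    stats = {
        "n_species_pool": float(len(net)),
        "n_species_surviving": float(len(pruned)),
        "survival_fraction": len(pruned) / max(len(net), 1),
        "neg_edges_pool": float(neg_edges_total),
        "neg_deleted_conversion_frac": (
            (neg_after_pruning - neg_after_conversion) / neg_after_pruning
            if neg_after_pruning else 0.0),
        "neg_deleted_simplification_frac": (
            (neg_after_conversion - kept_neg) / neg_after_pruning
            if neg_after_pruning else 0.0),
    }
    return SimplifiedModel(network=final_net, rules=simplified, stats=stats,
                           pruned_network=pruned)


# -- bnet-style serialization ----------------------------------------------

def _format_expr(rule: LogicRule) -> str:
    if rule.is_constant_zero:
        return "0"
    if rule.implicants == frozenset([frozenset()]):
        return "1"
    terms = []
    for imp in sorted(rule.implicants, key=sorted):
        lits = [n if v else f"!{n}" for n, v in sorted(imp)]
        terms.append(" & ".join(lits))
    return " | ".join(terms)


def write_rules(rules: Mapping[str, LogicRule], path: str | Path) -> Path:
    """bnet-style dialect: ``target, factor-expression`` per line."""
    path = Path(path)
    lines = [f"{t}, {_format_expr(r)}" for t, r in sorted(rules.items())]
    path.write_text("\n".join(lines) + "\n")
    return path


_TOKEN = re.compile(r"\s*(\(|\)|\||&|!|[A-Za-z0-9_~]+)")


class _Parser:
    """Recursive descent over the {!, &, |} dialect with parentheses."""

    def __init__(self, text: str):
        self.tokens = []
        pos = 0
        while pos < len(text):
            m = _TOKEN.match(text, pos)
            if not m:
                if text[pos:].strip():
                    raise ValueError(f"unknown token at: {text[pos:]!r}")
                break
            self.tokens.append(m.group(1))
            pos = m.end()
        self.i = 0

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def eat(self, tok=None):
        t = self.peek()
        if t is None or (tok is not None and t != tok):
            raise ValueError(f"expected {tok!r}, found {t!r}")
        self.i += 1
        return t

    def parse(self):
        node = self.or_expr()
        if self.peek() is not None:
            raise ValueError(f"trailing tokens: {self.tokens[self.i:]}")
        return node

    def or_expr(self):
        terms = [self.and_expr()]
        while self.peek() == "|":
            self.eat("|")
            terms.append(self.and_expr())
        return ("or", terms)

    def and_expr(self):
        terms = [self.atom()]
        while self.peek() == "&":
            self.eat("&")
            terms.append(self.atom())
        return ("and", terms)

    def atom(self):
        t = self.peek()
        if t == "!":
            self.eat("!")
            return ("not", self.atom())
        if t == "(":
            self.eat("(")
            node = self.or_expr()
            self.eat(")")
            return node
        name = self.eat()
        if name in ("0", "1"):
            return ("const", name == "1")
        if not re.fullmatch(r"[A-Za-z_][A-Za-z0-9_]*", name):
            raise ValueError(f"bad variable name {name!r}")
        return ("var", name)


def _eval_ast(node, state: Mapping[str, bool]) -> bool:
    kind = node[0]
    if kind == "var":
        return state[node[1]]
    if kind == "const":
        return node[1]
    if kind == "not":
        return not _eval_ast(node[1], state)
    if kind == "and":
        return all(_eval_ast(t, state) for t in node[1])
    return any(_eval_ast(t, state) for t in node[1])


def _ast_vars(node) -> set[str]:
    kind = node[0]
    if kind == "var":
        return {node[1]}
    if kind == "const":
        return set()
    if kind == "not":
        return _ast_vars(node[1])
    return set().union(*(_ast_vars(t) for t in node[1])) if node[1] else set()


def parse_expression(target: str, text: str) -> LogicRule:
    """Parse one factor expression into complete-sum prime-implicant form."""
    ast = _Parser(text).parse()
    variables = sorted(_ast_vars(ast))
    if not variables:
        value = _eval_ast(ast, {})
        return LogicRule(target, frozenset([frozenset()]) if value else frozenset())
    return LogicRule(target, complete_sum_from_function(
        variables, lambda st: _eval_ast(ast, st)))


def read_rules(path: str | Path) -> dict[str, LogicRule]:
    """Inverse of :func:`write_rules`; ``parse(print(r)) == r``."""
    rules: dict[str, LogicRule] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "," not in line:
            raise ValueError(f"line {lineno}: expected 'target, expression'")
        target, expr = line.split(",", 1)
        target = target.strip()
        try:
            rules[target] = parse_expression(target, expr.strip())
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from exc
    return rules
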