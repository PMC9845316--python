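"""Shared fixtures: generated ensembles at two scales, analyzed once."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from motifpol.attractors import ModelAnalysis, analyze
from motifpol.logic import SimplifiedModel, simplify_network
from motifpol.netgen import EnsembleConfig, generate_network


def make_models(n_plants: int, n_pollinators: int, n_networks: int,
                seed0: int = 0, min_species: int = 2) -> list[SimplifiedModel]:
    models = []
    for seed in range(seed0, seed0 + n_networks):
        cfg = EnsembleConfig(n_plants=n_plants, n_pollinators=n_pollinators, seed=seed)
        model = simplify_network(generate_network(cfg), np.random.default_rng(seed))
        if len(model.rules) >= min_species:
            models.append(model)
    return models


def brute_force_fixed_points(rules) -> set[frozenset]:
    """All synchronous fixed points by exhaustive state enumeration."""
    species = sorted(rules)
    out = set()
    for bits in itertools.product([False, True], repeat=len(species)):
        state = dict(zip(species, bits))
        if all(r.evaluate(state) == state[s] for s, r in rules.items()):
            out.add(frozenset(s for s, v in state.items() if v))
    return out


@pytest.fixture(scope="session")
def small_models() -> list[SimplifiedModel]:
    """Tiny pools (4+4) whose simplified models have at most 8 species."""
    return [m for m in make_models(4, 4, 40, seed0=100) if len(m.rules) <= 8]


@pytest.fixture(scope="session")
def midsize_analyses() -> list[tuple[str, ModelAnalysis]]:
    """Analyzed 25+25 networks used by the experiment-level tests."""
    models = make_models(25, 25, 30, seed0=0, min_species=4)
    return [(f"net{i}", analyze(m)) for i, m in enumerate(models)]
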