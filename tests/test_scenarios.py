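"""Extinction cascades, blocking, restoration and attractor control."""

import numpy as np
import pytest

from motifpol import fixtures, scenarios
from motifpol.attractors import analyze
from motifpol.scenarios import (apply_extinction, apply_restoration,
                                damage_percentage, restoration_percentages,
                                synchronous_closure)


@pytest.fixture(scope="module")
def collapse_analysis():
    return analyze(fixtures.generalist_collapse_model())


@pytest.fixture(scope="module")
def cascade_analysis():
    return analyze(fixtures.restoration_cascade_model())


def test_generalist_extinction_collapses_the_community(collapse_analysis):
    an = collapse_analysis
    maxrich = an.maximal_richness
    assert maxrich.richness == 5
    post = apply_extinction(an.model, maxrich, {"pl_2"})
    assert post.active == frozenset()
    assert damage_percentage(maxrich, post, {"pl_2"}) == 100.0


def test_peripheral_extinction_stays_local(collapse_analysis):
    an = collapse_analysis
    post = apply_extinction(an.model, an.maximal_richness, {"pl_1"})
    # pl_1 feeds nothing downstream: only the extinct species changes state
    assert an.maximal_richness.active - post.active == {"pl_1"}
    assert damage_percentage(an.maximal_richness, post, {"pl_1"}) == 0.0


def test_extinction_requires_established_species(collapse_analysis):
    an = collapse_analysis
    all_off = [a for a in an.attractors if a.richness == 0][0]
    with pytest.raises(ValueError):
        apply_extinction(an.model, all_off, {"pl_2"})


def test_damage_percentage_hand_case():
    from motifpol.attractors import Attractor
    pre = Attractor(states=(("a", True), ("b", True), ("c", True), ("d", True)))
    post = Attractor(states=(("a", False), ("b", False), ("c", True), ("d", False)))
    # 'a' was the initial extinction; b and d cascaded: 2 of 3 remaining
    assert damage_percentage(pre, post, {"a"}) == pytest.approx(200 / 3)


def test_extinction_equals_synchronous_simulation(small_models):
    """Percolation overlay equals the synchronous closure oracle."""
    rng = np.random.default_rng(0)
    checked = 0
    for model in small_models:
        an = analyze(model)
        maxrich = an.maximal_richness
        if maxrich.richness < 2 or maxrich.free:
            continue
        active = sorted(maxrich.active)
        ext = {active[int(rng.integers(len(active)))]}
        post = apply_extinction(model, maxrich, ext)
        stable, free = synchronous_closure(model, maxrich.state_dict,
                                           {e: False for e in ext})
        assert post.state_dict == stable
        checked += 1
    assert checked >= 5


def test_single_attractor_after_extinction(midsize_analyses):
    """Extinction from the maximal richness community has one outcome: the
    percolated trap state is a fixed point of the pinned dynamics and the
    synchronous closure lands on exactly the same state."""
    rng = np.random.default_rng(1)
    for _, an in midsize_analyses:
        maxrich = an.maximal_richness
        if maxrich.richness < 2 or maxrich.free:
            continue
        active = sorted(maxrich.active)
        for _ in range(3):
            k = int(rng.integers(1, min(3, len(active)) + 1))
            ext = set(rng.choice(active, size=k, replace=False).tolist())
            post = apply_extinction(an.model, maxrich, ext)
            stable, _ = synchronous_closure(an.model, maxrich.state_dict,
                                            {e: False for e in ext})
            assert post.state_dict == stable


def test_restoring_the_generalist_rebuilds_everything(cascade_analysis):
    an = cascade_analysis
    maxrich = an.maximal_richness
    assert maxrich.richness == 6
    damaged = apply_extinction(an.model, maxrich, {"po_1", "po_2"})
    assert damaged.active == frozenset()  # the double loss cascades fully
    post = apply_restoration(an.model, damaged, {"pl_2"})
    assert post.active == maxrich.active
    extinct = maxrich.active - damaged.active
    inc, exc = restoration_percentages(extinct, post, frozenset({"pl_2"}))
    assert inc == 100.0 and exc == 100.0


def test_restoration_tallies_inclusive_and_exclusive():
    from motifpol.attractors import Attractor
    post = Attractor(states=(("a", True), ("b", True), ("c", False)))
    inc, exc = restoration_percentages(frozenset({"a", "b", "c"}), post,
                                       restored=frozenset({"a"}))
    assert inc == pytest.approx(200 / 3)  # a and b of three extinct
    assert exc == pytest.approx(50.0)     # b of the two not re-introduced


def test_driver_extinctions_outdamage_nondriver_extinctions(midsize_analyses):
    rng = np.random.default_rng(2)
    for size in (1, 2):
        drv = scenarios.extinction_experiment(midsize_analyses, "driver", size, rng)
        non = scenarios.extinction_experiment(midsize_analyses, "nondriver", size,
                                              rng, set_cap=100)
        assert drv.mean_damage_pct.mean() > non.mean_damage_pct.mean()


def test_structural_candidate_pools_have_ten_percent_size(midsize_analyses):
    import math
    for _, an in midsize_analyses[:3]:
        n = len(an.model.network.species)
        pool = scenarios._structural_pool(an, "betweenness")
        assert len(pool) == math.ceil(0.1 * n)


def test_structural_modes_produce_damage_distributions(midsize_analyses):
    rng = np.random.default_rng(8)
    for measure in ("betweenness", "nestedness", "musrank_plant",
                    "musrank_pollinator"):
        df = scenarios.extinction_experiment(
            midsize_analyses[:8], f"structural:{measure}", 1, rng, set_cap=20)
        scored = df.mean_damage_pct.dropna()
        assert len(scored) >= 1
        assert ((scored >= 0) & (scored <= 100)).all()


def test_blocking_reduces_mean_damage(midsize_analyses):
    rng = np.random.default_rng(3)
    blocked, unblocked = [], []
    for nid, an in midsize_analyses:
        res = scenarios.blocking_experiment(nid, an, rng, set_cap=40)
        if res is not None:
            blocked.append(res["blocked_mean_damage"])
            unblocked.append(res["unblocked_mean_damage"])
    assert len(blocked) >= 5
    assert np.mean(blocked) < np.mean(unblocked)


def test_motif_driver_restoration_reports(midsize_analyses):
    rng = np.random.default_rng(4)
    n_rep = 0
    for nid, an in midsize_analyses:
        wd = scenarios.worst_driver_damage(an, 1)
        if wd is None:
            continue
        damaged, extinct = wd
        for rep in scenarios.restoration_by_motif_drivers(nid, an, damaged, 1):
            assert 0.0 <= rep.restoration_pct <= 100.0
            assert rep.restored <= extinct
            n_rep += 1
    assert n_rep >= 3


def test_threshold_verification_never_exceeds_simplified(midsize_analyses):
    """Simplified-model restoration may overestimate but the discrepancy
    runs in one direction: the threshold model restores at most as much."""
    for nid, an in midsize_analyses[:10]:
        wd = scenarios.worst_driver_damage(an, 1)
        if wd is None:
            continue
        damaged, _ = wd
        for rep in scenarios.restoration_by_motif_drivers(nid, an, damaged, 1)[:2]:
            thr = scenarios.verify_restoration_on_threshold(
                an, damaged, rep.restored, nid)
            assert thr.restoration_pct <= rep.restoration_pct + 1e-9


def test_fd_restoration_draws_from_top_contributors(midsize_analyses):
    rng = np.random.default_rng(5)
    n_rep = 0
    for nid, an in midsize_analyses:
        wd = scenarios.worst_driver_damage(an, 1)
        if wd is None:
            continue
        damaged, extinct = wd
        pool = scenarios.fd_candidate_pool(an, damaged)
        for rep in scenarios.restoration_by_functional_diversity(
                nid, an, damaged, 1, rng, set_cap=10):
            assert rep.restored <= set(pool) and rep.restored <= extinct
            n_rep += 1
    assert n_rep >= 3


def test_control_experiment_sizes_are_verified(midsize_analyses):
    for _, an in midsize_analyses[:8]:
        df = scenarios.restoration_control_experiment(an)
        for _, row in df.iterrows():
            assert row.band in ("70-80", "80-90", "90-100")
            if not np.isnan(row.min_control_size):
                assert row.min_control_size >= 0
    # the maximal richness attractor itself always qualifies
    an = midsize_analyses[0][1]
    df = scenarios.restoration_control_experiment(an, richness_fraction=1.0)
    assert (df.richness_pct == 100.0).any()
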