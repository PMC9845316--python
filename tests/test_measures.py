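"""Structural rankings and functional-diversity dendrograms."""

import itertools

import numpy as np
import pandas as pd
import pytest

from motifpol import fixtures
from motifpol.measures import (betweenness_ranking, fd_dendrogram,
                               fd_restoration_ranking, functional_diversity,
                               guild_profiles, musrank, nestedness_contribution)
from motifpol.network import InteractionNetwork, SpeciesNode


def _net(pairs, signs=None):
    net = InteractionNetwork()
    species = {s for p in pairs for s in p}
    for s in sorted(species):
        guild = "plant" if s.startswith("pl_") else "pollinator"
        net.add_species(SpeciesNode(s, guild, 1.0))
    for i, (pl, po) in enumerate(pairs):
        net.add_interaction(pl, po, signs[i] if signs else (1, 1))
    return net


def test_betweenness_peaks_at_path_middle():
    net = _net([("pl_1", "po_1"), ("pl_2", "po_1"), ("pl_2", "po_2")])
    bc = betweenness_ranking(net)
    assert bc.idxmax() == "pl_2"  # the connector between the two pollinators


def test_betweenness_zero_on_disconnected_pairs():
    net = _net([("pl_1", "po_1"), ("pl_2", "po_2")])
    assert (betweenness_ranking(net) == 0).all()


def test_betweenness_matches_pair_dependency_count():
    """Directed betweenness equals brute-force all-pairs path accounting."""
    import networkx as nx
    net = _net([("pl_1", "po_1"), ("pl_2", "po_1"), ("pl_2", "po_2"),
                ("pl_3", "po_2"), ("pl_3", "po_1")])
    got = betweenness_ranking(net)
    nodes = sorted(net.graph.nodes)
    expected = dict.fromkeys(nodes, 0.0)
    for s, t in itertools.permutations(nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(net.graph, s, t))
        except nx.NetworkXNoPath:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            on_path = sum(1 for p in paths if v in p)
            expected[v] += on_path / len(paths)
    for v in nodes:
        assert got[v] == pytest.approx(expected[v])


def test_nestedness_contribution_direct_evaluation():
    """Two plants fed only by the same pollinator: eta = 1/N = 1/3."""
    net = _net([("pl_1", "po_1"), ("pl_2", "po_1")],
               signs=[(1, -1), (1, -1)])  # benefit flows to plants only
    # drop the superfluous negative edges, as conversion would
    net.graph.remove_edge("pl_1", "po_1")
    net.graph.remove_edge("pl_2", "po_1")
    with pytest.warns(UserWarning):
        eta = nestedness_contribution(net)  # po_1 has in-degree 0: excluded
    assert eta["pl_1"] == pytest.approx(1 / 3)
    assert eta["pl_2"] == pytest.approx(1 / 3)
    assert "po_1" not in eta.index


def test_nestedness_no_shared_benefactors_scores_zero():
    net = _net([("pl_1", "po_1"), ("pl_2", "po_2")])
    eta = nestedness_contribution(net)
    # disjoint pairs share no in-neighbour with any other species
    assert (eta == 0).all()


def test_nestedness_invariant_under_relabeling():
    pairs = [("pl_1", "po_1"), ("pl_2", "po_1"), ("pl_2", "po_2")]
    swapped = [("pl_2", "po_1"), ("pl_1", "po_1"), ("pl_1", "po_2")]
    a = sorted(nestedness_contribution(_net(pairs)).values)
    b = sorted(nestedness_contribution(_net(swapped)).values)
    assert a == pytest.approx(b)


def test_nestedness_matches_matrix_product_formula():
    net = _net([("pl_1", "po_1"), ("pl_2", "po_1"), ("pl_2", "po_2"),
                ("pl_3", "po_2")])
    species = net.species
    idx = {s: i for i, s in enumerate(species)}
    m = np.zeros((len(species), len(species)))
    for u, v in net.graph.edges:
        m[idx[v], idx[u]] = 1
    k = m.sum(axis=1)
    eta = nestedness_contribution(net)
    for s in species:
        i = idx[s]
        expected = sum((m @ m.T)[i, j] / (k[i] * k[j])
                       for j in range(len(species)) if j != i) / len(species)
        assert eta[s] == pytest.approx(expected)


def test_musrank_symmetric_network_is_uniform():
    net = _net([(pl, po) for pl in ("pl_1", "pl_2") for po in ("po_1", "po_2")])
    importance, vulnerability = musrank(net)
    assert np.allclose(importance, 1.0) and np.allclose(vulnerability, 1.0)


def test_musrank_normalization_and_degree_ordering():
    net = _net([("pl_1", "po_1"), ("pl_2", "po_1"), ("pl_1", "po_2")])
    importance, vulnerability = musrank(net)
    assert importance.mean() == pytest.approx(1.0)
    assert vulnerability.mean() == pytest.approx(1.0)
    # the generalist pollinator visiting both plants outranks the specialist
    assert importance["po_1"] > importance["po_2"]


def test_musrank_fixed_point_is_independent_of_start():
    net = _net([("pl_1", "po_1"), ("pl_2", "po_1"), ("pl_1", "po_2"),
                ("pl_3", "po_2")])
    base_i, base_v = musrank(net)
    rng = np.random.default_rng(0)
    m = np.zeros((2, 3))
    pollinators, plants = ["po_1", "po_2"], ["pl_1", "pl_2", "pl_3"]
    for pl, po in net.interacting_pairs():
        m[pollinators.index(po), plants.index(pl)] = 1
    for _ in range(5):
        imp = rng.uniform(0.2, 3.0, size=2)
        vul = rng.uniform(0.2, 3.0, size=3)
        for _ in range(50_000):
            imp_new = m @ vul
            imp_new /= imp_new.mean()
            vul_new = 1.0 / (m.T @ (1.0 / imp_new))
            vul_new /= vul_new.mean()
            if max(np.abs(imp_new - imp).max(), np.abs(vul_new - vul).max()) < 1e-10:
                break
            imp, vul = imp_new, vul_new
        assert np.allclose(imp, base_i.to_numpy(), atol=1e-6)
        assert np.allclose(vul, base_v.to_numpy(), atol=1e-6)


# -- functional diversity ---------------------------------------------------

def test_worked_example_distances_and_total_branch_length():
    profiles = fixtures.fd_worked_profiles()
    x = profiles.to_numpy(dtype=float)
    d12 = np.linalg.norm(x[:, 0] - x[:, 1])
    assert d12 == pytest.approx(1.73, abs=0.005)
    dendro = fd_dendrogram(profiles)
    assert functional_diversity(dendro, dendro.leaves) == pytest.approx(4.46, abs=0.005)
    assert functional_diversity(dendro, ["po_3"]) == pytest.approx(1.73, abs=0.005)


def test_identical_profiles_merge_at_height_zero():
    profiles = pd.DataFrame({"po_1": [1, 0], "po_2": [1, 0]}, index=["pl_1", "pl_2"])
    dendro = fd_dendrogram(profiles)
    assert dendro.heights == (0.0,)
    assert functional_diversity(dendro, dendro.leaves) == 0.0


def test_merge_heights_equal_single_linkage_brute_force():
    rng = np.random.default_rng(4)
    profiles = pd.DataFrame(rng.integers(0, 2, size=(6, 5)),
                            columns=[f"po_{i}" for i in range(5)])
    dendro = fd_dendrogram(profiles)
    # brute force: repeatedly merge the two clusters at minimal pointwise gap
    clusters = [{i} for i in range(5)]
    cols = profiles.to_numpy(float).T
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            d = min(np.linalg.norm(cols[i] - cols[j])
                    for i in clusters[a] for j in clusters[b])
            if best is None or d < best[0]:
                best = (d, a, b)
        d, a, b = best
        heights.append(d)
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + \
            [clusters[a] | clusters[b]]
    assert sorted(dendro.heights) == pytest.approx(sorted(heights))


def test_fd_monotone_under_inclusion():
    dendro = fd_dendrogram(fixtures.fd_worked_profiles())
    subsets = [set(c) for r in range(4)
               for c in itertools.combinations(dendro.leaves, r)]
    for s in subsets:
        for bigger in subsets:
            if s <= bigger:
                assert functional_diversity(dendro, s) <= \
                    functional_diversity(dendro, bigger) + 1e-12


def test_restoration_ranking_prefers_the_irreplaceable_pollinator():
    dendro = fd_dendrogram(fixtures.fd_worked_profiles())
    ranking = fd_restoration_ranking(dendro, ["po_1", "po_2"], ["po_3"])
    assert list(ranking.index) == ["po_2", "po_1"]
    assert ranking["po_2"] == pytest.approx(1.73, abs=0.005)
    assert ranking["po_1"] == pytest.approx(1.0, abs=1e-9)


def test_sequential_restoration_accounts_for_all_branches():
    """Greedily restoring everything adds exactly FD(all) - FD(survivors)."""
    rng = np.random.default_rng(9)
    profiles = pd.DataFrame(rng.integers(0, 2, size=(5, 6)),
                            columns=[f"po_{i}" for i in range(6)])
    dendro = fd_dendrogram(profiles)
    survivors = {"po_0"}
    extinct = [f"po_{i}" for i in range(1, 6)]
    total_gain = 0.0
    current = set(survivors)
    for s in extinct:
        total_gain += functional_diversity(dendro, current | {s}) - \
            functional_diversity(dendro, current)
        current.add(s)
    expected = functional_diversity(dendro, dendro.leaves) - \
        functional_diversity(dendro, survivors)
    assert total_gain == pytest.approx(expected)


def test_unknown_leaf_is_rejected():
    dendro = fd_dendrogram(fixtures.fd_worked_profiles())
    with pytest.raises(KeyError):
        functional_diversity(dendro, ["po_9"])


def test_guild_profiles_match_incoming_edges():
    model = fixtures.expanded_example_model()
    profiles = guild_profiles(model.network, "pollinator")
    for po in profiles.columns:
        for pl in profiles.index:
            assert profiles.loc[pl, po] == int(model.network.graph.has_edge(po, pl))
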