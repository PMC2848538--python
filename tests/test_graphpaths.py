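import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mbpkit.chemistry import build_network
from mbpkit.fixtures import FixtureSpec, generate_fixture
from mbpkit.graphpaths import (
    UNREACHABLE,
    all_pairs_shortest,
    build_graph,
    efm_nearest_size_matrix,
    nearest_size_matrix,
    read_stoichiometric_tsv,
)
from mbpkit.milp import mbp_length_table


@pytest.fixture()
def toy(tmp_path):
    manifest = generate_fixture(FixtureSpec(kind="toy_central_carbon"), tmp_path)
    stoich = read_stoichiometric_tsv(tmp_path / manifest["network"])
    carbons = {}
    for line in (tmp_path / manifest["carbons"]).read_text().splitlines():
        m, c = line.split("\t")
        carbons[m] = int(c)
    return manifest, stoich, carbons


def test_zero_carbon_and_cofactor_removal(toy):
    manifest, stoich, carbons = toy
    bg = build_graph(stoich, carbon_counts=carbons)
    for met in manifest["zero_carbon"]:
        assert met not in bg.graph
    bg.validate()
    bg2 = build_graph(stoich, cofactors={"glc"}, carbon_counts=carbons)
    assert "glc" not in bg2.graph


def test_adjacent_metabolites_are_one_reaction_apart(toy):
    _, stoich, carbons = toy
    bg = build_graph(stoich, carbon_counts=carbons)
    dist = all_pairs_shortest(bg)
    assert dist.at["glc", "g6p"] == 1
    assert dist.at["g6p", "glc"] == 1  # undirected symmetry


def test_planted_distances_recovered(toy):
    manifest, stoich, carbons = toy
    bg = build_graph(stoich, carbon_counts=carbons)
    dist = all_pairs_shortest(bg)
    for spec_pair, d in manifest["planted_distances"].items():
        a, b = spec_pair.split("->")
        assert dist.at[a, b] == d


def test_johnson_equals_breadth_first_search(toy):
    _, stoich, carbons = toy
    bg = build_graph(stoich, carbon_counts=carbons)
    dist = all_pairs_shortest(bg)
    for src in bg.metabolites:
        bfs = nx.single_source_shortest_path_length(bg.graph, src)
        for dst in bg.metabolites:
            expect = bfs[dst] / 2 if dst in bfs else UNREACHABLE
            assert dist.at[src, dst] == expect


def test_directed_edges_follow_stoichiometric_signs():
    stoich = pd.DataFrame({"r1": [-1, 1]}, index=["a", "b"])
    bg = build_graph(stoich, directed=True)
    dist = all_pairs_shortest(bg)
    assert dist.at["a", "b"] == 1
    assert math.isinf(dist.at["b", "a"])  # no reverse route when directed


def test_unreachable_pairs_get_sentinel():
    stoich = pd.DataFrame(
        {"r1": [-1, 1, 0, 0], "r2": [0, 0, -1, 1]},
        index=["a", "b", "c", "d"])
    bg = build_graph(stoich)
    dist = all_pairs_shortest(bg)
    assert dist.at["a", "b"] == 1
    assert math.isinf(dist.at["a", "c"])


def test_nearest_size_min_then_average():
    """Two 1-carbon inputs at distances 2 and 4 from their nearest 3-carbon
    target must average to 3."""
    dist = pd.DataFrame(
        [[0, 2, 2], [2, 0, 4], [2, 4, 0]],
        index=["x1", "x2", "y"], columns=["x1", "x2", "y"], dtype=float)
    carbons = {"x1": 1, "x2": 1, "y": 3}
    A = nearest_size_matrix(dist, carbons)
    assert A.values.at[1, 3] == pytest.approx(3.0)
    assert A.contributors.at[1, 3] == 2
    # self excluded: nearest *other* 1-carbon compound
    assert A.values.at[1, 1] == pytest.approx(2.0)
    # a singleton class has no other member: sentinel
    assert math.isinf(A.values.at[3, 3])


def test_geodesic_fixture(tmp_path):
    manifest = generate_fixture(
        FixtureSpec(kind="planted_geodesic_graph", seed=3, geodesic_length=4),
        tmp_path)
    stoich = read_stoichiometric_tsv(tmp_path / manifest["network"])
    bg = build_graph(stoich)
    dist = all_pairs_shortest(bg)
    planted = manifest["planted_distance"]
    assert dist.at[planted["from"], planted["to"]] == planted["reactions"]


def test_efm_matrix_on_artificial_chemistry_matches_milp(net10=None):
    """With one compound per size, the mode-based nearest-size matrix is the
    exact pathway-length table."""
    net = build_network(6)
    ids = [s.id for s in net.species]
    stoich = pd.DataFrame(net.S_internal,
                          index=ids,
                          columns=[r.id for r in net.internal_reactions])
    carbons = {f"a{k}": k for k in range(1, 7)}
    A = efm_nearest_size_matrix(stoich, carbons, max_internal_support=6)
    L, _ = mbp_length_table(net)
    for i in range(1, 7):
        for j in range(1, 7):
            if i != j:
                assert A.values.at[i, j] == L[i, j]


def test_efm_matrix_dominates_graph_distances(toy):
    _, stoich, carbons = toy
    bg = build_graph(stoich, carbon_counts=carbons)
    graph_A = nearest_size_matrix(all_pairs_shortest(bg), carbons)
    efm_A = efm_nearest_size_matrix(stoich, carbons, allow_large=True,
                                    max_internal_support=9)
    for i in efm_A.values.index:
        for j in efm_A.values.columns:
            g = graph_A.values.at[i, j] if i in graph_A.values.index else UNREACHABLE
            e = efm_A.values.at[i, j]
            if math.isfinite(e) and math.isfinite(g):
                assert e >= g - 1e-9
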