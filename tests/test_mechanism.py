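"""Network stage: seed mapping, Steiner heuristic vs exhaustive optimum,
TrustRank closed forms, centralities vs all-pairs brute force, drug ranking."""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest
from scipy.sparse.csgraph import shortest_path

from proteoharm.mechanism import (
    MechanismNetwork,
    centralities,
    map_seeds,
    must_connect,
    rank_drugs,
    steiner_approx,
    trustrank,
)

# ---------------------------------------------------------------------------
# seed mapping
# ---------------------------------------------------------------------------


def _net(edges, drugs=None, approved=None):
    g = nx.Graph()
    for e in edges:
        g.add_edge(*e[:2], weight=(e[2] if len(e) > 2 else 1.0))
    return MechanismNetwork(
        graph=g,
        drug_targets={d: frozenset(t) for d, t in (drugs or {}).items()},
        drug_approved=approved or {},
    )


def test_map_seeds_triangle_and_disjoint_edges():
    net = _net([("A", "B"), ("B", "C"), ("A", "C")])
    _, report = map_seeds(net, ["A", "B", "C"])
    assert report.largest_induced_component == 3

    net2 = _net([("A", "B"), ("C", "D"), ("B", "C")])
    _, report2 = map_seeds(net2, ["A", "B", "C", "D"])
    assert report2.largest_induced_component == 4
    _, report3 = map_seeds(net2, ["A", "D"])
    assert report3.induced_component_sizes == (1, 1)
    assert report3.network_component_sizes == (2,)  # reachable via B-C


def test_unmapped_seeds_are_reported_not_dropped():
    net = _net([("A", "B")])
    mapped, report = map_seeds(net, ["A", "GHOST"])
    assert mapped == {"A"}
    assert report.unmapped == ("GHOST",)


def test_map_seeds_matches_component_labeling():
    rng = np.random.default_rng(21)
    g = nx.gnp_random_graph(30, 0.08, seed=17)
    g = nx.relabel_nodes(g, {i: f"N{i}" for i in g.nodes})
    nx.set_edge_attributes(g, 1.0, "weight")
    net = MechanismNetwork(graph=g)
    seeds = [f"N{i}" for i in rng.choice(30, size=10, replace=False)]
    _, report = map_seeds(net, seeds)
    induced = g.subgraph(seeds)
    sizes = sorted((len(c) for c in nx.connected_components(induced)),
                   reverse=True)
    assert report.induced_component_sizes == tuple(sizes)


# ---------------------------------------------------------------------------
# Steiner heuristic
# ---------------------------------------------------------------------------


def test_steiner_on_path_recovers_unique_tree():
    g = nx.Graph([("A", "B"), ("B", "C")])
    tree = steiner_approx(g, {"A", "C"})
    assert sorted(tuple(sorted(e)) for e in tree.edges) == [
        ("A", "B"), ("B", "C")
    ]


def test_steiner_on_star_uses_hub():
    g = nx.Graph([("H", "L1"), ("H", "L2"), ("H", "L3"), ("H", "L4")])
    tree = steiner_approx(g, {"L1", "L2", "L3"})
    assert set(tree.nodes) == {"H", "L1", "L2", "L3"}


def test_steiner_prunes_nonseed_leaves():
    # attachment may route through a longer path; final tree has no
    # non-seed leaf
    g = nx.Graph()
    g.add_edge("A", "X", weight=1)
    g.add_edge("X", "B", weight=1)
    g.add_edge("X", "Y", weight=1)
    tree = steiner_approx(g, {"A", "B"})
    for node in tree.nodes:
        assert tree.degree(node) > 1 or node in {"A", "B"}


def _optimal_steiner_weight(graph, seeds):
    """Exhaustive oracle: min over Steiner-node subsets of the MST weight of
    the induced connected subgraph covering all seeds."""

    def mst_weight(nodes):
        nodes = list(nodes)
        if any(s not in nodes for s in seeds):
            return None
        in_tree = {nodes[0]}
        weight = 0.0
        while len(in_tree) < len(nodes):
            best = None
            for u in in_tree:
                for v in graph[u]:
                    if v in nodes and v not in in_tree:
                        w = graph[u][v]["weight"]
                        if best is None or w < best[0]:
                            best = (w, v)
            if best is None:
                return None  # disconnected
            weight += best[0]
            in_tree.add(best[1])
        return weight

    others = [n for n in graph.nodes if n not in seeds]
    best = None
    for k in range(len(others) + 1):
        for extra in combinations(others, k):
            w = mst_weight(set(seeds) | set(extra))
            if w is not None and (best is None or w < best):
                best = w
    return best


def test_steiner_within_twice_optimum_on_small_graphs():
    rng = np.random.default_rng(2)
    checked = 0
    while checked < 60:
        n = int(rng.integers(4, 10))
        g = nx.gnp_random_graph(n, 0.45, seed=int(rng.integers(2**31)))
        if not nx.is_connected(g):
            continue
        for u, v in g.edges:
            g.edges[u, v]["weight"] = float(rng.integers(1, 6))
        k = int(rng.integers(2, min(5, n + 1)))
        seeds = set(int(x) for x in rng.choice(n, size=k, replace=False))
        tree = steiner_approx(g, seeds)
        heur = sum(d["weight"] for _, _, d in tree.edges(data=True))
        opt = _optimal_steiner_weight(g, seeds)
        assert opt is not None
        assert heur <= 2 * opt + 1e-9
        checked += 1


# ---------------------------------------------------------------------------
# Multi-Steiner-Tree
# ---------------------------------------------------------------------------


def test_single_iteration_reduces_to_one_tree():
    g = nx.Graph([("A", "B"), ("B", "C"), ("A", "D"), ("D", "C")])
    nx.set_edge_attributes(g, 1.0, "weight")
    sol = must_connect(g, {"A", "C"}, n_trees=1, rng_seed=0)
    assert len(sol.trees) == 1
    assert sol.union_nodes >= {"A", "C"}
    assert not set(sol.connectors) & {"A", "C"}


def test_connected_seed_set_needs_no_connectors():
    g = nx.Graph([("A", "B"), ("B", "C"), ("C", "D")])
    nx.set_edge_attributes(g, 1.0, "weight")
    sol = must_connect(g, {"A", "B", "C"}, n_trees=5, rng_seed=1)
    assert sol.connectors == ()


def test_planted_bridge_recovered_across_seeded_runs(network_fixture):
    net = network_fixture.network
    hits = sum(
        1
        for s in range(100)
        if set(network_fixture.planted_connectors)
        <= set(must_connect(net, set(network_fixture.seeds),
                            n_trees=10, rng_seed=s).connectors)
    )
    assert hits >= 95


def test_must_connect_validates_arguments():
    g = nx.Graph([("A", "B")])
    with pytest.raises(ValueError, match="n_trees"):
        must_connect(g, {"A"}, n_trees=0)
    with pytest.raises(ValueError, match="seeds"):
        must_connect(g, set())
    with pytest.raises(ValueError, match="hub_penalty"):
        must_connect(g, {"A"}, hub_penalty=2.0)


def test_seeds_in_two_components_warn_and_yield_per_component_trees():
    g = nx.Graph([("A", "B"), ("C", "D")])
    nx.set_edge_attributes(g, 1.0, "weight")
    with pytest.warns(UserWarning, match="components"):
        sol = must_connect(g, {"A", "B", "C", "D"}, n_trees=2, rng_seed=0)
    assert sol.union_nodes == {"A", "B", "C", "D"}


# ---------------------------------------------------------------------------
# TrustRank
# ---------------------------------------------------------------------------


def test_trustrank_single_self_seeded_node():
    g = nx.Graph()
    g.add_node("A")
    assert trustrank(g, {"A"})["A"] == pytest.approx(1.0, abs=1e-12)


def test_trustrank_two_node_closed_form():
    # stationary system: s1 = 0.15 + 0.85 s2, s2 = 0.85 s1, solved exactly
    d = 0.85
    a = np.array([[1.0, -d], [-d, 1.0]])
    b = np.array([1.0 - d, 0.0])
    s1, s2 = np.linalg.solve(a, b)
    g = nx.Graph([("n1", "n2")])
    scores = trustrank(g, {"n1"}, damping=d, tolerance=1e-12)
    assert scores["n1"] == pytest.approx(s1, abs=1e-8)
    assert scores["n2"] == pytest.approx(s2, abs=1e-8)


def test_trustrank_uniform_on_fully_seeded_regular_graph():
    g = nx.circulant_graph(8, [1, 2])  # 4-regular
    scores = trustrank(g, set(g.nodes))
    for v in scores.values():
        assert v == pytest.approx(1 / 8, abs=1e-9)


def test_trustrank_mass_conservation_and_errors():
    g = nx.gnp_random_graph(20, 0.2, seed=4)
    g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
    scores = trustrank(g, {next(iter(g.nodes))})
    assert sum(scores.values()) == pytest.approx(1.0, abs=1e-6)
    with pytest.raises(ValueError, match="seed"):
        trustrank(g, set())
    with pytest.raises(ValueError, match="not in network"):
        trustrank(g, {"ABSENT"})


# ---------------------------------------------------------------------------
# centralities vs all-pairs brute force
# ---------------------------------------------------------------------------


def _brute_force_centralities(g):
    nodes = sorted(g.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    adj = np.zeros((n, n))
    for u, v in g.edges:
        adj[idx[u], idx[v]] = adj[idx[v], idx[u]] = 1
    dist = shortest_path(adj, method="FW", unweighted=True)

    degree = {v: float(adj[idx[v]].sum()) for v in nodes}
    harmonic = {
        v: float(sum(1.0 / dist[idx[v], j] for j in range(n)
                     if j != idx[v] and np.isfinite(dist[idx[v], j])))
        for v in nodes
    }
    closeness = {}
    for v in nodes:
        row = dist[idx[v]]
        reach = [row[j] for j in range(n) if j != idx[v] and np.isfinite(row[j])]
        if not reach:
            closeness[v] = 0.0
        else:
            r = len(reach)
            closeness[v] = (r / sum(reach)) * (r / (n - 1))

    # betweenness from explicit shortest-path counts: num_paths[s, j] is the
    # number of geodesics s->j, filled in order of increasing distance
    num_paths = np.zeros((n, n))
    for s in range(n):
        num_paths[s, s] = 1.0
        order = sorted(
            (j for j in range(n) if np.isfinite(dist[s, j])),
            key=lambda j: dist[s, j],
        )
        for j in order:
            if j == s:
                continue
            num_paths[s, j] = sum(
                num_paths[s, k]
                for k in range(n)
                if adj[k, j] and dist[s, k] + 1 == dist[s, j]
            )
    betweenness = {}
    for v in nodes:
        i = idx[v]
        total = 0.0
        for s in range(n):
            for t in range(s + 1, n):
                if s == i or t == i or not np.isfinite(dist[s, t]):
                    continue
                if dist[s, i] + dist[i, t] == dist[s, t]:
                    total += num_paths[s, i] * num_paths[i, t] / num_paths[s, t]
        betweenness[v] = total
    return degree, closeness, harmonic, betweenness


def test_path_and_complete_graph_centralities():
    path = nx.path_graph(["A", "B", "C"])
    assert centralities(path, "betweenness")["B"] == pytest.approx(1.0)
    assert centralities(path, "degree")["B"] == 2.0
    k4 = nx.complete_graph(4)
    assert all(v == 0.0 for v in centralities(k4, "betweenness").values())


def test_all_centralities_match_all_pairs_brute_force():
    rng = np.random.default_rng(8)
    for trial in range(50):
        g = nx.gnp_random_graph(12, float(rng.uniform(0.15, 0.5)),
                                seed=int(rng.integers(2**31)))
        degree, closeness, harmonic, betweenness = _brute_force_centralities(g)
        for measure, expected in (
            ("degree", degree),
            ("closeness", closeness),
            ("harmonic", harmonic),
            ("betweenness", betweenness),
        ):
            got = centralities(g, measure)
            for v in g.nodes:
                assert got[v] == pytest.approx(expected[v], abs=1e-9), (
                    trial, measure, v
                )


def test_unknown_measure_rejected():
    with pytest.raises(ValueError, match="unknown centrality"):
        centralities(nx.path_graph(3), "eigenvector")


# ---------------------------------------------------------------------------
# drug ranking
# ---------------------------------------------------------------------------


def test_degree_method_sums_target_scores():
    net = _net(
        [("M1", "M2"), ("M2", "M3"), ("M1", "M3"), ("M1", "X")],
        drugs={"D1": {"M1", "M2"}, "D2": {"M1"}},
    )
    ranked = rank_drugs(net, {"M1", "M2", "M3"}, method="degree")
    assert [d.drug for d in ranked] == ["D1", "D2"]
    # hand-computed: deg(M1)=3, deg(M2)=2 -> D1=5, D2=3
    assert ranked[0].score == pytest.approx(5.0)
    assert ranked[1].score == pytest.approx(3.0)
    assert ranked[0].targets == ("M1", "M2")


def test_no_drug_edges_yields_empty_ranking():
    net = _net([("M1", "M2")])
    assert rank_drugs(net, {"M1"}) == []
    assert rank_drugs(net, set()) == []


def test_top_k_truncation_and_approval_filter(network_fixture):
    net = network_fixture.network
    mechanism = set(network_fixture.seeds)
    all_ranked = rank_drugs(net, mechanism, method="degree",
                            include_non_approved=True)
    approved_only = rank_drugs(net, mechanism, method="degree")
    assert len(approved_only) < len(all_ranked)
    assert all(net.drug_approved[d.drug] for d in approved_only)
    top = rank_drugs(net, mechanism, method="degree", top_k=5,
                     include_non_approved=True)
    assert len(top) == 5
    assert [d.drug for d in top] == [d.drug for d in all_ranked[:5]]


def test_trustrank_ranking_is_deterministic(network_fixture):
    net = network_fixture.network
    mech = set(network_fixture.seeds)
    first = rank_drugs(net, mech, method="trustrank", top_k=10,
                       include_non_approved=True)
    second = rank_drugs(net, mech, method="trustrank", top_k=10,
                        include_non_approved=True)
    assert first == second
    assert all(d.score > 0 for d in first)


def test_mechanism_nodes_must_exist(network_fixture):
    with pytest.raises(ValueError, match="not in protein network"):
        rank_drugs(network_fixture.network, {"GHOST"})
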