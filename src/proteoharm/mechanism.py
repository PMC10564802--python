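"""Network-based mechanism mining and drug-repurposing candidate ranking.

Multi-study biomarker candidates rarely form a connected subnetwork of the
protein–protein interactome on their own. This module maps them onto a PPI
network as *seeds*, finds the non-seed *connector* proteins needed to join
them via a Multi-Steiner-Tree procedure (union of several approximate
Steiner trees, diversified by edge reweighting between iterations), scores
nodes by seed-personalized TrustRank propagation or classical centralities,
and finally ranks drugs that target proteins of the resulting mechanism.

The Steiner heuristic is the Takahashi–Matsuyama shortest-path attachment:
grow a tree from one seed by repeatedly joining the nearest unconnected seed
along a weighted shortest path, then prune non-seed leaves. On the metric
closure this carries the classical 2(1−1/ℓ) < 2 approximation guarantee in
the number of terminals ℓ.
"""

from __future__ import annotations

import csv
import os
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "MechanismNetwork",
    "SeedReport",
    "SteinerSolution",
    "DrugScore",
    "load_network",
    "map_seeds",
    "steiner_approx",
    "must_connect",
    "trustrank",
    "centralities",
    "rank_drugs",
]

CENTRALITY_MEASURES = ("degree", "closeness", "harmonic", "betweenness")


@dataclass
class MechanismNetwork:
    """An undirected protein graph with drug nodes attached by target edges.

    ``graph`` holds only protein nodes (edge attribute ``weight``, default
    1.0, no self-loops); drugs live in ``drug_targets`` (drug id → protein
    targets) plus ``drug_approved`` flags, and touch the graph only through
    ``combined_graph()``. ``seeds`` is the mapped seed set.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    drug_targets: dict[str, frozenset[str]] = field(default_factory=dict)
    drug_approved: dict[str, bool] = field(default_factory=dict)
    seeds: frozenset[str] = frozenset()

    def combined_graph(self) -> nx.Graph:
        """Protein graph plus drug nodes and drug–target edges (weight 1)."""
        combined = self.graph.copy()
        for drug, targets in self.drug_targets.items():
            for protein in targets:
                if protein in self.graph:
                    combined.add_edge(drug, protein, weight=1.0)
        return combined

    @property
    def protein_nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)


def load_network(
    ppi_path: str | os.PathLike,
    drug_path: str | os.PathLike | None = None,
    seed_path: str | os.PathLike | None = None,
) -> MechanismNetwork:
    """Load a PPI edge list, optional drug–target edges and optional seeds.

    ``ppi_path``: TSV with header ``node_a  node_b  [weight]``;
    ``drug_path``: TSV with header ``drug_id  protein_id  [approved]``
    (approved 0/1, default 1); ``seed_path``: newline-delimited symbols.
    Self-loops are rejected, duplicate edges keep the first weight.
    """
    graph = nx.Graph()
    with open(os.fspath(ppi_path), newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for i, row in enumerate(reader, start=2):
            a, b = row["node_a"], row["node_b"]
            if a == b:
                raise ValueError(f"{ppi_path}, line {i}: self-loop {a!r}")
            weight = float(row.get("weight") or 1.0)
            if weight < 0:
                raise ValueError(f"{ppi_path}, line {i}: negative weight")
            if not graph.has_edge(a, b):
                graph.add_edge(a, b, weight=weight)
    network = MechanismNetwork(graph=graph)
    if drug_path is not None:
        targets: dict[str, set[str]] = {}
        approved: dict[str, bool] = {}
        with open(os.fspath(drug_path), newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            for row in reader:
                drug, protein = row["drug_id"], row["protein_id"]
                targets.setdefault(drug, set()).add(protein)
                approved[drug] = (row.get("approved") or "1") == "1"
        network.drug_targets = {d: frozenset(t) for d, t in targets.items()}
        network.drug_approved = approved
    if seed_path is not None:
        with open(os.fspath(seed_path)) as fh:
            symbols = [line.strip() for line in fh if line.strip()]
        network.seeds = frozenset(s for s in symbols if s in graph)
    return network


@dataclass(frozen=True)
class SeedReport:
    """Connectivity of a seed list after mapping onto the network.

    Two readings of "spanning a connected subnetwork" are reported side by
    side: component sizes of the seed-*induced* subgraph (seeds adjacent to
    seeds) and groupings of seeds by reachability through the full network
    (seeds in the same network component, possibly via non-seed nodes).
    """

    mapped: tuple[str, ...]
    unmapped: tuple[str, ...]
    induced_component_sizes: tuple[int, ...]
    network_component_sizes: tuple[int, ...]

    @property
    def largest_induced_component(self) -> int:
        return self.induced_component_sizes[0] if self.induced_component_sizes else 0


def map_seeds(
    network: MechanismNetwork, seed_symbols: list[str]
) -> tuple[frozenset[str], SeedReport]:
    """Map seed symbols onto protein nodes; unmapped seeds are reported,
    never silently dropped."""
    mapped = [s for s in seed_symbols if s in network.graph]
    unmapped = [s for s in seed_symbols if s not in network.graph]
    induced = network.graph.subgraph(mapped)
    induced_sizes = sorted(
        (len(c) for c in nx.connected_components(induced)), reverse=True
    )
    by_component: dict[int, int] = {}
    component_of: dict[str, int] = {}
    for idx, comp in enumerate(nx.connected_components(network.graph)):
        for node in comp:
            component_of[node] = idx
    for s in mapped:
        idx = component_of[s]
        by_component[idx] = by_component.get(idx, 0) + 1
    report = SeedReport(
        mapped=tuple(sorted(set(mapped))),
        unmapped=tuple(sorted(set(unmapped))),
        induced_component_sizes=tuple(induced_sizes),
        network_component_sizes=tuple(sorted(by_component.values(), reverse=True)),
    )
    return frozenset(mapped), report


def _tree_weight(tree: nx.Graph, weight: str = "weight") -> float:
    return sum(d.get(weight, 1.0) for _, _, d in tree.edges(data=True))


def steiner_approx(
    graph: nx.Graph,
    seeds: set[str],
    weight: str = "weight",
    start: str | None = None,
) -> nx.Graph:
    """One approximate Steiner tree over ``seeds`` (shortest-path attachment).

    All seeds must lie in one connected component of ``graph``; ties between
    equally near seeds break on node id so the result is deterministic for a
    fixed start. Non-seed leaves are pruned from the final tree.
    """
    seeds = sorted(set(seeds))
    if not seeds:
        raise ValueError("steiner_approx requires at least one seed")
    missing = [s for s in seeds if s not in graph]
    if missing:
        raise ValueError(f"seeds not in graph: {missing}")
    if start is None:
        start = seeds[0]
    tree = nx.Graph()
    tree.add_node(start)
    remaining = set(seeds) - {start}
    while remaining:
        dist, paths = nx.multi_source_dijkstra(graph, set(tree.nodes), weight=weight)
        reachable = [s for s in remaining if s in dist]
        if not reachable:
            raise ValueError(
                "seeds span multiple connected components; "
                "run per component"
            )
        nearest = min(reachable, key=lambda s: (dist[s], s))
        path = paths[nearest]
        for u, v in zip(path, path[1:]):
            tree.add_edge(u, v, **graph.edges[u, v])
        remaining.discard(nearest)
    # prune non-seed leaves introduced by path overshoot
    seed_set = set(seeds)
    pruned = True
    while pruned:
        pruned = False
        for node in [n for n in tree.nodes if tree.degree(n) == 1 and n not in seed_set]:
            tree.remove_node(node)
            pruned = True
    return tree


@dataclass(frozen=True)
class SteinerSolution:
    """Union of the Multi-Steiner-Tree iterations.

    ``connectors`` are the non-seed nodes of the union, ordered by how many
    iterations used them (participation), then by network degree, then id.
    """

    trees: tuple[tuple[tuple[str, str], ...], ...]
    union_nodes: frozenset[str]
    connectors: tuple[str, ...]
    participation: dict[str, int]
    seeds: frozenset[str]


def _hub_penalized(graph: nx.Graph, hub_penalty: float) -> nx.Graph:
    """Copy of ``graph`` with weights inflated on high-degree endpoints:
    w → w·(1 + hp·avg_degree(u,v)/max_degree)."""
    out = graph.copy()
    if hub_penalty <= 0 or graph.number_of_edges() == 0:
        return out
    max_degree = max(d for _, d in graph.degree())
    for u, v, data in out.edges(data=True):
        base = data.get("weight", 1.0)
        avg = (graph.degree(u) + graph.degree(v)) / 2.0
        data["weight"] = base * (1.0 + hub_penalty * avg / max_degree)
    return out


def must_connect(
    network: MechanismNetwork | nx.Graph,
    seeds: set[str] | None = None,
    n_trees: int = 10,
    hub_penalty: float = 0.0,
    delta: float = 0.05,
    rng_seed: int = 42,
) -> SteinerSolution:
    """Multi-Steiner-Tree connector search.

    Runs ``n_trees`` attachment-heuristic iterations, each starting from a
    seed drawn by the seeded RNG; after every iteration the weights of the
    edges just used are multiplied by ``(1 + delta)`` so later iterations
    explore alternative near-optimal trees. Seeds falling into different
    network components are connected per component (with a warning).
    """
    if isinstance(network, MechanismNetwork):
        graph = network.graph
        seeds = set(seeds) if seeds is not None else set(network.seeds)
    else:
        graph = network
        seeds = set(seeds or ())
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    if not (0.0 <= hub_penalty <= 1.0):
        raise ValueError("hub_penalty must lie in [0, 1]")
    if not seeds:
        raise ValueError("must_connect requires seeds")
    missing = sorted(s for s in seeds if s not in graph)
    if missing:
        raise ValueError(f"seeds not in graph: {missing}")

    component_of: dict[str, int] = {}
    for idx, comp in enumerate(nx.connected_components(graph)):
        for node in comp:
            component_of[node] = idx
    groups: dict[int, list[str]] = {}
    for s in sorted(seeds):
        groups.setdefault(component_of[s], []).append(s)
    if len(groups) > 1:
        warnings.warn(
            f"seeds span {len(groups)} components; computing one tree union "
            "per component",
            stacklevel=2,
        )

    rng = np.random.default_rng(rng_seed)
    work = _hub_penalized(graph, hub_penalty)
    trees: list[tuple[tuple[str, str], ...]] = []
    participation: dict[str, int] = {}
    union_nodes: set[str] = set()
    for _ in range(n_trees):
        iteration_edges: list[tuple[str, str]] = []
        iteration_nodes: set[str] = set()
        for comp_seeds in groups.values():
            start = comp_seeds[int(rng.integers(len(comp_seeds)))]
            tree = steiner_approx(work, set(comp_seeds), start=start)
            iteration_edges += [tuple(sorted(e)) for e in tree.edges]
            iteration_nodes |= set(tree.nodes)
            for u, v in tree.edges:
                work.edges[u, v]["weight"] = work.edges[u, v].get(
                    "weight", 1.0
                ) * (1.0 + delta)
        trees.append(tuple(sorted(iteration_edges)))
        union_nodes |= iteration_nodes
        for node in iteration_nodes:
            participation[node] = participation.get(node, 0) + 1
    connectors = sorted(
        (n for n in union_nodes if n not in seeds),
        key=lambda n: (-participation[n], -graph.degree(n), n),
    )
    return SteinerSolution(
        trees=tuple(trees),
        union_nodes=frozenset(union_nodes),
        connectors=tuple(connectors),
        participation=participation,
        seeds=frozenset(seeds),
    )


def trustrank(
    network: MechanismNetwork | nx.Graph,
    seeds: set[str],
    damping: float = 0.85,
    tolerance: float = 1e-8,
    max_iter: int = 1000,
) -> dict[str, float]:
    """Seed-personalized damped score propagation over the combined graph.

    Iterates ``s ← (1−d)·p + d·M·s`` where ``p`` is uniform over the seeds
    and ``M`` spreads each node's score equally over its neighbors
    (column-normalized adjacency); mass sitting on isolated (degree-0) nodes
    is redistributed along ``p``, the usual dangling-node correction.
    Converges when the L1 change drops below ``tolerance``; scores then sum
    to ≈1 over the nodes reachable from the seeds.
    """
    graph = (
        network.combined_graph()
        if isinstance(network, MechanismNetwork)
        else network
    )
    if graph.number_of_nodes() == 0:
        raise ValueError("trustrank requires a nonempty network")
    seeds = set(seeds)
    if not seeds:
        raise ValueError("trustrank requires at least one seed")
    unknown = sorted(s for s in seeds if s not in graph)
    if unknown:
        raise ValueError(f"seeds not in network: {unknown}")
    nodes = sorted(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    adjacency = nx.to_scipy_sparse_array(
        graph, nodelist=nodes, weight="weight", format="csr"
    ).astype(float)
    degree = np.asarray(adjacency.sum(axis=0)).ravel()
    inv_degree = np.where(degree > 0, 1.0 / np.maximum(degree, 1e-300), 0.0)
    p = np.zeros(len(nodes))
    for s in seeds:
        p[index[s]] = 1.0 / len(seeds)
    dangling = degree == 0
    s_vec = p.copy()
    for _ in range(max_iter):
        spread = adjacency @ (s_vec * inv_degree)
        if dangling.any():
            spread = spread + s_vec[dangling].sum() * p
        s_new = (1.0 - damping) * p + damping * spread
        if np.abs(s_new - s_vec).sum() < tolerance:
            s_vec = s_new
            break
        s_vec = s_new
    return {n: float(s_vec[index[n]]) for n in nodes}


def centralities(
    network: MechanismNetwork | nx.Graph, measure: str
) -> dict[str, float]:
    """Classical node centralities on the undirected protein graph.

    ``degree`` is the raw degree, ``betweenness`` the unnormalized
    pair-count convention, ``closeness`` the per-component generalization
    scaled by component coverage, and ``harmonic`` sums reciprocal distances
    with 1/∞ = 0 — all well defined on disconnected graphs.
    """
    graph = network.graph if isinstance(network, MechanismNetwork) else network
    if measure == "degree":
        return {n: float(d) for n, d in graph.degree()}
    if measure == "closeness":
        return nx.closeness_centrality(graph)
    if measure == "harmonic":
        return nx.harmonic_centrality(graph)
    if measure == "betweenness":
        return nx.betweenness_centrality(graph, normalized=False)
    raise ValueError(
        f"unknown centrality {measure!r}; choose from {CENTRALITY_MEASURES}"
    )


@dataclass(frozen=True)
class DrugScore:
    """One ranked drug candidate and the mechanism nodes it targets."""

    drug: str
    score: float
    targets: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.score > 0 and not self.targets:
            raise ValueError("positive score requires >=1 targeted mechanism node")


def rank_drugs(
    network: MechanismNetwork,
    mechanism_nodes: set[str],
    method: str = "trustrank",
    top_k: int | None = None,
    include_non_approved: bool = False,
) -> list[DrugScore]:
    """Rank drugs targeting at least one mechanism node.

    ``method="trustrank"`` scores drugs directly by propagation in the
    combined protein+drug graph seeded on the mechanism nodes; a centrality
    method scores a drug as the sum of the centralities of its mechanism
    targets. Ties break by number of mechanism targets, then drug id.
    """
    mechanism = set(mechanism_nodes)
    outside = sorted(m for m in mechanism if m not in network.graph)
    if outside:
        raise ValueError(f"mechanism nodes not in protein network: {outside}")
    if not mechanism:
        return []
    candidates: dict[str, tuple[str, ...]] = {}
    for drug, targets in network.drug_targets.items():
        if not include_non_approved and not network.drug_approved.get(drug, True):
            continue
        hit = tuple(sorted(targets & mechanism))
        if hit:
            candidates[drug] = hit
    if not candidates:
        return []
    if method == "trustrank":
        scores = trustrank(network, mechanism)
        drug_score = {d: scores.get(d, 0.0) for d in candidates}
    elif method in CENTRALITY_MEASURES:
        node_scores = centralities(network, method)
        drug_score = {
            d: sum(node_scores.get(t, 0.0) for t in targets)
            for d, targets in candidates.items()
        }
    else:
        raise ValueError(f"unknown ranking method {method!r}")
    ranked = sorted(
        (
            DrugScore(d, drug_score[d], candidates[d])
            for d in candidates
        ),
        key=lambda ds: (-ds.score, -len(ds.targets), ds.drug),
    )
    if top_k is not None:
        ranked = ranked[:top_k]
    return ranked
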