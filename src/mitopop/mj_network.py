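"""Median-joining haplotype networks.

The construction follows the published median-joining scheme: build the
minimum spanning network (all links within epsilon of the minimal
connection level), then repeatedly add quasi-medians — per-site majority
consensus of connected node triplets, with all combinations retained on
three-way ties — as inferred "median vector" (mv) nodes until no new
median arises, and finally prune mv nodes that lie on no minimal path
between observed haplotypes.  Edge labels are the 1-based alignment
positions at which the two endpoint sequences differ, so every edge's
label count equals the Hamming distance between its endpoints.

With epsilon = 0 and homoplasy-free data the result collapses to the
unique minimum spanning tree with multi-site edges kept as single labelled
links.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product

import networkx as nx

from .haplotypes import HaplotypeTable


@dataclass(frozen=True)
class NetworkParams:
    epsilon: int = 0
    #: per-site weights (uniform by default); parallel to the variable sites
    weights: tuple[float, ...] | None = None
    #: quasi-median explosion guard per triplet
    tie_cap: int = 2 ** 10

    def __post_init__(self):
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")


@dataclass
class HaplotypeNetwork:
    """Observed haplotypes plus inferred median vectors in one graph.

    Nodes are labelled ``H1..Hk`` (observed, carrying ``frequency`` and
    ``members``) and ``mv1..`` (median vectors, frequency 0); every node
    has a ``pattern`` over the variable sites and a ``kind`` attribute.
    Edges carry ``positions`` — the original alignment positions mutated
    along the link.
    """

    graph: nx.Graph
    sites: tuple[int, ...]
    epsilon: int = 0

    @property
    def observed(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "observed"]

    @property
    def median_vectors(self) -> list[str]:
        return [
            n for n, d in self.graph.nodes(data=True) if d["kind"] == "median_vector"
        ]


def condense_characters(table: HaplotypeTable) -> tuple[list[str], tuple[int, ...]]:
    """Per-haplotype state strings over the variable sites only.

    Returns (patterns, positions); positions are original 1-based alignment
    columns and are retained for edge labelling.  Duplicate columns are
    kept separately — each contributes its own edge label.
    """
    col_index = {c: i for i, c in enumerate(table.analyzed_columns)}
    idx = [col_index[s] for s in table.sites]
    condensed = ["".join(h.pattern[i] for i in idx) for h in table.haplotypes]
    return condensed, table.sites


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _msn_edges(patterns: list[str], epsilon: int) -> list[tuple[int, int, int]]:
    """Minimum-spanning-network links among ``patterns``.

    Links are added level by level (ascending Hamming distance); a link at
    level d is feasible when its endpoints' components were still separate
    before level d - epsilon ... i.e. when d <= (component connection
    level) + epsilon.
    """
    n = len(patterns)
    if n <= 1:
        return []
    dist = {(i, j): _hamming(patterns[i], patterns[j]) for i, j in combinations(range(n), 2)}
    levels = sorted(set(dist.values()))
    # epsilon = 0 pass to find the connection level of each pair of components
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    conn_level = {}
    for lvl in levels:
        before = {x: find(x) for x in range(n)}
        for i, j in ((i, j) for (i, j), d in dist.items() if d == lvl):
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[ri] = rj
        for a, b in combinations(range(n), 2):
            if (a, b) not in conn_level and find(a) == find(b):
                if before[a] != before[b]:
                    conn_level[(a, b)] = lvl
        if all(find(x) == find(0) for x in range(n)):
            break
    edges = []
    for (i, j), d in dist.items():
        if d == 0:
            continue
        if d <= conn_level[(i, j)] + epsilon:
            edges.append((i, j, d))
    return edges


def quasi_medians(u: str, v: str, w: str, cap: int = 2 ** 10) -> list[str]:
    """Per-site majority consensus of three sequences.

    Where two of the three states agree the majority state is taken; a
    three-way tie keeps all three alternatives (all combinations are
    generated, capped at ``cap`` per triplet).
    """
    choices = []
    n_combo = 1
    for a, b, c in zip(u, v, w):
        if a == b or a == c:
            choices.append((a,))
        elif b == c:
            choices.append((b,))
        else:
            choices.append((a, b, c))
            n_combo *= 3
            if n_combo > cap:
                raise ValueError(f"quasi-median explosion: > {cap} combinations")
    return ["".join(combo) for combo in product(*choices)]


def median_joining(
    table: HaplotypeTable, params: NetworkParams = NetworkParams()
) -> HaplotypeNetwork:
    """Build the median-joining network of a haplotype table."""
    condensed, sites = condense_characters(table)
    names = [f"H{i+1}" for i in range(table.H)]
    patterns = list(condensed)
    observed_set = set(condensed)

    # growth phase: add novel quasi-medians of connected triplets to fixpoint
    while True:
        edges = _msn_edges(patterns, params.epsilon)
        nbrs: dict[int, set[int]] = {i: set() for i in range(len(patterns))}
        for i, j, _ in edges:
            nbrs[i].add(j)
            nbrs[j].add(i)
        known = set(patterns)
        new: list[str] = []
        for v, neigh in nbrs.items():
            for u, w in combinations(sorted(neigh), 2):
                for m in quasi_medians(patterns[u], patterns[v], patterns[w], params.tie_cap):
                    if m not in known:
                        known.add(m)
                        new.append(m)
        if not new:
            break
        patterns.extend(sorted(new))  # sorted: deterministic node ids

    # assemble graph over final node set
    mv_count = 0
    node_ids = []
    g = nx.Graph()
    for k, pat in enumerate(patterns):
        if k < len(condensed):
            node = names[k]
            h = table.haplotypes[k]
            g.add_node(
                node,
                kind="observed",
                pattern=pat,
                frequency=h.count,
                members=",".join(h.members),
            )
        else:
            mv_count += 1
            node = f"mv{mv_count}"
            g.add_node(node, kind="median_vector", pattern=pat, frequency=0, members="")
        node_ids.append(node)
    for i, j, d in _msn_edges(patterns, params.epsilon):
        positions = [
            sites[k] for k, (a, b) in enumerate(zip(patterns[i], patterns[j])) if a != b
        ]
        g.add_edge(node_ids[i], node_ids[j], positions=positions, weight=d)
    if len(patterns) == 1:
        pass  # single-node network; nothing to connect

    net = HaplotypeNetwork(graph=g, sites=sites, epsilon=params.epsilon)
    _prune_obsolete(net)
    return net


def _prune_obsolete(net: HaplotypeNetwork) -> None:
    """Remove median vectors on no minimal observed-observed path, to fixpoint."""
    while True:
        g = net.graph
        obs = net.observed
        mvs = net.median_vectors
        if not mvs:
            return
        dist = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
        doomed = []
        for mv in mvs:
            on_path = False
            for a, b in combinations(obs, 2):
                if b in dist.get(a, {}) and mv in dist.get(a, {}) and b in dist.get(mv, {}):
                    if abs(dist[a][mv] + dist[mv][b] - dist[a][b]) < 1e-9:
                        on_path = True
                        break
            if not on_path:
                doomed.append(mv)
        if not doomed:
            return
        g.remove_nodes_from(doomed)


def network_summary(net: HaplotypeNetwork) -> dict:
    """Integer summary: observed nodes, median vectors, edges, modal node."""
    g = net.graph
    obs = net.observed
    max_node = max(obs, key=lambda n: g.nodes[n]["frequency"]) if obs else None
    return {
        "n_observed": len(obs),
        "n_median_vectors": len(net.median_vectors),
        "n_edges": g.number_of_edges(),
        "max_frequency_node": max_node,
    }


def edge_list_text(net: HaplotypeNetwork) -> str:
    """Plain-text edge list with mutated-position labels."""
    lines = ["node_a\tnode_b\tn_mutations\tpositions"]
    for a, b, data in sorted(net.graph.edges(data=True)):
        pos = ";".join(str(p) for p in data["positions"])
        lines.append(f"{a}\t{b}\t{len(data['positions'])}\t{pos}")
    return "\n".join(lines) + "\n"
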