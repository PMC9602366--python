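"""Minimum-spanning and median-joining haplotype networks.

The minimum spanning network (MSN) at relaxation ``epsilon`` contains a link
u-v whenever d(u,v) <= minimax(u,v) + epsilon, where minimax(u,v) is the
smallest possible largest step over all paths between u and v; at epsilon=0
this is exactly the union of all minimum spanning trees.

The median-joining construction (after Bandelt, Forster & Roehl 1999)
iterates: build the MSN over the current node set; for every node u and
every pair of its network neighbours v, w, compute the quasi-median of
(u, v, w) — per column the majority state, or every observed state of the
column when all three differ; add novel medians; repeat to closure.  As a
final maximum-parsimony cleanup, median vectors lying on no shortest path
between two observed haplotypes are removed (iterated to a fixed point).

All tie-breaking is lexicographic on node sequences, making output
deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations, product

import networkx as nx

from .seqio import HaplotypeTable

__all__ = [
    "NetworkNode",
    "NetworkEdge",
    "HaplotypeNetwork",
    "minimum_spanning_network",
    "median_joining",
    "quasi_medians",
    "export_network",
    "read_network",
]


@dataclass(frozen=True)
class NetworkNode:
    node_id: str
    sequence: str
    kind: str  # "observed" | "median_vector"
    frequency: int = 0
    pop_composition: dict[str, int] = field(default_factory=dict)


@dataclass(frozen=True)
class NetworkEdge:
    u: str
    v: str
    weight: int
    positions: tuple[int, ...]  # 1-based differing columns


@dataclass(frozen=True)
class HaplotypeNetwork:
    nodes: tuple[NetworkNode, ...]
    edges: tuple[NetworkEdge, ...]
    epsilon: int = 0

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(epsilon=self.epsilon)
        for n in self.nodes:
            g.add_node(
                n.node_id,
                sequence=n.sequence,
                kind=n.kind,
                frequency=n.frequency,
                pop_composition=dict(n.pop_composition),
            )
        for e in self.edges:
            g.add_edge(e.u, e.v, weight=e.weight, positions=e.positions)
        return g

    @property
    def observed(self) -> tuple[NetworkNode, ...]:
        return tuple(n for n in self.nodes if n.kind == "observed")

    @property
    def median_vectors(self) -> tuple[NetworkNode, ...]:
        return tuple(n for n in self.nodes if n.kind == "median_vector")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _diff_positions(a: str, b: str) -> tuple[int, ...]:
    return tuple(j + 1 for j, (x, y) in enumerate(zip(a, b)) if x != y)


def _minimax_distances(seqs: list[str]) -> dict[tuple[int, int], int]:
    """Minimax (bottleneck) distance for every pair, by level-wise merging."""
    n = len(seqs)
    d = {(i, j): _hamming(seqs[i], seqs[j]) for i in range(n) for j in range(i + 1, n)}
    comp = list(range(n))
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    mm: dict[tuple[int, int], int] = {}
    for level in sorted(set(d.values())):
        # merge all components connected by edges at this level
        for (i, j), dist in d.items():
            if dist != level:
                continue
            ci, cj = comp[i], comp[j]
            if ci == cj:
                continue
            for a in members[ci]:
                for b in members[cj]:
                    mm[(min(a, b), max(a, b))] = level
            for b in members[cj]:
                comp[b] = ci
            members[ci].extend(members.pop(cj))
        if len(members) == 1:
            break
    return mm


def _msn_edges(seqs: list[str], epsilon: int) -> list[tuple[int, int, int]]:
    """(i, j, weight) links of the epsilon-relaxed minimum spanning network."""
    if len(seqs) < 2:
        return []
    mm = _minimax_distances(seqs)
    edges = []
    for (i, j), level in mm.items():
        dist = _hamming(seqs[i], seqs[j])
        if dist <= level + epsilon:
            edges.append((i, j, dist))
    return sorted(edges)


def quasi_medians(u: str, v: str, w: str) -> list[str]:
    """Quasi-medians of three equal-length sequences.

    Per column: the majority state; when all three states differ, every one
    of the three is kept, and all combinations across such columns are
    generated (sorted lexicographically).
    """
    options: list[tuple[str, ...]] = []
    for a, b, c in zip(u, v, w):
        if a == b or a == c:
            options.append((a,))
        elif b == c:
            options.append((b,))
        else:
            options.append(tuple(sorted({a, b, c})))
    return sorted("".join(combo) for combo in product(*options))


def _build(
    ht: HaplotypeTable, seqs: list[str], observed: dict[str, str], epsilon: int
) -> HaplotypeNetwork:
    """Assemble a HaplotypeNetwork from a node sequence set."""
    pops = ht.populations
    nodes = []
    med_counter = 0
    id_of: dict[str, str] = {}
    for s in seqs:
        if s in observed:
            hid = observed[s]
            comp = {
                p: ht.counts[(hid, p)] for p in pops if (hid, p) in ht.counts
            }
            nodes.append(
                NetworkNode(hid, s, "observed", sum(comp.values()), comp)
            )
            id_of[s] = hid
        else:
            med_counter += 1
            mid = f"mv{med_counter}"
            nodes.append(NetworkNode(mid, s, "median_vector", 0, {}))
            id_of[s] = mid
    edges = [
        NetworkEdge(
            id_of[seqs[i]],
            id_of[seqs[j]],
            w,
            _diff_positions(seqs[i], seqs[j]),
        )
        for i, j, w in _msn_edges(seqs, epsilon)
    ]
    return HaplotypeNetwork(tuple(nodes), tuple(edges), epsilon)


def _node_order(ht: HaplotypeTable, extra: set[str]) -> list[str]:
    observed_seqs = list(ht.haplotypes.values())
    return observed_seqs + sorted(extra - set(observed_seqs))


def minimum_spanning_network(
    ht: HaplotypeTable, epsilon: int = 0
) -> HaplotypeNetwork:
    """Epsilon-relaxed minimum spanning network over observed haplotypes."""
    seqs = _node_order(ht, set())
    observed = {s: h for h, s in ht.haplotypes.items()}
    return _build(ht, seqs, observed, epsilon)


def median_joining(
    ht: HaplotypeTable,
    epsilon: int = 0,
    max_iter: int = 50,
    max_nodes: int = 5000,
) -> HaplotypeNetwork:
    """Median-joining network over observed haplotypes.

    Returns a connected network of all observed haplotypes plus the median
    vectors that survive the shortest-path pruning step.
    """
    observed = {s: h for h, s in ht.haplotypes.items()}
    current: set[str] = set(observed)
    for _ in range(max_iter):
        seqs = _node_order(ht, current)
        index = {s: i for i, s in enumerate(seqs)}
        adj: dict[int, set[int]] = {i: set() for i in range(len(seqs))}
        for i, j, _w in _msn_edges(seqs, epsilon):
            adj[i].add(j)
            adj[j].add(i)
        new: set[str] = set()
        for i, nbrs in adj.items():
            for a, b in combinations(sorted(nbrs), 2):
                for m in quasi_medians(seqs[i], seqs[a], seqs[b]):
                    if m not in index:
                        new.add(m)
        if not new:
            break
        current |= new
        if len(current) > max_nodes:
            raise RuntimeError(
                "median-joining closure exceeded the node budget; "
                "raise max_nodes or epsilon"
            )

    # maximum-parsimony cleanup: drop medians off every shortest
    # observed-observed path, then rebuild, to a fixed point
    while True:
        seqs = _node_order(ht, current)
        net = _build(ht, seqs, observed, epsilon)
        g = net.to_networkx()
        obs_ids = [n.node_id for n in net.observed]
        dist = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
        drop: set[str] = set()
        for n in net.median_vectors:
            if not _on_some_shortest_path(n.node_id, obs_ids, dist):
                drop.add(n.sequence)
        if not drop:
            return net
        current -= drop


def _on_some_shortest_path(mid: str, obs_ids: list[str], dist) -> bool:
    for a, b in combinations(obs_ids, 2):
        if b not in dist.get(a, {}):
            continue
        da = dist[a].get(mid)
        db = dist[b].get(mid)
        if da is not None and db is not None and da + db == dist[a][b]:
            return True
    return False


# ---------------------------------------------------------------------------
# Export / import


def export_network(net: HaplotypeNetwork, path, format: str = "edge_tsv") -> None:
    """Write a network losslessly as tagged TSV or GraphML."""
    if format == "edge_tsv":
        with open(path, "w") as fh:
            fh.write(f"#epsilon\t{net.epsilon}\n")
            fh.write("#N\tnode_id\tkind\tsequence\tfrequency\tpop_composition\n")
            for n in net.nodes:
                fh.write(
                    "N\t{}\t{}\t{}\t{}\t{}\n".format(
                        n.node_id,
                        n.kind,
                        n.sequence,
                        n.frequency,
                        json.dumps(n.pop_composition, sort_keys=True),
                    )
                )
            fh.write("#E\tu\tv\tweight\tpositions\n")
            for e in net.edges:
                fh.write(
                    "E\t{}\t{}\t{}\t{}\n".format(
                        e.u, e.v, e.weight, ",".join(map(str, e.positions))
                    )
                )
    elif format == "graphml":
        g = net.to_networkx()
        for _n, data in g.nodes(data=True):
            data["pop_composition"] = json.dumps(
                data["pop_composition"], sort_keys=True
            )
        for _u, _v, data in g.edges(data=True):
            data["positions"] = ",".join(map(str, data["positions"]))
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path, format: str = "edge_tsv") -> HaplotypeNetwork:
    """Read a network written by :func:`export_network`."""
    if format != "edge_tsv":
        raise ValueError("only edge_tsv read-back is supported")
    nodes: list[NetworkNode] = []
    edges: list[NetworkEdge] = []
    epsilon = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#epsilon"):
                epsilon = int(line.split("\t")[1])
            elif line.startswith("N\t"):
                _, nid, kind, seq, freq, comp = line.split("\t")
                nodes.append(
                    NetworkNode(nid, seq, kind, int(freq), json.loads(comp))
                )
            elif line.startswith("E\t"):
                _, u, v, w, pos = line.split("\t")
                positions = tuple(int(x) for x in pos.split(",")) if pos else ()
                edges.append(NetworkEdge(u, v, int(w), positions))
    return HaplotypeNetwork(tuple(nodes), tuple(edges), epsilon)
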