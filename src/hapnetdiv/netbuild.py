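"""Distance-based haplotype network construction.

The network is a minimum spanning tree over pairwise mutational distances,
augmented with "alternative" links: non-tree pairs whose distance does not
exceed the largest weight on the tree path between them (plus an optional
slack ``epsilon``). With ``epsilon=0`` the alternative links are exactly the
equal-cost connections a minimum-spanning-network display would show.

Edge weights (mutational steps) are retained for export only; no diversity
metric depends on them — only node degrees matter downstream.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Optional, Sequence

import networkx as nx
import numpy as np

from .errors import NetworkValidationError
from .haplotypes import POLICIES, HaplotypeTable
from .seqio import UNAMBIGUOUS

logger = logging.getLogger(__name__)

Node = Hashable


@dataclass(frozen=True)
class Edge:
    u: Node
    v: Node
    weight: float
    alternative: bool = False


@dataclass
class HaplotypeNetwork:
    """Nodes are haplotypes (with individual counts); edges carry mutational
    step weights and an alternative-link flag. Spanning (non-alternative)
    edges must form a tree over all nodes."""

    counts: dict[Node, int]
    edges: list[Edge] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        nodes = set(self.counts)
        if not nodes:
            raise NetworkValidationError("network has no nodes")
        if any(c < 1 for c in self.counts.values()):
            raise NetworkValidationError("every haplotype needs >= 1 individual")
        seen: set[frozenset] = set()
        for e in self.edges:
            if e.u == e.v:
                raise NetworkValidationError(f"self-loop on node {e.u!r}")
            pair = frozenset((e.u, e.v))
            if pair in seen:
                raise NetworkValidationError(f"duplicate edge {e.u!r}-{e.v!r}")
            seen.add(pair)
            if e.u not in nodes or e.v not in nodes:
                raise NetworkValidationError(
                    f"edge {e.u!r}-{e.v!r} references a node missing from counts"
                )
        if len(nodes) >= 2:
            g = nx.Graph()
            g.add_nodes_from(nodes)
            g.add_edges_from((e.u, e.v) for e in self.spanning_edges)
            if len(self.spanning_edges) != len(nodes) - 1 or not nx.is_connected(g):
                raise NetworkValidationError(
                    "spanning (non-alternative) edges must form a tree: expected "
                    f"{len(nodes) - 1} edges connecting all nodes, got "
                    f"{len(self.spanning_edges)}"
                )

    @property
    def nodes(self) -> list[Node]:
        return list(self.counts)

    @property
    def nH(self) -> int:
        return len(self.counts)

    @property
    def n(self) -> int:
        """Total individuals across haplotypes."""
        return sum(self.counts.values())

    @property
    def spanning_edges(self) -> list[Edge]:
        return [e for e in self.edges if not e.alternative]

    @property
    def alternative_edges(self) -> list[Edge]:
        return [e for e in self.edges if e.alternative]

    def degrees(self, count_alternative: bool = True) -> dict[Node, int]:
        """Subtending branches per haplotype: incident spanning edges plus,
        by default, incident alternative links."""
        deg = {node: 0 for node in self.counts}
        for e in self.edges:
            if e.alternative and not count_alternative:
                continue
            deg[e.u] += 1
            deg[e.v] += 1
        return deg

    def degree_of(self, node: Node, count_alternative: bool = True) -> int:
        return self.degrees(count_alternative)[node]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for node, count in self.counts.items():
            g.add_node(node, individuals=int(count))
        for e in self.edges:
            g.add_edge(e.u, e.v, weight=float(e.weight), alternative=e.alternative)
        return g

    def write_edges_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(["u", "v", "weight", "alternative"])
            for e in self.edges:
                writer.writerow([e.u, e.v, e.weight, str(e.alternative).lower()])

    def write_gml(self, path: str | Path) -> None:
        nx.write_gml(self.to_networkx(), str(path), stringizer=str)


def hamming_distances(table: HaplotypeTable, policy: str = "strict") -> np.ndarray:
    """Pairwise mutational distances between haplotype keys.

    A column contributes 1 when both characters are unambiguous bases
    (``ACGT``) and differ; columns where either character is a gap/ambiguity
    code contribute 0 (pairwise deletion). Under ``ignore-ambiguous-sites``
    those columns were already removed during collapsing, so plain Hamming
    distance results.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown ambiguity policy {policy!r}; choose from {POLICIES}")
    keys = [h.key for h in table.haplotypes]
    k = len(keys)
    dist = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i + 1, k):
            d = sum(
                1
                for a, b in zip(keys[i], keys[j])
                if a != b and a in UNAMBIGUOUS and b in UNAMBIGUOUS
            )
            dist[i, j] = dist[j, i] = d
            if d == 0:
                # possible under strict policy when haplotypes differ only at
                # ambiguous/gap sites; kept, but worth flagging
                logger.warning(
                    "haplotypes %d and %d are distinct but at pairwise-deletion "
                    "distance 0",
                    i,
                    j,
                )
    return dist


def _validate_distances(dist: np.ndarray) -> None:
    dist = np.asarray(dist)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise NetworkValidationError("distance matrix must be square")
    if not np.array_equal(dist, dist.T):
        raise NetworkValidationError("distance matrix must be symmetric")
    if np.any(np.diag(dist) != 0):
        raise NetworkValidationError("distance matrix diagonal must be zero")
    if np.any(dist < 0):
        raise NetworkValidationError("distances must be non-negative")


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def build_msn(
    dist: np.ndarray,
    counts: Optional[Sequence[int]] = None,
    epsilon: int = 0,
) -> HaplotypeNetwork:
    """Build a minimum spanning network from a distance matrix.

    Spanning edges are a Kruskal minimum spanning tree with edges examined in
    (weight, min(u, v), max(u, v)) order, which makes the tree deterministic
    among equal-cost alternatives. Every non-tree pair (u, v) whose distance
    is at most the largest weight on the tree path between u and v, plus
    *epsilon*, is added as an alternative link.

    *counts* gives individuals per haplotype (defaults to 1 each, e.g. for a
    purely topological network).
    """
    _validate_distances(dist)
    dist = np.asarray(dist)
    k = dist.shape[0]
    if k < 2:
        raise NetworkValidationError(
            "need at least 2 haplotypes to build a network (degenerate input)"
        )
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if counts is None:
        counts = [1] * k
    if len(counts) != k:
        raise NetworkValidationError("counts length must match distance matrix size")

    candidates = sorted(
        ((int(dist[u, v]), u, v) for u in range(k) for v in range(u + 1, k)),
        key=lambda t: (t[0], t[1], t[2]),
    )
    uf = _UnionFind(k)
    tree_edges: list[tuple[int, int, int]] = []
    for w, u, v in candidates:
        if uf.union(u, v):
            tree_edges.append((u, v, w))
            if len(tree_edges) == k - 1:
                break

    tree = nx.Graph()
    tree.add_nodes_from(range(k))
    for u, v, w in tree_edges:
        tree.add_edge(u, v, weight=w)

    edges = [Edge(u, v, w, alternative=False) for u, v, w in tree_edges]
    in_tree = {frozenset((u, v)) for u, v, _ in tree_edges}
    for u in range(k):
        for v in range(u + 1, k):
            if frozenset((u, v)) in in_tree:
                continue
            path = nx.shortest_path(tree, u, v)
            bottleneck = max(
                tree[a][b]["weight"] for a, b in zip(path, path[1:])
            )
            if dist[u, v] <= bottleneck + epsilon:
                edges.append(Edge(u, v, int(dist[u, v]), alternative=True))

    return HaplotypeNetwork(
        counts={i: int(c) for i, c in enumerate(counts)}, edges=edges
    )


def network_from_table(
    table: HaplotypeTable, policy: str = "strict", epsilon: int = 0
) -> HaplotypeNetwork:
    """Convenience: distances + MSN in one step, with counts from the table."""
    dist = hamming_distances(table, policy=policy)
    return build_msn(dist, counts=table.counts, epsilon=epsilon)


def _parse_bool(text: str) -> bool:
    val = text.strip().lower()
    if val in ("true", "1", "yes"):
        return True
    if val in ("false", "0", "no", ""):
        return False
    raise NetworkValidationError(f"cannot parse boolean field {text!r}")


def read_network(edge_list_path: str | Path, counts_path: str | Path) -> HaplotypeNetwork:
    """Ingest an externally built network.

    *edge_list_path*: TSV with header ``u, v, weight[, alternative]``.
    *counts_path*: TSV with header ``node, individuals``. Every node used in
    an edge must appear in the counts file, and the non-alternative edges
    must form a spanning tree.
    """
    counts: dict[str, int] = {}
    with open(counts_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {"node", "individuals"} <= set(
            reader.fieldnames
        ):
            raise NetworkValidationError(
                f"counts file {counts_path} must have columns node, individuals"
            )
        for row in reader:
            node = row["node"].strip()
            if node in counts:
                raise NetworkValidationError(f"duplicate node in counts: {node!r}")
            counts[node] = int(row["individuals"])

    edges: list[Edge] = []
    with open(edge_list_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {"u", "v", "weight"} <= set(
            reader.fieldnames
        ):
            raise NetworkValidationError(
                f"edge list {edge_list_path} must have columns u, v, weight"
            )
        for row in reader:
            u, v = row["u"].strip(), row["v"].strip()
            for node in (u, v):
                if node not in counts:
                    raise NetworkValidationError(
                        f"edge references node {node!r} missing from counts file"
                    )
            alt = _parse_bool(row.get("alternative", "") or "")
            edges.append(Edge(u, v, float(row["weight"]), alternative=alt))

    return HaplotypeNetwork(counts=counts, edges=edges)
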