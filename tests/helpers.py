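"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: diversity values come
from explicit enumeration of individual pairs, and minimum-spanning-tree
weights from exhaustive search over all spanning trees.
"""

from __future__ import annotations

import itertools

import numpy as np


def pair_diversity(counts: list[int]) -> float:
    """Probability that two individuals drawn without replacement carry
    different labels, by explicit enumeration of all unordered pairs."""
    labels = [i for i, c in enumerate(counts) for _ in range(c)]
    pairs = list(itertools.combinations(range(len(labels)), 2))
    different = sum(1 for a, b in pairs if labels[a] != labels[b])
    return different / len(pairs)


def _is_spanning_tree(n_nodes: int, edges: list[tuple[int, int]]) -> bool:
    parent = list(range(n_nodes))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru == rv:
            return False
        parent[rv] = ru
    return True


def brute_force_mst_weight(dist: np.ndarray) -> int:
    """Minimum total weight over every spanning tree of the complete graph
    on the matrix's nodes, by exhaustive enumeration (small n only)."""
    k = dist.shape[0]
    all_edges = [(u, v) for u in range(k) for v in range(u + 1, k)]
    best = None
    for combo in itertools.combinations(all_edges, k - 1):
        if not _is_spanning_tree(k, list(combo)):
            continue
        weight = sum(int(dist[u, v]) for u, v in combo)
        if best is None or weight < best:
            best = weight
    assert best is not None
    return best


def random_count_vector(rng: np.random.Generator, max_n: int = 60) -> list[int]:
    """A random partition of n <= max_n individuals into labeled groups."""
    n = int(rng.integers(2, max_n + 1))
    k = int(rng.integers(1, n + 1))
    # random composition of n into k positive parts
    cuts = sorted(rng.choice(np.arange(1, n), size=k - 1, replace=False).tolist())
    parts = [b - a for a, b in zip([0, *cuts], [*cuts, n])]
    assert sum(parts) == n and all(p >= 1 for p in parts)
    return parts
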