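"""Shared fixtures: the seeded default synthetic dataset and tree oracles."""
from __future__ import annotations

import numpy as np
import pytest

from rakerid.barcode_core import DistanceMatrix
from rakerid.synthetic_data import GeneratorConfig, generate_dataset

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def default_cfg() -> GeneratorConfig:
    return GeneratorConfig(seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def default_dataset(default_cfg):
    """(panel, specimen_set) for the seeded default market survey."""
    return generate_dataset(default_cfg)


@pytest.fixture(scope="session")
def panel(default_dataset):
    return default_dataset[0]


@pytest.fixture(scope="session")
def specimen_set(default_dataset):
    return default_dataset[1]


# ---------------------------------------------------------------------------
# independent tree oracle: random additive trees and path-sum distances


def random_additive_tree(rng: np.random.Generator, n_taxa: int):
    """Random unrooted binary tree as an adjacency map with positive lengths.

    Built by sequential attachment: each new leaf is grafted onto a uniformly
    chosen existing edge. Returns (adjacency, leaf names).
    """
    leaves = [f"T{i}" for i in range(n_taxa)]
    adj: dict[str, dict[str, float]] = {}
    next_internal = [0]

    def add_edge(a, b, w):
        adj.setdefault(a, {})[b] = w
        adj.setdefault(b, {})[a] = w

    def drop_edge(a, b):
        del adj[a][b]
        del adj[b][a]

    def blen():
        return float(rng.uniform(0.05, 1.0))

    add_edge(leaves[0], leaves[1], blen())
    for leaf in leaves[2:]:
        edges = [(a, b) for a in adj for b in adj[a] if a < b]
        a, b = edges[rng.integers(0, len(edges))]
        w = adj[a][b]
        node = f"I{next_internal[0]}"
        next_internal[0] += 1
        split = float(rng.uniform(0.2, 0.8)) * w
        drop_edge(a, b)
        add_edge(a, node, split)
        add_edge(node, b, w - split)
        add_edge(node, leaf, blen())
    return adj, leaves


def path_distance_matrix(adj, leaves) -> DistanceMatrix:
    """Leaf-to-leaf path-sum distances (the additivity oracle)."""
    n = len(leaves)
    d = np.zeros((n, n))
    for i, src in enumerate(leaves):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u].items():
                if v not in dist:
                    dist[v] = dist[u] + w
                    stack.append(v)
        for j, dst in enumerate(leaves):
            d[i, j] = dist[dst]
    np.fill_diagonal(d, 0.0)
    ones = np.ones((n, n))
    return DistanceMatrix(tuple(leaves), d, ones, np.zeros((n, n)), np.zeros((n, n)))


def tree_splits_oracle(adj, leaves) -> set[frozenset]:
    """Nontrivial splits of the oracle tree, anchored off the smallest leaf."""
    anchor = min(leaves)
    all_leaves = frozenset(leaves)
    splits = set()
    for a in adj:
        for b in adj[a]:
            if a >= b:
                continue
            # leaves on b's side of edge (a, b)
            side = set()
            stack = [b]
            seen = {a, b}
            while stack:
                u = stack.pop()
                if u in leaves:
                    side.add(u)
                for v in adj[u]:
                    if v not in seen:
                        seen.add(v)
                        stack.append(v)
            if 1 < len(side) < len(leaves) - 1:
                key = frozenset(side) if anchor not in side else all_leaves - frozenset(side)
                splits.add(key)
    return splits
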