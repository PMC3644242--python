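"""Independent oracles used by the tests.

Brute-force phylogenetic machinery: explicit enumeration of unrooted
topologies with least-squares branch-length fitting, plus split-set
extraction for topology comparison.  Kept deliberately independent of
the package's neighbour-joining implementation.
"""

from __future__ import annotations

import itertools

import numpy as np


def enumerate_topologies(n: int):
    """All unrooted binary topologies on taxa 0..n-1 as edge lists.

    Internal nodes are labelled with negative integers.  n=4 yields 3
    topologies, n=5 yields 15.
    """
    base = [(-1, 0), (-1, 1), (-1, 2)]
    trees = [base]
    next_internal = -2
    for taxon in range(3, n):
        new_trees = []
        for edges in trees:
            for k, (u, v) in enumerate(edges):
                w = next_internal
                new = edges[:k] + edges[k + 1 :] + [(u, w), (w, v), (w, taxon)]
                new_trees.append(new)
        trees = new_trees
        next_internal -= 1
    return trees


def _paths(edges, n):
    """Pair -> set of edge indices on the path, via BFS on the tree."""
    adj: dict = {}
    for k, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, k))
        adj.setdefault(v, []).append((u, k))
    out = {}
    for i in range(n):
        # BFS from taxon i recording the edge path
        prev = {i: (None, None)}
        queue = [i]
        while queue:
            node = queue.pop(0)
            for nb, ek in adj[node]:
                if nb not in prev:
                    prev[nb] = (node, ek)
                    queue.append(nb)
        for j in range(i + 1, n):
            path = set()
            node = j
            while node != i:
                node, ek = prev[node]
                path.add(ek)
            out[(i, j)] = path
    return out


def ls_best_topology(D: np.ndarray):
    """Least-squares topology search: fit branch lengths for every
    topology and return (edges, rss) of the best fit."""
    n = D.shape[0]
    pairs = list(itertools.combinations(range(n), 2))
    d = np.array([D[i, j] for i, j in pairs])
    best = None
    for edges in enumerate_topologies(n):
        paths = _paths(edges, n)
        A = np.zeros((len(pairs), len(edges)))
        for r, (i, j) in enumerate(pairs):
            for ek in paths[(i, j)]:
                A[r, ek] = 1.0
        b, *_ = np.linalg.lstsq(A, d, rcond=None)
        rss = float(((A @ b - d) ** 2).sum())
        if best is None or rss < best[1] - 1e-12:
            best = (edges, rss)
    return best


def splits_of_edges(edges, n) -> frozenset:
    """Non-trivial splits (bipartitions of taxa) induced by a topology."""
    adj: dict = {}
    for (u, v) in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    splits = set()
    taxa = frozenset(range(n))
    for (u, v) in edges:
        # taxa on v's side when edge (u, v) is removed
        seen = {v}
        stack = [v]
        while stack:
            node = stack.pop()
            for nb in adj[node]:
                if (node, nb) == (v, u):
                    continue
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        side = frozenset(t for t in seen if t >= 0)
        if 2 <= len(side) <= n - 2:
            splits.add(frozenset({side, taxa - side}))
    return frozenset(splits)


def splits_of_treenode(tree, name_to_taxon: dict) -> frozenset:
    """Non-trivial splits of a scikit-bio TreeNode (unrooted sense)."""
    taxa = frozenset(name_to_taxon.values())
    n = len(taxa)
    splits = set()
    for node in tree.traverse(include_self=False):
        tips = frozenset(name_to_taxon[t.name] for t in node.tips(include_self=True))
        if 2 <= len(tips) <= n - 2:
            splits.add(frozenset({tips, taxa - tips}))
    return frozenset(splits)


def random_additive_tree(rng: np.random.Generator, n: int):
    """A random unrooted topology with branch lengths, and its exact
    path-distance matrix."""
    topologies = enumerate_topologies(n)
    edges = topologies[int(rng.integers(len(topologies)))]
    lengths = rng.uniform(0.5, 1.5, len(edges))
    paths = _paths(edges, n)
    D = np.zeros((n, n))
    for (i, j), path in paths.items():
        D[i, j] = D[j, i] = sum(lengths[k] for k in path)
    return edges, D
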