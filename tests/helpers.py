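"""Independent oracles used by the tests.

Everything here is deliberately naive (nested loops, graph traversal on an
adjacency dict) and shares no code path with the package implementation it
checks.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np


def naive_scan(seq: str, spacers: tuple[int, int, int]) -> list[int]:
    """Four-nested-position motif scanner; 1-based starts, overlaps included."""
    i, j, k = spacers
    length = 4 + i + j + k
    out = []
    for s in range(len(seq) - length + 1):
        if (seq[s] == "C" and seq[s + 1 + i] == "C"
                and seq[s + 2 + i + j] == "C" and seq[s + 3 + i + j + k] == "C"):
            out.append(s + 1)
    return out


# ---------------------------------------------------------------------------
# Random additive matrices from random unrooted binary trees
# ---------------------------------------------------------------------------

def random_additive_tree(rng: np.random.Generator, n_leaves: int):
    """Random unrooted binary tree as a weighted adjacency dict.

    Leaves are 0..n-1; internal nodes get higher ids.  Built by repeatedly
    attaching a new leaf to a uniformly chosen existing edge.
    """
    adj: dict[int, dict[int, float]] = defaultdict(dict)
    center, nxt = n_leaves, n_leaves + 1
    for leaf in range(3):
        w = float(rng.uniform(0.1, 1.0))
        adj[leaf][center] = adj[center][leaf] = w
    for leaf in range(3, n_leaves):
        edges = sorted((a, b) for a in adj for b in adj[a] if a < b)
        a, b = edges[int(rng.integers(len(edges)))]
        w = adj[a][b]
        u = float(rng.uniform(0.2, 0.8))
        m, nxt = nxt, nxt + 1
        del adj[a][b], adj[b][a]
        adj[a][m] = adj[m][a] = w * u
        adj[b][m] = adj[m][b] = w * (1.0 - u)
        wl = float(rng.uniform(0.1, 1.0))
        adj[leaf][m] = adj[m][leaf] = wl
    return adj


def leaf_path_distances(adj, n_leaves: int) -> np.ndarray:
    """All leaf-to-leaf path lengths by depth-first traversal."""
    d = np.zeros((n_leaves, n_leaves))
    for start in range(n_leaves):
        stack = [(start, None, 0.0)]
        while stack:
            node, prev, dist = stack.pop()
            if node < n_leaves and node != start:
                d[start, node] = dist
            for nb, w in adj[node].items():
                if nb != prev:
                    stack.append((nb, node, dist + w))
    return d


def tree_splits(adj, leaf_names: list[str]) -> set[frozenset]:
    """Canonical non-trivial splits of an adjacency-dict tree."""
    n = len(leaf_names)
    all_names = frozenset(leaf_names)
    smallest = min(all_names)
    splits: set[frozenset] = set()
    internal_edges = [
        (a, b) for a in adj for b in adj[a]
        if a < b and len(adj[a]) > 1 and len(adj[b]) > 1
    ]
    for a, b in internal_edges:
        # leaves on the a-side of edge (a, b)
        side = set()
        stack = [(a, b)]
        while stack:
            node, prev = stack.pop()
            if node < n:
                side.add(leaf_names[node])
            for nb in adj[node]:
                if nb != prev:
                    stack.append((nb, node))
        side_f = frozenset(side)
        if len(side_f) < 2 or len(side_f) > n - 2:
            continue
        if smallest in side_f:
            side_f = all_names - side_f
        splits.add(side_f)
    return splits


# ---------------------------------------------------------------------------
# Random Newick topologies and brute-force split counting
# ---------------------------------------------------------------------------

def random_newick(rng: np.random.Generator, labels: list[str]) -> str:
    """Random binary topology over ``labels`` with unit branch lengths."""
    items = [f"{l}:0.1" for l in labels]
    while len(items) > 3:
        j = int(rng.integers(1, len(items)))
        i = int(rng.integers(0, j))
        b = items.pop(j)
        a = items.pop(i)
        items.append(f"({a},{b}):0.1")
    return "(" + ",".join(items) + ");"


def dendropy_edge_sides(tree) -> list[frozenset]:
    """Leaf set under every internal non-root node (uncanonicalized)."""
    sides = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        sides.append(frozenset(l.taxon.label for l in node.leaf_iter()))
    return sides


def brute_force_node_counts(ref_tree, gene_trees) -> dict[frozenset, int]:
    """(edge x tree) double-loop membership count, matching either side."""
    all_taxa = frozenset(l.taxon.label for l in ref_tree.leaf_node_iter())
    smallest = min(all_taxa)
    gene_sides = [dendropy_edge_sides(gt) for gt in gene_trees]
    counts: dict[frozenset, int] = {}
    for side in dendropy_edge_sides(ref_tree):
        if len(side) < 2 or len(side) > len(all_taxa) - 2:
            continue
        canon = all_taxa - side if smallest in side else side
        c = 0
        for sides in gene_sides:
            if any(s == side or s == all_taxa - side for s in sides):
                c += 1
        counts[canon] = c
    return counts


def brute_force_grid(presence_rows, arch_thresholds, eub_thresholds):
    """Double-loop stringency-grid recount: {(a, b): count}."""
    out = {}
    for a in arch_thresholds:
        for b in eub_thresholds:
            c = 0
            for _fam, n_arch, n_eub in presence_rows:
                if n_arch >= a and n_eub >= b:
                    c += 1
            out[(a, b)] = c
    return out
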