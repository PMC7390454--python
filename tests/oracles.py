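"""Independent brute-force oracles used by the test suite.

Each function recomputes a quantity by direct enumeration, deliberately
avoiding the code paths it is used to check.
"""

from __future__ import annotations

import itertools
from collections import defaultdict

import numpy as np


def hypergeom_tail_by_enumeration(k: int, n: int, K: int, N: int) -> float:
    """P(|subset ∩ seed| >= k) by enumerating all C(N, n) subsets."""
    universe = range(N)
    seeds = set(range(K))
    hits = total = 0
    for subset in itertools.combinations(universe, n):
        total += 1
        if len(seeds.intersection(subset)) >= k:
            hits += 1
    return hits / total


def overlap_distribution_by_enumeration(n: int, K: int, N: int) -> dict:
    """P(|subset ∩ seed| = k) for all k, one pass over all C(N, n) subsets."""
    seeds = set(range(K))
    counts: dict[int, int] = defaultdict(int)
    total = 0
    for subset in itertools.combinations(range(N), n):
        counts[len(seeds.intersection(subset))] += 1
        total += 1
    return {k: c / total for k, c in counts.items()}


def bh_adjust_bruteforce(pvals) -> np.ndarray:
    """O(m^2) step-up BH: adjusted_(i) = min_{j >= i} m * p_(j) / (j+1)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    for rank_i, idx in enumerate(order):
        candidates = [
            m * p[order[j]] / (j + 1) for j in range(rank_i, m)
        ]
        adjusted[idx] = min(1.0, min(candidates))
    return adjusted


def label_permutation_classes(graph):
    """Degree classes of a graph, as lists of nodes."""
    classes = defaultdict(list)
    for node, deg in graph.degree():
        classes[deg].append(node)
    return list(classes.values())


def enumerate_label_null_counts(graph, gene_set):
    """Within-set edge counts over ALL degree-preserving label permutations.

    Enumerates the full product of within-degree-class permutations (the
    label-stage null exactly, valid when no node has unique degree eligible
    for edge swaps) and returns the list of within-``gene_set`` edge counts.
    """
    genes = set(gene_set)
    classes = label_permutation_classes(graph)
    edges = [tuple(e) for e in graph.edges()]
    counts = []
    perm_sets = [list(itertools.permutations(members)) for members in classes]
    for combo in itertools.product(*perm_sets):
        mapping = {}
        for members, perm in zip(classes, combo):
            mapping.update(dict(zip(members, perm)))
        counts.append(
            sum(1 for u, v in edges if mapping[u] in genes and mapping[v] in genes)
        )
    return counts


def exact_label_null_tail(graph, gene_set, observed) -> float:
    """Exact P(count >= observed) under the label-permutation null."""
    counts = enumerate_label_null_counts(graph, gene_set)
    return sum(1 for c in counts if c >= observed) / len(counts)


def expected_within_set_edges_label_null(graph, gene_set) -> float:
    """Exact expectation of the within-set edge count under the label null.

    For an edge with endpoints in degree classes c1 != c2, the probability
    both images land in S is (s1/n1) * (s2/n2); within one class it is
    s*(s-1) / (n*(n-1)), with s = |S ∩ class| and n the class size.
    """
    genes = set(gene_set)
    cls_of = {}
    sizes = defaultdict(int)
    inset = defaultdict(int)
    for node, deg in graph.degree():
        cls_of[node] = deg
        sizes[deg] += 1
        if node in genes:
            inset[deg] += 1
    total = 0.0
    for u, v in graph.edges():
        c1, c2 = cls_of[u], cls_of[v]
        if c1 != c2:
            total += (inset[c1] / sizes[c1]) * (inset[c2] / sizes[c2])
        else:
            n, s = sizes[c1], inset[c1]
            total += s * (s - 1) / (n * (n - 1)) if n > 1 else float(s == n == 1) * 0.0
    return total


def local_clustering_by_triangle_count(graph, node) -> float:
    """Local clustering as triangles / neighbor-pairs, by direct enumeration."""
    nbrs = list(graph.neighbors(node))
    if len(nbrs) < 2:
        return 0.0
    pairs = list(itertools.combinations(nbrs, 2))
    triangles = sum(1 for a, b in pairs if graph.has_edge(a, b))
    return triangles / len(pairs)
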