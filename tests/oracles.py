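"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's algorithms: alignment scores
come from exhaustive enumeration of all global alignments, and clusters from
networkx connected components on the explicit threshold graph.
"""

from __future__ import annotations

import itertools
import math


def brute_force_align_score(seq_a, seq_b, sub, gap_open, gap_extend):
    """Best global-alignment score by enumerating every alignment path.

    Gap cost convention: a run of L gaps costs gap_open + (L-1)*gap_extend.
    Feasible only for short sequences (the number of alignments grows like
    the Delannoy numbers).
    """
    best = -math.inf
    # moves: 'd' diagonal, 'u' gap in b (consume a), 'l' gap in a (consume b)
    stack = [(0, 0, None, 0.0)]
    while stack:
        i, j, prev, score = stack.pop()
        if i == len(seq_a) and j == len(seq_b):
            best = max(best, score)
            continue
        if i < len(seq_a) and j < len(seq_b):
            stack.append((i + 1, j + 1, "d", score + sub[seq_a[i], seq_b[j]]))
        if i < len(seq_a):
            cost = gap_extend if prev == "u" else gap_open
            stack.append((i + 1, j, "u", score - cost))
        if j < len(seq_b):
            cost = gap_extend if prev == "l" else gap_open
            stack.append((i, j + 1, "l", score - cost))
    return best


def brute_force_clusters(points, cutoff):
    """Connected components of the distance-threshold graph via networkx."""
    import networkx as nx
    import numpy as np

    g = nx.Graph()
    g.add_nodes_from(range(len(points)))
    for i, j in itertools.combinations(range(len(points)), 2):
        if np.linalg.norm(np.asarray(points[i]) - np.asarray(points[j])) <= cutoff:
            g.add_edge(i, j)
    return {frozenset(c) for c in nx.connected_components(g)}


def binomial_tail_by_enumeration(k, n, p):
    """P(X >= k) for X ~ Binomial(n, p) by summing the pmf from combinatorics."""
    total = 0.0
    for x in range(k, n + 1):
        total += math.comb(n, x) * p**x * (1 - p) ** (n - x)
    return total
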