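"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive (all-pairs scans, exhaustive DFS,
direct definitions) and shares no code with the package.
"""

from __future__ import annotations

import itertools
import math


def hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y)


def brute_force_edges(strings: list[str]) -> set[frozenset]:
    """All unordered pairs at Hamming distance exactly 1."""
    return {
        frozenset((u, v))
        for u, v in itertools.combinations(strings, 2)
        if hamming(u, v) == 1
    }


def brute_force_squares(edges: set[frozenset], nodes: list) -> set[frozenset]:
    """All distinct 4-cycles, identified by their diagonal pairing.

    For every 4-subset, each of the three ways to split it into two
    diagonal pairs is checked: the cycle exists iff all four 'side' edges
    are present.
    """
    cycles = set()
    for quad in itertools.combinations(nodes, 4):
        a, b, c, d = quad
        for diag1, diag2 in (((a, b), (c, d)), ((a, c), (b, d)), ((a, d), (b, c))):
            u, w = diag1
            v, x = diag2
            sides = [
                frozenset((u, v)), frozenset((v, w)),
                frozenset((w, x)), frozenset((x, u)),
            ]
            if all(s in edges for s in sides):
                cycles.add(frozenset((frozenset(diag1), frozenset(diag2))))
    return cycles


def brute_force_shortest_paths(
    adj: dict, source, target
) -> list[tuple]:
    """All shortest paths by exhaustive depth-first search over simple
    paths, keeping only those of minimal length."""
    best: list[tuple] = []
    best_len = math.inf

    def dfs(node, path):
        nonlocal best, best_len
        if len(path) - 1 > best_len:
            return
        if node == target:
            length = len(path) - 1
            if length < best_len:
                best, best_len = [tuple(path)], length
            elif length == best_len:
                best.append(tuple(path))
            return
        for nbr in adj[node]:
            if nbr not in path:
                dfs(nbr, path + [nbr])

    dfs(source, [source])
    return best


def brute_force_betweenness(adj: dict) -> dict:
    """Normalised betweenness (endpoints excluded) from exhaustive
    shortest-path enumeration."""
    nodes = sorted(adj)
    n = len(nodes)
    score = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = brute_force_shortest_paths(adj, s, t)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            score[v] += through / len(paths)
    norm = (n - 1) * (n - 2) / 2
    if norm > 0:
        for v in nodes:
            score[v] /= norm
    return score


def classify_oracle(v_ab, v_Ab, v_aB, v_AB, delta) -> str:
    """Independent epistasis classifier from the sign-pattern definition.

    Assumes the square is already oriented (AB strictly maximal).
    """
    eps = v_AB + v_ab - v_Ab - v_aB
    if eps == 0 or abs(eps) < delta:
        return "none"

    def sgn(dv):
        if abs(dv) <= delta:
            return 0
        return 1 if dv > 0 else -1

    a1, a2 = sgn(v_Ab - v_ab), sgn(v_AB - v_aB)
    b1, b2 = sgn(v_aB - v_ab), sgn(v_AB - v_Ab)
    flip_a = a1 * a2 == -1
    flip_b = b1 * b2 == -1
    if flip_a and flip_b:
        return "reciprocal_sign"
    if flip_a or flip_b:
        return "simple_sign"
    return "magnitude"


def kendall_tau_b(x: list, y: list) -> float:
    """Tie-corrected Kendall tau from the O(n^2) pair definition."""
    n = len(x)
    concordant = discordant = 0
    tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            tx += 1
            ty += 1
        elif dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx * dy > 0:
            concordant += 1
        else:
            discordant += 1
    n0 = n * (n - 1) / 2
    denom = math.sqrt((n0 - tx) * (n0 - ty))
    if denom == 0:
        return math.nan
    return (concordant - discordant) / denom
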