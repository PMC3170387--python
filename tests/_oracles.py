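"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package internals: the mapper
oracle scans every offset and strand, the parsimony oracle enumerates every
internal state assignment, and the alignment oracle is a from-scratch Gotoh
dynamic program.
"""
from __future__ import annotations

import itertools

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def brute_force_map(tag: str, ref: str, max_mm: int):
    """All end-to-end ungapped placements with <= max_mm mismatches."""
    hits = []
    L = len(tag)
    for strand, query in (("+", tag), ("-", rc(tag))):
        for start in range(len(ref) - L + 1):
            mm = sum(1 for a, b in zip(query, ref[start : start + L]) if a != b)
            if mm <= max_mm:
                hits.append((start, strand, mm))
    return sorted(hits)


def brute_force_parsimony(topology, column):
    """Minimum changes for one column by enumerating every internal-node
    state assignment.

    ``topology``: nested tuple of leaf indices (binary, rooted anywhere).
    ``column``: dict leaf index -> set of allowed states (a leaf edge is
    free when the adjacent internal state is in the leaf's set).
    """
    internal_edges: list[tuple[int, int]] = []  # (parent index, child index)
    leaf_edges: list[tuple[int, frozenset]] = []  # (parent index, leaf states)
    n_internal = 0

    def collect(node, parent_idx):
        nonlocal n_internal
        if not isinstance(node, tuple):
            leaf_edges.append((parent_idx, frozenset(column[node])))
            return
        me = n_internal
        n_internal += 1
        if parent_idx is not None:
            internal_edges.append((parent_idx, me))
        for c in node:
            collect(c, me)

    collect(topology, None)
    best = None
    for assign in itertools.product("ACGT", repeat=n_internal):
        total = sum(assign[p] != assign[c] for p, c in internal_edges)
        total += sum(assign[p] not in states for p, states in leaf_edges)
        if best is None or total < best:
            best = total
    return best


def gotoh_score(a: str, b: str, match=1, mismatch=-1, gap_open=-4, gap_extend=-1):
    """Affine-gap global alignment score (gap of length L costs
    gap_open + (L-1)*gap_extend)."""
    NEG = float("-inf")
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a consumed)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = gap_open + (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = gap_open + (j - 1) * gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)
    return max(M[n][m], X[n][m], Y[n][m])


def alignment_score(row_a: str, row_b: str, match=1, mismatch=-1,
                    gap_open=-4, gap_extend=-1) -> float:
    """Score an explicit gapped alignment under the same affine scheme."""
    score = 0.0
    in_gap_a = in_gap_b = False
    for x, y in zip(row_a, row_b):
        if x == "-":
            score += gap_extend if in_gap_a else gap_open
            in_gap_a, in_gap_b = True, False
        elif y == "-":
            score += gap_extend if in_gap_b else gap_open
            in_gap_b, in_gap_a = True, False
        else:
            score += match if x == y else mismatch
            in_gap_a = in_gap_b = False
    return score
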