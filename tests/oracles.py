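"""Independent reference implementations used only by the test suite.

Each oracle re-derives a quantity by a different route than the package:
top-down memoized recursion and exhaustive path enumeration for global
alignment, an all-shift scan for read merging, literal splice construction
for chimera detection, and a hash-map for dereplication.
"""

from __future__ import annotations

import sys
from functools import lru_cache


def nw_oracle(a: str, b: str, match: int = 1, mismatch: int = -1, gap: int = -2):
    """Top-down recursion maximizing (score, matches, -columns) lexicographically."""
    sys.setrecursionlimit(10000)

    @lru_cache(maxsize=None)
    def go(i: int, j: int):
        if i == len(a) and j == len(b):
            return (0, 0, 0)
        best = None
        if i < len(a) and j < len(b):
            s, m, c = go(i + 1, j + 1)
            eq = a[i] == b[j]
            best = (s + (match if eq else mismatch), m + (1 if eq else 0), c - 1)
        if i < len(a):
            s, m, c = go(i + 1, j)
            cand = (s + gap, m, c - 1)
            best = cand if best is None or cand > best else best
        if j < len(b):
            s, m, c = go(i, j + 1)
            cand = (s + gap, m, c - 1)
            best = cand if best is None or cand > best else best
        return best

    s, m, c = go(0, 0)
    return s, m, -c


def nw_enumerate_oracle(a: str, b: str, match: int = 1, mismatch: int = -1, gap: int = -2):
    """Enumerate every global alignment (tiny inputs only) and select the best
    by the same (score, matches, -columns) key."""
    best: list[tuple[int, int, int] | None] = [None]

    def walk(i: int, j: int, score: int, matches: int, columns: int) -> None:
        if i == len(a) and j == len(b):
            key = (score, matches, -columns)
            if best[0] is None or key > best[0]:
                best[0] = key
            return
        if i < len(a) and j < len(b):
            eq = a[i] == b[j]
            walk(i + 1, j + 1, score + (match if eq else mismatch),
                 matches + (1 if eq else 0), columns + 1)
        if i < len(a):
            walk(i + 1, j, score + gap, matches, columns + 1)
        if j < len(b):
            walk(i, j + 1, score + gap, matches, columns + 1)

    walk(0, 0, 0, 0, 0)
    s, m, c = best[0]
    return s, m, -c


def merge_oracle(fwd: str, rev: str, min_overlap: int):
    """All-shift scan for the largest exact suffix/prefix overlap."""
    from sedaforam.io import revcomp

    rc = revcomp(rev)
    best = None
    for k in range(min_overlap, min(len(fwd), len(rc)) + 1):
        if fwd[-k:] == rc[:k]:
            best = k
    if best is None:
        return None
    return fwd + rc[best:]


def chimera_splice_oracle(query, parents, threshold=0.99):
    """Exhaustive literal breakpoint search: splice every ordered parent pair
    at every query-length breakpoint and re-align against the query."""
    from sedaforam.pipeline import nw_identity

    best_single = max(nw_identity(query, p) for p in parents)
    best_splice = 0.0
    for a in parents:
        for b in parents:
            if a == b:
                continue
            for k in range(1, min(len(a), len(b))):
                model = a[:k] + b[k:]
                best_splice = max(best_splice, nw_identity(query, model))
    return best_splice >= threshold and best_splice > best_single


def dereplicate_oracle(pairs):
    table: dict[str, dict[str, int]] = {}
    for sample, seq in pairs:
        table.setdefault(seq, {}).setdefault(sample, 0)
        table[seq][sample] += 1
    return table
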