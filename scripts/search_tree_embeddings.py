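#!/usr/bin/env python
"""Regenerate the exact minimal-network embeddings frozen in fwstream.synth.

A Strahler order-k drainage network needs at least 2**k - 1 cells: a
complete binary merge tree of depth k-1.  On a D8 grid every donor must be
one of its recipient's 8 neighbours, so all 2**k - 1 cells lie within
Chebyshev radius k-1 of the outlet — impossible for k >= 8 because
2**k - 1 > (2k - 1)**2.  This script settles the remaining orders by
exhaustive backtracking: it finds embeddings for tree depths 1..5 (orders
2..6) and proves depth 6 (order 7) infeasible, which is why
fwstream.synth._EXACT_TREES stops at order 6.

Run time: a few minutes (the depth-6 infeasibility proof dominates).

    python scripts/search_tree_embeddings.py
"""

from __future__ import annotations

import sys

NB = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]


def search(depth: int):
    """Embed a complete binary tree of ``depth`` in the king graph, children
    adjacent to parents, all nodes distinct; returns (cell, parent) pairs or
    None if exhaustively infeasible."""
    sys.setrecursionlimit(10_000)
    used = {(0, 0)}

    def place(pos, d):
        if d == 0:
            return []
        cand = sorted(
            ((pos[0] + dr, pos[1] + dc) for dr, dc in NB),
            key=lambda p: -max(abs(p[0]), abs(p[1])),  # spread outward first
        )
        free = [p for p in cand if p not in used]
        for i in range(len(free)):
            for j in range(len(free)):
                if i == j:
                    continue
                a, b = free[i], free[j]
                used.add(a)
                la = place(a, d - 1)
                if la is None or b in used:
                    if la is not None:
                        for p, _ in la:
                            used.remove(p)
                    used.remove(a)
                    continue
                used.add(b)
                lb = place(b, d - 1)
                if lb is not None:
                    return [(a, pos), (b, pos)] + la + lb
                used.remove(b)
                for p, _ in la:
                    used.remove(p)
                used.remove(a)
        return None

    return place((0, 0), depth)


def main() -> None:
    for depth in range(1, 7):
        result = search(depth)
        if result is None:
            print(f"depth {depth} (order {depth + 1}): exhaustively infeasible")
            continue
        n = len(result) + 1
        assert n == 2 ** (depth + 1) - 1
        table = [((0, 0), None)] + [(cell, parent) for cell, parent in result]
        print(f"depth {depth} (order {depth + 1}): {n} cells")
        print(f"    {table!r}")


if __name__ == "__main__":
    main()
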