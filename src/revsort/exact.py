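"""Exact reversal distance by breadth-first search over the reversal graph.

Vertices are permutations of 1..n, edges connect permutations one reversal
apart.  Because every reversal is its own inverse, the distance from p to
the identity equals the distance from the identity to p, so a single BFS
from the identity yields the whole distance table.  The problem is NP-hard
in general; these oracles are meant for small n (validating the greedy
heuristics), and refuse sizes above a configurable bound.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Dict, Sequence

from .core import Permutation, Reversal, as_permutation, identity
from .greedy import SortingResult

DEFAULT_BOUND = 9
TABLE_BOUND = 8


class SizeLimitError(ValueError):
    """Requested n exceeds the exhaustive-search bound."""


@dataclass(frozen=True)
class DistanceTable:
    """Exact reversal distance to the identity for every permutation of 1..n."""

    n: int
    entries: Dict[Permutation, int]

    def __getitem__(self, p: Sequence[int]) -> int:
        return self.entries[tuple(p)]


def _neighbours(p: Permutation):
    n = len(p)
    for i in range(n - 1):
        for j in range(i + 1, n):
            yield Reversal(i + 1, j + 1), p[:i] + p[i : j + 1][::-1] + p[j + 1 :]


def exact_sort(p: Sequence[int], bound: int = DEFAULT_BOUND) -> SortingResult:
    """Shortest sorting sequence from ``p`` to the identity (BFS witness).

    Ties are broken by BFS discovery order with reversals enumerated by
    (i, j) ascending, so the witness is deterministic.
    """
    p = as_permutation(p)
    if len(p) > bound:
        raise SizeLimitError(f"n={len(p)} exceeds exact-search bound {bound}")
    target = identity(len(p))
    if p == target:
        return SortingResult(0, [], "exact")
    parent: dict[Permutation, tuple[Permutation, Reversal]] = {p: None}
    frontier = deque([p])
    while frontier:
        cur = frontier.popleft()
        for r, nxt in _neighbours(cur):
            if nxt in parent:
                continue
            parent[nxt] = (cur, r)
            if nxt == target:
                seq: list[Reversal] = []
                node = target
                while parent[node] is not None:
                    node, rev = parent[node]
                    seq.append(rev)
                seq.reverse()
                return SortingResult(len(seq), seq, "exact")
            frontier.append(nxt)
    raise AssertionError("reversal graph is connected; unreachable")


def exact_distance(p: Sequence[int], bound: int = DEFAULT_BOUND) -> int:
    """Length of a shortest reversal sequence sorting ``p``."""
    return exact_sort(p, bound).distance


def distance_table(n: int, bound: int = TABLE_BOUND) -> DistanceTable:
    """Exact distances for all n! permutations, by one BFS from the identity."""
    if n > bound:
        raise SizeLimitError(f"n={n} exceeds table bound {bound}")
    start = identity(n)
    dist = {start: 0}
    frontier = deque([start])
    while frontier:
        cur = frontier.popleft()
        d = dist[cur] + 1
        for _, nxt in _neighbours(cur):
            if nxt not in dist:
                dist[nxt] = d
                frontier.append(nxt)
    return DistanceTable(n, dist)
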