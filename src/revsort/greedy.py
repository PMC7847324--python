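"""Greedy heuristics for sorting an unsigned permutation by reversals.

Three classic greedy strategies are provided, all returning a certified
:class:`SortingResult` (the reversal list always replays to the identity, so
the reported distance is an upper bound on the true reversal distance and
never smaller than the breakpoint lower bound ceil(b/2)):

``fdsr_sort``
    First Descending Strip Reversal: repeatedly take the smallest element v
    of the leftmost descending strip and reverse the block between v and
    v-1, flipping ascending strips to descending as needed.
``bpgraph_sort``
    Breakpoint-graph greedy: among reversals removing two breakpoints (else
    one), pick the one whose result has the most descending strips; when no
    breakpoint can be removed, fall back to a reversal spanning two
    breakpoint ends.
``bpelim_sort``
    Breakpoint-elimination greedy (2-approximation): strict priority of
    remove-two, then remove-one-leaving-a-descending-strip, then remove-one,
    then place the smallest out-of-position value.

Every algorithm counts *every* applied reversal, including auxiliary strip
flips, so distance == len(reversals) by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

from .core import (
    ASCENDING,
    ExtendedPermutation,
    Permutation,
    Reversal,
    ValidationError,
    apply_reversal,
    as_permutation,
    extend,
    interior,
    is_identity,
    strips,
)


class NonTerminationError(RuntimeError):
    """Defensive cap on the number of reversals was exceeded."""


@dataclass
class SortingResult:
    """A certified sorting sequence: replaying ``reversals`` yields identity."""

    distance: int
    reversals: list[Reversal]
    algorithm: str
    trace: Optional[list[ExtendedPermutation]] = None

    def replay(self, p: Sequence[int]) -> Permutation:
        """Apply the recorded reversals, in order, to ``p``."""
        e = extend(p)
        for r in self.reversals:
            e = apply_reversal(e, r)
        return interior(e)


def descending_strip_count(e: ExtendedPermutation) -> int:
    return sum(1 for s in strips(e) if s.descending)


def candidate_reversals(e: ExtendedPermutation, delta: int) -> list[Reversal]:
    """All reversals with the given breakpoint change (-1 or -2).

    Only intervals with at least one breakpoint on a boundary pair can
    remove a breakpoint, so enumeration is restricted to those; the result
    is ordered by (i, j) ascending.
    """
    if delta not in (-1, -2):
        raise ValueError("delta must be -1 or -2")
    n = len(e) - 2
    is_bp = [abs(e[k] - e[k + 1]) != 1 for k in range(n + 1)]
    bp_right_ends = [j for j in range(1, n + 1) if is_bp[j]]
    out: list[Reversal] = []
    for i in range(1, n + 1):
        js = range(i, n + 1) if is_bp[i - 1] else [j for j in bp_right_ends if j >= i]
        left_before = is_bp[i - 1]
        for j in js:
            before = left_before + is_bp[j]
            after = (abs(e[i - 1] - e[j]) != 1) + (abs(e[i] - e[j + 1]) != 1)
            if after - before == delta:
                out.append(Reversal(i, j))
    return out


class StripIntervalOracle:
    """Constant-time strip queries over a fixed extended permutation.

    Built in linear time from prefix tallies of strip starts by orientation
    (plus per-pair adjacency-direction and per-position singleton-strip
    tallies).  Supports two queries:

    * does the position window ``a..b`` fully contain an ascending /
      descending strip;
    * after reversing ``[i, j]``, would the permutation contain a descending
      strip (used by :func:`bpelim_sort` to preview a candidate without
      materialising it).
    """

    def __init__(self, e: ExtendedPermutation):
        self.e = e
        self.n = len(e) - 2
        self.strips = strips(e)
        # strip index covering each position
        self._strip_of = [0] * len(e)
        for idx, s in enumerate(self.strips):
            for pos in range(s.start, s.end + 1):
                self._strip_of[pos] = idx
        self._desc_pref = _prefix(int(s.descending) for s in self.strips)
        self._asc_pref = _prefix(int(not s.descending) for s in self.strips)
        # pair tallies: e[k] - e[k+1] == 1 is a descending adjacency, == -1 ascending
        diffs = [e[k] - e[k + 1] for k in range(self.n + 1)]
        self._desc_adj_pref = _prefix(int(d == 1) for d in diffs)
        self._asc_adj_pref = _prefix(int(d == -1) for d in diffs)
        # interior positions that are singleton strips (both pairs breakpoints)
        bp = [abs(d) != 1 for d in diffs]
        self._single_pref = _prefix(
            int(bp[p - 1] and bp[p]) for p in range(1, self.n + 1)
        )  # index shifted by one: position p -> slot p-1

    # -- window queries ---------------------------------------------------
    def has_descending(self, a: int, b: int) -> bool:
        """Is some descending strip fully contained in positions a..b?"""
        return self._count_strips(a, b, self._desc_pref) > 0

    def has_ascending(self, a: int, b: int) -> bool:
        return self._count_strips(a, b, self._asc_pref) > 0

    def _count_strips(self, a: int, b: int, pref: list[int]) -> int:
        if a > b:
            return 0
        lo = self._strip_of[a]
        if self.strips[lo].start < a:
            lo += 1
        hi = self._strip_of[b]
        if self.strips[hi].end > b:
            hi -= 1
        if lo > hi:
            return 0
        return pref[hi + 1] - pref[lo]

    # -- reversal preview -------------------------------------------------
    def descending_after_reversal(self, i: int, j: int) -> bool:
        """Would reversing [i, j] leave a permutation with a descending strip?

        A permutation has a descending strip iff it has a descending
        adjacency (pair differing by +1) or an interior singleton strip;
        both are checked from the pre-reversal tallies plus O(1) boundary
        inspection, without building the reversed permutation.
        """
        e, n = self.e, self.n
        # descending adjacencies: untouched flanks keep their direction,
        # the reversed block flips ascending ones, the two boundary pairs
        # are formed anew.
        if _rng(self._desc_adj_pref, 0, i - 2) or _rng(self._desc_adj_pref, j + 1, n):
            return True
        if _rng(self._asc_adj_pref, i, j - 1):
            return True
        if e[i - 1] - e[j] == 1 or e[i] - e[j + 1] == 1:
            return True
        # singleton strips: interior ones survive wherever both flanking
        # pairs are untouched (or internally mirrored); positions bordering
        # the cut points are re-examined directly.
        if _rng(self._single_pref, 0, i - 3) or _rng(self._single_pref, j + 1, n - 1):
            return True
        if _rng(self._single_pref, i, j - 2):
            return True
        for p in {i - 1, i, j, j + 1}:
            if 1 <= p <= n and self._pair_bp_after(i, j, p - 1) and self._pair_bp_after(i, j, p):
                return True
        return False

    def _pair_bp_after(self, i: int, j: int, k: int) -> bool:
        """Is pair k a breakpoint after reversing [i, j]?"""
        e = self.e
        if k <= i - 2 or k >= j + 1:
            a, b = e[k], e[k + 1]
        elif k == i - 1:
            a, b = e[i - 1], e[j]
        elif k == j:
            a, b = e[i], e[j + 1]
        else:  # interior of the reversed block, mirrored
            a, b = e[i + j - k], e[i + j - k - 1]
        return abs(a - b) != 1


def _prefix(flags) -> list[int]:
    out = [0]
    for f in flags:
        out.append(out[-1] + f)
    return out


def _rng(pref: list[int], lo: int, hi: int) -> int:
    """Sum of flags in slots lo..hi (clamped; empty range -> 0)."""
    lo = max(lo, 0)
    hi = min(hi, len(pref) - 2)
    if lo > hi:
        return 0
    return pref[hi + 1] - pref[lo]


# ---------------------------------------------------------------------------
# the three greedy sorters
# ---------------------------------------------------------------------------


def _run(
    p: Sequence[int],
    keep_trace: bool,
    algorithm: str,
    stepper: Callable[[ExtendedPermutation, "_Recorder"], None],
) -> SortingResult:
    p = as_permutation(p)
    rec = _Recorder(extend(p), keep_trace, cap=4 * len(p) + 8, algorithm=algorithm)
    while not is_identity(rec.e):
        stepper(rec.e, rec)
    return rec.result()


@dataclass
class _Recorder:
    e: ExtendedPermutation
    keep_trace: bool
    cap: int
    algorithm: str
    reversals: list[Reversal] = field(default_factory=list)
    trace: list[ExtendedPermutation] = field(default_factory=list)

    def apply(self, r: Reversal) -> None:
        if len(self.reversals) >= self.cap:
            raise NonTerminationError(
                f"{self.algorithm}: exceeded {self.cap} reversals without sorting"
            )
        self.e = apply_reversal(self.e, r)
        self.reversals.append(r)
        if self.keep_trace:
            self.trace.append(self.e)

    def result(self) -> SortingResult:
        return SortingResult(
            distance=len(self.reversals),
            reversals=self.reversals,
            algorithm=self.algorithm,
            trace=self.trace if self.keep_trace else None,
        )


def fdsr_sort(p: Sequence[int], keep_trace: bool = False) -> SortingResult:
    """First Descending Strip Reversal greedy.

    Each round: (a) if the first strip after the one holding the sentinel 0
    is ascending, flip it; (b) take v, the smallest (last) element of the
    leftmost descending strip, at position i, and locate j, the position of
    v-1; (c) if v-1 heads a descending strip, flip that strip first; (d)
    reverse the block strictly between them ([i+1, j] if j > i, else
    [j+1, i]), creating the adjacency (v-1, v).
    """
    return _run(p, keep_trace, "fdsr", _fdsr_step)


def _fdsr_step(e: ExtendedPermutation, rec: _Recorder) -> None:
    ss = strips(e)
    # (a) first strip other than the strip holding position 0
    first = ss[1]
    if first.orientation == ASCENDING:
        rec.apply(Reversal(first.start, first.end))
        e = rec.e
        ss = strips(e)
    # (b) smallest element of the leftmost descending strip
    fd = next(s for s in ss if s.descending)
    v = e[fd.end]
    i = fd.end
    j = e.index(v - 1)
    # (c) pre-flip if v-1 heads a descending strip; a singleton strip is its
    # own flip, so only genuine (length >= 2) flips are applied and counted
    holder = next(s for s in ss if s.start <= j <= s.end)
    if holder.descending and holder.start == j and len(holder) > 1:
        rec.apply(Reversal(holder.start, holder.end))
        e = rec.e
        i = e.index(v)
        j = e.index(v - 1)
    # (d) bring v next to v-1
    rec.apply(Reversal(i + 1, j) if j > i else Reversal(j + 1, i))


def bpgraph_sort(p: Sequence[int], keep_trace: bool = False) -> SortingResult:
    """Breakpoint-graph greedy.

    Prefers reversals removing two breakpoints, then one, choosing among
    equals the reversal whose result has the most descending strips (ties:
    smallest interval endpoints).  When no reversal removes a breakpoint,
    falls back to reversing between a breakpoint's right end and another
    breakpoint's left end.
    """
    return _run(p, keep_trace, "bpgraph", _bpgraph_step)


def _bpgraph_step(e: ExtendedPermutation, rec: _Recorder) -> None:
    for delta in (-2, -1):
        cands = candidate_reversals(e, delta)
        if cands:
            best, best_score = None, -1
            for r in cands:
                score = descending_strip_count(apply_reversal(e, r))
                if score > best_score:
                    best, best_score = r, score
            rec.apply(best)
            return
    rec.apply(_bpgraph_fallback(e))


def _bpgraph_fallback(e: ExtendedPermutation) -> Reversal:
    n = len(e) - 2
    bps = sorted(k for k in range(n + 1) if abs(e[k] - e[k + 1]) != 1)
    left_ends = [k + 1 for k in bps if k + 1 <= n]  # right end position of a breakpoint
    right_ends = [k for k in bps if 1 <= k <= n]  # left end position of a breakpoint
    for strict in (True, False):
        for m in left_ends:
            for nn in right_ends:
                if (m + 1 < nn) if strict else (m < nn):
                    return Reversal(m, nn)
    raise NonTerminationError("bpgraph: no fallback reversal available")


def bpelim_sort(p: Sequence[int], keep_trace: bool = False) -> SortingResult:
    """Breakpoint-elimination greedy (Kececioglu-Sankoff style, 2-approx).

    Strict priority per round: remove two breakpoints; remove one leaving a
    descending strip (previewed via :class:`StripIntervalOracle`); remove
    one; otherwise reverse [i, pos(i)] for the smallest position i with
    value != i, which parks value i in place and creates a descending strip.
    """
    return _run(p, keep_trace, "bpelim", _bpelim_step)


def _bpelim_step(e: ExtendedPermutation, rec: _Recorder) -> None:
    s2 = candidate_reversals(e, -2)
    if s2:
        rec.apply(s2[0])
        return
    s1 = candidate_reversals(e, -1)
    if s1:
        oracle = StripIntervalOracle(e)
        chosen = next(
            (r for r in s1 if oracle.descending_after_reversal(r.i, r.j)), s1[0]
        )
        rec.apply(chosen)
        return
    n = len(e) - 2
    i0 = next(k for k in range(1, n + 1) if e[k] != k)
    rec.apply(Reversal(i0, e.index(i0)))


ALGORITHMS: dict[str, Callable[..., SortingResult]] = {
    "fdsr": fdsr_sort,
    "bpgraph": bpgraph_sort,
    "bpelim": bpelim_sort,
}
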