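"""Combinatorial model for unsigned reversal sorting of gene orders.

A genome is modelled as an ordered arrangement of distinct gene labels
(:class:`GeneOrder`).  Comparing two genomes with the same gene content
reduces, by relabelling, to sorting a single permutation ``pi`` of ``1..n``
to the identity using reversals (:func:`reduce_pair`).  To make boundary
pairs well defined, permutations are *extended* with sentinels ``pi_0 = 0``
and ``pi_{n+1} = n + 1``.

On the extended permutation, a consecutive pair whose values differ by
exactly 1 is an *adjacency*; any other pair is a *breakpoint*.  Maximal
breakpoint-free runs are *strips*, oriented ascending or descending; a
single-element strip is descending by convention, except the runs holding
the sentinel values 0 and n+1, which are ascending.  Since a reversal can
change the breakpoint count b by at most 2, every sorting sequence has
length >= ceil(b / 2) — the classic breakpoint lower bound.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Hashable, Iterable, Sequence

Label = Hashable

ASCENDING = "ascending"
DESCENDING = "descending"


class ValidationError(ValueError):
    """Input fails a structural requirement (duplicates, bad interval, ...)."""


class IncompatibleGenomesError(ValidationError):
    """Two gene orders do not share the same label set."""


@dataclass(frozen=True)
class Reversal:
    """Interval rho = [i, j] of 1-based gene positions, reversed inclusively."""

    i: int
    j: int

    def __post_init__(self) -> None:
        if not (1 <= self.i <= self.j):
            raise ValidationError(f"invalid reversal interval [{self.i}, {self.j}]")

    def as_tuple(self) -> tuple[int, int]:
        return (self.i, self.j)


@dataclass(frozen=True)
class Strip:
    """Maximal breakpoint-free run of an extended permutation.

    ``start`` and ``end`` are inclusive positions in ``0..n+1``.
    """

    start: int
    end: int
    orientation: str

    def __len__(self) -> int:
        return self.end - self.start + 1

    @property
    def descending(self) -> bool:
        return self.orientation == DESCENDING


@dataclass(frozen=True)
class ValidationReport:
    ok: bool
    is_permutation: bool
    message: str = ""


GeneOrder = tuple  # ordered, distinct labels; alias kept for readability
Permutation = tuple  # integers, each of 1..n exactly once
ExtendedPermutation = tuple  # 0, <permutation>, n+1


def validate_gene_order(raw: Iterable[Label]) -> ValidationReport:
    """Check that ``raw`` is a legal gene order (distinct, non-empty tokens).

    For integer labels, additionally reports whether they form a permutation
    of ``1..n`` — the form every sorting algorithm here requires.
    """
    tokens = list(raw)
    seen: set[Label] = set()
    for pos, tok in enumerate(tokens, start=1):
        if tok is None or tok == "":
            return ValidationReport(False, False, f"empty token at position {pos}")
        if tok in seen:
            return ValidationReport(False, False, f"duplicate gene {tok!r} at position {pos}")
        seen.add(tok)
    is_perm = all(isinstance(t, int) for t in tokens) and sorted(tokens) == list(
        range(1, len(tokens) + 1)
    )
    return ValidationReport(True, is_perm)


def as_permutation(values: Sequence[int]) -> Permutation:
    """Validate and freeze ``values`` as a permutation of 1..n."""
    p = tuple(values)
    if sorted(p) != list(range(1, len(p) + 1)):
        raise ValidationError(f"not a permutation of 1..{len(p)}: {p}")
    return p


def extend(p: Sequence[int]) -> ExtendedPermutation:
    """Insert sentinels 0 and n+1 around a permutation of 1..n."""
    p = as_permutation(p)
    return (0,) + p + (len(p) + 1,)


def interior(e: ExtendedPermutation) -> Permutation:
    """Strip the sentinels off an extended permutation."""
    return tuple(e[1:-1])


def breakpoints(e: ExtendedPermutation) -> frozenset[int]:
    """Pair-indices k in 0..n where |e[k] - e[k+1]| != 1."""
    return frozenset(k for k in range(len(e) - 1) if abs(e[k] - e[k + 1]) != 1)


def breakpoint_count(e: ExtendedPermutation) -> int:
    return sum(1 for k in range(len(e) - 1) if abs(e[k] - e[k + 1]) != 1)


def adjacencies(e: ExtendedPermutation) -> frozenset[int]:
    """Pair-indices k in 0..n where |e[k] - e[k+1]| == 1."""
    return frozenset(k for k in range(len(e) - 1) if abs(e[k] - e[k + 1]) == 1)


def strips(e: ExtendedPermutation) -> list[Strip]:
    """Partition positions 0..n+1 into maximal breakpoint-free strips.

    Orientation follows the field convention: a run of length >= 2 takes the
    direction of its values; a singleton is descending, unless it is a
    sentinel run (contains value 0 or n+1), which is ascending.  Sentinels
    merge with adjacent interior values (the identity is one ascending strip).
    """
    n_plus_1 = len(e) - 1
    out: list[Strip] = []
    start = 0
    for k in range(len(e) - 1):
        if abs(e[k] - e[k + 1]) != 1:
            out.append(_make_strip(e, start, k, n_plus_1))
            start = k + 1
    out.append(_make_strip(e, start, n_plus_1, n_plus_1))
    return out


def _make_strip(e: ExtendedPermutation, start: int, end: int, n_plus_1: int) -> Strip:
    if end > start:
        orient = ASCENDING if e[start] < e[end] else DESCENDING
    elif e[start] in (0, n_plus_1):
        orient = ASCENDING
    else:
        orient = DESCENDING
    return Strip(start, end, orient)


def apply_reversal(e: ExtendedPermutation, r: Reversal) -> ExtendedPermutation:
    """Reverse the block at positions r.i..r.j; sentinels are never touched."""
    n = len(e) - 2
    if not (1 <= r.i <= r.j <= n):
        raise ValidationError(f"reversal [{r.i}, {r.j}] out of range for n={n}")
    return e[: r.i] + e[r.i : r.j + 1][::-1] + e[r.j + 1 :]


def breakpoint_delta(e: ExtendedPermutation, r: Reversal) -> int:
    """Change in breakpoint count caused by ``r``, from the boundary pairs only.

    A reversal can only create or destroy breakpoints at the two pairs
    (i-1, i) and (j, j+1); interior pairs keep their absolute difference.
    """
    i, j = r.i, r.j
    before = (abs(e[i - 1] - e[i]) != 1) + (abs(e[j] - e[j + 1]) != 1)
    after = (abs(e[i - 1] - e[j]) != 1) + (abs(e[i] - e[j + 1]) != 1)
    return after - before


def is_identity(e: ExtendedPermutation) -> bool:
    return all(e[k] == k for k in range(len(e)))


def identity(n: int) -> Permutation:
    return tuple(range(1, n + 1))


def inverse(p: Sequence[int]) -> Permutation:
    """Inverse permutation q with q[p[z]] = z (1-based)."""
    p = as_permutation(p)
    q = [0] * len(p)
    for pos, val in enumerate(p, start=1):
        q[val - 1] = pos
    return tuple(q)


def compose(p: Sequence[int], q: Sequence[int]) -> Permutation:
    """(p . q)(z) = p(q(z))."""
    p, q = as_permutation(p), as_permutation(q)
    if len(p) != len(q):
        raise ValidationError("composition of permutations of different sizes")
    return tuple(p[q[z - 1] - 1] for z in range(1, len(p) + 1))


def reduce_pair(source: Sequence[Label], target: Sequence[Label]) -> Permutation:
    """Relabel a genome pair (sigma, tau) to one permutation pi = tau^-1 . sigma.

    pi(z) is the 1-based position in ``target`` of the label at position z of
    ``source``; any reversal sequence sorting pi to the identity, replayed on
    ``source``, yields ``target``.
    """
    src, tgt = tuple(source), tuple(target)
    for g, name in ((src, "source"), (tgt, "target")):
        rep = validate_gene_order(g)
        if not rep.ok:
            raise ValidationError(f"{name}: {rep.message}")
    if set(src) != set(tgt):
        raise IncompatibleGenomesError("source and target gene sets differ")
    pos_in_target = {label: z for z, label in enumerate(tgt, start=1)}
    return tuple(pos_in_target[label] for label in src)


def breakpoint_lower_bound(p: Sequence[int]) -> int:
    """ceil(b/2): no reversal removes more than two breakpoints."""
    return math.ceil(breakpoint_count(extend(p)) / 2)
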