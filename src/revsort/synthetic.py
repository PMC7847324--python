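"""Seeded generators of test inputs.

Evolution by inversion is emulated as k reversals with endpoints drawn
uniformly at random applied to the identity, so every emitted permutation
carries a known upper bound on its true reversal distance (<= k).  Also
provides exhaustive enumeration for small n and labelled gene-order pairs
with the same provenance guarantee.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass
from typing import Iterator, Sequence

from .core import GeneOrder, Permutation, Reversal, identity
from .exact import SizeLimitError

ENUM_BOUND = 8


@dataclass(frozen=True)
class ScrambleRecipe:
    """Provenance of a scrambled permutation: replaying ``applied`` on the
    identity reproduces it exactly."""

    n: int
    k: int
    seed: int
    applied: tuple[Reversal, ...]


def _draw_reversals(rng: random.Random, n: int, k: int) -> tuple[Reversal, ...]:
    # i, j drawn independently uniform on 1..n, then ordered
    if n == 0:
        return ()
    out = []
    for _ in range(k):
        i, j = rng.randint(1, n), rng.randint(1, n)
        out.append(Reversal(min(i, j), max(i, j)))
    return tuple(out)


def _apply_all(values: list, revs: Sequence[Reversal]) -> list:
    for r in revs:
        values[r.i - 1 : r.j] = values[r.i - 1 : r.j][::-1]
    return values


def scramble(n: int, k: int, seed: int) -> tuple[Permutation, ScrambleRecipe]:
    """Identity of size n scrambled by k uniformly random reversals.

    Deterministic given (n, k, seed); the exact reversal distance of the
    result is at most k.  For n = 0 no interval exists and the empty
    permutation is returned untouched.
    """
    if n < 0 or k < 0:
        raise ValueError("n and k must be non-negative")
    revs = _draw_reversals(random.Random(seed), n, k)
    values = _apply_all(list(identity(n)), revs)
    return tuple(values), ScrambleRecipe(n=n, k=k, seed=seed, applied=revs)


def enumerate_all(n: int, bound: int = ENUM_BOUND) -> Iterator[Permutation]:
    """Yield all n! permutations of 1..n (n <= bound)."""
    if n > bound:
        raise SizeLimitError(f"n={n} exceeds enumeration bound {bound}")
    return iter(itertools.permutations(range(1, n + 1)))


def gene_order_pair(n: int, k: int, seed: int) -> tuple[GeneOrder, GeneOrder]:
    """A labelled genome pair (sigma, tau): tau is a random labelling, sigma
    is tau scrambled by k random reversals, so reduce_pair(sigma, tau) has
    exact reversal distance at most k."""
    if n < 0 or k < 0:
        raise ValueError("n and k must be non-negative")
    rng = random.Random(seed)
    labels = [f"g{z:04d}" for z in range(1, n + 1)]
    tau = rng.sample(labels, n)
    sigma = _apply_all(list(tau), _draw_reversals(rng, n, k))
    return tuple(sigma), tuple(tau)
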