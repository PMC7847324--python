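# Methods

## Problem and model

`revsort` studies genome rearrangement by inversion only: two genomes with
identical gene content, each modelled as an ordered arrangement of distinct
gene labels, are compared by the minimum number of reversals (inversions of a
contiguous block) turning one arrangement into the other.  Relabelling genes
by their position in the target genome (`reduce_pair`, π = τ⁻¹·σ) reduces the
two-genome problem to sorting a single unsigned permutation π of 1..n to the
identity.  Genes are unsigned: strand orientation is not modelled, which makes
the minimisation NP-hard and motivates the greedy heuristics.

All structure lives on the *extended* permutation with sentinels π₀ = 0 and
π_{n+1} = n+1.  A consecutive pair differing by exactly 1 is an adjacency,
anything else a breakpoint; maximal breakpoint-free runs are strips.  A strip
of length ≥ 2 is ascending or descending by its values; a singleton strip is
descending by convention, except the runs containing the sentinel values 0 and
n+1, which are ascending.  Sentinels merge with adjoining interior values, so
the identity is a single ascending strip.  Since one reversal changes the
breakpoint count b by at most 2 (only the two boundary pairs change), every
sorting sequence has length ≥ ⌈b/2⌉; all sorters expose this bound and their
results are checked against it.

## Algorithms

All three greedy sorters return a *certified* result: the emitted reversal
list replays to the identity, and the reported distance is exactly the list
length.  Every applied reversal is counted, including auxiliary strip flips.
Published pseudocode for FDSR increments the distance once per main loop even
when a loop applies two or three reversals; we deliberately report the true
sequence length instead, because a distance that is not the length of a
witnessing scenario is not falsifiable.  As a consequence our FDSR distances
can exceed what the once-per-loop accounting would print, and the empirical
worst-case ratio to the exact distance over all permutations of n ≤ 7 is 2.5
(the strategy's claimed approximation degree, 1.5, refers to the other
accounting; we report the measured value rather than asserting either bound).

**FDSR (first descending strip reversal).**  Per round: flip the first strip
after the sentinel-0 strip if it is ascending; take v, the smallest (= last)
element of the leftmost descending strip, at position i, and j, the position
of v−1; if v−1 heads a descending strip of length ≥ 2, flip that strip first
(a singleton is its own flip — applying and counting a no-op reversal [k,k]
would pad the scenario, so it is skipped); finally reverse [i+1, j] if j > i,
else [j+1, i], creating the adjacency (v−1, v).  Positions are recomputed
after every applied reversal.

**Breakpoint-graph greedy.**  Per round, build S2/S1, the reversals removing
two/one breakpoint(s) (enumerated over intervals with at least one breakpoint
on a boundary pair — a necessary condition for removal — in (i, j) order);
choose from S2, else S1, the reversal whose result has the most descending
strips; if both are empty, fall back to the interval from the right end of
one breakpoint to the left end of another (smallest such pair, preferring
gaps m+1 < n and relaxing to m < n only if needed).  Ties are always broken
toward the smallest left, then right, endpoint, making the sorter
deterministic.

**Breakpoint-elimination greedy** (Kececioglu–Sankoff style, factor-2
guarantee).  Strict priority per round: (1) remove two breakpoints; (2)
remove one breakpoint leaving a permutation with a descending strip; (3)
remove one breakpoint; (4) reverse [i, pos(i)] for the smallest position i
with value ≠ i, which parks value i and creates a descending strip.  Priority
(2) is decided in O(1) per candidate by `StripIntervalOracle`.

**Exact oracle.**  Breadth-first search over the reversal graph (vertices:
permutations of 1..n, edges: single reversals).  Because a reversal is its
own inverse, distance to the identity equals distance from it, so one BFS
from the identity fills the whole distance table.  Witnesses are tie-broken
by BFS discovery order with reversals enumerated by (i, j).  Bounds: n ≤ 9
for single distances, n ≤ 8 for full tables — beyond that the state space
(n!) stops being desk-scale; the bounds are arguments, not constants.

## StripIntervalOracle

Built in linear time from one extended permutation: prefix tallies of strip
starts by orientation (answering "does the window a..b fully contain an
ascending/descending strip"), plus per-pair tallies of adjacency direction
and per-position singleton-strip flags.  These suffice for an exact O(1)
preview of "would reversing [i, j] leave a descending strip": a permutation
has a descending strip iff it has a descending adjacency or an interior
singleton strip; untouched flanks keep their tallies, the reversed block
flips ascending adjacencies to descending, and only the two cut points need
direct inspection.  The preview is validated exhaustively against
reverse-and-rescan for all permutations of n ≤ 6 and all intervals.  The
oracle is rebuilt after each applied reversal (linear work, dominated by the
quadratic candidate enumeration) rather than patched incrementally.

## Synthetic data

`scramble(n, k, seed)` emulates evolution as k reversals with both endpoints
drawn independently and uniformly on 1..n (then ordered) applied to the
identity, via Python's seeded Mersenne generator, so runs are reproducible
across platforms.  The emitted recipe replays to the permutation, giving
every sample a provenance guarantee: exact distance ≤ k.  `gene_order_pair`
wraps the same process in random string labels to exercise the reduction
path.  This generator is uniform over intervals: it has no reversal-length
bias, hotspots, or any of the other inhomogeneities of real rearrangement
histories, so passing tests certify combinatorial correctness of the
sorters, not biological realism of inferred scenarios.  The one real dataset
shipped is the 193-gene mouse/human X-chromosome marker arrangement
(`mouse_193.txt`, `human_193.txt`), on which all three sorters produce
replayable scenarios (130 / 108 / 111 reversals for FDSR / breakpoint-graph /
breakpoint-elimination, against a breakpoint lower bound of 59).

## Numerical and design choices

- Coordinates are 1-based gene positions with sentinels at 0 and n+1;
  reversal intervals [i, j] are inclusive and may not touch the sentinels.
- n = 0 and n = 1 are valid inputs (already sorted, distance 0).
- A defensive cap of 4n + 8 applied reversals raises `NonTerminationError`;
  none of the algorithms approaches it (the mouse run peaks at 130 of 780).
- Exhaustive test sizes: n ≤ 6 for three-way certification against the BFS
  oracle, n ≤ 7 for ratio measurements (5040 permutations), n ≤ 8 for the
  scramble distance-bound check — sizes chosen so the whole suite stays in
  the minutes range while still covering every permutation at those n.
- Candidate enumeration is O(n²) per round with O(1) breakpoint-delta tests;
  at the shipped data scale (n = 193) a full sort takes well under a second
  per algorithm except breakpoint-graph's descending-strip maximisation,
  which rescans candidates and stays around a second.

## Limitations

Unsigned reversals only: no strand signs (hence no Hannenhalli–Pevzner exact
theory), no translocations, transpositions, duplications or losses.  Greedy
distances are upper bounds, not estimates with error bars; the exact oracle
is exponential and capped at n ≤ 9.  The CLI's file dialect (whitespace
tokens, `#` comments) is deliberately minimal — gene orders are not
sequences, so FASTA and friends do not apply.
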