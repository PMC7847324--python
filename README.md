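# revsort

Sorting unsigned gene-order permutations by reversals.

At the chromosome level genomes evolve less by point edits than by global
rearrangements, and for many taxa the dominant event is the **reversal**
(inversion) of a contiguous gene block.  Given two genomes with the same gene
content, written as orderings σ and τ of the same n genes, the *reversal
distance* d(σ, τ) is the minimum number of reversals ρ = [i, j] with
σ·ρ₁·ρ₂⋯ρ_d = τ.  Relabelling by π = τ⁻¹·σ reduces this to sorting one
unsigned permutation π of 1..n to the identity.  For unsigned genes the
problem is NP-hard, so practical tools use greedy heuristics guided by
**breakpoints** — consecutive pairs of the extended permutation
(0, π₁, …, πₙ, n+1) whose values differ by more than 1 — and by the
decomposition into **strips** (maximal breakpoint-free runs, ascending or
descending).  Any reversal changes the breakpoint count b by at most 2, so
d ≥ ⌈b/2⌉ always.

The package is aimed at comparative-genomics and algorithmics use: it
provides the combinatorial model (extension, breakpoints, strips, reduction
of a genome pair), three classic greedy sorters that each return a
*certified* reversal scenario, an exact BFS distance oracle for small n, a
seeded evolution-by-reversals simulator, and a small CLI.

| sorter | strategy | guarantee |
|---|---|---|
| `fdsr_sort` | first descending strip reversal | heuristic (see docs/methods.md) |
| `bpgraph_sort` | remove 2 (else 1) breakpoints, maximise descending strips | heuristic |
| `bpelim_sort` | strict breakpoint-elimination priority | ≤ 2 × optimal |
| `exact_sort` | BFS over the reversal graph | optimal, n ≤ 9 |

## Worked example

The shipped 193-gene mouse and human X-chromosome arrangements (packaged as
`mouse_193.txt` / `human_193.txt`; the human order is 1..193, so the reduced
permutation is the mouse order itself):

```python
from revsort import ALGORITHMS, breakpoint_lower_bound, packaged_fixture, reduce_pair

mouse = packaged_fixture("mouse_193")
human = packaged_fixture("human_193")
pi = reduce_pair(mouse, human)
print("lower bound:", breakpoint_lower_bound(pi))
for name, algo in ALGORITHMS.items():
    print(name, algo(pi).distance)
```

prints

```
lower bound: 59
fdsr 130
bpgraph 108
bpelim 111
```

i.e. each sorter emits an explicit scenario of that many reversals turning
the mouse arrangement into the human one (`SortingResult.replay` verifies
it); the true reversal distance lies between 59 and 108.  On the classic
8-gene example the anatomy functions report (`python
examples/worked_example.py`):

```
extended permutation: (0, 2, 1, 3, 4, 5, 8, 7, 6, 9)
breakpoints (4): [(0, 2), (1, 3), (5, 8), (6, 9)]
adjacencies (5): [(2, 1), (3, 4), (4, 5), (8, 7), (7, 6)]
  strip (0,)  ascending
  strip (2, 1)  descending
  strip (3, 4, 5)  ascending
  strip (8, 7, 6)  descending
  strip (9,)  ascending
reversal-distance lower bound ceil(b/2): 2
```

More narrative scripts live in `examples/` (simulated evolution, exhaustive
greedy-vs-exact benchmarking).  The same functionality is scriptable from a
shell:

```sh
revsort stats --source mouse.txt --target human.txt
revsort sort --algorithm bpelim --source mouse.txt --target human.txt \
        --output-mode intervals
revsort scramble --n 50 --k 20 --seed 1
revsort bench --max-n 6
```

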