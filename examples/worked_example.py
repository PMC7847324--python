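"""Breakpoint and strip anatomy of a small gene order.

Builds the 8-gene permutation (2,1,3,4,5,8,7,6), extends it with the
sentinels 0 and 9, and prints its breakpoints, adjacencies and strips.
Breakpoints are the pairs a reversal must mend; ceil(b/2) is a hard lower
bound on how many reversals any sorting scenario needs.
"""

from revsort import (
    adjacencies,
    breakpoint_lower_bound,
    breakpoints,
    extend,
    strips,
)

p = (2, 1, 3, 4, 5, 8, 7, 6)
e = extend(p)
print("extended permutation:", e)

bp = sorted(breakpoints(e))
print(f"breakpoints ({len(bp)}):", [(e[k], e[k + 1]) for k in bp])
adj = sorted(adjacencies(e))
print(f"adjacencies ({len(adj)}):", [(e[k], e[k + 1]) for k in adj])

for s in strips(e):
    print(f"  strip {e[s.start:s.end + 1]}  {s.orientation}")

print("reversal-distance lower bound ceil(b/2):", breakpoint_lower_bound(p))
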