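"""Simulated evolution by reversals, and how well sorting recovers it.

Scrambles the identity with k random reversals (the simulated evolutionary
events), then estimates the reversal distance back with the greedy sorters
and the exact BFS oracle.  The exact distance can be below k because random
reversals may partly cancel; greedy distances sit between the exact value
and their approximation guarantee.
"""

from revsort import ALGORITHMS, exact_distance, scramble

n, k, seed = 8, 5, 7
perm, recipe = scramble(n, k, seed)
print(f"identity of {n} after {k} random reversals (seed {seed}): {perm}")
print("events applied:", [r.as_tuple() for r in recipe.applied])
print("exact reversal distance:", exact_distance(perm))
for name, algo in ALGORITHMS.items():
    print(f"{name:>8}: {algo(perm).distance} reversals")
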