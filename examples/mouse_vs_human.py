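"""Reversal scenarios between the mouse and human X-chromosome gene orders.

Loads the packaged 193-gene mouse and human arrangements, reduces the pair
to a single permutation (the human order is the identity, so the reduction
is the mouse order itself), and sorts it with each greedy algorithm.  Each
reported distance is the length of an explicit reversal scenario turning
the mouse arrangement into the human one — an upper bound on the true
reversal distance, which can be no smaller than ceil(b/2).
"""

from revsort import (
    ALGORITHMS,
    breakpoint_lower_bound,
    identity,
    packaged_fixture,
    reduce_pair,
)

mouse = packaged_fixture("mouse_193")
human = packaged_fixture("human_193")
pi = reduce_pair(mouse, human)

print(f"genes: {len(pi)}, breakpoint lower bound: {breakpoint_lower_bound(pi)}")
for name, algo in ALGORITHMS.items():
    res = algo(pi)
    assert res.replay(pi) == identity(len(pi))
    first = ", ".join(f"[{r.i},{r.j}]" for r in res.reversals[:3])
    print(f"{name:>8}: {res.distance} reversals (first steps: {first}, ...)")
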