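"""Exhaustive greedy-vs-exact comparison for small genomes.

For every permutation of 1..n (n up to 6 here), computes the exact reversal
distance by BFS and the distance each greedy sorter reports, then prints
the worst observed ratio per algorithm.  The breakpoint-elimination greedy
carries a proven factor-2 guarantee; the ratios below are the empirically
observed worst cases at these sizes.
"""

from revsort import ALGORITHMS, distance_table
from revsort.synthetic import enumerate_all

for n in (4, 5, 6):
    table = distance_table(n)
    line = [f"n={n}:"]
    for name, algo in ALGORITHMS.items():
        worst = max(
            (algo(p).distance / table[p] for p in enumerate_all(n) if table[p]),
            default=0.0,
        )
        line.append(f"{name} {worst:.2f}")
    print("  max greedy/exact ratio  " + "  ".join(line))
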