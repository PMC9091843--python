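"""Megastar street graphs: a centre joined to m identical leaf chains.

Because the leaves are identical, the leaf sums cancel in the martingale
condition and the edge-equation system collapses to the cyclic one on the
class sizes [A, B, ...]; only the absorbing boundary changes, to
[A, mB, ...].  This script analyses a three-leaf megastar whose leaves are
the [3, 2] chain of the worked tripartite example, and shows that a
one-leaf megastar is exactly the tripartite cycle.
"""

from streetgraph import (
    exact_absorption_probability,
    fixation_probability,
    make_cycle_graph,
    make_megastar_graph,
)

mega = make_megastar_graph(5, [3, 2], num_leaves=3, r=1.2)
print(f"megastar: {mega.num_partitions} physical partitions, "
      f"N = {mega.population_size}, class boundary a = {mega.fixation_boundary}")

# one centre mutant plus two mutants in one leaf tip (class aggregate [1, 0, 2])
s0_physical = [1, 0, 0, 0, 0, 0, 2]
alpha = fixation_probability(mega, s0_physical)
print(f"alpha (martingale, class-aggregated) = {alpha:.6f}")
print(f"alpha (exact absorbing chain)        = "
      f"{exact_absorption_probability(mega, s0_physical):.6f}")

other_placement = [1, 0, 2, 0, 0, 0, 0]
print(f"alpha with the two mutants in a different leaf = "
      f"{exact_absorption_probability(mega, other_placement):.6f}")
print("-> the martingale predicts, and the chain confirms, that alpha only")
print("   depends on the per-class totals, not on which leaf holds the mutants.")

single = make_megastar_graph(5, [3, 2], num_leaves=1, r=1.5)
cycle = make_cycle_graph([5, 3, 2], 1.5)
print()
print("one-leaf megastar vs tripartite cycle, alpha from [1, 0, 0]:",
      f"{fixation_probability(single, [1, 0, 0]):.10f}",
      "=", f"{fixation_probability(cycle, [1, 0, 0]):.10f}")
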