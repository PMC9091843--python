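"""Conditional distributions of the active-step count by Fourier inversion.

Inverts the CCFs on a uniform phase grid (exact for the integer-valued
count) to recover Pr(C_T = n | fixation) and Pr(C_T = n | extinction) on
the [5, 3, 2] cycle, and shows the parity comb: every active step moves the
total mutant count by one, so fixation from a single mutant in a population
of ten needs 9, 11, 13, ... active steps.
"""

import numpy as np

from streetgraph import active_step_distribution, conditional_moments, make_cycle_graph

graph = make_cycle_graph([5, 3, 2], r=1.5)
s0 = [1, 0, 0]
p_fix, p_ext = active_step_distribution(graph, s0, n_max=400)

print("most likely active-step counts:")
print("  given fixation:  n =", np.argmax(p_fix), f" (p = {p_fix.max():.4f})")
print("  given extinction: n =", np.argmax(p_ext), f" (p = {p_ext.max():.4f})")
print(f"Pr(C_T = 1 | ext) = {p_ext[1]:.4f}  (one active step straight to extinction)")
print(f"mass on even n given fixation: {p_fix[::2].sum():.2e}  (parity comb)")
print(f"support starts at n = {np.nonzero(p_fix > 1e-12)[0][0]} given fixation "
      "(= N - number of initial mutants)")

m = conditional_moments(graph, s0, max_order=2)
print()
print(f"E[C_T | fix] = {m.fix[0]:.3f},  E[C_T^2 | fix] = {m.fix[1]:.1f}")
print(f"E[C_T | ext] = {m.ext[0]:.3f},  E[C_T^2 | ext] = {m.ext[1]:.1f}")
print("moments come from Richardson-extrapolated derivatives of the CCFs at 0")
print("and agree with summing n^k over the inverted distributions.")
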