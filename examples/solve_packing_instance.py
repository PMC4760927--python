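"""Solve one node-local packing problem both ways.

Two items of sizes 10 and 30 must be packed into bins of capacities 12
and 29 so the filled loads track the capacities in the least-squares
sense.  The exact route linearizes the 0-1 quadratic program into an
ILP; the oracle enumerates every assignment.  Both give objective
(12-10)^2 + (29-30)^2 = 5.
"""

from isopack import brute_force_pack, formulate_eq1, linearize, solve_exact

inst = formulate_eq1(bins=[12, 29], items=[10, 30])
ilp = linearize(inst)
print(f"instance: bins {inst.bin_capacities}, items {inst.item_sizes}")
print(f"linearized ILP variables: {ilp.n_vars} "
      f"(= m*n*(n+3)/2 = {inst.m}*{inst.n}*{inst.n + 3}//2)")

exact = solve_exact(inst)
oracle = brute_force_pack(inst)
print(f"ILP optimum:         {exact.objective}  assignment {exact.x}")
print(f"enumeration optimum: {oracle.objective}  assignment {oracle.x}")
assert exact.x == oracle.x
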