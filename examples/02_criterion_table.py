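"""Effect of the criterion number on the scaled variance parameter.

For equal-loading one-factor designs, prints phi_sc = phi * p * lambda^2 / p_c
over grids of loadings, numbers of manifest variables and criterion numbers.
When p_c is a fixed proportion of p the scaled variance is independent of p;
when p_c is absolute it grows with p, and it always shrinks as p_c grows.
"""

from latentscale import criterion_sensitivity_table

print("criterion number as a proportion of p (1, 1/2, 1/4):\n")
print(criterion_sensitivity_table([0.2, 0.4, 0.6], [4, 8, 12],
                                  ["1/1", "1/2", "1/4"]).round(2))

print("\ncriterion number independent of p (1, 5, 10):\n")
print(criterion_sensitivity_table([0.2, 0.4, 0.6], [4, 8, 12],
                                  [1, 5, 10]).round(3))

print(
    "\nReading the grids: within each proportion block the rows repeat (no"
    "\np-dependence); in the absolute blocks phi_sc increases with p; larger"
    "\nloadings always raise phi_sc and a larger criterion number lowers it."
)
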