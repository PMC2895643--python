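"""The contact-gated programmed-cell-death rule.

Prints the per-MCS death probability as a function of an IPC's contact
length with the surrounding ommatidial cores, for the survival thresholds
used in the simulations (L = 16 wild type; 12 and 10 reduced death).
"""

from eyecpm import DeathRule, death_probability

print("contact   P(death)/MCS")
print("links     L=16      L=12      L=10")
for cs in (0, 2, 4, 6, 8, 10, 12, 14, 16, 20):
    row = "  ".join(f"{death_probability(cs, DeathRule(threshold_length=L)):.6f}"
                    for L in (16, 12, 10))
    print(f"{cs:>5}     {row}")
print()
print("An IPC with no core contact dies with probability 0.01 per step;")
print("any cell holding at least L links of core contact never dies.")
print("Lowering L weakens selection and leaves surplus cells in the")
print("lattice, the signature of reduced-death mutants.")
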