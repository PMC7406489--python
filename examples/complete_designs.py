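"""Effective error of every 3-of-5 complete design.

Enumerates all complete designs that measure three of five equidistant
occasions and prints the variance of the measurement times next to the
effective error for a slope-variance test.  The pattern that spreads its
occasions widest (largest Var(t)) measures individual differences in change
most precisely (smallest effective error).
"""

from lgcdesign import (
    DEFAULT_GRID,
    REFERENCE_PARAMS,
    design_ee,
    enumerate_candidates,
    variance_of_times,
)

params, grid = REFERENCE_PARAMS, DEFAULT_GRID

print(f"{'design':<12}{'Var(t)':>8}{'slope EE':>10}")
for design in enumerate_candidates(5, occasions_range=(3, 3), max_patterns=1):
    occs = design.patterns[0].occasions
    ee = design_ee(design, grid, params)
    print(f"{str(design):<12}{variance_of_times(occs):>8.2f}{ee:>10.2f}")

print()
print("Smallest effective error = most efficient design for detecting")
print("slope variance; it coincides with the largest time variance.")
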