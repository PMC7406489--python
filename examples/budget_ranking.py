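"""Ranking candidate designs under a fixed budget.

Designs with fewer occasions per participant afford more participants, so
raw effective errors are rescaled to adjusted effective errors (AEE) against
the largest affordable sample size before ranking.  The table reproduces the
top-10 comparison for slope-variance tests on a $100,000 budget at $20 per
measurement.
"""

from lgcdesign import CostModel, DEFAULT_GRID, REFERENCE_PARAMS, rank_designs

params, grid = REFERENCE_PARAMS, DEFAULT_GRID
cost = CostModel(budget=100_000, cost_per_datapoint=20)

candidates = [
    "{1,2,5}", "{1,4,5}", "{1,2,5 | 1,3,5 | 1,4,5}", "{1,3,5}", "{1,2,4,5}",
    "{1,2,3,5 | 1,2,4,5}", "{1,2,4,5 | 1,3,4,5}",
    "{1,2,3,5 | 1,2,4,5 | 1,3,4,5}", "{1,3,4,5}", "{1,2,3,5}",
]

print(f"{'rank':<5}{'design':<38}{'N':>6}{'EE':>7}{'AEE':>7}{'RE':>6}{'WIF':>6}")
for r in rank_designs(candidates, grid, params, cost=cost):
    print(f"{r.rank:<5}{r.design_str:<38}{r.n:>6}{r.ee:>7.2f}"
          f"{r.adjusted_ee:>7.2f}{r.relative_efficiency:>6.2f}{r.width_inflation:>6.2f}")

print()
print("N: affordable sample size; EE: pooled effective error; AEE: EE scaled")
print("by max(N)/N; RE: best AEE / AEE; WIF: expected CI width inflation.")
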