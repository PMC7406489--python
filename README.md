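# lgcdesign

Asymptotic design-efficiency engine for **linear latent growth curve models**
(LGCMs) with planned and unplanned missing data.

Longitudinal studies of change — in child development, cognitive aging,
clinical follow-up — are expensive, and researchers increasingly use
*planned missing* (PM) designs that deliberately skip measurement occasions
for subgroups of participants. `lgcdesign` answers the design question
"which schedule of measurements buys the most statistical power per unit of
budget?" with closed-form asymptotics instead of large Monte Carlo
simulations, and ships its own simulator and maximum-likelihood fitter to
verify those asymptotics.

## The model and the metric

A linear LGCM represents person *i*'s measurement at occasion *j* as

```
y_ij = I_i + S_i · t_j + ε_ij,   (I, S) ~ N((μ_I, μ_S), Ψ),   ε_ij ~ N(0, σ_ε²)
```

with latent intercept variance σ_I², slope variance σ_S², intercept–slope
covariance σ_IS, and i.i.d. residuals.  The **effective error** σ_eff² of a
design for a target parameter is the residual variance of a hypothetical
power-equivalent study that measures the latent target directly, once per
person.  For a single response pattern observed at times t_1…t_M:

- slope (Wald limit): `σ_eff² = σ_ε² / (Σ t_j² − (Σ t_j)²/M)` — the residual
  variance divided by the centered sum of squares of the measurement times;
- intercept (Wald limit, time anchored at study onset, t_1 = 0):
  `σ_eff² = σ_ε² / (M − (Σ t_j)²/Σ t_j²)`;
- finite-nuisance variants that keep the other growth component as a random
  effect with finite variance, e.g. for the slope
  `σ_eff² = σ_ε² / (Σ t_j² − η_S (Σ t_j)²)` with `η_S = 1/(M + σ_ε²/σ_I²)`.

A PM design is a set of patterns with participant shares, written
`{1,2,5 | 1,3,5 | 1,4,5}` or, with explicit shares,
`{1 : 7.5% | 1,2 : 22.5% | 1,2,5 : 70%}`.  Its effective error is the
share-weighted harmonic mean of the pattern-level effective errors.  Linear
attrition (a share υ of the sample lost per wave) simply rewrites a planned
design as an implied weighted design over pattern prefixes, so the same
pooling rule covers unplanned dropout.  Under a fixed budget B and
per-measurement cost C, a design with T occasions per participant affords
N = ⌊B/(C·T)⌋ participants; effective errors are compared after rescaling to
a common reference N (**adjusted effective error**, AEE), and the effective
standard error of a variance test is `sqrt(2/(N−1)) · (σ_target² + σ_eff²)`.

## Worked example

```python
from lgcdesign import (AttritionModel, CostModel, DEFAULT_GRID,
                       REFERENCE_PARAMS, design_ee, expand_design,
                       format_design, parse_design, rank_designs)

params, grid = REFERENCE_PARAMS, DEFAULT_GRID   # five equidistant occasions

# pooled slope effective error of a three-form design
design_ee("{1,3,5 | 1,2,5 | 1,4,5}", grid, params)   # 3.55

# what a {1,4,5} study becomes under 7.5%-per-wave attrition
implied = expand_design(parse_design("{1,4,5}"), grid, AttritionModel(rate=0.075))
format_design(implied)       # '{1 : 22.5% | 1,4 : 7.5% | 1,4,5 : 70%}'
design_ee(implied, grid, params)   # 4.68
```

Ranking candidates under a $100,000 budget at $20 per measurement
(`python examples/budget_ranking.py`) prints:

```
rank design                                     N     EE    AEE    RE   WIF
1    {1,2,5}                                 1666   3.46   3.46  1.00  1.00
1    {1,4,5}                                 1666   3.46   3.46  1.00  1.00
3    {1,2,5 | 1,3,5 | 1,4,5}                 1666   3.55   3.55  0.97  1.01
4    {1,3,5}                                 1666   3.75   3.75  0.92  1.04
5    {1,2,4,5}                               1250   3.00   4.00  0.87  1.07
...
```

The maximum-spread three-occasion designs win: they afford 1,666
participants and carry the smallest adjusted effective error, so they give
the tightest confidence intervals on the slope variance per dollar.  The WIF
column says how much wider a confidence interval from each competitor is
expected to be.

The Monte Carlo validator (`python examples/monte_carlo_validation.py`)
simulates the complete design 200 times at N = 1000, refits the model by
pattern-wise maximum likelihood, and compares the empirical sampling SD of
the slope-variance estimate (0.470) with the closed-form prediction (0.501)
— agreement within a few percent, which is the entire case for replacing
simulation with the closed forms.

A thin CLI wraps the same functions:

```sh
lgcdesign pattern-ee --pattern "1,2,5" --target slope_var     # 3.46
lgcdesign attrition-expand --design "{1,2,5}" --rate 0.075
lgcdesign rank --design "{1,2,5}" --design "{1,2,4,5}" \
    --budget 100000 --cost-per-datapoint 20
```

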