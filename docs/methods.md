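# Methods

## Model

`lgcdesign` works with the linear latent growth curve model (LGCM): person
*i*'s observation at occasion *j* is

    y_ij = I_i + S_i t_j + ε_ij

where the latent intercept–slope pair is bivariate normal with mean
(μ_I, μ_S) and covariance Ψ = [[σ_I², σ_IS], [σ_IS, σ_S²]], and residuals
are i.i.d. N(0, σ_ε²) across persons and occasions (homoscedastic, no
autocorrelation, no retest effects).  The implied observed moments are
μ = Λν and Σ = ΛΨΛ′ + σ_ε²I with Λ = [[1, t_1], …, [1, t_M]].  All
closed-form results in the package are exact consequences of this model;
they say nothing about nonlinear change, heteroscedastic or autocorrelated
residuals, or non-normal data.

The bundled reference parameterization (μ_I = 39.46, σ_I² = 28.78,
μ_S = 8.06, σ_S² = 8.20, σ_IS = 1.56, σ_ε² = 30, five equidistant
occasions) is a published developmental example that has become a de facto
benchmark for PM-design comparisons; every number in the README and the
acceptance report derives from it.  Note the implied intercept–slope
correlation is ≈ 0.10.

## Effective error

For Wald-type tests, the effective error of a design for a latent component
is the inverse of the asymptotic precision with which the design measures
that component; it equals the residual variance of a power-equivalent
one-measurement study.  For a single pattern at times t_1…t_M:

| target | formula | nuisance handling |
|---|---|---|
| slope, Wald limit | σ_ε² / (Σt² − (Σt)²/M) | intercept profiled out |
| slope, finite η | σ_ε² / (Σt² − η_S(Σt)²), η_S = 1/(M + σ_ε²/σ_I²) | intercept a random effect with variance σ_I² |
| intercept, Wald limit | σ_ε² / (M − (Σt)²/Σt²) | slope profiled out |
| intercept, finite η | σ_ε² / (M − η(Σt)²), η = 1/(Σt² + σ_ε²/σ_S²) | slope a random effect with variance σ_S² |

Each closed form equals 1 / (x′V⁻¹x) where x is the target component's
loading vector (t for the slope, 1 for the intercept) and V the
residual-plus-nuisance covariance; the test suite verifies this against
dense linear algebra to 1e−9 relative error, and verifies that the finite-η
forms converge to the Wald limits as the nuisance variance grows.

Because asymptotic precision is the same currency for tests on a
component's mean and variance, the mean targets alias the variance targets;
rankings coincide by construction.

**Time coding.**  The slope Wald formula is translation invariant, so any
anchoring works.  The other formulas are not:

- intercept formulas use the **zero-anchored study grid** (t_1 = 0), and a
  sub-pattern's times are read off that grid *without re-anchoring* — the
  intercept is a study-level quantity, so pattern {1,4,5} on a five-wave
  grid has intercept times (0, 3, 4);
- the finite-η slope formula uses **one-based** times (t_1 = 1 for the full
  grid).

`pattern_ee`/`design_ee` convert explicitly from whichever coding the
`TimeGrid` records; the CLI logs the resolved coding on stderr.

**Infinite effective error** is a first-class value, not an error: a single
occasion carries no information about change, and a never-measured dropout
group carries none about anything.  Such groups contribute zero precision
to pooling while their participant share still counts (see below).

## Pooling across patterns

The arms of a PM design are independent groups, so design-level effective
error is the share-weighted harmonic mean

    σ_eff² = 1 / Σ_j (w_j / σ_eff,j²),

bounded between min_j σ_eff,j² and k·min_j σ_eff,j² for k equal-weight
arms.  Infinite components drop out of the sum but keep their weight in the
normalization, which exactly reproduces the dilution caused by dropout
groups with zero or one informative occasion.

## Attrition

Unplanned dropout is modelled as a linear MCAR process: the probability of
having left the study before the occasion at time t is υ·(t − t_onset),
with υ the attrition rate per unit of elapsed time (0.075 and 0.175 are the
conventional "low"/"high" settings).  Dropout is permanent and runs on the
scheduled study clock, so a planned pattern expands into its prefixes with
weights given by differences of the cumulative dropout share at the
pattern's own occasion times, plus an empty group for dropout before the
first scheduled measurement of that arm.  Mass is conserved by
construction, expansion with υ = 0 is the identity, and pooled effective
error is weakly increasing in υ (property-tested).  The formulation
"p(missing at occasion j) = υ·t_j" is implemented as elapsed time t_j −
t_onset; on a one-based grid this is υ·(t_j − 1), which is the only reading
consistent with the worked implied designs it must reproduce.

## Budget rule and ranking

With budget B and cost C per data point, a design affords
N = ⌊B / (C·T̄)⌋ participants, where T̄ is the share-weighted mean number of
observed occasions per participant.  T̄ generalizes the uniform-length rule
N = B/(T·C) to mixed-length designs; for uniform designs they coincide.
Attrition does not change N: the budget is committed for the planned
schedule.  Adjusted effective error is AEE = EE · (N_ref/N) with N_ref the
largest affordable N among compared designs (configurable); relative
efficiency is best-AEE/AEE, and the width inflation factor is
sqrt(AEE/best-AEE), the expected relative widening of a confidence
interval.  Rankings sort ascending by AEE; exact ties share the better rank
and are ordered by the canonical design string so reports are byte-stable.

Two documented facts about published comparison tables that this package
reproduces asymptotically rather than by simulation: (a) for intercept
targets the asymptotic ranking is known to deviate slightly from
simulation-based rankings for a few multi-pattern designs (the asymptotics
are mildly over-optimistic there); (b) in the low-attrition slope
comparison the designs {1,2,5} (pooled EE 4.855) and the three-form design
(4.869) are a near-tie whose order differs between pre-rounded and exact
arithmetic.  The package always reports the exact asymptotic order and
leaves reconciliation with simulation studies to the user.

## Maximum likelihood and Monte Carlo validation

The simulator draws each participant's complete response from the implied
multivariate normal and masks unobserved occasions; pattern assignment uses
deterministic largest-remainder apportionment of the design shares (an
optional flag switches to multinomial assignment), so worked examples are
exactly reproducible.  The generator emulates the model's own assumptions —
MCAR missingness, normal latents and residuals, homoscedasticity — and
deliberately nothing else; passing validation therefore shows the
asymptotics are correct *under the model*, not that the model fits any
particular real dataset.

The fitter maximizes the observed-data (full-information) log-likelihood,
computed per missingness pattern from sufficient statistics (count, mean,
scatter), which makes each evaluation O(patterns · M³) independent of N.
Optimization is L-BFGS-B on transformed parameters — log variances and an
atanh-transformed latent correlation — so every iterate is admissible;
non-PSD implied covariances are rejected with −∞ likelihood.  Defaults:
gradient tolerance 1e−8, 5 jittered multistarts for one-off fits (the
simulate–fit loop uses 1 start from data-driven moment estimates, which is
empirically sufficient on complete and planned-missing data at the sample
sizes used).  Non-convergent replications are dropped and counted; the
convergence rate is always reported and a rate below 80% triggers a
warning, since selective convergence biases empirical SDs.  All randomness
descends from one user seed via `numpy.random.SeedSequence` spawning.

Validation scale: the acceptance suite uses 500 replications at N = 1,000
for the sampling-SD check (empirical SD of the slope-variance estimate
within 10% of the closed-form effective standard error; observed agreement
is ≈ 0.1%) and 200 replications at N = 2,000 for bias (each parameter
within 3 Monte Carlo SEs of truth).  These sizes keep the full suite under
a minute while leaving the stochastic checks comfortably powered.

## Numerical conventions

- Printed-table comparisons in tests use ±0.005 at two decimals, widened to
  ±0.01 for values the source tables themselves computed from pre-rounded
  intermediates.
- Design strings: weights may be percentages (`70%`, or any bare number
  > 1) or proportions (≤ 1); patterns without explicit weights share the
  remaining mass equally; all-explicit weights must total 100% ± 0.1%.
  The empty pattern prints as `-`.
- Duplicate patterns merge by summing shares; shares are normalized on
  construction.
- `affordable_n` floors; a budget that cannot fund one participant is an
  error.

## Limitations

Linear change only; i.i.d. residuals; Wald-type tests (likelihood-ratio
power can depend on parameters that cancel here); no item-level multiform
designs; no MAR/MNAR dropout, re-entry, or nonlinear hazards; no
continuous-time optimization of the occasion times themselves.  Asymptotic
results can be optimistic at small N or when non-convergence is
non-negligible — that is precisely what the Monte Carlo module is for.
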