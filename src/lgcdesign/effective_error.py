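"""Closed-form effective error of slope- and intercept-variance tests.

Effective error is the residual variance of a hypothetical power-equivalent
study that measures the latent quantity of interest (slope or intercept)
directly, once per person.  Two designs with the same effective error have
the same asymptotic power for Wald-type tests on that quantity, so effective
error is a sample-size-free currency for comparing designs.

For a single response pattern observed at times ``t_1..t_M`` with residual
variance ``var_e``:

* slope, Wald limit:        ``var_e / (sum t^2 - (sum t)^2 / M)``
* slope, finite-nuisance:   ``var_e / (sum t^2 - eta_s (sum t)^2)`` with
  ``eta_s = 1 / (M + var_e / var_i)``; converges to the Wald limit as the
  intercept variance grows.
* intercept, Wald limit:    ``var_e / (M - (sum t)^2 / sum t^2)``
* intercept, finite-nuisance: ``var_e / (M - eta (sum t)^2)`` with
  ``eta = 1 / (sum t^2 + var_e / var_s)``.

The "finite" variants keep the other growth component as a random nuisance
with finite variance instead of profiling it out; each equals the inverse of
``x' V^{-1} x`` where ``x`` is the loading vector of the target component and
``V`` the residual-plus-nuisance covariance (see tests for the linear-algebra
oracle).

Time coding matters.  The slope Wald formula is translation invariant, so
either coding works; the finite slope variant requires one-based times
(t_1 = 1 for the full grid), and both intercept variants require the
zero-anchored study grid (t_1 = 0), with sub-pattern times read off that grid
without re-anchoring.  :func:`pattern_ee` performs the conversion.

An infinite effective error is a legitimate value meaning the pattern carries
no information on the target (e.g. a single occasion tells you nothing about
the slope); it participates in design pooling with zero precision.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

from .model import GrowthParams, TimeCoding, TimeGrid


class Target(enum.Enum):
    """Parameter whose test the design is optimized for.

    Asymptotically the effective error of a latent component is the same for
    tests on its mean and on its variance, so the mean targets alias the
    variance targets.
    """

    slope_var = "slope_var"
    intercept_var = "intercept_var"
    slope_mean = "slope_mean"
    intercept_mean = "intercept_mean"

    @property
    def is_slope(self) -> bool:
        return self in (Target.slope_var, Target.slope_mean)


class Formula(enum.Enum):
    wald_limit = "wald_limit"
    finite_eta = "finite_eta"


@dataclass(frozen=True)
class EffectiveError:
    """Effective error of one pattern (or pooled design) for one target."""

    value: float
    target: Target
    formula: Formula


@dataclass(frozen=True)
class EffectiveSE:
    """Asymptotic standard error of a latent variance estimate at sample size n."""

    value: float
    n: int


def _sums(times: Sequence[float]) -> tuple[int, float, float]:
    m = len(times)
    st = float(sum(times))
    st2 = float(sum(t * t for t in times))
    return m, st, st2


def slope_ee_wald(times: Sequence[float], residual_var: float) -> float:
    """Effective error of the slope in the Wald limit.

    ``var_e / (sum t^2 - (sum t)^2 / M)``; the denominator is the centered
    sum of squares of the measurement times, so the value is invariant under
    time translation and shrinks quadratically when the time axis is
    stretched.  Returns ``inf`` for patterns with fewer than two distinct
    times (zero information about change).
    """
    if len(times) == 0:
        raise ValueError("times must be non-empty")
    if residual_var <= 0:
        raise ValueError("residual_var must be > 0")
    m, st, st2 = _sums(times)
    denom = st2 - st * st / m
    if denom <= 0:
        return math.inf
    return residual_var / denom


def slope_ee_finite(
    times: Sequence[float], residual_var: float, intercept_var: float
) -> float:
    """Effective error of the slope with the intercept as a finite-variance nuisance.

    ``var_e / (sum t^2 - eta_s (sum t)^2)`` with
    ``eta_s = 1 / (M + var_e / var_i)``.  Times must be one-based study-grid
    times (t_1 = 1).  Converges to :func:`slope_ee_wald` as ``var_i -> inf``.
    """
    if len(times) == 0:
        raise ValueError("times must be non-empty")
    if residual_var <= 0:
        raise ValueError("residual_var must be > 0")
    if intercept_var <= 0:
        raise ValueError("intercept_var must be > 0 for the finite-eta slope formula")
    m, st, st2 = _sums(times)
    eta = 1.0 / (m + residual_var / intercept_var)
    denom = st2 - eta * st * st
    if denom <= 0:
        return math.inf
    return residual_var / denom


def intercept_ee_wald(times: Sequence[float], residual_var: float) -> float:
    """Effective error of the intercept in the Wald limit.

    ``var_e / (M - (sum t)^2 / sum t^2)`` on zero-anchored study-grid times.
    For the singleton pattern at the anchor (t=0), the ratio term is 0 and the
    value is ``var_e``.  Invariant under rescaling of the time axis: waiting
    longer does not sharpen the intercept.
    """
    if len(times) == 0:
        raise ValueError("times must be non-empty")
    if residual_var <= 0:
        raise ValueError("residual_var must be > 0")
    m, st, st2 = _sums(times)
    ratio = 0.0 if st2 == 0 else st * st / st2
    denom = m - ratio
    if denom <= 0:
        return math.inf
    return residual_var / denom


def intercept_ee_finite(
    times: Sequence[float], residual_var: float, slope_var: float
) -> float:
    """Effective error of the intercept with the slope as a finite-variance nuisance.

    ``var_e / (M - eta (sum t)^2)`` with ``eta = 1 / (sum t^2 + var_e / var_s)``
    on zero-anchored times.  Converges to :func:`intercept_ee_wald` as
    ``var_s -> inf``.
    """
    if len(times) == 0:
        raise ValueError("times must be non-empty")
    if residual_var <= 0:
        raise ValueError("residual_var must be > 0")
    if slope_var <= 0:
        raise ValueError("slope_var must be > 0 for the finite-eta intercept formula")
    m, st, st2 = _sums(times)
    eta = 1.0 / (st2 + residual_var / slope_var)
    denom = m - eta * st * st
    if denom <= 0:
        return math.inf
    return residual_var / denom


def effective_se(effective_error: float, target_var: float, n: int) -> float:
    """Asymptotic standard error of a latent variance estimate.

    ``sqrt(2 / (n - 1)) * (target_var + effective_error)`` where ``target_var``
    is the population variance of the tested component (slope variance for
    slope targets, intercept variance for intercept targets).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not math.isfinite(effective_error):
        raise ValueError("effective error must be finite for a standard error")
    return math.sqrt(2.0 / (n - 1)) * (target_var + effective_error)


def variance_of_times(times: Sequence[float]) -> float:
    """Sample variance (divisor M-1) of the measurement times.

    Among patterns with the same number of occasions, slope efficiency is a
    monotone function of this quantity: spread your measurements out.
    """
    if len(times) < 2:
        raise ValueError("need at least 2 times for a variance")
    m, st, st2 = _sums(times)
    return (st2 - st * st / m) / (m - 1)


def pattern_ee(
    occasions: Sequence[int],
    grid: TimeGrid,
    params: GrowthParams,
    target: Target | str = Target.slope_var,
    formula: Formula | str = Formula.wald_limit,
) -> EffectiveError:
    """Effective error of one response pattern for a given target and formula.

    Converts the grid to the coding the formula requires (one-based for slope
    targets, zero-anchored for intercept targets) and reads the pattern's
    times off the converted study grid.
    """
    target = Target(target)
    formula = Formula(formula)
    if target.is_slope:
        times = grid.one_based().pattern_times(occasions)
        if formula is Formula.wald_limit:
            value = slope_ee_wald(times, params.residual_var)
        else:
            value = slope_ee_finite(times, params.residual_var, params.intercept_var)
    else:
        times = grid.zero_anchored().pattern_times(occasions)
        if formula is Formula.wald_limit:
            value = intercept_ee_wald(times, params.residual_var)
        else:
            value = intercept_ee_finite(times, params.residual_var, params.slope_var)
    return EffectiveError(value=value, target=target, formula=formula)
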