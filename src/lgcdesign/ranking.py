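"""Budget-constrained comparison and ranking of candidate designs.

Designs with fewer measurements per participant can afford more participants
under a fixed budget.  With budget ``B`` and per-datapoint cost ``C``, a
design whose participants are measured ``T`` times on average affords
``N = floor(B / (C * T))`` participants.  To compare designs with different
affordable sample sizes on the effective-error scale, the effective error of
a design with sample size ``N`` is rescaled by the discount factor
``psi = N_ref / N`` against the largest affordable sample size ``N_ref`` in
the comparison set, giving the adjusted effective error (AEE).  Relative
efficiency is ``best AEE / AEE`` (1 for the best design) and the width
inflation factor ``sqrt(AEE / best AEE)`` says how much wider a confidence
interval is expected to be.

Because effective error is asymptotically the inverse precision of the latent
component, rankings for tests on a component's mean coincide with rankings
for tests on its variance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

from .attrition import NO_ATTRITION, AttritionModel, expand_design
from .designs import Pattern, WeightedDesign, design_ee, format_design
from .effective_error import Formula, Target
from .model import GrowthParams, TimeGrid


@dataclass(frozen=True)
class CostModel:
    """Fixed total budget and a constant cost per collected data point."""

    budget: float
    cost_per_datapoint: float

    def __post_init__(self) -> None:
        if self.budget <= 0 or self.cost_per_datapoint <= 0:
            raise ValueError("budget and cost_per_datapoint must be > 0")


@dataclass(frozen=True)
class EfficiencyReport:
    """One ranked candidate: sample size, effective error and derived metrics."""

    design: WeightedDesign
    design_str: str
    n: int
    ee: float
    adjusted_ee: float
    relative_efficiency: float
    width_inflation: float
    discount: float
    rank: int


def affordable_n(cost: CostModel, design: WeightedDesign) -> int:
    """Largest sample size affordable under the budget.

    ``floor(B / (C * T))`` where ``T`` is the share-weighted mean number of
    observed occasions per participant (exactly the occasions-per-pattern
    count for designs whose patterns all have the same length).
    """
    t_bar = design.expected_occasions()
    if t_bar <= 0:
        raise ValueError("design has no observed occasions")
    n = math.floor(cost.budget / (cost.cost_per_datapoint * t_bar))
    if n < 1:
        raise ValueError(
            f"budget {cost.budget} cannot afford a single participant at "
            f"{t_bar:.2f} occasions and cost {cost.cost_per_datapoint} per data point"
        )
    return n


def adjusted_ee(ee: float, n: int, n_ref: int) -> float:
    """Sample-size-adjusted effective error: ``ee * (n_ref / n)``.

    ``n_ref`` is the largest affordable sample size among the compared
    designs, so the adjustment is an identity for the best-funded design and
    a penalty (``psi > 1``) for designs that afford fewer participants.
    """
    if n < 1 or n_ref < 1:
        raise ValueError("sample sizes must be >= 1")
    return ee * (n_ref / n)


def relative_efficiency(aee: float, best_aee: float) -> float:
    """``best_aee / aee``: 1 for the best design, < 1 otherwise."""
    if aee <= 0 or best_aee <= 0:
        raise ValueError("adjusted effective errors must be > 0")
    return best_aee / aee


def width_inflation(aee: float, best_aee: float) -> float:
    """Expected confidence-interval width inflation: ``sqrt(aee / best_aee)``."""
    if aee <= 0 or best_aee <= 0:
        raise ValueError("adjusted effective errors must be > 0")
    return math.sqrt(aee / best_aee)


def enumerate_candidates(
    n_occasions: int,
    occasions_range: tuple[int, int] | None = None,
    must_include: Iterable[int] = (),
    max_patterns: int = 1,
    pattern_pool: Sequence[Pattern] | None = None,
) -> list[WeightedDesign]:
    """Deterministically enumerate candidate designs.

    The pattern pool is every occasion subset whose size lies in
    ``occasions_range`` (default: all non-empty sizes) and which contains the
    ``must_include`` occasions, unless an explicit ``pattern_pool`` is given.
    Candidate designs are all equal-weight combinations of 1 to
    ``max_patterns`` pool patterns (single-pattern combinations are the
    complete designs).  Order and content are deterministic; duplicates
    cannot arise because combinations are over distinct patterns.
    """
    if n_occasions < 1:
        raise ValueError("n_occasions must be >= 1")
    lo, hi = occasions_range if occasions_range is not None else (1, n_occasions)
    must = set(int(o) for o in must_include)
    if any(not 1 <= o <= n_occasions for o in must):
        raise ValueError(f"must_include occasions {sorted(must)} out of range")

    if pattern_pool is None:
        pool = [
            Pattern(c)
            for size in range(lo, hi + 1)
            for c in combinations(range(1, n_occasions + 1), size)
            if must <= set(c)
        ]
    else:
        pool = [p if isinstance(p, Pattern) else Pattern(p) for p in pattern_pool]

    designs: list[WeightedDesign] = []
    for k in range(1, max_patterns + 1):
        for combo in combinations(pool, k):
            designs.append(WeightedDesign([(p, 1.0) for p in combo]))
    if not designs:
        warnings.warn("candidate enumeration produced no designs", stacklevel=2)
    return designs


def rank_designs(
    candidates: Sequence[WeightedDesign | str],
    grid: TimeGrid,
    params: GrowthParams,
    target: Target | str = Target.slope_var,
    formula: Formula | str = Formula.wald_limit,
    cost: CostModel | None = None,
    attrition: AttritionModel = NO_ATTRITION,
    n_ref: int | None = None,
) -> list[EfficiencyReport]:
    """Rank candidate designs by adjusted effective error.

    For each candidate: expand it under the attrition model, pool the
    pattern-level effective errors into the design effective error, compute
    the affordable sample size from the *planned* design (the budget is
    committed before anyone drops out), adjust against ``n_ref`` (default:
    the largest affordable N in the set) and derive relative efficiency and
    width inflation.  Results are sorted by AEE with ties broken by the
    canonical design string; tied designs share the better rank.
    """
    if not candidates:
        raise ValueError("no candidate designs")
    designs = [WeightedDesign.coerce(c) for c in candidates]

    if cost is not None:
        ns = [affordable_n(cost, d) for d in designs]
    else:
        ns = [1 for _ in designs]
    ref = n_ref if n_ref is not None else max(ns)

    rows = []
    for d, n in zip(designs, ns):
        implied = expand_design(d, grid, attrition)
        ee = design_ee(implied, grid, params, target, formula)
        aee = adjusted_ee(ee, n, ref)
        rows.append((d, n, ee, aee))

    rows.sort(key=lambda r: (r[3], format_design(r[0])))
    best_aee = rows[0][3]

    reports: list[EfficiencyReport] = []
    rank = 0
    prev_aee = None
    for i, (d, n, ee, aee) in enumerate(rows, start=1):
        if prev_aee is None or not math.isclose(aee, prev_aee, rel_tol=1e-12, abs_tol=1e-12):
            rank = i
        prev_aee = aee
        reports.append(
            EfficiencyReport(
                design=d,
                design_str=format_design(d),
                n=n,
                ee=ee,
                adjusted_ee=aee,
                relative_efficiency=relative_efficiency(aee, best_aee),
                width_inflation=width_inflation(aee, best_aee),
                discount=ref / n,
                rank=rank,
            )
        )
    return reports
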