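"""Linear MCAR attrition: expanding a planned design into its implied design.

Participants drop out permanently at a rate proportional to elapsed study
time: the probability that a participant has left the study before the
scheduled occasion at time ``t`` is ``rate * (t - t_onset)``, where
``t_onset`` is the time of the first scheduled occasion.  Because dropout
depends only on time (not on the data), the resulting missingness is MCAR and
a complete or planned-missing design with attrition is just another weighted
design: a ``{1,2,5}`` arm under a 7.5%-per-wave attrition rate becomes
``{1 : 7.5% | 1,2 : 22.5% | 1,2,5 : 70%}``.

Dropout is permanent and applies on the scheduled study clock, so the
implied sub-patterns are always prefixes of the parent pattern, and dropout
before an arm's first scheduled measurement yields an empty (never measured)
group whose participants still count in the design's denominator.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .designs import Pattern, WeightedDesign
from .model import TimeGrid


class AttritionKind(enum.Enum):
    none = "none"
    linear = "linear"


@dataclass(frozen=True)
class AttritionModel:
    """Linear dropout process: share ``rate`` of the sample lost per unit time."""

    rate: float = 0.0
    kind: AttritionKind = AttritionKind.linear

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError(f"attrition rate must be >= 0, got {self.rate}")
        if self.kind is AttritionKind.none and self.rate != 0:
            raise ValueError("kind 'none' requires rate 0")

    def validate_for(self, grid: TimeGrid) -> None:
        span = grid.times[-1] - grid.times[0]
        if self.rate * span > 1 + 1e-12:
            raise ValueError(
                f"attrition exceeds sample: rate {self.rate} over a span of "
                f"{span} time units implies cumulative dropout > 100%"
            )


NO_ATTRITION = AttritionModel(rate=0.0, kind=AttritionKind.none)


def dropout_share(
    occasion_time: float, model: AttritionModel, onset_time: float
) -> float:
    """Cumulative share of participants lost before the given occasion time.

    Linear in elapsed time since study onset: ``rate * (t - t_onset)``.
    """
    if occasion_time < onset_time:
        raise ValueError("occasion_time must be >= onset_time")
    share = model.rate * (occasion_time - onset_time)
    if share > 1 + 1e-12:
        raise ValueError(
            f"attrition exceeds sample: implied dropout share {share:.3f} > 1"
        )
    return min(share, 1.0)


def expand_pattern(
    pattern: Pattern, grid: TimeGrid, model: AttritionModel
) -> WeightedDesign:
    """Implied weighted design of one planned pattern under linear attrition.

    Each participant observes the prefix of the pattern consisting of the
    occasions they reached before dropping out.  The prefix ending at the
    pattern's i-th occasion receives the dropout mass accruing between that
    occasion and the next one observed by the pattern; the full pattern keeps
    the survivors; the empty prefix receives the mass lost before the
    pattern's first occasion.  Weights sum to one by construction.
    """
    if pattern.is_empty:
        raise ValueError("cannot expand an empty pattern")
    model.validate_for(grid)
    onset = grid.times[0]
    times = grid.pattern_times(pattern.occasions)
    if model.rate == 0:
        return WeightedDesign([(pattern, 1.0)])

    cum = [dropout_share(t, model, onset) for t in times]
    entries: list[tuple[Pattern, float]] = []
    if cum[0] > 0:  # lost before ever being measured
        entries.append((Pattern(()), cum[0]))
    for i in range(len(times) - 1):
        w = cum[i + 1] - cum[i]
        if w > 0:
            entries.append((Pattern(pattern.occasions[: i + 1]), w))
    entries.append((pattern, 1.0 - cum[-1]))
    return WeightedDesign(entries)


def expand_design(
    design: WeightedDesign, grid: TimeGrid, model: AttritionModel
) -> WeightedDesign:
    """Implied weighted design of a whole planned design under attrition.

    Expands each arm and scales the resulting sub-pattern weights by the arm's
    share; identical sub-patterns arising from different arms are merged.
    With a zero rate this is the identity.
    """
    if model.rate == 0:
        return design
    entries: list[tuple[Pattern, float]] = []
    for pat, w in design.entries:
        expanded = expand_pattern(pat, grid, model)
        for sub, sw in expanded.entries:
            entries.append((sub, w * sw))
    return WeightedDesign(entries)
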