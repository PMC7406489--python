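"""Design notation, parsing, and pooling of effective errors across patterns.

A planned-missing (PM) design is written in curly brackets listing its
response patterns separated by vertical bars, e.g. ``{1,2,5 | 1,3,5 | 1,4,5}``
for a three-arm design whose participants are measured at occasions 1,2,5 or
1,3,5 or 1,4,5.  Unequal participant shares are written after a colon:
``{1 : 7.5% | 1,2 : 22.5% | 1,2,5 : 70%}``.

Because the arms of a PM design are statistically independent groups, the
design-level effective error is the share-weighted harmonic mean of the
arm-level effective errors:

    ee_design = 1 / sum_j (w_j / ee_j)

Arms with infinite effective error contribute zero precision but their share
still dilutes the design (their weight stays in the normalization), which is
exactly how never-returning participants behave under attrition.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .effective_error import Formula, Target, pattern_ee
from .model import GrowthParams, TimeGrid


@dataclass(frozen=True)
class Pattern:
    """An observed-occasion subset, e.g. (1, 2, 5). Labels are 1-based."""

    occasions: tuple[int, ...]

    def __init__(self, occasions: Iterable[int]):
        occs = tuple(sorted(set(int(o) for o in occasions)))
        if any(o < 1 for o in occs):
            raise ValueError(f"occasion labels must be >= 1, got {occs}")
        object.__setattr__(self, "occasions", occs)

    def __str__(self) -> str:
        # "-" denotes the empty (never measured) pattern in design strings
        if not self.occasions:
            return "-"
        return ",".join(str(o) for o in self.occasions)

    def __len__(self) -> int:
        return len(self.occasions)

    @property
    def is_empty(self) -> bool:
        return len(self.occasions) == 0


@dataclass(frozen=True)
class WeightedDesign:
    """A set of response patterns with participant proportions.

    Proportions are normalized to sum to one; duplicate patterns are merged by
    summing their proportions.  Entries keep the order in which patterns first
    appear.
    """

    entries: tuple[tuple[Pattern, float], ...]

    def __init__(self, entries: Iterable[tuple[Pattern | Iterable[int], float]]):
        merged: dict[tuple[int, ...], float] = {}
        order: list[tuple[int, ...]] = []
        for pat, w in entries:
            if not isinstance(pat, Pattern):
                pat = Pattern(pat)
            w = float(w)
            if w < 0:
                raise ValueError(f"negative proportion {w} for pattern {{{pat}}}")
            key = pat.occasions
            if key not in merged:
                merged[key] = 0.0
                order.append(key)
            merged[key] += w
        total = sum(merged.values())
        if total <= 0:
            raise ValueError("design proportions must sum to > 0")
        object.__setattr__(
            self,
            "entries",
            tuple((Pattern(key), merged[key] / total) for key in order),
        )

    @classmethod
    def coerce(cls, obj) -> "WeightedDesign":
        """Accept a WeightedDesign, a design string, or a list of patterns."""
        if isinstance(obj, WeightedDesign):
            return obj
        if isinstance(obj, str):
            return parse_design(obj)
        return equal_design(obj)

    @property
    def patterns(self) -> tuple[Pattern, ...]:
        return tuple(p for p, _ in self.entries)

    @property
    def weights(self) -> tuple[float, ...]:
        return tuple(w for _, w in self.entries)

    def expected_occasions(self) -> float:
        """Share-weighted mean number of observed occasions per participant."""
        return sum(w * len(p) for p, w in self.entries)

    def __str__(self) -> str:
        return format_design(self)


def equal_design(patterns: Iterable[Pattern | Iterable[int]]) -> WeightedDesign:
    """Design assigning participants in equal shares to the given patterns."""
    patterns = list(patterns)
    if not patterns:
        raise ValueError("design needs at least one pattern")
    return WeightedDesign([(p, 1.0) for p in patterns])


def complete_design(pattern: Pattern | Iterable[int]) -> WeightedDesign:
    """A single-pattern ("complete") design: everyone shares one pattern."""
    return WeightedDesign([(pattern, 1.0)])


_ENTRY_RE = re.compile(r"^(?P<occs>-|[\d\s,]*)(?:\s*:\s*(?P<w>[\d.]+)\s*(?P<pct>%)?)?$")


def _parse_weight(text: str, has_pct: bool) -> float:
    value = float(text)
    if has_pct or value > 1:
        return value / 100.0
    return value


def parse_design(text: str, max_occasion: int | None = None) -> WeightedDesign:
    """Parse a design string such as ``{1,2,5 | 1,3,5}`` or with shares.

    Weights may be percentages (``70%`` or any bare number > 1) or proportions
    (numbers <= 1).  Patterns without an explicit weight share the remaining
    mass equally; if every weight is explicit the weights must sum to 100%
    (within 0.1%).  ``max_occasion`` optionally bounds the occasion labels.
    """
    stripped = text.strip()
    if not (stripped.startswith("{") and stripped.endswith("}")):
        raise ValueError(f"design string must be wrapped in curly brackets: {text!r}")
    body = stripped[1:-1]
    if not body.strip():
        raise ValueError("design string contains no patterns")

    entries: list[tuple[Pattern, float | None]] = []
    for raw in body.split("|"):
        m = _ENTRY_RE.match(raw.strip())
        if m is None:
            raise ValueError(f"malformed design entry: {raw.strip()!r}")
        occs_text = m.group("occs").strip()
        if occs_text == "-":
            occ_tokens: list[str] = []
        else:
            occ_tokens = [tok.strip() for tok in occs_text.split(",") if tok.strip()]
            if not occ_tokens:
                raise ValueError(f"design entry has no occasions: {raw.strip()!r}")
        try:
            occs = [int(tok) for tok in occ_tokens]
        except ValueError as exc:
            raise ValueError(f"bad occasion label in entry {raw.strip()!r}") from exc
        if max_occasion is not None:
            for o in occs:
                if not 1 <= o <= max_occasion:
                    raise ValueError(
                        f"occasion label {o} out of range 1..{max_occasion} "
                        f"in entry {raw.strip()!r}"
                    )
        weight = None
        if m.group("w") is not None:
            weight = _parse_weight(m.group("w"), m.group("pct") is not None)
        entries.append((Pattern(occs), weight))

    explicit = [w for _, w in entries if w is not None]
    n_free = sum(1 for _, w in entries if w is None)
    if n_free == 0:
        if abs(sum(explicit) - 1.0) > 1e-3:
            raise ValueError(
                f"explicit weights sum to {sum(explicit) * 100:.2f}%, expected 100%"
            )
        resolved = [(p, w) for p, w in entries]
    else:
        remaining = 1.0 - sum(explicit)
        if remaining < -1e-9:
            raise ValueError(f"explicit weights exceed 100% in {text!r}")
        share = max(remaining, 0.0) / n_free
        resolved = [(p, share if w is None else w) for p, w in entries]
    return WeightedDesign(resolved)


def format_design(design: WeightedDesign) -> str:
    """Canonical design string; shares are omitted when exactly equal.

    Unequal shares are printed as percentages with one decimal (trailing zero
    dropped when the share is a whole percent).
    """
    if not design.entries:
        raise ValueError("cannot format an empty design")
    k = len(design.entries)
    weights = design.weights
    equal = all(abs(w - 1.0 / k) < 1e-9 for w in weights)
    if equal:
        parts = [str(p) for p in design.patterns]
    else:
        parts = []
        for p, w in design.entries:
            pct = w * 100.0
            pct_str = f"{pct:.1f}".rstrip("0").rstrip(".")
            parts.append(f"{p} : {pct_str}%")
    return "{" + " | ".join(parts) + "}"


def combine_ee(components: Sequence[tuple[float, float]]) -> float:
    """Pool component effective errors into a design-level effective error.

    ``components`` is a list of (effective_error, weight) pairs.  Weights are
    normalized; the pooled value is the weighted harmonic mean
    ``1 / sum_j (w_j / ee_j)``.  Infinite components contribute zero precision
    while their weight still counts, and the result is infinite only when
    every component is.
    """
    if not components:
        raise ValueError("no components to combine")
    weights = [w for _, w in components]
    if any(w < 0 for w in weights):
        raise ValueError("negative weight in combine_ee")
    total = sum(weights)
    if total <= 0:
        raise ValueError("weights must sum to > 0")
    precision = 0.0
    for e, w in components:
        if e <= 0:
            raise ValueError(f"effective error must be positive, got {e}")
        if math.isfinite(e):
            precision += (w / total) / e
    if precision == 0.0:
        return math.inf
    return 1.0 / precision


def ee_bounds(components: Sequence[float], k: int | None = None) -> tuple[float, float]:
    """Bounds on the equal-weight pooled effective error.

    The harmonic mean of ``k`` equal-weight components is at least their
    minimum and at most ``k`` times their minimum: one excellent arm caps how
    bad the design can get.
    """
    components = list(components)
    if not components:
        raise ValueError("no components")
    if k is None:
        k = len(components)
    lo = min(components)
    return lo, k * lo


def design_ee(
    design: WeightedDesign | str | Iterable,
    grid: TimeGrid,
    params: GrowthParams,
    target: Target | str = Target.slope_var,
    formula: Formula | str = Formula.wald_limit,
) -> float:
    """Design-level effective error: per-pattern values pooled by share.

    Empty patterns (participants never measured) carry infinite effective
    error for every target and enter the pool with zero precision.
    """
    design = WeightedDesign.coerce(design)
    target = Target(target)
    formula = Formula(formula)
    components = []
    for pat, w in design.entries:
        if pat.is_empty:
            components.append((math.inf, w))
        else:
            ee = pattern_ee(pat.occasions, grid, params, target, formula)
            components.append((ee.value, w))
    return combine_ee(components)
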