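"""Linear latent growth curve model: parameters, implied moments, simulation.

The linear latent growth curve model (LGCM) represents each participant's
repeated measurements as a noisy linear trajectory.  Two correlated latent
variables -- an intercept ``I`` and a slope ``S`` -- vary across
participants, and homoscedastic, uncorrelated residuals are added at every
measurement occasion:

    y_ij = I_i + S_i * t_j + e_ij,   (I, S) ~ N(nu, Psi),   e_ij ~ N(0, var_e)

so that the model-implied moments of the observed vector are

    mu    = Lambda @ nu
    Sigma = Lambda @ Psi @ Lambda' + Theta

with loading matrix ``Lambda = [[1, t_1], ..., [1, t_M]]``, latent covariance
``Psi = [[var_i, cov_is], [cov_is, var_s]]`` and ``Theta = var_e * I``.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class TimeCoding(enum.Enum):
    """Where the time axis is anchored.

    ``one_based`` labels the first scheduled occasion t=1 (occasion labels and
    times coincide on an equidistant grid); ``zero_anchored`` places the
    intercept at study onset, t=0.  Effective-error formulas are sensitive to
    this choice, so the grid records it explicitly.
    """

    one_based = "one_based"
    zero_anchored = "zero_anchored"


@dataclass(frozen=True)
class GrowthParams:
    """Population parameters of a linear latent growth curve model.

    Parameters
    ----------
    intercept_mean, slope_mean
        Means of the latent intercept and slope (``mu_i``, ``mu_s``).
    intercept_var, slope_var
        Variances of the latent intercept and slope; must be non-negative.
    intercept_slope_cov
        Covariance of intercept and slope; the implied 2x2 latent covariance
        matrix must be positive semi-definite.
    residual_var
        Occasion-specific residual variance (``var_e``); must be positive.
    """

    intercept_mean: float
    slope_mean: float
    intercept_var: float
    slope_var: float
    intercept_slope_cov: float
    residual_var: float

    def __post_init__(self) -> None:
        if self.residual_var <= 0:
            raise ValueError(f"residual_var must be > 0, got {self.residual_var}")
        if self.intercept_var < 0:
            raise ValueError(f"intercept_var must be >= 0, got {self.intercept_var}")
        if self.slope_var < 0:
            raise ValueError(f"slope_var must be >= 0, got {self.slope_var}")
        if self.intercept_slope_cov**2 > self.intercept_var * self.slope_var + 1e-12:
            raise ValueError(
                "latent covariance matrix is not positive semi-definite: "
                f"cov_is^2 = {self.intercept_slope_cov**2:.6g} exceeds "
                f"var_i * var_s = {self.intercept_var * self.slope_var:.6g}"
            )

    @property
    def latent_cov(self) -> np.ndarray:
        """The 2x2 latent covariance matrix Psi."""
        return np.array(
            [
                [self.intercept_var, self.intercept_slope_cov],
                [self.intercept_slope_cov, self.slope_var],
            ]
        )

    @property
    def latent_mean(self) -> np.ndarray:
        """The latent mean vector nu = (mu_i, mu_s)."""
        return np.array([self.intercept_mean, self.slope_mean])


#: Reference parameterization used throughout the documentation and examples:
#: a five-occasion developmental study with substantial individual differences
#: in both level and change.
REFERENCE_PARAMS = GrowthParams(
    intercept_mean=39.46,
    slope_mean=8.06,
    intercept_var=28.78,
    slope_var=8.20,
    intercept_slope_cov=1.56,
    residual_var=30.0,
)


@dataclass(frozen=True)
class TimeGrid:
    """Scheduled measurement occasions of a study.

    ``times[j]`` is the time of occasion label ``j+1`` (labels run 1..M).
    Times must be strictly increasing.  ``coding`` records the anchoring of
    the axis; :meth:`one_based` and :meth:`zero_anchored` convert by a pure
    shift, which preserves spacing.
    """

    times: tuple[float, ...]
    coding: TimeCoding = TimeCoding.one_based

    def __init__(self, times: Iterable[float], coding: TimeCoding | str = TimeCoding.one_based):
        times = tuple(float(t) for t in times)
        if len(times) == 0:
            raise ValueError("a time grid needs at least one occasion")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(f"times must be strictly increasing, got {times}")
        coding = TimeCoding(coding)
        if coding is TimeCoding.zero_anchored and times[0] != 0.0:
            raise ValueError("zero_anchored grid must start at t=0")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "coding", coding)

    @property
    def n_occasions(self) -> int:
        return len(self.times)

    def loadings(self) -> np.ndarray:
        """The M x 2 loading matrix Lambda = [[1, t_1], ..., [1, t_M]]."""
        t = np.asarray(self.times)
        return np.column_stack([np.ones_like(t), t])

    def zero_anchored(self) -> "TimeGrid":
        """Shift times so the first scheduled occasion is at t=0."""
        if self.coding is TimeCoding.zero_anchored:
            return self
        shift = self.times[0]
        return TimeGrid([t - shift for t in self.times], TimeCoding.zero_anchored)

    def one_based(self) -> "TimeGrid":
        """Shift times so the first scheduled occasion is at t=1."""
        if self.coding is TimeCoding.one_based:
            return self
        shift = 1.0 - self.times[0]
        return TimeGrid([t + shift for t in self.times], TimeCoding.one_based)

    def pattern_times(self, occasions: Sequence[int]) -> tuple[float, ...]:
        """Times of the given occasion labels (1-based), in this grid's coding.

        Sub-pattern times are read off the study grid without re-anchoring:
        pattern {2,4} on a zero-anchored five-occasion grid has times (1, 3).
        """
        for occ in occasions:
            if not 1 <= occ <= self.n_occasions:
                raise ValueError(
                    f"occasion label {occ} outside grid 1..{self.n_occasions}"
                )
        return tuple(self.times[occ - 1] for occ in occasions)


def equidistant_grid(n_occasions: int, coding: TimeCoding | str = TimeCoding.one_based) -> TimeGrid:
    """Equidistant unit-spaced grid with ``n_occasions`` occasions."""
    coding = TimeCoding(coding)
    start = 0 if coding is TimeCoding.zero_anchored else 1
    return TimeGrid(range(start, start + n_occasions), coding)


@dataclass(frozen=True)
class MomentPair:
    """Model-implied mean vector and covariance matrix."""

    mean: np.ndarray
    covariance: np.ndarray


def implied_moments(params: GrowthParams, grid: TimeGrid) -> MomentPair:
    """Model-implied moments of the observed vector on the full grid.

    Returns ``mu = Lambda @ nu`` and ``Sigma = Lambda @ Psi @ Lambda' + var_e * I``,
    i.e. ``mean[j] = mu_i + t_j * mu_s`` and
    ``cov[j,k] = var_i + (t_j + t_k) * cov_is + t_j * t_k * var_s + [j==k] * var_e``.
    """
    lam = grid.loadings()
    mean = lam @ params.latent_mean
    cov = lam @ params.latent_cov @ lam.T + params.residual_var * np.eye(grid.n_occasions)
    return MomentPair(mean=mean, covariance=cov)


def pattern_moments(
    params: GrowthParams, grid: TimeGrid, occasions: Sequence[int]
) -> MomentPair:
    """Marginal moments for the subset of occasions observed in a pattern.

    Marginalizing a multivariate normal is row/column selection, so this is
    ``implied_moments`` restricted to the pattern's occasions.
    """
    occasions = list(occasions)
    if not occasions:
        raise ValueError("no observed occasions: pattern is empty")
    full = implied_moments(params, grid)
    idx = np.array([occ - 1 for occ in occasions])
    if np.any(idx < 0) or np.any(idx >= grid.n_occasions):
        raise ValueError(f"occasion labels {occasions} outside grid 1..{grid.n_occasions}")
    return MomentPair(mean=full.mean[idx], covariance=full.covariance[np.ix_(idx, idx)])


def largest_remainder_allocation(weights: Sequence[float], n: int) -> list[int]:
    """Apportion ``n`` participants to groups by largest-remainder rounding.

    Quotas ``w_j * n`` are floored; leftover slots go to the groups with the
    largest fractional remainders (earlier groups win exact ties).  The result
    sums to ``n`` exactly, making weighted designs reproducible without a
    multinomial draw.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative and sum to > 0")
    w = w / w.sum()
    quota = w * n
    counts = np.floor(quota).astype(int)
    remainder = quota - counts
    short = n - counts.sum()
    # stable sort => ties broken by group order
    for j in np.argsort(-remainder, kind="stable")[:short]:
        counts[j] += 1
    return counts.tolist()


def simulate_dataset(
    params: GrowthParams,
    grid: TimeGrid,
    design,
    n: int,
    seed: int | np.random.Generator | None = None,
    random_assignment: bool = False,
) -> pd.DataFrame:
    """Simulate a wide-format dataset under a weighted missing-data design.

    Each participant's complete response vector is drawn from the full
    model-implied multivariate normal; occasions outside the participant's
    assigned pattern are then set to missing (NaN).  Patterns are assigned by
    deterministic largest-remainder apportionment of the design proportions
    (or multinomially if ``random_assignment`` is set); rows are shuffled so
    pattern membership is not confounded with row order.

    Returns a DataFrame with columns ``id``, ``y1..yM`` and ``pattern`` (the
    comma-separated observed occasion labels, empty for never-measured rows).
    """
    from .designs import WeightedDesign  # local import to avoid a cycle

    if n < 1:
        raise ValueError("n must be >= 1")
    design = WeightedDesign.coerce(design)
    rng = np.random.default_rng(seed)
    if n < len(design.entries):
        warnings.warn(
            f"n={n} is smaller than the number of patterns ({len(design.entries)}); "
            "some patterns receive no participants",
            stacklevel=2,
        )

    weights = [w for _, w in design.entries]
    if random_assignment:
        assignment = rng.choice(len(weights), size=n, p=np.asarray(weights) / sum(weights))
    else:
        counts = largest_remainder_allocation(weights, n)
        assignment = np.repeat(np.arange(len(counts)), counts)
        rng.shuffle(assignment)

    moments = implied_moments(params, grid)
    y = rng.multivariate_normal(moments.mean, moments.covariance, size=n, method="cholesky")

    m = grid.n_occasions
    mask = np.zeros((n, m), dtype=bool)  # True = observed
    labels = []
    for i, j in enumerate(assignment):
        occs = design.entries[j][0].occasions
        mask[i, [o - 1 for o in occs]] = True
        labels.append(",".join(str(o) for o in occs))
    y = np.where(mask, y, np.nan)

    out = pd.DataFrame(y, columns=[f"y{j}" for j in range(1, m + 1)])
    out.insert(0, "id", np.arange(1, n + 1))
    out["pattern"] = labels
    return out


def write_dataset(df: pd.DataFrame, path) -> None:
    """Write a wide-format dataset to CSV; missing cells are left empty."""
    df.to_csv(path, index=False, na_rep="")


def read_dataset(path) -> pd.DataFrame:
    """Read a wide-format CSV dataset; empty cells and 'NA' become missing."""
    df = pd.read_csv(path, na_values=["NA", ""], keep_default_na=True)
    return df
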