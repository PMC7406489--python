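"""Run configuration: schema-validated YAML/JSON loading.

A configuration file describes the population model and, optionally, the
study comparison to run::

    mu_i: 39.46
    mu_s: 8.06
    var_i: 28.78
    var_s: 8.20
    cov_is: 1.56
    var_e: 30
    times: [1, 2, 3, 4, 5]
    designs:
      - "{1,2,5}"
      - "{1,2,5 | 1,3,5 | 1,4,5}"
    target: slope_var
    formula: wald_limit
    budget: 100000
    cost_per_datapoint: 20
    attrition_rate: 0.075
    seed: 1

Unknown keys are rejected with a message naming the offending key.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .attrition import NO_ATTRITION, AttritionModel
from .effective_error import Formula, Target
from .model import GrowthParams, REFERENCE_PARAMS, TimeCoding, TimeGrid
from .ranking import CostModel

_PARAM_KEYS = {"mu_i", "mu_s", "var_i", "var_s", "cov_is", "var_e"}
_KNOWN_KEYS = _PARAM_KEYS | {
    "times",
    "coding",
    "designs",
    "target",
    "formula",
    "budget",
    "cost_per_datapoint",
    "attrition_rate",
    "output",
    "seed",
}


@dataclass(frozen=True)
class RunConfig:
    """Everything one analysis run needs, parsed and validated."""

    params: GrowthParams
    grid: TimeGrid
    designs: tuple[str, ...] = ()
    target: Target = Target.slope_var
    formula: Formula = Formula.wald_limit
    cost: CostModel | None = None
    attrition: AttritionModel = NO_ATTRITION
    output: str | None = None
    seed: int | None = None


#: Default five-occasion study grid used when a config omits ``times``.
DEFAULT_GRID = TimeGrid([1, 2, 3, 4, 5], TimeCoding.one_based)


def config_from_mapping(raw: dict) -> RunConfig:
    """Build a :class:`RunConfig` from a plain mapping, rejecting unknown keys."""
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(
            f"unknown config key(s): {', '.join(sorted(unknown))}; "
            f"known keys are {', '.join(sorted(_KNOWN_KEYS))}"
        )

    if _PARAM_KEYS & set(raw):
        missing = _PARAM_KEYS - set(raw)
        if missing:
            raise ValueError(f"incomplete model parameters, missing: {sorted(missing)}")
        params = GrowthParams(
            intercept_mean=float(raw["mu_i"]),
            slope_mean=float(raw["mu_s"]),
            intercept_var=float(raw["var_i"]),
            slope_var=float(raw["var_s"]),
            intercept_slope_cov=float(raw["cov_is"]),
            residual_var=float(raw["var_e"]),
        )
    else:
        params = REFERENCE_PARAMS

    if "times" in raw:
        coding = TimeCoding(raw.get("coding", "one_based"))
        grid = TimeGrid(raw["times"], coding)
    else:
        grid = DEFAULT_GRID

    cost = None
    if ("budget" in raw) != ("cost_per_datapoint" in raw):
        raise ValueError("budget and cost_per_datapoint must be given together")
    if "budget" in raw:
        cost = CostModel(float(raw["budget"]), float(raw["cost_per_datapoint"]))

    attrition = NO_ATTRITION
    if "attrition_rate" in raw:
        attrition = AttritionModel(rate=float(raw["attrition_rate"]))

    designs = raw.get("designs", ())
    if isinstance(designs, str):
        designs = (designs,)

    return RunConfig(
        params=params,
        grid=grid,
        designs=tuple(designs),
        target=Target(raw.get("target", "slope_var")),
        formula=Formula(raw.get("formula", "wald_limit")),
        cost=cost,
        attrition=attrition,
        output=raw.get("output"),
        seed=raw.get("seed"),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML or JSON configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    return config_from_mapping(raw or {})
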