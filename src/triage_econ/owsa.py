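"""One-way sensitivity analysis with tornado ranking.

Each parameter is pushed to a low and a high bound while everything else
stays at base (accuracy rates and timing means at +-1 SE, unit costs at
+-20% by convention); the full table-mode pipeline is re-evaluated at
each bound — exactly two evaluations per parameter — and parameters are
ranked by the width of the resulting outcome interval for the tornado
display.  Probability parameters are clipped to [0, 1] after
perturbation, with a logged warning.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass
from typing import Any, Callable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: dotted config paths treated as probabilities (clipped to [0, 1])
PROBABILITY_PREFIXES = ("accuracy.", "shares.")


@dataclass(frozen=True)
class ParameterSpec:
    """One perturbation: a dotted config path and its low/high bounds."""

    name: str
    low: float
    high: float


@dataclass(frozen=True)
class OWSAResult:
    parameter: str
    base_value: float
    low_input: float
    high_input: float
    outcomes_low: Mapping[str, float]
    outcomes_high: Mapping[str, float]

    def outcome_range(self, endpoint: str) -> float:
        return abs(self.outcomes_high[endpoint] - self.outcomes_low[endpoint])


def get_path(config: Any, path: str) -> Any:
    """Navigate attributes and mapping keys along a dotted path."""
    obj = config
    for part in path.split("."):
        if isinstance(obj, Mapping):
            if part not in obj:
                raise KeyError(f"unknown parameter path {path!r} (at {part!r})")
            obj = obj[part]
        elif hasattr(obj, part):
            obj = getattr(obj, part)
        else:
            raise KeyError(f"unknown parameter path {path!r} (at {part!r})")
    return obj


def set_path(config: Any, path: str, value: Any) -> None:
    parts = path.split(".")
    obj = get_path(config, ".".join(parts[:-1])) if len(parts) > 1 else config
    leaf = parts[-1]
    if isinstance(obj, Mapping):
        if leaf not in obj:
            raise KeyError(f"unknown parameter path {path!r} (at {leaf!r})")
        obj[leaf] = value
    elif hasattr(obj, leaf):
        object.__setattr__(obj, leaf, value) if _is_frozen(obj) else setattr(
            obj, leaf, value
        )
    else:
        raise KeyError(f"unknown parameter path {path!r} (at {leaf!r})")


def _is_frozen(obj: Any) -> bool:
    params = getattr(type(obj), "__dataclass_params__", None)
    return bool(params and params.frozen)


def _clip_probability(name: str, value: float) -> float:
    if any(name.startswith(p) for p in PROBABILITY_PREFIXES):
        clipped = min(1.0, max(0.0, value))
        if clipped != value:
            logger.warning(
                "parameter %s perturbed to %.4f; clipped to %.4f", name, value, clipped
            )
        return clipped
    return value


def run_owsa(
    base_config: Any,
    parameter_specs: Sequence[ParameterSpec],
    evaluate: Callable[[Any], Mapping[str, float]],
) -> list[OWSAResult]:
    """Evaluate every parameter at its two bounds (2k pipeline runs).

    ``evaluate`` maps a config to endpoint values (e.g. LoS reduction in
    hours, cost savings per country); it is called exactly twice per
    parameter, all other parameters held at base.
    """
    results = []
    for spec in parameter_specs:
        base_value = float(get_path(base_config, spec.name))
        outcomes = {}
        for bound_name, bound in (("low", spec.low), ("high", spec.high)):
            cfg = copy.deepcopy(base_config)
            set_path(cfg, spec.name, _clip_probability(spec.name, float(bound)))
            outcomes[bound_name] = dict(evaluate(cfg))
        results.append(
            OWSAResult(
                parameter=spec.name,
                base_value=base_value,
                low_input=spec.low,
                high_input=spec.high,
                outcomes_low=outcomes["low"],
                outcomes_high=outcomes["high"],
            )
        )
    return results


def tornado_table(results: Sequence[OWSAResult], endpoint: str) -> pd.DataFrame:
    """Rank results by outcome range (descending; ties alphabetical)."""
    if len(results) == 0:
        raise ValueError("no OWSA results to rank")
    rows = [
        {
            "parameter": r.parameter,
            "base_value": r.base_value,
            "low_input": r.low_input,
            "high_input": r.high_input,
            "outcome_low": r.outcomes_low[endpoint],
            "outcome_high": r.outcomes_high[endpoint],
            "range": r.outcome_range(endpoint),
        }
        for r in results
    ]
    df = pd.DataFrame(rows)
    return (
        df.sort_values(["range", "parameter"], ascending=[False, True], kind="stable")
        .reset_index(drop=True)
    )
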