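"""Relative-prediction-error cost and iterative grid-search model fitting.

The cost for one outcome variable (mean swim speed, bout rate or bout
initial speed) is the root-mean-square of the per-condition prediction
errors divided by the grand mean of the observed values — a dimensionless
relative error insensitive to the choice of units.  Fitting several outcomes
at once averages their relative errors with equal weight.

The optimizer is a translated/shrinking grid search: a rectangular grid of
candidate parameter sets is evaluated; while the best point is off-centre
the grid recentres on it; once the best point sits in the centre every
pitch is shrunk, until all pitches fall below a stopping factor.  Gains and
time constants span several orders of magnitude, so grids are laid out
multiplicatively (log scale) with the pitch a factor per step.  Cost
evaluations reuse common random numbers (fixed per-condition seeds) so the
stochastic cost surface is a deterministic function of the parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .controller import ModelParams, SpeedProfile
from .simulator import Condition, run_grid

__all__ = [
    "relative_prediction_error",
    "combined_cost",
    "FitSpec",
    "FitResult",
    "grid_search",
    "fit_model",
]

#: Summary-table column per fittable outcome variable.
OUTCOME_COLUMNS = {
    "swim_speed": "swim_speed_mm_s",
    "bout_rate": "bout_rate_hz",
    "bout_initial_speed": "bout_initial_speed_mm_s",
}


def relative_prediction_error(observed, predicted) -> float:
    """RMSE over conditions divided by the observed grand mean."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must align on conditions")
    if observed.size == 0:
        raise ValueError("empty condition set")
    grand_mean = observed.mean()
    if grand_mean == 0:
        raise ValueError("observed grand mean is zero")
    rmse = float(np.sqrt(np.mean((observed - predicted) ** 2)))
    return rmse / grand_mean


def combined_cost(errors: Mapping[str, float] | Sequence[float]) -> float:
    """Unweighted mean of per-outcome relative errors."""
    values = list(errors.values()) if isinstance(errors, Mapping) else list(errors)
    if not values:
        raise ValueError("need at least one outcome error")
    return float(np.mean(values))


@dataclass
class FitSpec:
    """What to fit and how to evaluate the model against observations.

    ``free`` maps parameter names to (initial centre, initial pitch factor);
    searched values are ``centre * pitch**k``.  ``observed`` is a summary
    table in the simulator schema covering ``conditions``.
    """

    base_params: ModelParams
    free: dict[str, tuple[float, float]]
    outcomes: tuple[str, ...]
    conditions: tuple[Condition, ...]
    observed: pd.DataFrame
    n_fish: int = 30
    seed: int = 0
    n_steps: int = 3000
    warmup_steps: int = 1000
    profile: Optional[SpeedProfile] = None

    def __post_init__(self) -> None:
        if not self.outcomes:
            raise ValueError("outcome set must be non-empty")
        for name in self.outcomes:
            if name not in OUTCOME_COLUMNS:
                raise ValueError(f"unknown outcome {name!r}")
        for name in self.free:
            if not hasattr(self.base_params, name):
                raise ValueError(f"{name!r} is not a model parameter")


@dataclass
class FitResult:
    """Best parameters found and the search history."""

    params: dict[str, float]
    errors: dict[str, float]
    cost: float
    trace: pd.DataFrame  # one row per iteration: centre, pitches, cost
    n_evaluations: int


def grid_search(
    center: Mapping[str, float],
    cost_fn: Callable[[dict[str, float]], tuple[float, dict[str, float]]],
    pitch: Mapping[str, float] | float = 2.0,
    shrink: float = 0.5,
    stop_pitch: float = 1.05,
    max_evaluations: int = 2000,
) -> FitResult:
    """Iterative translated/shrinking multiplicative grid search.

    ``cost_fn`` maps a parameter dict to ``(cost, per_outcome_errors)`` and
    must be deterministic (use common random numbers for stochastic models).
    Each iteration evaluates the full 3^d grid around the centre; if a
    strictly better off-centre point exists the grid translates there,
    otherwise every pitch is raised to the ``shrink`` power.  Terminates when
    all pitches are at most ``stop_pitch`` (or the evaluation budget runs
    out).  Evaluations are cached, so translation steps only pay for the
    newly exposed face of the grid.
    """
    names = sorted(center)
    centre = {k: float(center[k]) for k in names}
    if isinstance(pitch, Mapping):
        pitches = {k: float(pitch[k]) for k in names}
    else:
        pitches = {k: float(pitch) for k in names}
    if any(p <= 1.0 for p in pitches.values()):
        raise ValueError("pitch factors must exceed 1")

    cache: dict[tuple, tuple[float, dict]] = {}
    trace_rows = []

    def evaluate(point: dict[str, float]) -> tuple[float, dict]:
        key = tuple(round(np.log(point[k]), 10) if point[k] > 0 else point[k]
                    for k in names)
        if key not in cache:
            cache[key] = cost_fn(point)
        return cache[key]

    iteration = 0
    while True:
        grid = [{}]
        for k in names:
            grid = [
                {**pt, k: centre[k] * pitches[k] ** step}
                for pt in grid
                for step in (-1, 0, 1)
            ]
        best_point, (best_cost, best_errors) = None, (np.inf, {})
        centre_cost = None
        for pt in grid:
            cost, errors = evaluate(pt)
            if all(pt[k] == centre[k] for k in names):
                centre_cost = cost
            if np.isfinite(cost) and cost < best_cost:
                best_point, (best_cost, best_errors) = pt, (cost, errors)
        if best_point is None:
            raise RuntimeError("cost is non-finite at every grid point")
        iteration += 1
        trace_rows.append(
            {
                **{f"centre_{k}": centre[k] for k in names},
                **{f"pitch_{k}": pitches[k] for k in names},
                "cost": best_cost,
            }
        )
        at_centre = centre_cost is not None and best_cost >= centre_cost
        if at_centre:
            if all(p <= stop_pitch for p in pitches.values()):
                break
            pitches = {k: max(p**shrink, 1.0 + 1e-12) for k, p in pitches.items()}
        else:
            centre = best_point
        if len(cache) >= max_evaluations:
            break

    final_cost, final_errors = evaluate(centre)
    return FitResult(
        params=dict(centre),
        errors=dict(final_errors),
        cost=final_cost,
        trace=pd.DataFrame(trace_rows),
        n_evaluations=len(cache),
    )


def _make_cost_fn(spec: FitSpec) -> Callable[[dict[str, float]], tuple[float, dict]]:
    keys = [(c.height, c.stimulus_speed) for c in spec.conditions]
    observed = spec.observed.set_index(["height_mm", "stimulus_speed_mm_s"])
    missing = [k for k in keys if k not in observed.index]
    if missing:
        raise ValueError(f"observed table lacks conditions {missing}")
    observed = observed.loc[keys].sort_index()

    def cost_fn(point: dict[str, float]) -> tuple[float, dict[str, float]]:
        params = spec.base_params.replace(**point)
        predicted = run_grid(
            params,
            spec.conditions,
            n_fish=spec.n_fish,
            seed=spec.seed,  # common random numbers across evaluations
            n_steps=spec.n_steps,
            warmup_steps=spec.warmup_steps,
            profile=spec.profile,
        ).set_index(["height_mm", "stimulus_speed_mm_s"]).sort_index()
        errors = {}
        for outcome in spec.outcomes:
            col = OUTCOME_COLUMNS[outcome]
            errors[outcome] = relative_prediction_error(
                observed[col].to_numpy(), predicted[col].to_numpy()
            )
        return combined_cost(errors), errors

    return cost_fn


def fit_model(
    spec: FitSpec,
    shrink: float = 0.5,
    stop_pitch: float = 1.05,
    max_evaluations: int = 2000,
) -> FitResult:
    """Fit the free parameters of ``spec`` by iterative grid search."""
    center = {k: c for k, (c, _) in spec.free.items()}
    pitch = {k: p for k, (_, p) in spec.free.items()}
    return grid_search(
        center,
        _make_cost_fn(spec),
        pitch=pitch,
        shrink=shrink,
        stop_pitch=stop_pitch,
        max_evaluations=max_evaluations,
    )
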