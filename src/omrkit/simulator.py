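"""Agent-based simulation of free-swimming sessions and condition grids.

Each simulated fish runs the discrete-time controller in closed loop: its
swim speed feeds back into the optic flow ``(s - v) / h`` it will sense 220 ms
later.  A session is 30 s (3000 steps at 10 ms) with the first 10 s treated
as warm-up and excluded from all summaries, giving the controller time to
reach a statistical steady state.  Thirty fish per condition are simulated
by default, each with an independent random stream derived from the master
seed, so grids are reproducible and embarrassingly parallel.

The per-condition summaries (mean swim speed, OMR ratio, bout rate, mean
initial bout speed) use the same definitions as the trace-analysis pipeline
so that model predictions and recovered observations are directly joinable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .controller import ModelParams, SpeedProfile, canonical_profile
from .optics import BASELINE_FLOWS, HEIGHTS, stimulus_speed_for_baseline_flow

__all__ = [
    "Condition",
    "SimResult",
    "ConditionSummary",
    "run_session",
    "run_condition",
    "run_grid",
    "condition_grids",
    "REGULATION_SPEEDS",
    "SUMMARY_COLUMNS",
]

#: Stimulus speeds (mm/s) of the OMR-regulation procedure.  The published
#: bounds are 4 mm/s (slowest speed that fully engages the OMR) and 12 mm/s
#: (above which fast bouts start to appear); the grid between them is spaced
#: at 2 mm/s and is configurable.
REGULATION_SPEEDS = (4.0, 6.0, 8.0, 10.0, 12.0)

SUMMARY_COLUMNS = [
    "procedure",
    "height_mm",
    "stimulus_speed_mm_s",
    "baseline_flow_rad_s",
    "swim_speed_mm_s",
    "omr_ratio",
    "bout_rate_hz",
    "bout_initial_speed_mm_s",
]


@dataclass(frozen=True)
class Condition:
    """One experimental cell: height, stimulus speed, procedure, direction."""

    height: float
    stimulus_speed: float
    procedure: str = "omr_regulation"
    direction: str = "forward"

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValueError("height must be positive")
        if self.procedure not in ("omr_regulation", "baseline_flow"):
            raise ValueError(f"unknown procedure {self.procedure!r}")
        if self.direction not in ("forward", "backward"):
            raise ValueError(f"unknown direction {self.direction!r}")

    @property
    def baseline_flow(self) -> float:
        return self.stimulus_speed / self.height


@dataclass
class SimResult:
    """Per-fish traces and events from one simulated session."""

    condition: Condition
    seed: int
    dt: float
    warmup_steps: int
    v: np.ndarray
    omega: np.ndarray
    Y: np.ndarray
    M: np.ndarray
    p: np.ndarray
    onsets: np.ndarray  # step indices
    magnitudes: np.ndarray

    @property
    def analyzed_slice(self) -> slice:
        return slice(self.warmup_steps, None)

    def mean_swim_speed(self) -> float:
        return float(self.v[self.analyzed_slice].mean())

    def bout_rate(self) -> float:
        n = np.sum(self.onsets >= self.warmup_steps)
        duration = (len(self.v) - self.warmup_steps) * self.dt
        return float(n / duration)

    def summary(self) -> "ConditionSummary":
        speed = self.mean_swim_speed()
        s = self.condition.stimulus_speed
        return ConditionSummary(
            condition=self.condition,
            n_fish=1,
            swim_speed=speed,
            omr_ratio=speed / s if s > 0 else np.nan,
            bout_rate=self.bout_rate(),
            bout_initial_speed=_mean_initial_speed(
                self.v, [self.onsets], self.warmup_steps
            ),
        )


@dataclass
class ConditionSummary:
    """Aggregated behavior of one condition's simulated fish."""

    condition: Condition
    n_fish: int
    swim_speed: float
    omr_ratio: float
    bout_rate: float
    bout_initial_speed: float

    def as_row(self) -> dict:
        c = self.condition
        return {
            "procedure": c.procedure,
            "height_mm": c.height,
            "stimulus_speed_mm_s": c.stimulus_speed,
            "baseline_flow_rad_s": c.baseline_flow,
            "swim_speed_mm_s": self.swim_speed,
            "omr_ratio": self.omr_ratio,
            "bout_rate_hz": self.bout_rate,
            "bout_initial_speed_mm_s": self.bout_initial_speed,
        }


def _fish_uniforms(seed: int, fish_index: int, n_steps: int) -> np.ndarray:
    """Independent per-fish uniform stream (one draw per step)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, fish_index]))
    return rng.random(n_steps)


def _simulate(
    params: ModelParams,
    condition: Condition,
    uniforms: np.ndarray,
    profile: SpeedProfile,
    record: bool = False,
):
    """Vectorized closed-loop simulation; `uniforms` is (n_steps, n_fish).

    Returns (v, onsets_per_fish, magnitudes_per_fish[, traces]).  The step
    order matches :func:`omrkit.controller.controller_step` exactly: both
    paths consume one uniform per fish per step.
    """
    n_steps, n_fish = uniforms.shape
    s, h = condition.stimulus_speed, condition.height
    dt = params.dt
    g = profile.g
    L = len(g)
    delay = params.delay_steps
    refr = params.refractory_steps
    pass_through = params.tau_f is None
    single = params.variant == "single"

    omega = np.empty((n_steps + delay, n_fish))
    omega[:delay] = s / h  # fish at rest in the moving stimulus before t = 0

    v = np.zeros(n_fish)
    Y = np.zeros(n_fish)
    M = np.zeros(n_fish)
    last = np.full(n_fish, -(10**9), dtype=np.int64)
    mag = np.zeros(n_fish)

    v_series = np.empty((n_steps, n_fish))
    if record:
        Y_series = np.empty((n_steps, n_fish))
        M_series = np.empty((n_steps, n_fish))
        p_series = np.empty((n_steps, n_fish))
    onsets: list[list[int]] = [[] for _ in range(n_fish)]
    mags: list[list[float]] = [[] for _ in range(n_fish)]

    for t in range(n_steps):
        omega[t + delay] = (s - v) / h
        delayed = omega[t]
        y_f = np.maximum(delayed, 0.0)
        y_b = np.maximum(-delayed, 0.0)
        u = params.k_f * y_f - params.k_b * y_b
        if pass_through:
            Y = u
        else:
            Y = Y + dt * (u - Y / params.tau_f)
        # motor signal: speed of the bout active before any new onset
        off = t - last
        active = (off >= 0) & (off < L)
        motor = np.where(active, mag * g[np.clip(off, 0, L - 1)], 0.0)
        M = M + dt * (motor - M / params.tau_m)
        drive = Y if single else y_f
        p = np.clip(dt * (params.k_r * drive - params.k_m * M), 0.0, 1.0)
        fire = (uniforms[t] < p) & (t - last >= refr)
        if np.any(fire):
            mag = np.where(fire, params.k_i * Y, mag)
            last = np.where(fire, t, last)
            for i in np.nonzero(fire)[0]:
                onsets[i].append(t)
                mags[i].append(mag[i])
        off = t - last
        active = (off >= 0) & (off < L)
        v = np.maximum(np.where(active, mag * g[np.clip(off, 0, L - 1)], 0.0), 0.0)
        v_series[t] = v
        if record:
            Y_series[t] = Y
            M_series[t] = M
            p_series[t] = p
        if not np.all(np.isfinite(Y)):
            raise FloatingPointError("non-finite controller state (parameter pathology)")

    onset_arrays = [np.array(o, dtype=np.int64) for o in onsets]
    mag_arrays = [np.array(m) for m in mags]
    if record:
        traces = {
            "omega": omega[delay:],
            "Y": Y_series,
            "M": M_series,
            "p": p_series,
        }
        return v_series, onset_arrays, mag_arrays, traces
    return v_series, onset_arrays, mag_arrays


def _mean_initial_speed(
    v_series: np.ndarray, onsets: Sequence[np.ndarray], warmup: int, n_init: int = 10
) -> float:
    """Mean over bouts of the mean swim speed over the first 100 ms.

    Averages per fish first, then across fish with at least one bout, the
    same weighting the experimental sessions receive.
    """
    per_fish = []
    n_steps = v_series.shape[0] if v_series.ndim == 2 else len(v_series)
    for i, fish_onsets in enumerate(onsets):
        vals = []
        for t0 in fish_onsets:
            if t0 < warmup or t0 + n_init > n_steps:
                continue
            column = v_series[:, i] if v_series.ndim == 2 else v_series
            vals.append(column[t0 : t0 + n_init].mean())
        if vals:
            per_fish.append(np.mean(vals))
    return float(np.mean(per_fish)) if per_fish else np.nan


def run_session(
    params: ModelParams,
    condition: Condition,
    seed: int,
    n_steps: int = 3000,
    warmup_steps: int = 1000,
    profile: Optional[SpeedProfile] = None,
) -> SimResult:
    """Simulate one fish for one session and return its full traces."""
    if profile is None:
        profile = canonical_profile(dt=params.dt)
    uniforms = _fish_uniforms(seed, 0, n_steps)[:, None]
    v, onsets, mags, traces = _simulate(
        params, condition, uniforms, profile, record=True
    )
    return SimResult(
        condition=condition,
        seed=seed,
        dt=params.dt,
        warmup_steps=warmup_steps,
        v=v[:, 0],
        omega=traces["omega"][:, 0],
        Y=traces["Y"][:, 0],
        M=traces["M"][:, 0],
        p=traces["p"][:, 0],
        onsets=onsets[0],
        magnitudes=mags[0],
    )


def run_condition(
    params: ModelParams,
    condition: Condition,
    n_fish: int = 30,
    seed: int = 0,
    n_steps: int = 3000,
    warmup_steps: int = 1000,
    profile: Optional[SpeedProfile] = None,
) -> ConditionSummary:
    """Simulate ``n_fish`` independent fish and aggregate the analyzed 20 s."""
    if n_fish < 1:
        raise ValueError("n_fish must be at least 1")
    if profile is None:
        profile = canonical_profile(dt=params.dt)
    uniforms = np.column_stack(
        [_fish_uniforms(seed, i, n_steps) for i in range(n_fish)]
    )
    v, onsets, mags = _simulate(params, condition, uniforms, profile)
    analyzed = v[warmup_steps:]
    duration = analyzed.shape[0] * params.dt
    mean_speed = float(analyzed.mean())
    rates = [np.sum(o >= warmup_steps) / duration for o in onsets]
    s = condition.stimulus_speed
    return ConditionSummary(
        condition=condition,
        n_fish=n_fish,
        swim_speed=mean_speed,
        omr_ratio=mean_speed / s if s > 0 else np.nan,
        bout_rate=float(np.mean(rates)),
        bout_initial_speed=_mean_initial_speed(v, onsets, warmup_steps),
    )


def condition_grids(
    procedure: str,
    heights: Sequence[float] = HEIGHTS,
    regulation_speeds: Sequence[float] = REGULATION_SPEEDS,
    baseline_flows: Sequence[float] = BASELINE_FLOWS,
) -> list[Condition]:
    """Full condition grid for one procedure.

    ``baseline_flow``: 3 heights x 5 flows with stimulus speed ``flow * h``
    (15 conditions); ``omr_regulation``: 3 heights x the regulation speed set.
    """
    conditions = []
    if procedure == "baseline_flow":
        for h in heights:
            for f in baseline_flows:
                conditions.append(
                    Condition(
                        height=h,
                        stimulus_speed=stimulus_speed_for_baseline_flow(f, h),
                        procedure="baseline_flow",
                    )
                )
    elif procedure == "omr_regulation":
        for h in heights:
            for s in regulation_speeds:
                conditions.append(
                    Condition(height=h, stimulus_speed=s, procedure="omr_regulation")
                )
    else:
        raise ValueError(f"unknown procedure {procedure!r}")
    return conditions


def run_grid(
    params: ModelParams,
    conditions: Iterable[Condition],
    n_fish: int = 30,
    seed: int = 0,
    n_steps: int = 3000,
    warmup_steps: int = 1000,
    profile: Optional[SpeedProfile] = None,
) -> pd.DataFrame:
    """Simulate every condition; returns a tidy summary table.

    Each condition draws its fish streams from ``[seed, condition_index]`` so
    the table is reproducible regardless of iteration order or parallelism.
    """
    if profile is None:
        profile = canonical_profile(dt=params.dt)
    rows = []
    for ci, cond in enumerate(conditions):
        cond_seed = int(
            np.random.SeedSequence([seed, ci]).generate_state(1, np.uint32)[0]
        )
        summary = run_condition(
            params,
            cond,
            n_fish=n_fish,
            seed=cond_seed,
            n_steps=n_steps,
            warmup_steps=warmup_steps,
            profile=profile,
        )
        rows.append(summary.as_row())
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
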