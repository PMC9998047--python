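"""Feedback-control models of bout initiation and bout speed.

The fish is modelled as a discrete-time (dt = 10 ms) closed-loop controller:

* the visual system reports the optic flow with a fixed 220 ms delay,
  rectified into non-negative forward (``y_f``) and backward (``y_b``)
  components;
* a leaky integrator with time constant ``tau_f`` accumulates a linear
  combination ``k_f * y_f - k_b * y_b`` of the two, giving the intensity
  signal ``Y`` (a "no integration" mode passes the input straight through);
* bout initiation is an inhomogeneous Bernoulli/Poisson process: each step a
  bout starts with probability ``p = clip(dt * (k_r * drive - k_m * M), 0, 1)``
  subject to a 250 ms refractory period, where ``drive`` is ``Y`` for the
  single-factor model and the undelayed-by-further-processing forward flow
  ``y_f`` for the dual-factor models, and ``M`` is a leaky integral (time
  constant ``tau_m``) of the motor output providing motor inhibition;
* bout speed is ballistic: a bout initiated at step ``t0`` fixes a magnitude
  ``k_i * Y[t0]`` and thereafter the swim speed follows the fixed relative
  speed profile ``g`` scaled by that magnitude, a new bout replacing (not
  superposing on) the previous one.

Model variants: ``single`` (one control signal for both initiation and
intensity, no motor inhibition), and dual-factor ``A`` (k_f = k_b = 1),
``B`` (k_f, k_b free, k_i = 1) and ``C`` (k_b = 0, k_i = 1, forward flow only).
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ModelParams",
    "ControllerState",
    "SpeedProfile",
    "canonical_profile",
    "leaky_integrator_step",
    "sensed_flow",
    "flow_combiner",
    "initiation_probability",
    "maybe_initiate",
    "swim_speed",
    "motor_integrator_step",
    "preset",
    "load_table",
]

VARIANTS = ("single", "A", "B", "C")


@dataclass(frozen=True)
class ModelParams:
    """Parameter set for one controller variant.

    ``tau_f = None`` selects the pass-through ("no integration") flow
    processor.  ``sensory_delay``, ``refractory`` and ``dt`` are part of the
    model definition and fixed in advance rather than fitted.
    """

    variant: str
    k_r: float
    k_i: float = 1.0
    k_m: float = 0.0
    tau_m: float = 1.0
    k_f: float = 1.0
    k_b: float = 0.0
    tau_f: Optional[float] = None
    sensory_delay: float = 0.220
    refractory: float = 0.250
    dt: float = 0.010

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        for name in ("k_r", "k_i", "k_m", "tau_m", "k_f", "k_b"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.tau_f is not None and self.dt >= self.tau_f:
            raise ValueError("unstable discretization: dt >= tau_f")
        if self.k_m > 0 and self.dt >= self.tau_m:
            raise ValueError("unstable discretization: dt >= tau_m")
        if self.variant == "single":
            if self.k_m != 0:
                raise ValueError("single-factor model has no motor inhibition")
            # the single control signal integrates the overall sensed flow
            object.__setattr__(self, "k_f", 1.0)
            object.__setattr__(self, "k_b", 1.0)
        if self.variant == "A" and not (self.k_f == 1.0 and self.k_b == 1.0):
            raise ValueError("variant A fixes k_f = k_b = 1")
        if self.variant in ("B", "C") and self.k_i != 1.0:
            raise ValueError(f"variant {self.variant} fixes k_i = 1")
        if self.variant == "C" and self.k_b != 0.0:
            raise ValueError("variant C fixes k_b = 0")
        steps = self.sensory_delay / self.dt
        if abs(steps - round(steps)) > 1e-9:
            raise ValueError("sensory_delay must be an integer multiple of dt")

    @property
    def delay_steps(self) -> int:
        return round(self.sensory_delay / self.dt)

    @property
    def refractory_steps(self) -> int:
        return round(self.refractory / self.dt)

    def replace(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelParams":
        return cls(**json.loads(text))


@dataclass
class SpeedProfile:
    """Fixed relative bout-speed profile ``g`` sampled at ``dt`` offsets.

    ``g`` is non-negative, has a single global maximum, and averages exactly 1
    over the first second: speeds are expressed relative to the mean bout
    speed.
    """

    g: np.ndarray
    dt: float = 0.010

    def __post_init__(self) -> None:
        self.g = np.asarray(self.g, dtype=float)
        if np.any(self.g < 0):
            raise ValueError("profile must be non-negative")
        n_1s = round(1.0 / self.dt)
        if len(self.g) < n_1s:
            raise ValueError("profile support must be at least 1 s")
        mean = self.g[:n_1s].mean()
        if abs(mean - 1.0) > 1e-9:
            raise ValueError(f"profile mean over first 1 s is {mean}, not 1")
        if np.sum(self.g == self.g.max()) != 1:
            raise ValueError("profile must have a single global maximum")

    def __len__(self) -> int:
        return len(self.g)

    @property
    def peak(self) -> float:
        return float(self.g.max())

    @property
    def peak_time(self) -> float:
        return float(np.argmax(self.g) * self.dt)


def canonical_profile(
    dt: float = 0.010,
    support: float = 1.0,
    peak: float = 6.75,
    t_peak: float = 0.080,
    t_cross: float = 0.200,
) -> SpeedProfile:
    """Smooth profile satisfying the empirical bout-shape landmarks.

    The curve starts at 0, rises along a quarter-sine to its single peak of
    ``peak`` times the mean speed at ``t_peak``, decays exponentially so that
    it crosses 1.0 (the mean) exactly at ``t_cross``, and continues with a
    slower exponential tail (the post-bout coasting phase).  The quarter-sine
    rise puts the maximum acceleration at bout onset, matching the convention
    of marking onsets at acceleration maxima.  The tail rate is solved so
    that, after a final renormalization, the mean over the first second is
    exactly 1 while the peak value is exactly ``peak``.
    """
    if support < 1.0:
        raise ValueError("support must be at least 1 s")
    n = round(support / dt)
    n_1s = round(1.0 / dt)
    t = np.arange(n) * dt

    # Shape with the peak scaled to 1; everything below is scale-free.
    lam1 = np.log(peak) / (t_cross - t_peak)  # value 1/peak at t_cross
    cross_val = 1.0 / peak

    def shape(lam2: float) -> np.ndarray:
        g = np.empty(n)
        rise = t <= t_peak
        g[rise] = np.sin(0.5 * np.pi * t[rise] / t_peak)
        mid = (t > t_peak) & (t <= t_cross)
        g[mid] = np.exp(-lam1 * (t[mid] - t_peak))
        tail = t > t_cross
        g[tail] = cross_val * np.exp(-lam2 * (t[tail] - t_cross))
        return g

    # Mean over the first 1 s must equal 1/peak so that dividing by it yields
    # unit mean with the peak landing exactly on `peak`.
    def mean_residual(lam2: float) -> float:
        return shape(lam2)[:n_1s].mean() - cross_val

    lam2 = brentq(mean_residual, 1e-6, 200.0, xtol=1e-12)
    g = shape(lam2)
    g /= g[:n_1s].mean()
    return SpeedProfile(g=g, dt=dt)


def leaky_integrator_step(
    prev: float, value: float, tau: Optional[float], dt: float
) -> float:
    """One Euler step of ``dX/dt = u - X / tau``; ``tau=None`` passes through.

    For constant input ``u`` the output relaxes exponentially toward
    ``u * tau`` with time constant ``tau``.
    """
    if tau is None:
        return value
    if dt >= tau:
        raise ValueError("unstable discretization: dt >= tau")
    return prev + dt * (value - prev / tau)


def motor_integrator_step(m_prev: float, motor: float, params: ModelParams) -> float:
    """Leaky integration of the motor signal (inhibition memory ``M``)."""
    return leaky_integrator_step(m_prev, motor, params.tau_m, params.dt)


def flow_combiner(y_f: float, y_b: float, params: ModelParams) -> float:
    """Input to the flow integrator: ``k_f * y_f - k_b * y_b``.

    The single-factor model uses the overall sensed flow ``y_f - y_b``
    (``k_f = k_b = 1`` defaults); variant C reduces to ``k_f * y_f``.
    """
    return params.k_f * y_f - params.k_b * y_b


def initiation_probability(drive: float, M: float, params: ModelParams) -> float:
    """Per-step initiation probability ``clip(dt*(k_r*drive - k_m*M), 0, 1)``.

    ``drive`` is the intensity signal ``Y`` for the single-factor model and
    the sensed forward flow ``y_f`` for the dual-factor models.
    """
    p = params.dt * (params.k_r * drive - params.k_m * M)
    return min(max(p, 0.0), 1.0)


@dataclass
class ControllerState:
    """Mutable state of one simulated controller.

    ``flow_buffer`` holds the last ``delay_steps`` optic-flow samples and
    implements the sensory delay.  It is pre-filled with the condition's
    baseline flow ``s/h``: the fish has been resting in the moving stimulus
    before time zero.
    """

    params: ModelParams
    profile: SpeedProfile
    baseline_flow: float = 0.0
    flow_buffer: deque = field(init=False)
    Y: float = 0.0
    M: float = 0.0
    v: float = 0.0
    last_onset_step: int = -(10**9)
    last_magnitude: float = 0.0
    y_f: float = 0.0
    y_b: float = 0.0
    p: float = 0.0

    def __post_init__(self) -> None:
        d = self.params.delay_steps
        self.flow_buffer = deque([self.baseline_flow] * d, maxlen=d)


def sensed_flow(state: ControllerState, current_flow: float) -> tuple[float, float]:
    """Push the current optic flow; return delayed rectified components.

    Returns ``(y_f, y_b)`` where ``y_f = max(w, 0)`` and ``y_b = max(-w, 0)``
    for the flow ``w`` sensed now, i.e. the one that occurred ``delay_steps``
    steps ago.
    """
    delayed = state.flow_buffer[0]
    state.flow_buffer.append(current_flow)
    y_f = max(delayed, 0.0)
    y_b = max(-delayed, 0.0)
    state.y_f, state.y_b = y_f, y_b
    return y_f, y_b


def maybe_initiate(state: ControllerState, p: float, step: int, rng) -> int:
    """Draw the Bernoulli initiation event for this step (0 or 1).

    The event is suppressed if fewer than ``refractory_steps`` steps have
    passed since the previous onset, so consecutive onsets are separated by
    at least the 250 ms refractory period; under constant ``p`` the long-run
    rate is ``1/(t_ref + dt/p - dt)``, approximated by the renewal formula
    ``1/(t_ref + dt/p)`` when ``p`` is small.  On success the onset step and
    the scaled-impulse magnitude ``k_i * Y`` are latched.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if step - state.last_onset_step < state.params.refractory_steps:
        rng.random()  # keep the stream aligned with the unconstrained path
        return 0
    if rng.random() < p:
        state.last_onset_step = step
        state.last_magnitude = state.params.k_i * state.Y
        return 1
    return 0


def swim_speed(step: int, state: ControllerState) -> float:
    """Speed of the most recent bout at this step (replacement rule).

    ``max(magnitude * g[step - t0], 0)``; zero beyond the profile support or
    before any bout.  A new bout replaces the previous one outright.
    """
    offset = step - state.last_onset_step
    if offset < 0 or offset >= len(state.profile):
        return 0.0
    return max(state.last_magnitude * state.profile.g[offset], 0.0)


def controller_step(
    state: ControllerState, current_flow: float, step: int, rng
) -> float:
    """Advance the controller one timestep; returns the new swim speed.

    Order of operations within a step: sense (delayed) flow, update ``Y``,
    integrate the motor signal of the ongoing bout into ``M``, compute the
    initiation probability, draw the initiation event, then emit the swim
    speed (so an onset at this step contributes ``g[0]`` immediately).
    """
    params = state.params
    y_f, y_b = sensed_flow(state, current_flow)
    u = flow_combiner(y_f, y_b, params)
    state.Y = leaky_integrator_step(state.Y, u, params.tau_f, params.dt)
    motor = swim_speed(step, state)  # speed of the bout active before any new onset
    state.M = motor_integrator_step(state.M, motor, params)
    drive = state.Y if params.variant == "single" else y_f
    state.p = initiation_probability(drive, state.M, params)
    maybe_initiate(state, state.p, step, rng)
    state.v = swim_speed(step, state)
    return state.v


_PRESETS = {
    # (table file, key)
    "single_speed": ("single_factor.json", "swim_speed_fit"),
    "single_bout": ("single_factor.json", "bout_fit"),
    "dual_A": ("dual_factor.json", "A"),
    "dual_B": ("dual_factor.json", "B"),
    "dual_C": ("dual_factor.json", "C"),
}


def load_table(name: str) -> dict:
    """Load a packaged parameter table (raw JSON dict)."""
    text = resources.files("omrkit.data").joinpath(name).read_text()
    return json.loads(text)


def preset(name: str) -> ModelParams:
    """Published fitted parameter set by name.

    Names: ``single_speed`` and ``single_bout`` (single-factor model fitted to
    mean swim speed or to bout measures), ``dual_A`` / ``dual_B`` / ``dual_C``
    (dual-factor variants; C is the final model).
    """
    try:
        fname, key = _PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; options: {sorted(_PRESETS)}")
    return ModelParams(**load_table(fname)[key])
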