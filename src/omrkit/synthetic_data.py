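"""Experiment-like synthetic position recordings with known ground truth.

The generator emulates the free-swimming assay: 300 mm channels sampled at
100 frames/s, two 60 s trial traverses per session with the stimulus moving
first forward then backward, intermittent bout swimming following the fixed
relative speed profile, Gaussian position measurement noise and randomly
dropped frames (gaps in the emitted sample stream).

Two generator modes:

* ``script_driven`` — bout onsets follow a refractory-shifted exponential
  renewal process and bout magnitudes a truncated normal: the minimal
  structure the analysis pipeline assumes (renewal bout process, fixed
  relative profile, positive intensities).  Ground truth is exact.
* ``model_driven`` — bout trains come from closed-loop simulation of a
  controller (:mod:`omrkit.simulator`), so pipeline recoveries can be checked
  against the model's own statistics.

Default noise sd (0.05 mm) and frame-drop probability (0.01) are stated
conventions for a well-behaved tracker, not measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .controller import ModelParams, SpeedProfile, canonical_profile
from .simulator import Condition, _fish_uniforms, _simulate

__all__ = [
    "SynthSpec",
    "GroundTruth",
    "render_bout_train",
    "generate_session",
    "generate_experiment",
    "TRACE_COLUMNS",
]

TRACE_COLUMNS = [
    "fish_id",
    "traverse_id",
    "procedure",
    "height_mm",
    "stimulus_speed_mm_s",
    "direction",
    "t_s",
    "x_mm",
]

TRUTH_COLUMNS = [
    "fish_id",
    "traverse_id",
    "height_mm",
    "stimulus_speed_mm_s",
    "n_bouts",
    "mean_speed_mm_s",
    "bout_rate_hz",
    "displacement_mm",
    "duration_s",
    "onset_times",
    "magnitudes",
]


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for a synthetic recording campaign."""

    conditions: tuple[Condition, ...]
    mode: str = "script_driven"
    n_fish: int = 8
    seed: int = 0
    noise_sd: float = 0.05  # mm
    drop_probability: float = 0.01
    channel_length: float = 300.0
    traverse_duration: float = 60.0
    dt: float = 0.010
    start_offset: float = 10.0  # mm from the upstream channel end
    bout_rate: float = 1.0  # Hz, script-driven renewal rate
    refractory: float = 0.250
    magnitude_mean: float = 8.0  # mean bout speed, mm/s
    magnitude_sd: float = 3.0
    magnitude_min: float = 2.0
    contamination_rate: float = 0.0  # probability a bout swims against the flow
    params: Optional[ModelParams] = None  # model_driven controller

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.drop_probability <= 1:
            raise ValueError("drop_probability must lie in [0, 1]")
        if not 0 <= self.contamination_rate <= 1:
            raise ValueError("contamination_rate must lie in [0, 1]")
        if self.mode not in ("script_driven", "model_driven"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "model_driven" and self.params is None:
            raise ValueError("model_driven mode requires controller params")


@dataclass
class GroundTruth:
    """What actually happened in one rendered traverse."""

    onset_times: np.ndarray  # s
    magnitudes: np.ndarray
    signs: np.ndarray  # +1 with stimulus, -1 spontaneous reversal
    displacement: float  # mm, stimulus frame, before clipping/noise
    duration: float  # s
    mean_speed: float  # mm/s
    bout_rate: float  # Hz
    #: first time the fish comes within the 50 mm end margin (inf if never);
    #: behavior beyond this point is pruned by the analysis pipeline, and
    #: beyond the wall itself it is unobservable (the position clips), so
    #: recovery checks compare against the windowed quantities below.
    margin_time: float = np.inf
    speed_to_margin: float = np.nan  # mm/s over [0, margin_time]
    rate_to_margin: float = np.nan  # Hz over [0, margin_time]


def render_bout_train(
    onset_steps: Sequence[int],
    magnitudes: Sequence[float],
    n_steps: int,
    profile: SpeedProfile,
    signs: Optional[Sequence[int]] = None,
) -> np.ndarray:
    """Speed series for a bout train under the replacement rule.

    At each step the speed is the profile of the most recent onset scaled by
    its magnitude (signed when ``signs`` mark contaminating reversed bouts);
    zero before the first onset and beyond the profile support.
    """
    v = np.zeros(n_steps)
    g = profile.g
    onset_steps = list(onset_steps)
    for k, t0 in enumerate(onset_steps):
        stop = onset_steps[k + 1] if k + 1 < len(onset_steps) else n_steps
        stop = min(stop, t0 + len(g), n_steps)
        if stop <= t0:
            continue
        sign = signs[k] if signs is not None else 1
        v[t0:stop] = sign * magnitudes[k] * g[: stop - t0]
    return v


def _script_bouts(spec: SynthSpec, n_steps: int, rng: np.random.Generator):
    """Renewal onsets + truncated-normal magnitudes for one traverse."""
    if spec.bout_rate <= 0:
        return np.array([], dtype=int), np.array([]), np.array([], dtype=int)
    mean_interval = 1.0 / spec.bout_rate
    exp_mean = max(mean_interval - spec.refractory, 1e-3)
    times = []
    t = rng.exponential(exp_mean)  # first onset: no preceding refractory
    horizon = n_steps * spec.dt
    while t < horizon:
        times.append(t)
        t += spec.refractory + rng.exponential(exp_mean)
    onsets = np.unique((np.array(times) / spec.dt).round().astype(int))
    onsets = onsets[onsets < n_steps]
    mags = np.empty(len(onsets))
    for i in range(len(onsets)):  # rejection sampling of the truncated normal
        m = -np.inf
        while m < spec.magnitude_min:
            m = rng.normal(spec.magnitude_mean, spec.magnitude_sd)
        mags[i] = m
    signs = np.where(rng.random(len(onsets)) < spec.contamination_rate, -1, 1)
    return onsets, mags, signs


def _model_bouts(
    spec: SynthSpec,
    condition: Condition,
    n_steps: int,
    fish_seed: int,
    profile: SpeedProfile,
):
    """Closed-loop controller bout train for one traverse."""
    uniforms = _fish_uniforms(fish_seed, 0, n_steps)[:, None]
    _, onsets, mags = _simulate(spec.params, condition, uniforms, profile)
    signs = np.ones(len(onsets[0]), dtype=int)
    return onsets[0], mags[0], signs


def generate_session(
    spec: SynthSpec,
    condition: Condition,
    seed: int,
    profile: Optional[SpeedProfile] = None,
) -> tuple[pd.DataFrame, list[GroundTruth]]:
    """Raw samples and ground truth for one fish's two-traverse session.

    Traverse 0 runs with the stimulus moving forward (+x) and the fish
    starting near x = ``start_offset``; traverse 1 reverses both.  Speeds are
    integrated to position, clipped at the channel walls, then Gaussian noise
    is added and frames are dropped (rows omitted).
    """
    if profile is None:
        profile = canonical_profile(dt=spec.dt)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, seed]))
    n_steps = round(spec.traverse_duration / spec.dt)
    frames = []
    truths = []
    for traverse_id, direction in enumerate((1, -1)):
        if spec.mode == "script_driven":
            onsets, mags, signs = _script_bouts(spec, n_steps, rng)
        else:
            fish_seed = int(rng.integers(2**31 - 1))
            onsets, mags, signs = _model_bouts(
                spec, condition, n_steps, fish_seed, profile
            )
        v = render_bout_train(onsets, mags, n_steps, profile, signs)
        t = np.arange(n_steps) * spec.dt
        xs = spec.start_offset + np.concatenate([[0.0], np.cumsum(v[:-1]) * spec.dt])
        displacement = float(xs[-1] - xs[0])
        x = xs if direction == 1 else spec.channel_length - xs
        x = np.clip(x, 0.0, spec.channel_length)
        x_noisy = x + rng.normal(0.0, spec.noise_sd, n_steps)
        keep = rng.random(n_steps) >= spec.drop_probability
        keep[0] = True  # the traverse always has a first sample
        frames.append(
            pd.DataFrame(
                {
                    "fish_id": f"fish{seed}",
                    "traverse_id": traverse_id,
                    "procedure": condition.procedure,
                    "height_mm": condition.height,
                    "stimulus_speed_mm_s": condition.stimulus_speed,
                    "direction": "forward" if direction == 1 else "backward",
                    "t_s": t[keep],
                    "x_mm": x_noisy[keep],
                }
            )
        )
        duration = n_steps * spec.dt
        onset_times = onsets * spec.dt
        margin_hits = np.nonzero(xs >= spec.channel_length - 50.0)[0]
        if len(margin_hits):
            mi = int(margin_hits[0])
            margin_time = float(t[mi]) if mi > 0 else spec.dt
            speed_to_margin = float((xs[mi] - xs[0]) / margin_time)
            rate_to_margin = float(np.sum(onset_times <= margin_time) / margin_time)
        else:
            margin_time = np.inf
            speed_to_margin = displacement / duration
            rate_to_margin = len(onsets) / duration
        truths.append(
            GroundTruth(
                onset_times=onset_times,
                magnitudes=mags,
                signs=signs,
                displacement=displacement,
                duration=duration,
                mean_speed=displacement / duration,
                bout_rate=len(onsets) / duration,
                margin_time=margin_time,
                speed_to_margin=speed_to_margin,
                rate_to_margin=rate_to_margin,
            )
        )
    return pd.concat(frames, ignore_index=True), truths


def generate_experiment(
    spec: SynthSpec, profile: Optional[SpeedProfile] = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full condition grid x n_fish; returns (traces, ground truth) frames.

    Deterministic in the master seed: per-fish streams derive from
    ``[spec.seed, condition_index, fish_index]``.
    """
    trace_frames = []
    truth_rows = []
    for ci, condition in enumerate(spec.conditions):
        for fi in range(spec.n_fish):
            fish_seed = int(
                np.random.SeedSequence([ci, fi]).generate_state(1, np.uint32)[0]
            )
            traces, truths = generate_session(spec, condition, fish_seed, profile)
            traces["fish_id"] = f"c{ci}_f{fi}"
            trace_frames.append(traces)
            for traverse_id, truth in enumerate(truths):
                truth_rows.append(
                    {
                        "fish_id": f"c{ci}_f{fi}",
                        "traverse_id": traverse_id,
                        "height_mm": condition.height,
                        "stimulus_speed_mm_s": condition.stimulus_speed,
                        "n_bouts": len(truth.onset_times),
                        "mean_speed_mm_s": truth.mean_speed,
                        "bout_rate_hz": truth.bout_rate,
                        "displacement_mm": truth.displacement,
                        "duration_s": truth.duration,
                        "onset_times": ";".join(
                            f"{v:.3f}" for v in truth.onset_times
                        ),
                        "magnitudes": ";".join(f"{v:.4f}" for v in truth.magnitudes),
                    }
                )
    traces = pd.concat(trace_frames, ignore_index=True)[TRACE_COLUMNS]
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return traces, truth
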