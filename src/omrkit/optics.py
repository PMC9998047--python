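"""Stimulus geometry and optic-flow computations for a fish above a moving grid.

A larva swimming at height ``h`` (mm) above a grating translating at speed
``s`` (mm/s) while itself swimming at ``v`` (mm/s) experiences a whole-field
translational optic flow of ``(s - v) / h`` rad/s.  The sign convention is
positive ("forward" flow) when the fish is slower than the stimulus.  Because
the flow produced by the fish's own swimming is ``-v/h``, the closed-loop
feedback gain of the free-swimming preparation is ``-1/h``: height alone sets
how strongly a change in motor output feeds back onto the visual input.

The module also contains the Snell's-law correction for the apparent spatial
frequency of the grating: the channel bottom is treated as a flat air/water
interface, so rays from the screen refract once on entering the water below
the fish, compressing the perceived grid period.

All functions are pure and unit-fixed: mm, mm/s, rad/s, cycles/degree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import bisect

__all__ = [
    "optic_flow",
    "feedback_gain",
    "stimulus_speed_for_baseline_flow",
    "baseline_flow_table",
    "minimum_height_ratio",
    "RefractionSetup",
    "perceived_spatial_frequency",
]

#: Channel-midpoint heights (mm) used for the low / medium / high conditions.
HEIGHTS = (8.0, 32.0, 56.0)

#: Baseline optic flows (rad/s) of the constant-flow procedure.
BASELINE_FLOWS = (0.1, 0.2, 0.3, 0.4, 0.5)


def _check_height(height: float) -> None:
    if not height > 0:
        raise ValueError(f"height must be positive, got {height!r}")


def optic_flow(stimulus_speed: float, swim_speed: float, height: float) -> float:
    """Translational optic flow (rad/s) for the given speeds and height.

    Positive when the fish moves slower than the stimulus (forward flow),
    negative when it outruns the stimulus (reverse flow).
    """
    _check_height(height)
    return (stimulus_speed - swim_speed) / height


def feedback_gain(height: float) -> float:
    """Closed-loop feedback gain ``d(omega)/d(v) = -1/h`` (1/mm)."""
    _check_height(height)
    return -1.0 / height


def stimulus_speed_for_baseline_flow(baseline_flow: float, height: float) -> float:
    """Stimulus speed (mm/s) producing ``baseline_flow`` rad/s at rest."""
    _check_height(height)
    if baseline_flow < 0:
        raise ValueError("baseline_flow must be non-negative")
    return baseline_flow * height


def baseline_flow_table(heights=HEIGHTS, flows=BASELINE_FLOWS) -> np.ndarray:
    """Grid of stimulus speeds (mm/s), rows = heights, columns = flows."""
    return np.array(
        [[stimulus_speed_for_baseline_flow(f, h) for f in flows] for h in heights]
    )


def minimum_height_ratio(
    low_center: float = 8.0, high_center: float = 56.0, channel_depth: float = 8.0
) -> float:
    """Smallest possible high/low eye-height ratio given the channel depth.

    The fish may sit anywhere in the water column, so the eye height for a
    condition centred at ``c`` spans ``c +/- channel_depth / 2``.  The minimum
    ratio pairs the lowest possible high-condition height with the highest
    possible low-condition height.
    """
    half = channel_depth / 2.0
    lo = low_center + half
    hi = high_center - half
    if lo <= 0 or hi <= 0:
        raise ValueError("degenerate channel geometry")
    return hi / lo


@dataclass(frozen=True)
class RefractionSetup:
    """Geometry for the perceived-spatial-frequency computation.

    Parameters
    ----------
    nominal_spatial_frequency:
        Spatial frequency (cycles/degree) the grating would subtend with no
        refraction, computed at the eye directly above the grid.
    eye_height:
        Distance (mm) from the eye to the stimulus screen.
    water_depth_below_eye:
        Distance (mm) from the eye down to the air/water interface at the
        channel bottom.  Defaults to 4 mm (fish at mid-depth of the 8 mm
        channel); the experiments fix the channel, not the fish's depth.
    refractive_index:
        Index of the water relative to air (about 1.33).
    """

    nominal_spatial_frequency: float
    eye_height: float
    water_depth_below_eye: float = 4.0
    refractive_index: float = 1.33

    def __post_init__(self) -> None:
        if self.nominal_spatial_frequency <= 0:
            raise ValueError("nominal_spatial_frequency must be positive")
        if not 0 < self.water_depth_below_eye <= self.eye_height:
            raise ValueError("require 0 < water_depth_below_eye <= eye_height")
        if self.refractive_index < 1:
            raise ValueError("refractive_index must be >= 1")


def perceived_spatial_frequency(setup: RefractionSetup) -> float:
    """Apparent spatial frequency (cycles/degree) after refraction.

    One grid period centred directly below the eye extends a half-period to
    either side on the screen.  Without refraction the half-period subtends
    ``theta_nom / 2`` at the eye where ``theta_nom = 1 / f_nom`` degrees.  With
    the channel bottom acting as an air/water interface, a ray from the edge
    of the half-period travels through ``eye_height - water_depth`` of air at
    angle ``theta_a`` and ``water_depth`` of water at angle ``theta_w``, with
    ``sin(theta_a) = n * sin(theta_w)``.  The perceived frequency is
    ``1 / (2 * theta_w)`` with ``theta_w`` in degrees.
    """
    f = setup.nominal_spatial_frequency
    n = setup.refractive_index
    h = setup.eye_height
    d = setup.water_depth_below_eye

    theta_nom = math.radians(1.0 / f)  # full period angle, rad
    half_period = h * math.tan(theta_nom / 2.0)

    if n == 1.0:
        return f

    air = h - d

    def residual(theta_w: float) -> float:
        theta_a = math.asin(n * math.sin(theta_w))
        return air * math.tan(theta_a) + d * math.tan(theta_w) - half_period

    # Monotone increasing on (0, critical angle); bracket just inside.
    hi = math.asin(1.0 / n) - 1e-9
    if residual(hi) < 0:
        raise ValueError("no refracted ray reaches the half-period edge")
    theta_w = bisect(residual, 1e-12, hi, xtol=1e-10)
    return 1.0 / (2.0 * math.degrees(theta_w))
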