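"""Behavioral trace analysis: from raw position samples to condition summaries.

The pipeline mirrors the free-swimming assay's processing chain:

1. raw tracked positions (nominally 100 frames/s, with dropped frames) are
   resampled to a uniform 10 ms grid, filling gaps up to 120 ms by linear
   interpolation and marking longer gaps as missing;
2. *OMR trajectories* — maximal gap-free segments of at least 1 s during
   which the fish moves with the stimulus at a mean speed of at least
   0.5 mm/s — are extracted using zero crossings of the difference between a
   fast (alpha = 0.05) and a slow (alpha = 0.002) exponential moving average
   of position, with the time axis reversed when locating segment end points;
   segments are pruned at the first arrival 50 mm before the channel end;
3. swim bouts are detected on a zero-phase (forward-backward) Kaiser-window
   low-pass filtered position series as local maxima of acceleration, and
   validated by requiring active duration > 50 ms and displacement >= 0.5 mm;
4. per-bout measures (initial speed over the first 100 ms, peak speed,
   displacement to the next onset, active duration by the 5 mm/s
   50 ms-window rule) and relative speed profiles (instantaneous speeds from
   unsmoothed first differences, averaged over bouts and normalized to unit
   mean over the first second) are computed.

All positions are transformed into the stimulus-direction frame first, so
forward and backward traverses share one code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import filtfilt, find_peaks, firwin

__all__ = [
    "AnalysisConfig",
    "PositionTrace",
    "OMRTrajectory",
    "BoutEvent",
    "resample_trace",
    "ema",
    "direction_change_times",
    "extract_omr_trajectories",
    "mean_swim_speed",
    "omr_ratio",
    "extract_bouts",
    "bout_measures",
    "relative_speed_profile",
    "quartile_profiles",
    "bout_rate",
    "analyze_experiment",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable constants of the analysis pipeline (times in s, lengths mm)."""

    dt: float = 0.010
    ema_alpha_slow: float = 0.002
    ema_alpha_fast: float = 0.05
    gap_fill_max: float = 0.120
    end_margin: float = 50.0
    min_traverse_omr: float = 2.0
    min_trajectory_duration: float = 1.0
    min_trajectory_speed: float = 0.5
    kaiser_length: int = 20
    kaiser_cutoff: float = 0.02  # fraction of the Nyquist frequency
    kaiser_beta: float = 5.0
    min_bout_duration: float = 0.050
    min_bout_displacement: float = 0.5
    duration_threshold_speed: float = 5.0
    duration_window: float = 0.050
    profile_window: float = 1.0
    accel_prominence: float = 100.0  # mm/s^2; guard against noise peaks
    min_onset_separation: float = 0.150

    def __post_init__(self) -> None:
        if not (0 < self.ema_alpha_slow <= 1 and 0 < self.ema_alpha_fast <= 1):
            raise ValueError("EMA alphas must lie in (0, 1]")
        for name in ("dt", "gap_fill_max", "end_margin", "min_traverse_omr",
                     "profile_window", "duration_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PositionTrace:
    """Uniformly resampled 1-D position series for one traverse of one fish.

    ``x`` is in mm with NaN marking missing data; ``direction`` is +1 when
    the stimulus moves toward increasing x, -1 otherwise.
    """

    t: np.ndarray
    x: np.ndarray
    direction: int
    stimulus_speed: float
    fish_id: str = "f0"
    traverse_id: int = 0
    height: float = np.nan
    channel_length: float = 300.0
    dt: float = 0.010

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        if self.direction not in (1, -1):
            raise ValueError("direction must be +1 or -1")
        if len(self.t) != len(self.x):
            raise ValueError("t and x must have equal length")
        steps = np.diff(self.t)
        if len(steps) and not np.allclose(steps, self.dt, atol=1e-6):
            raise ValueError("trace must be uniformly sampled at dt")

    @property
    def xs(self) -> np.ndarray:
        """Position in the stimulus-direction frame (increasing = with flow)."""
        return self.direction * self.x

    def end_margin_index(self, margin: float) -> int:
        """Index of first arrival within ``margin`` of the channel end.

        Returns ``len(x)`` if the fish never gets there.
        """
        end = self.channel_length if self.direction == 1 else 0.0
        threshold = self.direction * end - margin
        hits = np.nonzero(self.xs >= threshold)[0]
        return int(hits[0]) if len(hits) else len(self.x)


@dataclass
class OMRTrajectory:
    """One gap-free with-stimulus swimming segment."""

    start_index: int
    end_index: int  # exclusive
    start_time: float
    end_time: float
    displacement: float  # mm, in the stimulus frame
    mean_speed: float
    direction: int

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time

    def contains_time(self, t: float) -> bool:
        return self.start_time <= t <= self.end_time


@dataclass
class BoutEvent:
    """One detected swim bout and its kinematic measures."""

    onset_index: int
    onset_time: float
    initial_speed: float
    peak_speed: float
    displacement: float
    active_duration: float
    interval_to_next: float  # NaN for the last bout
    omr_consistent: bool = False
    partial: bool = False  # truncated by the end of the trace
    degenerate: bool = False  # never exceeded the duration threshold speed


def resample_trace(
    t_raw: Sequence[float],
    x_raw: Sequence[float],
    config: AnalysisConfig = AnalysisConfig(),
    **trace_kwargs,
) -> PositionTrace:
    """Resample raw samples onto a uniform 10 ms grid.

    Linear interpolation bridges gaps of up to ``gap_fill_max`` between
    consecutive raw samples; grid points falling inside longer gaps are NaN.
    """
    t_raw = np.asarray(t_raw, dtype=float)
    x_raw = np.asarray(x_raw, dtype=float)
    if len(t_raw) == 0:
        raise ValueError("empty input")
    if np.any(np.diff(t_raw) < 0):
        raise ValueError("raw timestamps must be non-decreasing")
    dt = config.dt
    n = int(np.floor((t_raw[-1] - t_raw[0]) / dt + 1e-9)) + 1
    t = t_raw[0] + np.arange(n) * dt
    x = np.interp(t, t_raw, x_raw)
    # Mark grid points bridged by a raw gap longer than gap_fill_max.
    right = np.searchsorted(t_raw, t, side="left")
    right = np.clip(right, 1, len(t_raw) - 1)
    gap = t_raw[right] - t_raw[right - 1]
    inside = (t > t_raw[right - 1]) & (t < t_raw[right])
    x[inside & (gap > config.gap_fill_max + 1e-9)] = np.nan
    return PositionTrace(t=t, x=x, dt=dt, **trace_kwargs)


def ema(x: Sequence[float], alpha: float) -> np.ndarray:
    """Finite-history exponentially weighted average with adjusted weights.

    ``y_t = sum_k (1-a)^k x_{t-k} / sum_k (1-a)^k`` — the adjusted form, not
    the recursive infinite-history one.  NaNs are carried through without
    contributing weight.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    return (
        pd.Series(np.asarray(x, dtype=float))
        .ewm(alpha=alpha, adjust=True, ignore_na=False)
        .mean()
        .to_numpy()
    )


def _ema_difference(xs: np.ndarray, config: AnalysisConfig) -> np.ndarray:
    return ema(xs, config.ema_alpha_fast) - ema(xs, config.ema_alpha_slow)


def direction_change_times(
    trace: PositionTrace,
    config: AnalysisConfig = AnalysisConfig(),
    reverse_time: bool = False,
) -> np.ndarray:
    """Times at which the swimming direction flips.

    Zero crossings of (fast EMA - slow EMA) of stimulus-frame position.  With
    ``reverse_time`` the series is processed back-to-front, the convention
    for locating trajectory end points.
    """
    xs = trace.xs
    if reverse_time:
        d = _ema_difference(xs[::-1], config)[::-1]
    else:
        d = _ema_difference(xs, config)
    with np.errstate(invalid="ignore"):
        crossings = np.nonzero(d[:-1] * d[1:] < 0)[0]  # strict sign changes
    return trace.t[crossings + 1]


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, stop) runs of True."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.diff(padded.astype(int))
    starts = np.nonzero(edges == 1)[0]
    stops = np.nonzero(edges == -1)[0]
    return list(zip(starts, stops))


def extract_omr_trajectories(
    trace: PositionTrace, config: AnalysisConfig = AnalysisConfig()
) -> list[OMRTrajectory]:
    """All maximal OMR trajectories of one traverse.

    A sample belongs to a candidate segment when the forward-time EMA
    difference marks with-stimulus movement *and* the time-reversed
    computation agrees (the reversed pass trims segment end points).
    Candidates are split at missing samples, pruned at the end margin, and
    must last at least 1 s with mean speed at least 0.5 mm/s.
    """
    stop = trace.end_margin_index(config.end_margin)
    if stop < 2:
        return []
    xs = trace.xs[:stop]
    t = trace.t[:stop]
    d_fwd = _ema_difference(xs, config)
    d_rev = _ema_difference(xs[::-1], config)[::-1]
    moving = (d_fwd > 0) & (d_rev < 0) & np.isfinite(xs)
    out = []
    for start, end in _runs(moving):
        if end - start < 2:
            continue
        duration = t[end - 1] - t[start]
        if duration < config.min_trajectory_duration:
            continue
        displacement = xs[end - 1] - xs[start]
        speed = displacement / duration
        if speed < config.min_trajectory_speed:
            continue
        out.append(
            OMRTrajectory(
                start_index=start,
                end_index=end,
                start_time=float(t[start]),
                end_time=float(t[end - 1]),
                displacement=float(displacement),
                mean_speed=float(speed),
                direction=trace.direction,
            )
        )
    return out


def mean_swim_speed(trajectories: Sequence[OMRTrajectory]) -> float:
    """Total stimulus-frame distance over total duration of the trajectories."""
    if not trajectories:
        raise ValueError("no trajectories")
    total_disp = sum(tr.displacement for tr in trajectories)
    total_dur = sum(tr.duration for tr in trajectories)
    return total_disp / total_dur


def omr_ratio(speed: float, stimulus_speed: float) -> float:
    """Mean swim speed relative to stimulus speed (1 = perfect regulation)."""
    if stimulus_speed <= 0:
        raise ValueError("stimulus_speed must be positive")
    return speed / stimulus_speed


def _interpolate_nan(x: np.ndarray) -> np.ndarray:
    """Fill NaNs by linear interpolation (for filtering only)."""
    x = x.copy()
    bad = ~np.isfinite(x)
    if bad.any():
        good = np.nonzero(~bad)[0]
        if len(good) == 0:
            raise ValueError("trace contains no finite samples")
        x[bad] = np.interp(np.nonzero(bad)[0], good, x[good])
    return x


def instantaneous_speed(trace: PositionTrace) -> np.ndarray:
    """Stimulus-frame speed from unsmoothed forward first differences.

    Element ``i`` is the speed over ``[t_i, t_{i+1})``; the final element
    repeats its neighbour so the series keeps the trace length.
    """
    xs = trace.xs
    v = np.empty_like(xs)
    v[:-1] = np.diff(xs) / trace.dt
    v[-1] = v[-2] if len(v) > 1 else 0.0
    return v


def extract_bouts(
    trace: PositionTrace, config: AnalysisConfig = AnalysisConfig()
) -> list[BoutEvent]:
    """Detect swim bouts and compute their measures.

    Position is zero-phase low-pass filtered (Kaiser window FIR, length 20,
    cutoff 0.02 of Nyquist, beta 5); velocity and acceleration follow by
    differentiation; onsets are local maxima of acceleration exceeding the
    prominence guard and separated by at least ``min_onset_separation``.
    Candidates failing the duration (> 50 ms) or displacement (>= 0.5 mm)
    rules are rejected.
    """
    if len(trace.x) < 3 * config.kaiser_length:
        return []
    xs = _interpolate_nan(trace.xs)
    taps = firwin(
        config.kaiser_length,
        config.kaiser_cutoff,
        window=("kaiser", config.kaiser_beta),
    )
    smoothed = filtfilt(taps, [1.0], xs)
    velocity = np.gradient(smoothed, trace.dt)
    accel = np.gradient(velocity, trace.dt)
    distance = max(1, round(config.min_onset_separation / trace.dt))
    onsets, _ = find_peaks(
        accel, prominence=config.accel_prominence, distance=distance
    )
    candidates = bout_measures(trace, onsets, config)
    return [
        b
        for b in candidates
        if b.active_duration > config.min_bout_duration
        and b.displacement >= config.min_bout_displacement
    ]


def bout_measures(
    trace: PositionTrace,
    onsets: Sequence[int],
    config: AnalysisConfig = AnalysisConfig(),
    trajectories: Optional[Sequence[OMRTrajectory]] = None,
) -> list[BoutEvent]:
    """Kinematic measures for each candidate onset (sorted step indices).

    * initial speed: mean instantaneous speed over the first 100 ms;
    * peak speed: maximum instantaneous speed before the next onset;
    * displacement: onset-to-next-onset (to onset + profile window for the
      last bout, flagged partial if truncated by the trace end);
    * active duration: time until the 50 ms-window mean speed first drops
      below 5 mm/s after having reached it (0 and flagged degenerate if the
      bout never reaches the threshold).
    """
    onsets = np.asarray(onsets, dtype=int)
    v = instantaneous_speed(trace)
    xs = trace.xs
    n = len(xs)
    window = max(1, round(config.duration_window / trace.dt))
    kernel = np.ones(window) / window
    v_windowed = np.convolve(np.nan_to_num(v), kernel, mode="same")
    n_init = round(0.1 / trace.dt)
    n_profile = round(config.profile_window / trace.dt)

    events = []
    for k, t0 in enumerate(onsets):
        nxt = onsets[k + 1] if k + 1 < len(onsets) else min(t0 + n_profile, n - 1)
        partial = k + 1 >= len(onsets) and t0 + n_profile > n - 1
        seg = v[t0 : max(t0 + 1, nxt)]
        seg = seg[np.isfinite(seg)]
        init_seg = v[t0 : t0 + n_init]
        init_seg = init_seg[np.isfinite(init_seg)]
        initial = float(init_seg.mean()) if len(init_seg) else np.nan
        peak = float(seg.max()) if len(seg) else np.nan
        disp = float(xs[nxt] - xs[t0])
        # S-rule active duration on the windowed speed
        w = v_windowed[t0:nxt]
        above = np.nonzero(w >= config.duration_threshold_speed)[0]
        if len(above) == 0:
            active, degenerate = 0.0, True
        else:
            below = np.nonzero(
                (np.arange(len(w)) > above[0])
                & (w < config.duration_threshold_speed)
            )[0]
            stop = below[0] if len(below) else len(w)
            active, degenerate = stop * trace.dt, False
        t_onset = float(trace.t[t0])
        interval = (
            float((onsets[k + 1] - t0) * trace.dt) if k + 1 < len(onsets) else np.nan
        )
        consistent = (
            any(tr.contains_time(t_onset) for tr in trajectories)
            if trajectories is not None
            else False
        )
        events.append(
            BoutEvent(
                onset_index=int(t0),
                onset_time=t_onset,
                initial_speed=initial,
                peak_speed=peak,
                displacement=disp,
                active_duration=float(active),
                interval_to_next=interval,
                omr_consistent=consistent,
                partial=bool(partial),
                degenerate=degenerate,
            )
        )
    return events


def relative_speed_profile(
    traces: Sequence[PositionTrace],
    onsets_per_trace: Sequence[Sequence[int]],
    config: AnalysisConfig = AnalysisConfig(),
    all_onsets_per_trace: Optional[Sequence[Sequence[int]]] = None,
) -> np.ndarray:
    """Mean relative bout-speed profile over offsets 0..1 s.

    Instantaneous speeds (unsmoothed first differences) at each offset are
    averaged over the selected bouts, counting only timesteps that still
    belong to the bout — offsets past the next onset are excluded, otherwise
    the tail of the window would be contaminated by the following bout's
    speeds.  The averaged curve is divided by its own mean, so the result
    has unit mean exactly.  ``all_onsets_per_trace`` supplies the complete
    onset sequence used for that truncation when only a subset of bouts is
    being profiled (e.g. one quartile).
    """
    if all_onsets_per_trace is None:
        all_onsets_per_trace = onsets_per_trace
    n_profile = round(config.profile_window / config.dt)
    rows = []
    for trace, onsets, all_onsets in zip(
        traces, onsets_per_trace, all_onsets_per_trace
    ):
        v = instantaneous_speed(trace)
        all_sorted = np.sort(np.asarray(all_onsets, dtype=int))
        for t0 in onsets:
            if t0 + n_profile > len(v):
                continue
            row = v[t0 : t0 + n_profile].astype(float).copy()
            later = all_sorted[all_sorted > t0]
            if len(later) and later[0] - t0 < n_profile:
                row[later[0] - t0 :] = np.nan
            rows.append(row)
    if not rows:
        raise ValueError("no bouts with a full profile window")
    stacked = np.asarray(rows)
    with np.errstate(invalid="ignore"):
        mean_speed_curve = np.nanmean(stacked, axis=0)
    if np.any(~np.isfinite(mean_speed_curve)):
        raise ValueError("some profile offsets have no surviving bouts")
    return mean_speed_curve / mean_speed_curve.mean()


def quartile_profiles(
    traces: Sequence[PositionTrace],
    bouts_per_trace: Sequence[Sequence[BoutEvent]],
    config: AnalysisConfig = AnalysisConfig(),
) -> list[np.ndarray]:
    """Relative speed profiles for bouts split into initial-speed quartiles."""
    flat = [
        (i, b.onset_index, b.initial_speed)
        for i, bouts in enumerate(bouts_per_trace)
        for b in bouts
        if np.isfinite(b.initial_speed)
    ]
    if len(flat) < 4:
        raise ValueError("need at least 4 bouts for a quartile split")
    speeds = np.array([f[2] for f in flat])
    edges = np.quantile(speeds, [0.25, 0.5, 0.75])
    labels = np.searchsorted(edges, speeds, side="right")
    all_onsets = [
        [b.onset_index for b in bouts] for bouts in bouts_per_trace
    ]
    profiles = []
    for q in range(4):
        selected: dict[int, list[int]] = {}
        for (i, onset, _), lab in zip(flat, labels):
            if lab == q:
                selected.setdefault(i, []).append(onset)
        onsets_per_trace = [selected.get(i, []) for i in range(len(traces))]
        profiles.append(
            relative_speed_profile(
                traces, onsets_per_trace, config, all_onsets_per_trace=all_onsets
            )
        )
    return profiles


def bout_rate(
    bouts: Sequence[BoutEvent], trajectories: Sequence[OMRTrajectory]
) -> float:
    """OMR-consistent bout onsets per second of OMR-trajectory time."""
    total = sum(tr.duration for tr in trajectories)
    if total <= 0:
        raise ValueError("zero total trajectory duration")
    count = sum(
        1
        for b in bouts
        if any(tr.contains_time(b.onset_time) for tr in trajectories)
    )
    return count / total


def _session_summary(
    traces: Sequence[PositionTrace], config: AnalysisConfig
) -> Optional[dict]:
    """Summarize one fish's session (its traverses); None if no valid traverse."""
    traverse_speeds = []
    all_trajectories = []
    all_bouts = []
    for trace in traces:
        trajectories = extract_omr_trajectories(trace, config)
        total = sum(tr.duration for tr in trajectories)
        bouts = extract_bouts(trace, config)
        for b in bouts:
            b.omr_consistent = any(
                tr.contains_time(b.onset_time) for tr in trajectories
            )
        if total >= config.min_traverse_omr:
            traverse_speeds.append(mean_swim_speed(trajectories))
            all_trajectories.extend(trajectories)
            all_bouts.extend(bouts)
    if not traverse_speeds:
        return None
    speed = float(np.mean(traverse_speeds))  # traverses weighted equally
    omr_bouts = [b for b in all_bouts if b.omr_consistent]
    total_dur = sum(tr.duration for tr in all_trajectories)
    initial = (
        float(np.mean([b.initial_speed for b in omr_bouts])) if omr_bouts else np.nan
    )
    return {
        "swim_speed_mm_s": speed,
        "bout_rate_hz": len(omr_bouts) / total_dur,
        "bout_initial_speed_mm_s": initial,
    }


def analyze_experiment(
    frame: pd.DataFrame, config: AnalysisConfig = AnalysisConfig()
) -> pd.DataFrame:
    """Per-condition summary table from a tidy traces frame.

    Expects the traces CSV dialect: columns fish_id, traverse_id, height_mm,
    stimulus_speed_mm_s, direction, t_s, x_mm (dropped frames simply absent).
    Output schema matches the simulator summary table so observed and
    predicted values join directly.
    """
    from .simulator import SUMMARY_COLUMNS  # avoid import cycle at load

    rows = []
    for (height, speed), cond_df in frame.groupby(
        ["height_mm", "stimulus_speed_mm_s"], sort=True
    ):
        session_rows = []
        for fish, fish_df in cond_df.groupby("fish_id", sort=True):
            traces = []
            for trav, tdf in fish_df.groupby("traverse_id", sort=True):
                tdf = tdf.sort_values("t_s")
                direction = 1 if str(tdf["direction"].iloc[0]) == "forward" else -1
                traces.append(
                    resample_trace(
                        tdf["t_s"].to_numpy(),
                        tdf["x_mm"].to_numpy(),
                        config,
                        direction=direction,
                        stimulus_speed=float(speed),
                        fish_id=str(fish),
                        traverse_id=int(trav),
                        height=float(height),
                    )
                )
            summary = _session_summary(traces, config)
            if summary is not None:
                session_rows.append(summary)
        if not session_rows:
            continue
        sessions = pd.DataFrame(session_rows)
        mean_speed = float(sessions["swim_speed_mm_s"].mean())
        rows.append(
            {
                "procedure": str(cond_df["procedure"].iloc[0])
                if "procedure" in cond_df
                else "omr_regulation",
                "height_mm": float(height),
                "stimulus_speed_mm_s": float(speed),
                "baseline_flow_rad_s": float(speed) / float(height),
                "swim_speed_mm_s": mean_speed,
                "omr_ratio": omr_ratio(mean_speed, float(speed)),
                "bout_rate_hz": float(sessions["bout_rate_hz"].mean()),
                "bout_initial_speed_mm_s": float(
                    sessions["bout_initial_speed_mm_s"].mean()
                ),
            }
        )
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
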