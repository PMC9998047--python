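import numpy as np
import pytest

from omrkit.controller import canonical_profile, preset
from omrkit.simulator import Condition
from omrkit.synthetic_data import SynthSpec, generate_session
from omrkit.trace_analysis import AnalysisConfig, resample_trace


@pytest.fixture(scope="session")
def profile():
    return canonical_profile()


@pytest.fixture(scope="session")
def dual_c():
    return preset("dual_C")


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


def trace_from_frame(df, config, stimulus_speed):
    """Build a PositionTrace from one traverse of a synthetic traces frame."""
    direction = 1 if str(df["direction"].iloc[0]) == "forward" else -1
    return resample_trace(
        df["t_s"].to_numpy(),
        df["x_mm"].to_numpy(),
        config,
        direction=direction,
        stimulus_speed=stimulus_speed,
    )


@pytest.fixture(scope="session")
def synthetic_sessions(config):
    """Six script-driven sessions (12 traverses) at the default study
    conditions: 32 mm height, 8 mm/s stimulus, default noise and drop rate.

    Returns a list of (trace, ground_truth) pairs.
    """
    cond = Condition(height=32, stimulus_speed=8)
    spec = SynthSpec(conditions=(cond,), n_fish=1, seed=11)
    pairs = []
    for fish in range(6):
        traces, truths = generate_session(spec, cond, seed=fish)
        for trav in (0, 1):
            df = traces[traces["traverse_id"] == trav]
            pairs.append((trace_from_frame(df, config, 8.0), truths[trav]))
    return pairs
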