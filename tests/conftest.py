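import numpy as np
import pandas as pd
import pytest

from gastrogaze.synthetic import EGGSimConfig, GazeSimConfig
from gastrogaze.types import AOILayout, Fixation, GazeTrial
from gastrogaze.workflows import default_layout


@pytest.fixture
def layout() -> AOILayout:
    return default_layout()


@pytest.fixture
def fast_egg_cfg() -> EGGSimConfig:
    """Low-rate gastric simulation config keeping tests fast; the Hampel
    window must be rescaled to one cycle (200 samples at 10 Hz)."""
    return EGGSimConfig(sampling_rate=10.0, block_duration=300.0, seed=0)


@pytest.fixture
def fast_gaze_cfg() -> GazeSimConfig:
    return GazeSimConfig(sampling_rate=250.0, n_pairs=4, n_repeats=2, seed=0)


def make_trial(
    layout: AOILayout,
    fixations: list[Fixation],
    window_ms: float = 12000.0,
    dt_ms: float = 4.0,
    invalid_fraction: float = 0.0,
    participant_id: str = "",
    trial_index: int = 0,
) -> GazeTrial:
    """Hand-built trial: constant position inside each fixation, NaN
    elsewhere; optionally invalidates the leading fraction of samples."""
    n = int(round(window_ms / dt_ms))
    t = np.arange(n) * dt_ms
    x = np.full(n, np.nan)
    y = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    for fx in fixations:
        i0, i1 = int(fx.start_ms / dt_ms), int(fx.end_ms / dt_ms)
        x[i0:i1] = fx.x
        y[i0:i1] = fx.y
        valid[i0:i1] = True
    n_invalid = int(np.ceil(invalid_fraction * n))
    if n_invalid:
        valid[:n_invalid] = False
        x[:n_invalid] = np.nan
        y[:n_invalid] = np.nan
    samples = pd.DataFrame({"t_ms": t, "x": x, "y": y, "valid": valid})
    return GazeTrial(
        trial_index=trial_index,
        pair_id=0,
        presentation_number=1,
        samples=samples,
        fixations=fixations,
        layout=layout,
        participant_id=participant_id,
    )
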