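"""Synthetic preferential-looking gaze streams.

Trials are built at fixation granularity: alternating fixations whose
target (disgust vs neutral stimulus) is a Bernoulli draw with
``approach_bias`` during the initial approach phase and ``avoid_bias``
afterwards.  Fixations abut (no modelled saccade kinematics); positions
jump instantaneously between them, which is exactly what a
velocity-threshold detector needs to segment them.  Blink gaps are
contiguous runs of invalid samples with NaN coordinates.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..errors import ConfigError
from ..types import AOILayout, Fixation, GazeTrial

__all__ = ["GazeSimConfig", "generate_gaze", "degrade_trials"]


@dataclass
class GazeSimConfig:
    """Configuration of the gaze generator (times in the units named)."""

    sampling_rate: float = 1000.0  # samples/s
    n_pairs: int = 14
    n_repeats: int = 3
    fixation_cross_s: float = 1.0
    stimulus_s: float = 12.0
    iti_s: float = 3.0
    approach_duration_s: float = 1.0
    approach_bias: float = 0.7
    avoid_bias: float = 0.3
    mean_fixation_ms: float = 300.0
    min_fixation_ms: float = 80.0
    max_fixation_ms: float = 1500.0
    blink_rate: float = 6.0  # events/min
    blink_duration_ms: float = 150.0
    position_jitter_px: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.sampling_rate <= 0 or self.stimulus_s <= 0:
            raise ConfigError("sampling_rate and stimulus_s must be positive")
        if self.n_pairs < 1 or self.n_repeats < 1:
            raise ConfigError("n_pairs and n_repeats must be at least 1")
        for name in ("approach_bias", "avoid_bias"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {value}")
        if self.blink_rate < 0 or self.blink_duration_ms < 0:
            raise ConfigError("blink parameters must be non-negative")
        if not (0 < self.min_fixation_ms <= self.mean_fixation_ms <= self.max_fixation_ms):
            raise ConfigError("need 0 < min_fixation_ms <= mean_fixation_ms <= max_fixation_ms")


def _simulate_trial(
    cfg: GazeSimConfig,
    layout: AOILayout,
    trial_index: int,
    pair_id: int,
    presentation_number: int,
    rng: np.random.Generator,
    participant_id: str,
) -> GazeTrial:
    fs = cfg.sampling_rate
    n = int(round(cfg.stimulus_s * fs))
    ms_per_sample = 1000.0 / fs
    approach_end = int(round(cfg.approach_duration_s * fs))  # sample index

    x = np.empty(n)
    y = np.empty(n)
    fixations: list[Fixation] = []
    i = 0
    while i < n:
        duration_ms = float(
            np.clip(rng.exponential(cfg.mean_fixation_ms), cfg.min_fixation_ms, cfg.max_fixation_ms)
        )
        end = min(n, i + max(1, int(round(duration_ms / ms_per_sample))))
        # Phase is decided at fixation onset; fixations are truncated at the
        # approach/avoid boundary so the phase rule is exact per sample.
        if i < approach_end:
            end = min(end, approach_end)
            bias = cfg.approach_bias
        else:
            bias = cfg.avoid_bias
        span = layout.disgust_span if rng.random() < bias else layout.neutral_span
        margin = min(5.0, 0.25 * (span[1] - span[0]))
        fx = rng.uniform(span[0] + margin, span[1] - margin)
        fy = rng.uniform(0.4, 0.6) * layout.screen_height
        x[i:end] = fx
        y[i:end] = fy
        fixations.append(Fixation(i * ms_per_sample, end * ms_per_sample, fx, fy))
        i = end

    if cfg.position_jitter_px > 0:
        x += rng.normal(0.0, cfg.position_jitter_px, size=n)
        y += rng.normal(0.0, cfg.position_jitter_px, size=n)

    valid = np.ones(n, dtype=bool)
    if cfg.blink_rate > 0 and cfg.blink_duration_ms > 0:
        n_blinks = rng.poisson(cfg.blink_rate * cfg.stimulus_s / 60.0)
        blink_len = max(1, int(round(cfg.blink_duration_ms / ms_per_sample)))
        for start in rng.integers(0, n, size=n_blinks):
            valid[start : start + blink_len] = False
    x[~valid] = np.nan
    y[~valid] = np.nan

    samples = pd.DataFrame(
        {"t_ms": np.arange(n) * ms_per_sample, "x": x, "y": y, "valid": valid}
    )
    return GazeTrial(
        trial_index=trial_index,
        pair_id=pair_id,
        presentation_number=presentation_number,
        samples=samples,
        fixations=fixations,
        layout=layout,
        participant_id=participant_id,
    )


def generate_gaze(
    cfg: GazeSimConfig, layout: AOILayout, participant_id: str = ""
) -> list[GazeTrial]:
    """Generate ``n_pairs * n_repeats`` trials in seeded shuffled order."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    schedule = [
        (pair, repeat)
        for repeat in range(1, cfg.n_repeats + 1)
        for pair in range(cfg.n_pairs)
    ]
    rng.shuffle(schedule)
    return [
        _simulate_trial(cfg, layout, index, pair, repeat, rng, participant_id)
        for index, (pair, repeat) in enumerate(schedule)
    ]


def degrade_trials(
    trials: list[GazeTrial],
    trial_indices: list[int],
    missing_fraction: float = 0.6,
    seed: int = 0,
) -> list[GazeTrial]:
    """Copy of ``trials`` with the chosen trials' leading samples
    invalidated so their missing fraction is at least ``missing_fraction``.

    Used to plant known exclusion targets in synthetic cohorts.
    """
    if not (0.0 <= missing_fraction <= 1.0):
        raise ConfigError("missing_fraction must lie in [0, 1]")
    chosen = set(trial_indices)
    out = []
    for trial in trials:
        if trial.trial_index not in chosen:
            out.append(trial)
            continue
        trial = copy.deepcopy(trial)
        n_invalid = int(np.ceil(missing_fraction * trial.n_samples))
        trial.samples.loc[: n_invalid - 1, "valid"] = False
        trial.samples.loc[: n_invalid - 1, ["x", "y"]] = np.nan
        out.append(trial)
    return out
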