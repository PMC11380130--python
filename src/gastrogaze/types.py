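"""Shared domain types: recordings, layouts, trials.

All containers validate their invariants at construction; readers and
generators therefore cannot hand invariant-violating objects downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import FormatError, InputError, LayoutError

__all__ = [
    "BLOCK_DISGUST",
    "BLOCK_NEUTRAL",
    "Event",
    "Fixation",
    "EGGRecording",
    "AOILayout",
    "GazeTrial",
]

BLOCK_DISGUST = "block_disgust"
BLOCK_NEUTRAL = "block_neutral"


class Event(NamedTuple):
    """A labelled time interval within a recording, in seconds."""

    label: str
    start_s: float
    end_s: float


class Fixation(NamedTuple):
    """One fixation: interval in ms from stimulus onset, centroid in pixels."""

    start_ms: float
    end_ms: float
    x: float
    y: float

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms

    @property
    def midpoint_ms(self) -> float:
        return 0.5 * (self.start_ms + self.end_ms)


@dataclass
class EGGRecording:
    """Multi-channel gastric time series with condition-block annotations.

    ``channels`` is a DataFrame with one column per sensor (``ch1``..),
    sampled uniformly at ``sampling_rate``; sample ``i`` occurs at
    ``i / sampling_rate`` seconds.  ``events`` must contain exactly one
    disgust and one neutral block, which may not overlap.
    """

    sampling_rate: float
    channels: pd.DataFrame
    events: list[Event]
    participant_id: str = ""

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise FormatError("sampling_rate must be positive")
        if self.channels.shape[0] == 0 or self.channels.shape[1] == 0:
            raise FormatError("recording has no samples or no channels")
        if not np.isfinite(self.channels.to_numpy(dtype=float)).all():
            raise FormatError("recording contains non-finite samples")
        dur = self.duration_s
        for ev in self.events:
            if not (0.0 <= ev.start_s < ev.end_s <= dur + 1e-9):
                raise FormatError(
                    f"event {ev.label!r} [{ev.start_s}, {ev.end_s}] s lies outside "
                    f"the {dur:.3f} s recording"
                )
        for label in (BLOCK_DISGUST, BLOCK_NEUTRAL):
            n = sum(1 for ev in self.events if ev.label == label)
            if n != 1:
                raise FormatError(f"expected exactly one {label!r} event, found {n}")
        d = self.block_interval(BLOCK_DISGUST)
        n = self.block_interval(BLOCK_NEUTRAL)
        if d[0] < n[1] and n[0] < d[1]:
            raise FormatError("disgust and neutral block intervals overlap")

    @property
    def n_samples(self) -> int:
        return self.channels.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.channels.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def block_interval(self, label: str) -> tuple[float, float]:
        for ev in self.events:
            if ev.label == label:
                return (ev.start_s, ev.end_s)
        raise KeyError(label)

    def values(self) -> np.ndarray:
        """Channel data as an (n_samples, n_sensors) float array."""
        return self.channels.to_numpy(dtype=float)

    def with_values(self, values: np.ndarray) -> "EGGRecording":
        """Copy of this recording with channel data replaced."""
        frame = pd.DataFrame(np.asarray(values, dtype=float), columns=self.channels.columns)
        return EGGRecording(self.sampling_rate, frame, list(self.events), self.participant_id)


@dataclass(frozen=True)
class AOILayout:
    """Horizontal stimulus spans on screen, pixels, origin top-left.

    Span membership is half-open: x belongs to a span iff
    ``x_min <= x < x_max``.
    """

    left_span: tuple[float, float]
    right_span: tuple[float, float]
    disgust_side: str
    screen_width: float
    screen_height: float

    def __post_init__(self) -> None:
        if self.disgust_side not in ("left", "right"):
            raise LayoutError(f"disgust_side must be 'left' or 'right', got {self.disgust_side!r}")
        for name, span in (("left_span", self.left_span), ("right_span", self.right_span)):
            if not (0 <= span[0] < span[1] <= self.screen_width):
                raise LayoutError(f"{name} {span} not within screen width {self.screen_width}")
        lo, hi = sorted((self.left_span, self.right_span))
        if hi[0] < lo[1]:
            raise LayoutError(f"AOI spans {self.left_span} and {self.right_span} overlap")
        if self.screen_height <= 0:
            raise LayoutError("screen_height must be positive")

    def span(self, side: str) -> tuple[float, float]:
        if side == "left":
            return self.left_span
        if side == "right":
            return self.right_span
        raise InputError(f"unknown side {side!r}")

    @property
    def disgust_span(self) -> tuple[float, float]:
        return self.span(self.disgust_side)

    @property
    def neutral_span(self) -> tuple[float, float]:
        return self.span("right" if self.disgust_side == "left" else "left")

    def contains(self, x: np.ndarray, span: tuple[float, float]) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (x >= span[0]) & (x < span[1])


@dataclass
class GazeTrial:
    """One preferential-looking trial.

    ``samples`` has columns ``t_ms, x, y, valid`` covering the stimulus
    window; ``fixations`` may be empty, in which case downstream code
    detects them from the samples.
    """

    trial_index: int
    pair_id: int
    presentation_number: int
    samples: pd.DataFrame
    fixations: list[Fixation]
    layout: AOILayout
    participant_id: str = ""

    def __post_init__(self) -> None:
        required = {"t_ms", "x", "y", "valid"}
        missing = required - set(self.samples.columns)
        if missing:
            raise FormatError(f"gaze samples missing columns: {sorted(missing)}")
        t = self.samples["t_ms"].to_numpy(dtype=float)
        if len(t) == 0:
            raise FormatError("gaze trial has no samples")
        if np.any(np.diff(t) <= 0):
            raise FormatError(f"trial {self.trial_index}: sample timestamps not strictly increasing")
        prev_end = -np.inf
        for fx in self.fixations:
            if fx.end_ms <= fx.start_ms:
                raise FormatError(f"trial {self.trial_index}: fixation with non-positive duration")
            if fx.start_ms < prev_end:
                raise FormatError(f"trial {self.trial_index}: fixations overlap or are out of order")
            prev_end = fx.end_ms

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sampling_interval_ms(self) -> float:
        t = self.samples["t_ms"].to_numpy(dtype=float)
        if len(t) < 2:
            return 1.0
        return float(np.median(np.diff(t)))

    @property
    def window_ms(self) -> float:
        return self.n_samples * self.sampling_interval_ms

    @property
    def missing_fraction(self) -> float:
        valid = self.samples["valid"].to_numpy(dtype=bool)
        return float(1.0 - valid.mean())
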