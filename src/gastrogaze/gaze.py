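"""Preferential-looking computation: fixations, dwell times, exclusions,
avoidance score, and the within-trial time-course curve.

Dwell is primarily fixation-based (summed durations of fixations whose
x-centroid falls in a stimulus's half-open horizontal span, regardless of
y); a sample-count mode is provided for sensitivity checks.  Missing
fraction is computed over the stimulus window only, and trials with
strictly more than 50% missing samples are excluded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import InputError
from .types import Fixation, GazeTrial

__all__ = [
    "detect_fixations",
    "ensure_fixations",
    "DwellResult",
    "dwell",
    "exclude_trials",
    "avoidance_score",
    "TimeCourse",
    "time_course",
]


def detect_fixations(
    samples: pd.DataFrame,
    velocity_threshold: float = 1.0,
    min_duration_ms: float = 50.0,
) -> list[Fixation]:
    """Velocity-threshold fixation detection.

    Contiguous runs of valid samples whose point-to-point speed stays
    below ``velocity_threshold`` (pixels per ms) and that last at least
    ``min_duration_ms`` become fixations at the run's centroid.  This is a
    documented substitute for proprietary tracker firmware detectors.
    """
    if len(samples) == 0:
        return []
    t = samples["t_ms"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise InputError("sample timestamps must be strictly increasing")
    x = samples["x"].to_numpy(dtype=float)
    y = samples["y"].to_numpy(dtype=float)
    valid = samples["valid"].to_numpy(dtype=bool)

    n = len(t)
    dt = np.diff(t)
    speed = np.hypot(np.diff(x), np.diff(y)) / dt
    # slow[i]: the step from sample i-1 to i is slow and both ends valid
    slow = np.zeros(n, dtype=bool)
    slow[1:] = (speed < velocity_threshold) & valid[1:] & valid[:-1]

    fixations: list[Fixation] = []
    run_start: int | None = None
    for i in range(n):
        if run_start is None:
            if valid[i]:
                run_start = i
            continue
        if valid[i] and slow[i]:
            continue
        _append_run(fixations, run_start, i - 1, t, x, y, min_duration_ms)
        run_start = i if valid[i] else None
    if run_start is not None:
        _append_run(fixations, run_start, n - 1, t, x, y, min_duration_ms)
    return fixations


def _append_run(
    fixations: list[Fixation],
    i0: int,
    i1: int,
    t: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    min_duration_ms: float,
) -> None:
    if i1 <= i0:
        return
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    start, end = t[i0], t[i1] + dt  # half-open sample coverage
    if end - start < min_duration_ms:
        return
    fixations.append(
        Fixation(float(start), float(end), float(np.mean(x[i0 : i1 + 1])), float(np.mean(y[i0 : i1 + 1])))
    )


def ensure_fixations(trial: GazeTrial, **detect_kwargs) -> list[Fixation]:
    """The trial's provided fixations, or detected ones when absent."""
    if trial.fixations:
        return trial.fixations
    return detect_fixations(trial.samples, **detect_kwargs)


@dataclass
class DwellResult:
    """Per-trial dwell times (ms) and the missing-data fraction."""

    trial_index: int
    dwell_disgust: float
    dwell_neutral: float
    dwell_other: float
    missing_fraction: float
    excluded: bool = False
    participant_id: str = ""
    pair_id: int = -1
    presentation_number: int = 0

    @property
    def difference(self) -> float:
        """dwell_disgust - dwell_neutral; negative means avoidance."""
        return self.dwell_disgust - self.dwell_neutral


def dwell(trial: GazeTrial, mode: str = "fixation", **detect_kwargs) -> DwellResult:
    """Dwell time per stimulus for one trial.

    ``mode="fixation"`` (primary): sum durations of fixations assigned by
    x-centroid to each half-open AOI span.  ``mode="sample"``: count valid
    samples inside each span.  Unassigned time is "other".
    """
    if trial.layout is None:
        raise InputError("trial has no AOI layout")
    layout = trial.layout
    window_ms = trial.window_ms

    if mode == "fixation":
        fixations = ensure_fixations(trial, **detect_kwargs)
        d = n = 0.0
        for fx in fixations:
            duration = min(fx.end_ms, window_ms) - fx.start_ms
            if duration <= 0:
                continue
            if layout.contains(fx.x, layout.disgust_span):
                d += duration
            elif layout.contains(fx.x, layout.neutral_span):
                n += duration
        other = max(0.0, window_ms - d - n)
    elif mode == "sample":
        ms_per_sample = trial.sampling_interval_ms
        x = trial.samples["x"].to_numpy(dtype=float)
        valid = trial.samples["valid"].to_numpy(dtype=bool)
        in_d = layout.contains(x, layout.disgust_span) & valid
        in_n = layout.contains(x, layout.neutral_span) & valid
        d = float(in_d.sum()) * ms_per_sample
        n = float(in_n.sum()) * ms_per_sample
        other = window_ms - d - n
    else:
        raise InputError(f"unknown dwell mode {mode!r}")

    return DwellResult(
        trial_index=trial.trial_index,
        dwell_disgust=d,
        dwell_neutral=n,
        dwell_other=other,
        missing_fraction=trial.missing_fraction,
        participant_id=trial.participant_id,
        pair_id=trial.pair_id,
        presentation_number=trial.presentation_number,
    )


def exclude_trials(
    results: Iterable[DwellResult], missing_threshold: float = 0.5
) -> tuple[list[DwellResult], pd.DataFrame]:
    """Exclude trials with strictly more than ``missing_threshold`` missing
    data (a fraction of exactly 0.5 is retained).

    Returns the retained results and an exclusion log with one row per
    excluded trial (participant, trial index, missing fraction).
    """
    retained: list[DwellResult] = []
    log_rows = []
    for result in results:
        if result.missing_fraction > missing_threshold:
            result.excluded = True
            log_rows.append(
                {
                    "participant_id": result.participant_id,
                    "trial_index": result.trial_index,
                    "missing_fraction": result.missing_fraction,
                }
            )
        else:
            result.excluded = False
            retained.append(result)
    log = pd.DataFrame(log_rows, columns=["participant_id", "trial_index", "missing_fraction"])
    return retained, log


def avoidance_score(results: Iterable[DwellResult]) -> float | None:
    """Mean over retained trials of (dwell_disgust - dwell_neutral), ms.

    Negative values indicate avoidance.  ``None`` when no trial remains,
    flagging the participant missing for this measure.
    """
    differences = [r.difference for r in results if not r.excluded]
    if not differences:
        return None
    return float(np.mean(differences))


@dataclass
class TimeCourse:
    """Group time course of the dwell-share difference (disgust - neutral).

    ``mean_diff`` is in percentage points of valid looking time per bin,
    averaged first over trials within participant, then over participants;
    ``sem`` is the between-participant standard error.
    """

    bin_centres_s: np.ndarray
    mean_diff: np.ndarray
    sem: np.ndarray
    n_participants: np.ndarray
    presentation: int | None  # None = pooled


def _trial_curve(trial: GazeTrial, bin_edges_ms: np.ndarray) -> np.ndarray:
    layout = trial.layout
    t = trial.samples["t_ms"].to_numpy(dtype=float)
    x = trial.samples["x"].to_numpy(dtype=float)
    valid = trial.samples["valid"].to_numpy(dtype=bool)
    in_d = layout.contains(x, layout.disgust_span) & valid
    in_n = layout.contains(x, layout.neutral_span) & valid
    idx = np.clip(np.digitize(t, bin_edges_ms) - 1, 0, len(bin_edges_ms) - 2)
    n_bins = len(bin_edges_ms) - 1
    n_valid = np.bincount(idx[valid], minlength=n_bins).astype(float)
    n_disgust = np.bincount(idx[in_d], minlength=n_bins).astype(float)
    n_neutral = np.bincount(idx[in_n], minlength=n_bins).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        curve = 100.0 * (n_disgust - n_neutral) / n_valid
    curve[n_valid == 0] = np.nan
    return curve


def time_course(
    trials_by_participant: Mapping[str, list[GazeTrial]],
    bin_ms: float = 500.0,
    presentation: int | None = None,
) -> TimeCourse:
    """Binned dwell-share difference curve across the cohort.

    Only pass retained trials.  A bin with zero valid time in all of a
    participant's trials contributes a missing value for that participant.
    """
    if bin_ms <= 0:
        raise InputError("bin_ms must be positive")
    window_ms = None
    participant_curves = []
    for trials in trials_by_participant.values():
        selected = [
            trial
            for trial in trials
            if presentation is None or trial.presentation_number == presentation
        ]
        if not selected:
            continue
        if window_ms is None:
            window_ms = selected[0].window_ms
            n_bins = int(np.ceil(window_ms / bin_ms))
            bin_edges = np.arange(n_bins + 1) * bin_ms
        curves = np.array([_trial_curve(trial, bin_edges) for trial in selected])
        with warnings.catch_warnings():
            # all-NaN bins are the documented "participant contributes missing" case
            warnings.simplefilter("ignore", RuntimeWarning)
            participant_curves.append(np.nanmean(curves, axis=0))
    if not participant_curves:
        raise InputError("no trials to compute a time course from")
    stacked = np.array(participant_curves)
    counts = np.sum(~np.isnan(stacked), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stacked, axis=0)
        sd = np.nanstd(stacked, axis=0, ddof=1) if stacked.shape[0] > 1 else np.zeros(stacked.shape[1])
    sem = np.where(counts > 0, sd / np.sqrt(np.maximum(counts, 1)), np.nan)
    centres_s = (bin_edges[:-1] + bin_edges[1:]) / 2.0 / 1000.0
    return TimeCourse(centres_s, mean, sem, counts, presentation)
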