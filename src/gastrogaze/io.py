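"""Readers and writers for on-disk artefacts.

All formats are plain delimited text or JSON/YAML so that artefacts stay
portable and diffable.  Readers validate the type invariants and reject
violating files rather than repairing them.

Conventions
-----------
EGG recordings: CSV with header ``t_s,ch1..chN``; times in seconds.
Events: CSV ``label,start_s,end_s`` in a sibling ``*.events.csv`` file.
Gaze samples: CSV ``trial_index,pair_id,presentation_number,t_ms,x,y,valid``.
Gaze fixations (optional): CSV ``trial_index,start_ms,end_ms,x,y``.
AOI layout: JSON or YAML mapping.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError
from .types import AOILayout, EGGRecording, Event, Fixation, GazeTrial

__all__ = [
    "write_egg",
    "read_egg",
    "write_gaze",
    "read_gaze",
    "write_aoi",
    "read_aoi",
    "load_config",
    "write_ground_truth",
    "default_events_path",
]


def default_events_path(path: str | Path) -> Path:
    path = Path(path)
    return path.with_name(path.stem + ".events.csv")


# ---------------------------------------------------------------------------
# EGG


def write_egg(recording: EGGRecording, path: str | Path, events_path: str | Path | None = None) -> None:
    """Write an EGG recording and its annotations as two CSV files."""
    path = Path(path)
    if events_path is None:
        events_path = default_events_path(path)
    frame = recording.channels.copy()
    frame.insert(0, "t_s", recording.times_s)
    frame.to_csv(path, index=False)
    with open(events_path, "w") as fh:
        fh.write("label,start_s,end_s\n")
        for ev in recording.events:
            fh.write(f"{ev.label},{ev.start_s!r},{ev.end_s!r}\n")


def _read_events(events_path: Path) -> list[Event]:
    if not events_path.exists():
        raise FormatError(f"annotation file not found: {events_path}")
    events: list[Event] = []
    with open(events_path) as fh:
        lines = fh.read().splitlines()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) != 3:
            raise FormatError(f"{events_path}:{lineno}: expected 'label,start_s,end_s', got {line!r}")
        label = parts[0].strip()
        try:
            start_s, end_s = float(parts[1]), float(parts[2])
        except ValueError as exc:
            raise FormatError(f"{events_path}:{lineno}: unparseable interval in {line!r}") from exc
        events.append(Event(label, start_s, end_s))
    return events


def read_egg(
    path: str | Path,
    events_path: str | Path | None = None,
    participant_id: str = "",
) -> EGGRecording:
    """Read an EGG recording; the annotation file defaults to the sibling
    ``<stem>.events.csv``."""
    path = Path(path)
    if events_path is None:
        events_path = default_events_path(path)
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pandas raises several parser error types
        raise FormatError(f"{path}: {exc}") from exc
    if "t_s" not in frame.columns or frame.shape[1] < 2:
        raise FormatError(f"{path}: expected columns 't_s, ch1..chN'")
    channels = frame.drop(columns=["t_s"])
    bad = channels.isna().any(axis=0)
    if bad.any():
        col = bad[bad].index[0]
        row = int(channels[col].isna().idxmax())
        raise FormatError(f"{path}: unparseable or missing value in column {col!r} at data row {row + 1}")
    t = frame["t_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if len(dt) == 0 or np.any(dt <= 0):
        raise FormatError(f"{path}: time column not strictly increasing")
    sampling_rate = 1.0 / float(np.median(dt))
    events = _read_events(Path(events_path))
    return EGGRecording(sampling_rate, channels, events, participant_id)


# ---------------------------------------------------------------------------
# Gaze


def write_gaze(
    trials: list[GazeTrial],
    samples_path: str | Path,
    fixations_path: str | Path | None = None,
) -> None:
    """Write gaze trials as one flat samples CSV (+ optional fixations CSV)."""
    sample_frames = []
    fixation_rows = []
    for trial in trials:
        frame = trial.samples.copy()
        frame.insert(0, "presentation_number", trial.presentation_number)
        frame.insert(0, "pair_id", trial.pair_id)
        frame.insert(0, "trial_index", trial.trial_index)
        sample_frames.append(frame)
        for fx in trial.fixations:
            fixation_rows.append((trial.trial_index, fx.start_ms, fx.end_ms, fx.x, fx.y))
    flat = pd.concat(sample_frames, ignore_index=True)
    flat["valid"] = flat["valid"].astype(int)
    flat.to_csv(samples_path, index=False)
    if fixations_path is not None:
        pd.DataFrame(
            fixation_rows, columns=["trial_index", "start_ms", "end_ms", "x", "y"]
        ).to_csv(fixations_path, index=False)


def read_gaze(
    samples_path: str | Path,
    layout: AOILayout,
    fixations_path: str | Path | None = None,
    participant_id: str = "",
) -> list[GazeTrial]:
    """Read gaze trials; without a fixations file trials carry empty
    fixation lists and downstream code must detect fixations."""
    samples_path = Path(samples_path)
    try:
        flat = pd.read_csv(samples_path, float_precision="round_trip")
    except Exception as exc:
        raise FormatError(f"{samples_path}: {exc}") from exc
    required = {"trial_index", "pair_id", "presentation_number", "t_ms", "x", "y", "valid"}
    missing = required - set(flat.columns)
    if missing:
        raise FormatError(f"{samples_path}: missing columns {sorted(missing)}")
    fixmap: dict[int, list[Fixation]] = {}
    if fixations_path is not None:
        fixframe = pd.read_csv(fixations_path)
        for row in fixframe.itertuples(index=False):
            fixmap.setdefault(int(row.trial_index), []).append(
                Fixation(float(row.start_ms), float(row.end_ms), float(row.x), float(row.y))
            )
    trials = []
    for trial_index, group in flat.groupby("trial_index", sort=True):
        samples = group[["t_ms", "x", "y", "valid"]].reset_index(drop=True)
        samples["valid"] = samples["valid"].astype(bool)
        trials.append(
            GazeTrial(
                trial_index=int(trial_index),
                pair_id=int(group["pair_id"].iloc[0]),
                presentation_number=int(group["presentation_number"].iloc[0]),
                samples=samples,
                fixations=sorted(fixmap.get(int(trial_index), []), key=lambda f: f.start_ms),
                layout=layout,
                participant_id=participant_id,
            )
        )
    return trials


# ---------------------------------------------------------------------------
# AOI layout and config


def write_aoi(layout: AOILayout, path: str | Path) -> None:
    payload = {
        "left_span": list(layout.left_span),
        "right_span": list(layout.right_span),
        "disgust_side": layout.disgust_side,
        "screen_width": layout.screen_width,
        "screen_height": layout.screen_height,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_aoi(path: str | Path) -> AOILayout:
    """Read an AOI layout from JSON or YAML; geometry is always explicit."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)  # YAML is a superset of JSON
    try:
        return AOILayout(
            left_span=tuple(float(v) for v in payload["left_span"]),
            right_span=tuple(float(v) for v in payload["right_span"]),
            disgust_side=str(payload["disgust_side"]),
            screen_width=float(payload["screen_width"]),
            screen_height=float(payload["screen_height"]),
        )
    except KeyError as exc:
        raise FormatError(f"{path}: missing AOI field {exc}") from exc


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        loaded = yaml.safe_load(fh)
    if not isinstance(loaded, dict):
        raise FormatError(f"{path}: expected a mapping at top level")
    return loaded


def write_ground_truth(ground_truth: dict[str, Any], path: str | Path) -> None:
    """JSON sidecar with scalar/list ground-truth parameters (arrays are
    converted to lists; large sample-level arrays should be dropped by the
    caller first)."""

    def _default(obj: Any) -> Any:
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        raise TypeError(f"not JSON serialisable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(ground_truth, fh, indent=2, default=_default)
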