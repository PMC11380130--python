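"""Scoring of the four disgust-sensitivity instruments.

Instruments are described declaratively (item count, response range,
subscale map, reverse-keyed items) in editable JSON spec files bundled
under ``gastrogaze/data/instruments``.  The bundled subscale maps and
reverse-key sets are externally sourced defaults taken from the
instruments' publication conventions and should be adjusted to the exact
instrument version in use; the scoring engine itself is version-agnostic.

Missing responses are flagged and propagated (no imputation): any missing
item voids the total, and any missing mapped item voids its subscale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError

__all__ = ["InstrumentSpec", "load_instrument", "available_instruments", "score"]

_DATA_PACKAGE = "gastrogaze.data.instruments"


@dataclass(frozen=True)
class InstrumentSpec:
    """Declarative description of one questionnaire."""

    name: str
    n_items: int
    response_min: int
    response_max: int
    subscale_map: dict[int, str] = field(default_factory=dict)  # 1-based item -> label
    reverse_items: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.n_items < 1:
            raise ConfigError("n_items must be at least 1")
        if self.response_min >= self.response_max:
            raise ConfigError("response range must satisfy min < max")
        for item in list(self.subscale_map) + list(self.reverse_items):
            if not (1 <= item <= self.n_items):
                raise ConfigError(f"item index {item} outside 1..{self.n_items}")

    @property
    def subscales(self) -> list[str]:
        seen: list[str] = []
        for label in self.subscale_map.values():
            if label not in seen:
                seen.append(label)
        return seen

    @property
    def item_columns(self) -> list[str]:
        return [f"item_{i}" for i in range(1, self.n_items + 1)]

    @property
    def max_total(self) -> int:
        return self.n_items * self.response_max

    def partitions_items(self) -> bool:
        return len(self.subscale_map) == self.n_items


def available_instruments() -> list[str]:
    files = resources.files(_DATA_PACKAGE)
    return sorted(p.name.removesuffix(".json") for p in files.iterdir() if p.name.endswith(".json"))


def load_instrument(name_or_path: str | Path) -> InstrumentSpec:
    """Load an instrument spec by bundled name (e.g. ``"tdds"``) or from an
    explicit JSON file path."""
    path = Path(name_or_path)
    if path.suffix == ".json" and path.exists():
        payload = json.loads(path.read_text())
    else:
        try:
            payload = json.loads(
                resources.files(_DATA_PACKAGE).joinpath(f"{name_or_path}.json").read_text()
            )
        except FileNotFoundError as exc:
            raise ConfigError(
                f"unknown instrument {name_or_path!r}; available: {available_instruments()}"
            ) from exc
    return InstrumentSpec(
        name=payload["name"],
        n_items=int(payload["n_items"]),
        response_min=int(payload["response_range"][0]),
        response_max=int(payload["response_range"][1]),
        subscale_map={int(k): v for k, v in payload.get("subscale_map", {}).items()},
        reverse_items=frozenset(int(i) for i in payload.get("reverse_items", [])),
    )


def score(responses: pd.DataFrame, spec: InstrumentSpec) -> pd.DataFrame:
    """Score a response table into totals, subscale scores, and a missing
    report.

    ``responses`` must carry ``participant_id`` plus ``item_1..item_k``
    columns with integer responses in range, or missing (NaN).  Returns one
    row per respondent with columns ``total``, one per subscale, and
    ``n_missing``; scores touched by a missing item are NaN.
    """
    if "participant_id" not in responses.columns:
        raise InputError("response table must have a participant_id column")
    missing_cols = [c for c in spec.item_columns if c not in responses.columns]
    if missing_cols:
        raise InputError(f"{spec.name}: response table missing columns {missing_cols}")

    items = responses[spec.item_columns].to_numpy(dtype=float)
    present = ~np.isnan(items)
    in_range = (items >= spec.response_min) & (items <= spec.response_max)
    integral = np.isclose(items, np.round(items))
    bad = present & ~(in_range & integral)
    if bad.any():
        row, col = np.argwhere(bad)[0]
        pid = responses["participant_id"].iloc[row]
        raise InputError(
            f"{spec.name}: participant {pid!r} has out-of-range or non-integer "
            f"response {items[row, col]!r} on item_{col + 1} "
            f"(allowed {spec.response_min}..{spec.response_max})"
        )

    keyed = items.copy()
    for item in spec.reverse_items:
        keyed[:, item - 1] = spec.response_min + spec.response_max - keyed[:, item - 1]

    out = pd.DataFrame({"participant_id": responses["participant_id"].to_numpy()})
    any_missing = ~present.all(axis=1)
    total = keyed.sum(axis=1)
    total[any_missing] = np.nan
    out["total"] = total
    for label in spec.subscales:
        idx = [i - 1 for i, lab in spec.subscale_map.items() if lab == label]
        sub = keyed[:, idx].sum(axis=1)
        sub[~present[:, idx].all(axis=1)] = np.nan
        out[label] = sub
    out["n_missing"] = (~present).sum(axis=1)
    return out
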