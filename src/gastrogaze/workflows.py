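"""Cohort-scale orchestration built from the module-level primitives.

These helpers wire generator -> pipeline -> table for whole simulated
cohorts.  They exist so that parameter-recovery and calibration checks
(and the CLI) exercise exactly the same code paths end to end.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import egg as eggmod
from . import gaze as gazemod
from .synthetic.egg import EGGSimConfig, generate_egg
from .synthetic.gaze import GazeSimConfig, generate_gaze
from .types import AOILayout, GazeTrial

__all__ = [
    "default_layout",
    "simulate_gaze_cohort",
    "dwell_table",
    "simulate_dwell_cohort",
    "simulate_egg_cohort",
    "simulate_band_power_table",
]


def default_layout(disgust_side: str = "left") -> AOILayout:
    """A plausible two-stimulus layout on a 1920x1080 screen."""
    return AOILayout(
        left_span=(160.0, 860.0),
        right_span=(1060.0, 1760.0),
        disgust_side=disgust_side,
        screen_width=1920.0,
        screen_height=1080.0,
    )


def _family_ids(n: int, sibling_fraction: float, rng: np.random.Generator) -> list[str]:
    n_siblings = int(round(sibling_fraction * n))
    n_founders = max(1, n - n_siblings)
    parents = [f"P{i + 1:03d}" for i in range(n_founders)]
    out = list(parents)
    while len(out) < n:
        out.append(parents[rng.integers(0, n_founders)])
    return out


def simulate_gaze_cohort(
    n_participants: int,
    cfg: GazeSimConfig | None = None,
    layout: AOILayout | None = None,
    seed: int = 0,
    blink_rate_range: tuple[float, float] | None = None,
) -> dict[str, list[GazeTrial]]:
    """Independent gaze simulations for a cohort, one seeded generator per
    participant.  ``blink_rate_range`` draws a per-participant blink rate
    to create between-participant variance in data quality."""
    cfg = cfg or GazeSimConfig()
    layout = layout or default_layout()
    rng = np.random.default_rng(seed)
    cohort: dict[str, list[GazeTrial]] = {}
    for i in range(n_participants):
        pid = f"C{i + 1:03d}"
        participant_cfg = GazeSimConfig(**{**cfg.__dict__})
        participant_cfg.seed = int(rng.integers(0, 2**31 - 1))
        if blink_rate_range is not None:
            participant_cfg.blink_rate = float(rng.uniform(*blink_rate_range))
        cohort[pid] = generate_gaze(participant_cfg, layout, participant_id=pid)
    return cohort


def dwell_table(
    cohort: dict[str, list[GazeTrial]],
    mode: str = "fixation",
    missing_threshold: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-trial, per-condition long-format dwell table after exclusion.

    Returns ``(table, exclusion_log)``; the table has two rows per
    retained trial (condition disgust/neutral) ready for the model ledger.
    """
    rows = []
    logs = []
    for pid, trials in cohort.items():
        results = [gazemod.dwell(trial, mode=mode) for trial in trials]
        retained, log = gazemod.exclude_trials(results, missing_threshold)
        logs.append(log)
        for result in retained:
            for condition, value, is_disgust in (
                ("disgust", result.dwell_disgust, 1),
                ("neutral", result.dwell_neutral, 0),
            ):
                rows.append(
                    {
                        "participant_id": pid,
                        "trial_index": result.trial_index,
                        "pair_id": result.pair_id,
                        "presentation_number": result.presentation_number,
                        "condition": condition,
                        "is_disgust": is_disgust,
                        "dwell_ms": value,
                    }
                )
    table = pd.DataFrame(rows)
    logs = [l for l in logs if len(l)]
    if logs:
        log = pd.concat(logs, ignore_index=True)
    else:
        log = pd.DataFrame(columns=["participant_id", "trial_index", "missing_fraction"])
    return table, log


def simulate_dwell_cohort(
    n_participants: int,
    cfg: GazeSimConfig | None = None,
    seed: int = 0,
    sibling_fraction: float = 0.25,
    blink_rate_range: tuple[float, float] = (0.0, 12.0),
) -> pd.DataFrame:
    """Trial-level dwell table (with family ids and standardised columns)
    from a simulated cohort — the input format of the dwell model ledger."""
    cohort = simulate_gaze_cohort(
        n_participants, cfg=cfg, seed=seed, blink_rate_range=blink_rate_range
    )
    table, _log = dwell_table(cohort)
    rng = np.random.default_rng(seed + 1)
    parents = dict(zip(sorted(cohort), _family_ids(n_participants, sibling_fraction, rng)))
    table["parent_id"] = table["participant_id"].map(parents)
    from .stats import standardise

    table["dwell_z"] = standardise(table["dwell_ms"])
    table["trial_z"] = standardise(table["trial_index"].astype(float))
    return table


def simulate_egg_cohort(
    n_participants: int,
    attenuation_delta: float,
    seed: int = 0,
    sampling_rate: float = 10.0,
    block_duration: float = 300.0,
    noise_sd: float = 0.05,
    spike_rate: float = 1.0,
    spike_amplitude: float = 5.0,
    drift_slope: float = 0.002,
    run_full_pipeline: bool = True,
) -> pd.DataFrame:
    """Generate and analyse a cohort of gastric recordings.

    Returns one row per participant with the recovered gastric index and
    exclusion flag.  The simulation sampling rate defaults to 10 Hz to
    keep cohort-scale runs fast; the Hampel window is rescaled to one
    normogastric cycle at that rate, so the chain is unchanged.
    """
    rng = np.random.default_rng(seed)
    params = eggmod.FilterParams.for_rate(sampling_rate)
    rows = []
    for i in range(n_participants):
        pid = f"C{i + 1:03d}"
        cfg = EGGSimConfig(
            sampling_rate=sampling_rate,
            block_duration=block_duration,
            noise_sd=noise_sd,
            spike_rate=spike_rate,
            spike_amplitude=spike_amplitude,
            drift_slope=drift_slope,
            attenuation_delta=attenuation_delta,
            block_order="disgust_first" if rng.random() < 0.5 else "neutral_first",
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        recording, _truth = generate_egg(cfg, participant_id=pid)
        if run_full_pipeline:
            result = eggmod.run_pipeline(recording, params=params, seed=cfg.seed)
            rows.append(
                {
                    "participant_id": pid,
                    "block_order": cfg.block_order,
                    "excluded": result.excluded,
                    "gastric_index": result.index,
                    "n_kept_components": len(result.decomposition.kept),
                }
            )
        else:
            spec_d = eggmod.block_spectrum(recording, "block_disgust")
            spec_n = eggmod.block_spectrum(recording, "block_neutral")
            summary = eggmod.band_summary(spec_d, spec_n)
            rows.append(
                {
                    "participant_id": pid,
                    "block_order": cfg.block_order,
                    "excluded": False,
                    "gastric_index": eggmod.gastric_disgust_index(summary),
                    "n_kept_components": np.nan,
                }
            )
    return pd.DataFrame(rows)


def simulate_band_power_table(
    n_participants: int,
    seed: int = 0,
    sibling_fraction: float = 0.3,
    sampling_rate: float = 2.0,
    block_duration: float = 240.0,
    noise_sd: float = 1.5,
) -> pd.DataFrame:
    """Null-condition band-power table for calibration studies.

    Per participant: a no-attenuation recording with a random normogastric
    amplitude (between-participant variance), reduced straight to band
    spectra (the denoising/ICA stages are bypassed — appropriate for
    calibrating the statistics layer, where speed matters and the null
    must be exact).  Rows: participant x condition x band, with log mean
    band power as the response.
    """
    rng = np.random.default_rng(seed)
    parents = _family_ids(n_participants, sibling_fraction, rng)
    rows = []
    for i in range(n_participants):
        pid = f"C{i + 1:03d}"
        # The whole-signal gain is a participant trait: it scales tones and
        # noise floor alike, so it acts as a pure random intercept on the
        # log-power scale.
        amp = float(np.exp(rng.normal(0.0, 0.4)))
        cfg = EGGSimConfig(
            sampling_rate=sampling_rate,
            block_duration=block_duration,
            component_amplitudes=(amp, 0.4 * amp, 0.4 * amp),
            noise_sd=noise_sd * amp,
            spike_rate=0.0,
            drift_slope=0.0,
            attenuation_delta=0.0,
            block_order="disgust_first" if rng.random() < 0.5 else "neutral_first",
            freq_jitter=0.05,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        recording, _truth = generate_egg(cfg, participant_id=pid)
        spec_d = eggmod.block_spectrum(recording, "block_disgust")
        spec_n = eggmod.block_spectrum(recording, "block_neutral")
        summary = eggmod.band_summary(spec_d, spec_n)
        for condition in ("disgust", "neutral"):
            for band in eggmod.BANDS:
                rows.append(
                    {
                        "participant_id": pid,
                        "parent_id": parents[i],
                        "condition": condition,
                        "band": band,
                        "block_order": cfg.block_order,
                        "log_power": float(np.log(summary.stats[condition][band].mean)),
                    }
                )
    return pd.DataFrame(rows)
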