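"""Synthetic multi-channel gastric recordings with known ground truth.

The latent source model is three sinusoids — normogastric (~3 cpm),
bradygastric (~1 cpm) and tachygastric (~6 cpm) — mixed linearly onto the
sensors, plus per-sensor Gaussian noise, linear drift, and sparse
single-sample spike artifacts.  Pure sinusoids are used so spectral
expectations have closed forms; an optional per-cycle frequency jitter
roughens the rhythm when realism matters more than checkability.

During the disgust block the normogastric source amplitude is multiplied
by ``1 - attenuation_delta``, so the disgust-to-neutral normogastric
peak-power ratio has ground truth ``(1 - delta)**2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from ..errors import ConfigError
from ..types import BLOCK_DISGUST, BLOCK_NEUTRAL, EGGRecording, Event

__all__ = ["EGGSimConfig", "generate_egg", "DEFAULT_MIXING"]

# Fixed, well-conditioned default mixing map: 4 sensors x 3 sources.
DEFAULT_MIXING = np.array(
    [
        [1.0, 0.5, 0.3],
        [0.8, -0.6, 0.4],
        [0.6, 0.4, -0.7],
        [0.9, -0.3, -0.5],
    ]
)


@dataclass
class EGGSimConfig:
    """Configuration of the gastric-signal generator.

    Frequencies are in cycles/min; amplitudes and noise in arbitrary
    signal units.  ``component_amplitudes`` orders sources as
    (normogastric, bradygastric, tachygastric).
    """

    sampling_rate: float = 200.0
    n_sensors: int = 4
    normo_freq: float = 3.0
    brady_freq: float = 1.0
    tachy_freq: float = 6.0
    component_amplitudes: tuple[float, float, float] = (1.0, 0.3, 0.3)
    mixing_matrix: np.ndarray = field(default_factory=lambda: DEFAULT_MIXING.copy())
    noise_sd: float = 0.1
    spike_rate: float = 1.0  # events/min per sensor
    spike_amplitude: float = 20.0
    drift_slope: float = 0.0  # units/s
    attenuation_delta: float = 0.0
    block_order: str = "disgust_first"
    block_duration: float = 300.0  # seconds per block
    freq_jitter: float = 0.0  # fractional per-cycle jitter, e.g. 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise ConfigError("sampling_rate must be positive")
        if self.block_duration <= 0:
            raise ConfigError("block_duration must be positive")
        if not (0.0 <= self.attenuation_delta < 1.0):
            raise ConfigError("attenuation_delta must lie in [0, 1)")
        if self.block_order not in ("disgust_first", "neutral_first"):
            raise ConfigError(f"unknown block_order {self.block_order!r}")
        mixing = np.asarray(self.mixing_matrix, dtype=float)
        if mixing.shape != (self.n_sensors, len(self.component_amplitudes)):
            raise ConfigError(
                f"mixing_matrix must be {self.n_sensors} x {len(self.component_amplitudes)}, "
                f"got {mixing.shape}"
            )
        if np.linalg.matrix_rank(mixing) < mixing.shape[1]:
            raise ConfigError("mixing_matrix is rank deficient; source recovery is ill-posed")
        if self.noise_sd < 0 or self.spike_rate < 0:
            raise ConfigError("noise_sd and spike_rate must be non-negative")
        if not (0.0 <= self.freq_jitter < 1.0):
            raise ConfigError("freq_jitter must lie in [0, 1)")


def _source_phase(freq_cpm: float, n: int, fs: float, jitter: float, rng: np.random.Generator) -> np.ndarray:
    """Cumulative phase of a sinusoid whose frequency is redrawn each
    nominal cycle within ``freq * (1 +/- jitter)``."""
    freq_hz = freq_cpm / 60.0
    if jitter == 0.0:
        return 2.0 * np.pi * freq_hz * np.arange(n) / fs
    cycle_samples = max(1, int(round(fs / freq_hz)))
    n_cycles = n // cycle_samples + 2
    factors = 1.0 + rng.uniform(-jitter, jitter, size=n_cycles)
    inst_freq = np.repeat(freq_hz * factors, cycle_samples)[:n]
    return 2.0 * np.pi * np.cumsum(inst_freq) / fs


def generate_egg(cfg: EGGSimConfig, participant_id: str = "") -> tuple[EGGRecording, dict[str, Any]]:
    """Generate one two-block recording and its ground-truth record.

    Returns ``(recording, ground_truth)`` where ``ground_truth`` carries
    the latent source parameters, the simulated sources themselves (key
    ``"sources"``, shape ``(n_samples, 3)``), and the mixing matrix.
    Identical config and seed give bit-identical output.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sampling_rate
    n = int(round(2 * cfg.block_duration * fs))
    t = np.arange(n) / fs

    if cfg.block_order == "disgust_first":
        disgust = (0.0, cfg.block_duration)
        neutral = (cfg.block_duration, 2 * cfg.block_duration)
    else:
        neutral = (0.0, cfg.block_duration)
        disgust = (cfg.block_duration, 2 * cfg.block_duration)

    freqs = (cfg.normo_freq, cfg.brady_freq, cfg.tachy_freq)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=3)
    sources = np.empty((n, 3))
    for k, (freq, amp) in enumerate(zip(freqs, cfg.component_amplitudes)):
        phase = _source_phase(freq, n, fs, cfg.freq_jitter, rng)
        sources[:, k] = amp * np.sin(phase + phases[k])

    # Disgust-block attenuation of the normogastric source only.
    in_disgust = (t >= disgust[0]) & (t < disgust[1])
    sources[in_disgust, 0] *= 1.0 - cfg.attenuation_delta

    mixing = np.asarray(cfg.mixing_matrix, dtype=float)
    data = sources @ mixing.T
    if cfg.drift_slope != 0.0:
        data += cfg.drift_slope * t[:, None]
    if cfg.noise_sd > 0.0:
        data += rng.normal(0.0, cfg.noise_sd, size=data.shape)
    if cfg.spike_rate > 0.0 and cfg.spike_amplitude != 0.0:
        duration_min = n / fs / 60.0
        for ch in range(cfg.n_sensors):
            n_spikes = rng.poisson(cfg.spike_rate * duration_min)
            if n_spikes:
                idx = rng.integers(0, n, size=n_spikes)
                signs = rng.choice([-1.0, 1.0], size=n_spikes)
                data[idx, ch] += signs * cfg.spike_amplitude

    channels = pd.DataFrame(data, columns=[f"ch{i + 1}" for i in range(cfg.n_sensors)])
    events = [
        Event(BLOCK_DISGUST, disgust[0], disgust[1]),
        Event(BLOCK_NEUTRAL, neutral[0], neutral[1]),
    ]
    recording = EGGRecording(fs, channels, events, participant_id)
    ground_truth: dict[str, Any] = {
        "source_freqs_cpm": list(freqs),
        "component_amplitudes": list(cfg.component_amplitudes),
        "attenuation_delta": cfg.attenuation_delta,
        "expected_peak_power_ratio": (1.0 - cfg.attenuation_delta) ** 2,
        "block_order": cfg.block_order,
        "mixing_matrix": mixing,
        "sources": sources,
        "seed": cfg.seed,
    }
    return recording, ground_truth
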