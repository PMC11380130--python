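"""Frequency and sampling unit conversions.

Gastric rhythms are conventionally reported in cycles per minute (cpm);
filters and FFTs work in Hz.  These helpers keep the conversion in one
place so the 2-4 cpm normogastric band, its ~0.05 Hz equivalent, and the
samples-per-cycle arithmetic never drift apart.
"""

from __future__ import annotations

import math

__all__ = ["cpm_to_hz", "hz_to_cpm", "samples_per_cycle", "round_sig"]


def cpm_to_hz(cpm: float) -> float:
    """Convert cycles/minute to cycles/second (Hz)."""
    return cpm / 60.0


def hz_to_cpm(hz: float) -> float:
    """Convert cycles/second (Hz) to cycles/minute."""
    return hz * 60.0


def samples_per_cycle(freq_cpm: float, sampling_rate: float) -> int:
    """Number of samples spanning one cycle of ``freq_cpm`` at ``sampling_rate``.

    E.g. one 3 cpm gastric cycle (period 20 s) at 200 samples/s is 4000
    samples, the conventional Hampel window for gastric recordings.
    """
    if freq_cpm <= 0 or sampling_rate <= 0:
        raise ValueError("frequency and sampling rate must be positive")
    period_s = 60.0 / freq_cpm
    return int(round(period_s * sampling_rate))


def round_sig(x: float, n_digits: int = 2) -> float:
    """Round ``x`` to ``n_digits`` significant figures."""
    if x == 0:
        return 0.0
    exponent = math.floor(math.log10(abs(x)))
    return round(x, -exponent + n_digits - 1)
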