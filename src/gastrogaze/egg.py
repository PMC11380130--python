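"""Electrogastrogram data-reduction chain.

Stages run strictly in this order, each feeding the next:

    demean -> hampel -> bandpass -> decompose (ICA) ->
    select_and_reconstruct (SNR >= 3) -> block_spectrum -> band_summary

followed by the scalar gastric-disgust index
``ln(normo_peak_disgust / normo_peak_neutral)``.

Conventions (documented because the bin placement and band edges depend
on them):

* The Hampel dispersion is the Gaussian-consistent 1.4826 x MAD of each
  sample's centered window; edge windows are truncated symmetrically.
* The band-pass is a zero-phase (forward-backward) Butterworth of order
  ``bp_order`` so the slow gastric phase is not shifted.
* Spectra are Hann-windowed periodograms normalised so total power equals
  the mean square of the windowed segment divided by the window's mean
  square (Parseval identity, asserted by the tests).
* A bin at exactly 2 or 4 cpm belongs to the normogastric band (closed
  normogastric band, open neighbours).
* The SNR denominator averages power over the analysed 0.5-10 cpm range
  outside 2-4 cpm, i.e. it excludes frequencies the band-pass removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal as sps
from sklearn.decomposition import FastICA
from sklearn.exceptions import ConvergenceWarning

from .errors import InputError
from .types import BLOCK_DISGUST, BLOCK_NEUTRAL, EGGRecording

__all__ = [
    "FilterParams",
    "ComponentDecomposition",
    "PowerSpectrum",
    "BandStats",
    "BandPowerSummary",
    "PipelineResult",
    "demean",
    "hampel",
    "bandpass",
    "preprocess",
    "decompose",
    "component_snr",
    "select_and_reconstruct",
    "block_spectrum",
    "band_summary",
    "gastric_disgust_index",
    "run_pipeline",
    "BANDS",
]

MAD_SCALE = 1.4826  # Gaussian-consistent MAD-to-sigma factor

# Band edges in cycles/min; the bradygastric lower edge is configurable
# (0.5 by default, matching the band-pass high-pass).
BANDS = ("brady", "normo", "tachy")
NORMO_BAND = (2.0, 4.0)
TACHY_HIGH = 10.0


@dataclass(frozen=True)
class FilterParams:
    """Per-sensor denoising parameters.

    ``hampel_window`` is in samples (an even value is widened to the next
    odd count when centred); band-pass cutoffs are in cycles/min.
    """

    hampel_window: int = 4000
    hampel_threshold: float = 3.0
    bp_low: float = 0.5
    bp_high: float = 10.0
    bp_order: int = 4

    def __post_init__(self) -> None:
        if self.hampel_window < 3:
            raise InputError("hampel_window must be at least 3 samples")
        if self.hampel_threshold <= 0:
            raise InputError("hampel_threshold must be positive")
        if not (0 < self.bp_low < self.bp_high):
            raise InputError("need 0 < bp_low < bp_high (cycles/min)")
        if self.bp_order < 1:
            raise InputError("bp_order must be at least 1")

    @classmethod
    def for_rate(cls, sampling_rate: float, normo_freq_cpm: float = 3.0, **overrides) -> "FilterParams":
        """Defaults scaled to a sampling rate: the Hampel window spans one
        normogastric cycle (4000 samples at the conventional 200 Hz)."""
        period_s = 60.0 / normo_freq_cpm
        window = max(3, int(round(period_s * sampling_rate)))
        return cls(hampel_window=window, **overrides)


# ---------------------------------------------------------------------------
# Per-sensor denoising


def demean(recording: EGGRecording) -> EGGRecording:
    """Subtract each channel's mean."""
    values = recording.values()
    if values.shape[0] == 0:
        raise InputError("cannot demean an empty recording")
    return recording.with_values(values - values.mean(axis=0, keepdims=True))


def _hampel_stats_window(window: np.ndarray) -> tuple[float, float]:
    med = float(np.median(window))
    mad = float(np.median(np.abs(window - med)))
    return med, mad


def hampel(
    x: np.ndarray, window: int = 4000, threshold: float = 3.0, chunk: int = 4000
) -> np.ndarray:
    """Hampel outlier filter.

    Sample ``i`` is replaced by its centred window's median when it
    deviates from that median by more than ``threshold * 1.4826 * MAD``
    of the window.  Edge windows are truncated symmetrically (half-width
    ``min(h, i, n-1-i)``).  ``window`` is the full width; even values are
    centred as ``2*(window//2)+1``.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < window:
        raise InputError(f"signal of {n} samples is shorter than the Hampel window ({window})")
    h = window // 2
    med = np.empty(n)
    mad = np.empty(n)

    # Interior: full windows, vectorised in chunks to bound memory.
    if n >= 2 * h + 1:
        view = sliding_window_view(x, 2 * h + 1)
        for start in range(0, view.shape[0], chunk):
            block = view[start : start + chunk]
            m = np.median(block, axis=1)
            med[h + start : h + start + len(m)] = m
            mad[h + start : h + start + len(m)] = np.median(np.abs(block - m[:, None]), axis=1)

    # Edges: symmetric truncation.
    for i in range(min(h, n)):
        for j in (i, n - 1 - i):
            k = min(h, j, n - 1 - j)
            med[j], mad[j] = _hampel_stats_window(x[j - k : j + k + 1])

    out = x.copy()
    with np.errstate(invalid="ignore"):
        # threshold=inf with MAD=0 gives nan; the comparison is then False,
        # i.e. nothing exceeds an infinite threshold
        outlier = np.abs(x - med) > threshold * MAD_SCALE * mad
    out[outlier] = med[outlier]
    return out


def _design_bandpass(sampling_rate: float, params: FilterParams) -> np.ndarray:
    low_hz = params.bp_low / 60.0
    high_hz = params.bp_high / 60.0
    nyquist = sampling_rate / 2.0
    if high_hz >= nyquist:
        raise InputError(
            f"band-pass upper cutoff {params.bp_high} cpm ({high_hz:.4g} Hz) is at or above "
            f"Nyquist ({nyquist:.4g} Hz) for rate {sampling_rate}"
        )
    return sps.butter(params.bp_order, [low_hz, high_hz], btype="bandpass", fs=sampling_rate, output="sos")


def bandpass(x: np.ndarray, sampling_rate: float, params: FilterParams) -> np.ndarray:
    """Zero-phase Butterworth band-pass (applied forward and backward)."""
    sos = _design_bandpass(sampling_rate, params)
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float))


def bandpass_gain(freq_cpm: float, sampling_rate: float, params: FilterParams) -> float:
    """Magnitude response of the zero-phase filter at ``freq_cpm`` (the
    forward-backward application squares the single-pass magnitude)."""
    sos = _design_bandpass(sampling_rate, params)
    _, h = sps.sosfreqz(sos, worN=[2 * np.pi * freq_cpm / 60.0 / sampling_rate])
    return float(np.abs(h[0]) ** 2)


def preprocess(recording: EGGRecording, params: FilterParams) -> EGGRecording:
    """demean -> hampel -> bandpass, per sensor, in that order."""
    rec = demean(recording)
    values = rec.values()
    cleaned = np.column_stack(
        [
            bandpass(
                hampel(values[:, ch], params.hampel_window, params.hampel_threshold),
                rec.sampling_rate,
                params,
            )
            for ch in range(values.shape[1])
        ]
    )
    return rec.with_values(cleaned)


# ---------------------------------------------------------------------------
# Spectrum estimation (shared by SNR screening and block spectra)


def _hann_power_spectrum(segment: np.ndarray, sampling_rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Hann-windowed periodogram.

    Normalised so that ``sum(power) == mean((w*x)**2) / mean(w**2)``; the
    frequency grid is returned in cycles/min.
    """
    segment = np.asarray(segment, dtype=float)
    n = len(segment)
    window = sps.windows.hann(n, sym=False)
    spectrum = np.fft.rfft(window * segment)
    power = np.abs(spectrum) ** 2
    scale = np.full(len(power), 2.0)
    scale[0] = 1.0
    if n % 2 == 0:
        scale[-1] = 1.0
    power = power * scale / (n * np.sum(window**2))
    freqs_cpm = np.fft.rfftfreq(n, d=1.0 / sampling_rate) * 60.0
    return freqs_cpm, power


# ---------------------------------------------------------------------------
# ICA decomposition and SNR screening


@dataclass
class ComponentDecomposition:
    """Unmixed sources with their normogastric SNRs.

    ``sources @ mixing.T + mean`` reconstructs the preprocessed channels.
    ``kept`` is filled by :func:`select_and_reconstruct`.
    """

    sources: np.ndarray  # (n_samples, n_components)
    mixing: np.ndarray  # (n_sensors, n_components)
    mean: np.ndarray  # (n_sensors,)
    snr: np.ndarray  # (n_components,)
    seed: int
    converged: bool
    preprocessed: EGGRecording
    kept: list[int] = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.sources.shape[1]

    def reconstruct(self, component_indices: list[int] | None = None) -> np.ndarray:
        idx = list(range(self.n_components)) if component_indices is None else component_indices
        return self.sources[:, idx] @ self.mixing[:, idx].T + self.mean


def component_snr(
    source: np.ndarray,
    sampling_rate: float,
    normo_band: tuple[float, float] = NORMO_BAND,
    analysis_band: tuple[float, float] = (0.5, 10.0),
) -> float:
    """Peak normogastric power over mean power at the remaining analysed
    frequencies.

    Returns ``inf`` (with a warning) when the denominator is zero.
    """
    source = np.asarray(source, dtype=float)
    duration_s = len(source) / sampling_rate
    resolution_cpm = 60.0 / duration_s
    if resolution_cpm > 0.5:
        raise InputError(
            f"source of {duration_s:.1f} s gives {resolution_cpm:.2f} cpm resolution; "
            "need at least 0.5 cpm (>= 120 s)"
        )
    freqs, power = _hann_power_spectrum(source, sampling_rate)
    in_analysis = (freqs >= analysis_band[0]) & (freqs <= analysis_band[1])
    in_normo = in_analysis & (freqs >= normo_band[0]) & (freqs <= normo_band[1])
    out_normo = in_analysis & ~in_normo
    if not in_normo.any() or not out_normo.any():
        raise InputError("frequency grid has no bins inside or outside the normogastric band")
    numerator = float(power[in_normo].max())
    denominator = float(power[out_normo].mean())
    if denominator == 0.0:
        warnings.warn("zero power outside the normogastric band; SNR is infinite", stacklevel=2)
        return np.inf
    return numerator / denominator


def decompose(
    recording: EGGRecording, n_components: int = 4, seed: int = 0, max_iter: int = 500, tol: float = 1e-4
) -> ComponentDecomposition:
    """ICA of the preprocessed channels into ``n_components`` sources.

    Non-convergence is flagged on the result (``converged=False``), never
    silently ignored.
    """
    values = recording.values()
    if n_components > values.shape[1]:
        raise InputError(f"cannot extract {n_components} components from {values.shape[1]} channels")
    if not np.isfinite(values).all():
        raise InputError("recording contains non-finite values")
    ica = FastICA(
        n_components=n_components,
        whiten="unit-variance",
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    )
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        sources = ica.fit_transform(values)
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            converged = False
    snr = np.array([component_snr(sources[:, k], recording.sampling_rate) for k in range(n_components)])
    return ComponentDecomposition(
        sources=sources,
        mixing=ica.mixing_,
        mean=ica.mean_,
        snr=snr,
        seed=seed,
        converged=converged,
        preprocessed=recording,
    )


def select_and_reconstruct(
    decomposition: ComponentDecomposition, threshold: float = 3.0
) -> tuple[EGGRecording | None, list[int]]:
    """Keep components with SNR >= ``threshold`` ("under 3" is excluded,
    exactly 3 is kept) and inverse-transform them.

    Returns ``(cleaned_recording, kept_indices)``; the recording is
    ``None`` when no component survives, flagging participant exclusion.
    """
    kept = [k for k in range(decomposition.n_components) if decomposition.snr[k] >= threshold]
    decomposition.kept = kept
    if not kept:
        return None, kept
    values = decomposition.reconstruct(kept)
    return decomposition.preprocessed.with_values(values), kept


# ---------------------------------------------------------------------------
# Block spectra and band summaries


@dataclass
class PowerSpectrum:
    """Sensor-averaged power spectrum of one condition block."""

    freqs_cpm: np.ndarray
    power: np.ndarray
    condition: str
    n_sensors_averaged: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freqs_cpm) <= 0) or np.any(self.freqs_cpm < 0):
            raise InputError("frequency grid must be non-negative and strictly increasing")
        if np.any(self.power < 0):
            raise InputError("power must be non-negative")


def block_spectrum(
    recording: EGGRecording,
    block_label: str,
    condition: str | None = None,
    min_cycles: float = 2.0,
    normo_freq_cpm: float = 3.0,
) -> PowerSpectrum:
    """Hann/FFT spectrum of one condition block, averaged over sensors."""
    start_s, end_s = recording.block_interval(block_label)
    fs = recording.sampling_rate
    min_s = min_cycles * 60.0 / normo_freq_cpm
    if end_s - start_s < min_s:
        raise InputError(
            f"block {block_label!r} of {end_s - start_s:.1f} s is shorter than the "
            f"minimum {min_s:.1f} s ({min_cycles:g} normogastric cycles)"
        )
    i0, i1 = int(round(start_s * fs)), int(round(end_s * fs))
    values = recording.values()[i0:i1]
    spectra = []
    freqs = None
    for ch in range(values.shape[1]):
        freqs, power = _hann_power_spectrum(values[:, ch], fs)
        spectra.append(power)
    if condition is None:
        condition = "disgust" if block_label == BLOCK_DISGUST else "neutral"
    return PowerSpectrum(freqs, np.mean(spectra, axis=0), condition, values.shape[1])


@dataclass(frozen=True)
class BandStats:
    mean: float
    sd: float
    max: float
    proportion: float


@dataclass
class BandPowerSummary:
    """Per-band, per-condition power statistics plus the normogastric peak.

    ``missing[condition]`` is True when that condition's spectrum carried
    no power in the analysed range (proportions undefined); the dependent
    statistics are then NaN rather than silently propagated.
    """

    stats: dict[str, dict[str, BandStats]]  # condition -> band -> stats
    normo_peak: dict[str, float]
    missing: dict[str, bool]
    band_edges: dict[str, tuple[float, float]]


def _band_masks(freqs: np.ndarray, brady_low: float) -> dict[str, np.ndarray]:
    # Closed normogastric band; neighbours open at the shared edges.
    normo = (freqs >= NORMO_BAND[0]) & (freqs <= NORMO_BAND[1])
    brady = (freqs >= brady_low) & (freqs < NORMO_BAND[0])
    tachy = (freqs > NORMO_BAND[1]) & (freqs <= TACHY_HIGH)
    return {"brady": brady, "normo": normo, "tachy": tachy}


def band_summary(
    spectrum_disgust: PowerSpectrum,
    spectrum_neutral: PowerSpectrum,
    brady_low: float = 0.5,
) -> BandPowerSummary:
    """Reduce the two condition spectra to per-band statistics.

    ``brady_low`` defaults to 0.5 cpm (matching the band-pass high-pass);
    0.1 is available as a documented alternative convention.
    """
    if not np.array_equal(spectrum_disgust.freqs_cpm, spectrum_neutral.freqs_cpm):
        raise InputError("condition spectra must share one frequency grid")
    freqs = spectrum_disgust.freqs_cpm
    masks = _band_masks(freqs, brady_low)
    if not all(mask.any() for mask in masks.values()):
        raise InputError("frequency grid too coarse: at least one band has no bins")

    stats: dict[str, dict[str, BandStats]] = {}
    normo_peak: dict[str, float] = {}
    missing: dict[str, bool] = {}
    for spectrum in (spectrum_disgust, spectrum_neutral):
        condition = spectrum.condition
        power = spectrum.power
        total = float(sum(power[mask].sum() for mask in masks.values()))
        missing[condition] = total <= 0.0
        per_band: dict[str, BandStats] = {}
        for band, mask in masks.items():
            band_power = power[mask]
            proportion = float(band_power.sum() / total) if total > 0 else float("nan")
            per_band[band] = BandStats(
                mean=float(band_power.mean()),
                sd=float(band_power.std(ddof=0)),
                max=float(band_power.max()),
                proportion=proportion,
            )
        stats[condition] = per_band
        normo_peak[condition] = float(power[masks["normo"]].max())
    return BandPowerSummary(
        stats=stats,
        normo_peak=normo_peak,
        missing=missing,
        band_edges={"brady": (brady_low, 2.0), "normo": NORMO_BAND, "tachy": (4.0, TACHY_HIGH)},
    )


def gastric_disgust_index(summary: BandPowerSummary) -> float:
    """ln(normogastric peak power, disgust / neutral); negative values
    indicate attenuation under disgust.  NaN (with a warning) when either
    peak is missing or non-positive."""
    peak_d = summary.normo_peak.get("disgust", float("nan"))
    peak_n = summary.normo_peak.get("neutral", float("nan"))
    if summary.missing.get("disgust") or summary.missing.get("neutral"):
        warnings.warn("gastric index undefined: all-zero spectrum", stacklevel=2)
        return float("nan")
    if not (peak_d > 0 and peak_n > 0):
        warnings.warn("gastric index undefined: non-positive normogastric peak", stacklevel=2)
        return float("nan")
    return float(np.log(peak_d / peak_n))


# ---------------------------------------------------------------------------
# Orchestration


@dataclass
class PipelineResult:
    participant_id: str
    preprocessed: EGGRecording
    decomposition: ComponentDecomposition
    cleaned: EGGRecording | None
    excluded: bool
    spectrum_disgust: PowerSpectrum | None
    spectrum_neutral: PowerSpectrum | None
    summary: BandPowerSummary | None
    index: float


def run_pipeline(
    recording: EGGRecording,
    params: FilterParams | None = None,
    n_components: int = 4,
    seed: int = 0,
    snr_threshold: float = 3.0,
    brady_low: float = 0.5,
) -> PipelineResult:
    """Full chain from raw recording to band summary and gastric index."""
    if params is None:
        params = FilterParams.for_rate(recording.sampling_rate)
    pre = preprocess(recording, params)
    dec = decompose(pre, n_components=n_components, seed=seed)
    cleaned, _kept = select_and_reconstruct(dec, threshold=snr_threshold)
    if cleaned is None:
        return PipelineResult(
            recording.participant_id, pre, dec, None, True, None, None, None, float("nan")
        )
    spec_d = block_spectrum(cleaned, BLOCK_DISGUST)
    spec_n = block_spectrum(cleaned, BLOCK_NEUTRAL)
    summary = band_summary(spec_d, spec_n, brady_low=brady_low)
    index = gastric_disgust_index(summary)
    return PipelineResult(
        recording.participant_id, pre, dec, cleaned, False, spec_d, spec_n, summary, index
    )
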