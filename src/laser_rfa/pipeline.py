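"""Resonance-frequency extraction from trigger-synchronized vibrometer records.

The measurement chain converts a laser-Doppler-vibrometer velocity trace into a
single resonance frequency (RF):

1. ``segment_pulses``   — cut the record into one segment per excitation pulse,
   aligned on the laser Q-switch trigger times;
2. ``average_segments`` — pointwise (time-synchronous) average of the segments,
   suppressing uncorrelated noise by ~1/sqrt(N);
3. ``purge_early``      — discard the first 4.5 ms after the trigger, where the
   laser-ablation plume/plasma transient contaminates the signal;
4. ``compute_spectrum`` — magnitude FFT under a rectangular (boxcar) window;
5. ``detect_rf``        — the frequency of the highest magnitude inside the
   1000–5000 Hz search band.

``analyze_record`` composes the five stages.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "VibrationRecord",
    "PulseSegment",
    "AnalysisWindow",
    "FrequencySpectrum",
    "ResonanceResult",
    "segment_pulses",
    "average_segments",
    "purge_early",
    "compute_spectrum",
    "detect_rf",
    "analyze_record",
    "DEFAULT_BAND",
]

#: Default RF search band in Hz: the peak is looked up in 1000–5000 Hz only.
DEFAULT_BAND: tuple[float, float] = (1000.0, 5000.0)


@dataclass(frozen=True)
class VibrationRecord:
    """A sampled single-channel velocity trace with excitation trigger times.

    Parameters
    ----------
    samples : ndarray
        Velocity samples (arbitrary velocity units unless ``units`` says
        otherwise).
    sampling_rate : float
        Samples per second (Hz).
    trigger_times : ndarray
        Laser-pulse trigger instants in seconds, sorted strictly increasing,
        all inside ``[0, duration)``.
    units : str
        Label for the sample values, e.g. ``"mm/s"`` or ``"a.u."``.
    """

    samples: np.ndarray
    sampling_rate: float
    trigger_times: np.ndarray
    units: str = "a.u."

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        object.__setattr__(
            self, "trigger_times", np.asarray(self.trigger_times, dtype=float)
        )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.samples.ndim != 1:
            raise ValueError("samples must be a one-dimensional sequence")
        t = self.trigger_times
        if t.ndim != 1 or t.size == 0:
            raise ValueError("at least one trigger time is required")
        if np.any(np.diff(t) <= 0):
            raise ValueError("trigger_times must be sorted strictly increasing")
        if t[0] < 0 or t[-1] >= self.duration:
            raise ValueError(
                f"trigger_times must lie within [0, {self.duration:g}) s"
            )

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.sampling_rate

    @property
    def n_triggers(self) -> int:
        return int(self.trigger_times.size)


@dataclass(frozen=True)
class PulseSegment:
    """One trigger-aligned slice of a record (or an average of such slices)."""

    samples: np.ndarray
    sampling_rate: float
    time_origin: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate


@dataclass(frozen=True)
class AnalysisWindow:
    """Per-pulse analysis window: segment length and early-time purge.

    ``purge_time`` (default 4.5 ms) is the post-trigger interval discarded to
    remove the broadband ablation transient; ``segment_length`` (default
    100 ms, one 10 Hz inter-pulse period) is the analyzed span per pulse.
    """

    purge_time: float = 0.0045
    segment_length: float = 0.1

    def __post_init__(self) -> None:
        if not 0 <= self.purge_time < self.segment_length:
            raise ValueError(
                "require 0 <= purge_time < segment_length "
                f"(got purge_time={self.purge_time}, "
                f"segment_length={self.segment_length})"
            )


@dataclass(frozen=True)
class FrequencySpectrum:
    """One-sided magnitude spectrum on a uniform grid starting at 0 Hz."""

    frequencies: np.ndarray
    magnitudes: np.ndarray
    resolution: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "frequencies", np.asarray(self.frequencies, dtype=float)
        )
        object.__setattr__(
            self, "magnitudes", np.asarray(self.magnitudes, dtype=float)
        )
        if self.frequencies.shape != self.magnitudes.shape:
            raise ValueError("frequencies and magnitudes must have equal shape")
        if np.any(self.magnitudes < 0):
            raise ValueError("magnitudes must be non-negative")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")


@dataclass(frozen=True)
class ResonanceResult:
    """Detected resonance frequency with its search band and provenance."""

    rf: float
    peak_magnitude: float
    search_band: tuple[float, float] = DEFAULT_BAND
    resolution: float = float("nan")
    n_segments: int | None = None

    def __post_init__(self) -> None:
        low, high = self.search_band
        if not low <= self.rf <= high:
            raise ValueError(
                f"rf={self.rf} outside search band [{low}, {high}]"
            )

    def to_dict(self) -> dict:
        return {
            "rf_hz": self.rf,
            "peak_magnitude": self.peak_magnitude,
            "band_hz": list(self.search_band),
            "resolution_hz": self.resolution,
            "n_segments": self.n_segments,
        }


def _trigger_start_index(t: float, sampling_rate: float) -> int:
    """Nearest sample index at or after time ``t`` (with float-rounding grace)."""
    exact = t * sampling_rate
    nearest = round(exact)
    if math.isclose(exact, nearest, rel_tol=0.0, abs_tol=1e-9 * max(1.0, exact)):
        return int(nearest)
    return int(math.ceil(exact))


def segment_pulses(
    record: VibrationRecord, window: AnalysisWindow | None = None
) -> list[PulseSegment]:
    """Divide a record into one segment per usable trigger.

    Each segment starts at its trigger sample and spans ``segment_length``
    (half-open in samples). Triggers without a full window of signal after
    them are dropped with a warning.

    Raises
    ------
    ValueError
        If no trigger has a complete analysis window.
    """
    window = window or AnalysisWindow()
    n_seg = round(window.segment_length * record.sampling_rate)
    if n_seg < 2:
        raise ValueError("segment_length too short for the sampling rate")

    segments: list[PulseSegment] = []
    dropped: list[float] = []
    for t in record.trigger_times:
        start = _trigger_start_index(float(t), record.sampling_rate)
        if start + n_seg <= record.samples.size:
            segments.append(
                PulseSegment(
                    samples=record.samples[start : start + n_seg],
                    sampling_rate=record.sampling_rate,
                    time_origin=float(t),
                )
            )
        else:
            dropped.append(float(t))
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} trigger(s) without a full "
            f"{window.segment_length:g} s window: {dropped}",
            stacklevel=2,
        )
    if not segments:
        raise ValueError("no trigger has a complete analysis window")
    return segments


def average_segments(segments: list[PulseSegment]) -> PulseSegment:
    """Pointwise arithmetic mean of trigger-aligned segments.

    All segments must share length and sampling rate. The average keeps the
    coherent (trigger-locked) vibration while uncorrelated noise variance
    falls as 1/N.
    """
    if not segments:
        raise ValueError("need at least one segment to average")
    n = segments[0].samples.size
    fs = segments[0].sampling_rate
    for s in segments[1:]:
        if s.samples.size != n:
            raise ValueError("segments have mixed lengths")
        if s.sampling_rate != fs:
            raise ValueError("segments have mixed sampling rates")
    # reduce along the fast axis so numpy's pairwise summation applies: the
    # mean of 2^k identical segments is then bit-exact
    mean = np.mean(np.stack([s.samples for s in segments], axis=-1), axis=-1)
    return PulseSegment(samples=mean, sampling_rate=fs, time_origin=0.0)


def purge_early(
    segment: PulseSegment, window: AnalysisWindow | None = None
) -> PulseSegment:
    """Discard the first ``purge_time`` seconds (the ablation transient).

    Returns the samples from ``purge_time`` to the segment end; the retained
    length is ``round((segment_length - purge_time) * sampling_rate)`` when the
    segment spans the full window.
    """
    window = window or AnalysisWindow()
    if window.purge_time >= segment.duration:
        raise ValueError(
            f"purge_time {window.purge_time:g} s >= segment duration "
            f"{segment.duration:g} s"
        )
    start = round(window.purge_time * segment.sampling_rate)
    return PulseSegment(
        samples=segment.samples[start:],
        sampling_rate=segment.sampling_rate,
        time_origin=segment.time_origin + start / segment.sampling_rate,
    )


def compute_spectrum(
    segment: PulseSegment, *, remove_mean: bool = True, pad_pow2: bool = False
) -> FrequencySpectrum:
    """Magnitude spectrum under a rectangular window.

    The segment mean is subtracted by default so DC leakage does not spill
    into the low edge of the search band; the rectangular window means the
    samples enter the FFT untapered. ``pad_pow2`` zero-pads to the next power
    of two, refining the frequency grid (the resolution metadata follows the
    transform length).
    """
    x = segment.samples
    if x.size < 2:
        raise ValueError("segment must contain at least 2 samples")
    if remove_mean:
        x = x - x.mean()
    n = x.size
    nfft = 1 << (n - 1).bit_length() if pad_pow2 else n
    spectrum = np.abs(np.fft.rfft(x, n=nfft))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / segment.sampling_rate)
    return FrequencySpectrum(
        frequencies=freqs,
        magnitudes=spectrum,
        resolution=segment.sampling_rate / nfft,
    )


def detect_rf(
    spectrum: FrequencySpectrum, band: tuple[float, float] = DEFAULT_BAND
) -> ResonanceResult:
    """Resonance frequency: argmax of magnitude inside the closed band.

    Ties are broken toward the lowest frequency; spectral maxima outside the
    band are ignored.
    """
    low, high = band
    if low > high:
        raise ValueError(f"band low {low} exceeds band high {high}")
    if high > spectrum.frequencies[-1] + 1e-9 or low < 0:
        raise ValueError(
            f"band [{low}, {high}] exceeds the spectrum grid "
            f"[0, {spectrum.frequencies[-1]:g}]"
        )
    mask = (spectrum.frequencies >= low) & (spectrum.frequencies <= high)
    if not mask.any():
        raise ValueError(f"band [{low}, {high}] contains no grid point")
    idx = np.flatnonzero(mask)
    # np.argmax returns the first maximum -> lowest frequency on the
    # ascending grid, which is the documented tie-break.
    best = idx[np.argmax(spectrum.magnitudes[idx])]
    return ResonanceResult(
        rf=float(spectrum.frequencies[best]),
        peak_magnitude=float(spectrum.magnitudes[best]),
        search_band=(low, high),
        resolution=spectrum.resolution,
    )


def analyze_record(
    record: VibrationRecord,
    window: AnalysisWindow | None = None,
    band: tuple[float, float] = DEFAULT_BAND,
) -> ResonanceResult:
    """Full chain: segment -> average -> purge -> spectrum -> detect.

    Raises
    ------
    ValueError
        ``"no signal"`` for an all-zero record (no resonance to detect), plus
        whatever the individual stages raise.
    """
    window = window or AnalysisWindow()
    segments = segment_pulses(record, window)
    averaged = average_segments(segments)
    purged = purge_early(averaged, window)
    if not np.any(purged.samples - purged.samples.mean()):
        raise ValueError("no signal: record is constant after averaging and purge")
    spectrum = compute_spectrum(purged)
    result = detect_rf(spectrum, band)
    return ResonanceResult(
        rf=result.rf,
        peak_magnitude=result.peak_magnitude,
        search_band=result.search_band,
        resolution=result.resolution,
        n_segments=len(segments),
    )
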