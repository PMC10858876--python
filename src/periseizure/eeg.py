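"""EEG preprocessing and spectral quantification.

The seizure-intensity measure used throughout the package is the integrated
4-14 Hz power of the EEG in the 30 s following seizure induction.  The chain
is: zero-phase low-pass at 100 Hz plus a second-order 50 Hz notch, Welch
power spectral density over non-overlapping 1-s Hann-tapered epochs, then a
trapezoidal integral of the PSD over the band of interest.

Conventions
-----------
* Time is seconds from the start of the recording; analysis windows are
  half-open ``[start, end)``.
* The PSD is one-sided with density normalization (units uV^2/Hz), so the
  integral over ``[0, fs/2]`` equals the analyzed window's variance
  (Parseval) for stationary signals, and "band power" carries units of
  uV^2.  Per-segment means are *not* subtracted, so a DC offset shows up
  in the 0 Hz bin rather than silently vanishing.
* Welch epochs are non-overlapping 1-s segments; a trailing partial
  second is discarded.  The spectrogram is the per-epoch stack of the same
  periodograms, so averaging its columns reproduces the Welch estimate
  exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .errors import PeriSeizureError, SamplingRateError, WindowError

__all__ = [
    "EEGRecording",
    "SpectralEstimate",
    "BandPowerResult",
    "Spectrogram",
    "preprocess",
    "welch_psd",
    "band_power",
    "seizure_power",
    "spectrogram",
]

DEFAULT_BAND = (4.0, 14.0)
SEIZURE_ANALYSIS_S = 30.0


@dataclass
class EEGRecording:
    """A uniformly sampled voltage trace (uV) with stimulation-event annotations.

    ``events`` is a list of ``(onset_s, label, stim_hz)`` tuples; the seizure
    induction event carries the optogenetic stimulation frequency.
    """

    samples: np.ndarray
    fs: float
    events: list[tuple[float, str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise PeriSeizureError("EEG samples must be one-dimensional")
        if not self.fs > 0:
            raise PeriSeizureError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise PeriSeizureError("EEG samples contain non-finite values")
        for onset, label, _ in self.events:
            if not 0.0 <= onset <= self.duration_s:
                raise PeriSeizureError(
                    f"event '{label}' at {onset} s lies outside [0, {self.duration_s}] s"
                )

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(len(self.samples)) / self.fs


@dataclass
class SpectralEstimate:
    """One-sided Welch PSD (uV^2/Hz) averaged over 1-s epochs of a window."""

    frequencies: np.ndarray
    psd: np.ndarray
    epoch_count: int
    band: tuple[float, float]
    window: tuple[float, float]


@dataclass
class BandPowerResult:
    """Integrated PSD (uV^2) over a frequency band within a time window."""

    band_power: float
    band: tuple[float, float]
    window: tuple[float, float]


@dataclass
class Spectrogram:
    """Per-1-s-epoch PSDs: ``power[i, j]`` is frequency i, epoch j (uV^2/Hz)."""

    frequencies: np.ndarray
    times: np.ndarray  # epoch start times, s
    power: np.ndarray  # shape (n_frequencies, n_epochs)


def preprocess(
    rec: EEGRecording,
    lowpass_hz: float = 100.0,
    notch_hz: float = 50.0,
    notch_q: float = 30.0,
    lowpass_order: int = 4,
) -> EEGRecording:
    """Zero-phase low-pass (Butterworth, 4th order) then 50 Hz notch (2nd order).

    Both filters are applied forward-backward (``filtfilt``), so the quoted
    orders describe the design; the effective magnitude response is squared
    and the phase is zero.  Events and sampling rate are preserved.
    """
    if rec.fs <= 2 * lowpass_hz:
        raise SamplingRateError(
            f"sampling rate {rec.fs} Hz too low for a {lowpass_hz} Hz low-pass"
        )
    sos = signal.butter(lowpass_order, lowpass_hz, btype="low", fs=rec.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.samples)
    b, a = signal.iirnotch(notch_hz, notch_q, fs=rec.fs)
    filtered = signal.filtfilt(b, a, filtered)
    return replace(rec, samples=filtered, events=list(rec.events))


def _window_slice(rec: EEGRecording, window: tuple[float, float]) -> np.ndarray:
    start, end = window
    if not (0.0 <= start < end <= rec.duration_s + 1e-9):
        raise WindowError(
            f"window [{start}, {end}) s outside recording of {rec.duration_s} s"
        )
    i0 = int(round(start * rec.fs))
    i1 = int(round(end * rec.fs))
    return rec.samples[i0:i1]


def _segment_periodograms(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Hann-tapered one-sided periodograms of consecutive 1-s segments.

    Returns ``(frequencies, psd)`` with ``psd`` of shape (n_segments, n_freq).
    Density normalization: ``sum(psd) * df`` of white noise estimates its
    variance.  No per-segment detrending.
    """
    n = int(round(fs))
    n_seg = len(x) // n
    if n_seg < 1:
        raise WindowError("window shorter than one 1-s epoch")
    segs = x[: n_seg * n].reshape(n_seg, n)
    taper = signal.get_window("hann", n)
    scale = 1.0 / (fs * float(np.sum(taper * taper)))
    spec = np.fft.rfft(segs * taper, axis=1)
    psd = (spec.real**2 + spec.imag**2) * scale
    if n % 2 == 0:
        psd[:, 1:-1] *= 2.0  # last bin is Nyquist, not doubled
    else:
        psd[:, 1:] *= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs, psd


def welch_psd(rec: EEGRecording, window: tuple[float, float]) -> SpectralEstimate:
    """Welch PSD over ``[start, end)``: mean of non-overlapping 1-s periodograms."""
    x = _window_slice(rec, window)
    if len(x) < int(round(rec.fs)):
        raise WindowError("window must span at least 1 s")
    freqs, psd = _segment_periodograms(x, rec.fs)
    return SpectralEstimate(
        frequencies=freqs,
        psd=psd.mean(axis=0),
        epoch_count=psd.shape[0],
        band=(0.0, rec.fs / 2.0),
        window=(float(window[0]), float(window[1])),
    )


def band_power(
    est: SpectralEstimate, band: tuple[float, float] = DEFAULT_BAND
) -> BandPowerResult:
    """Trapezoidal integral of the PSD over ``[band_lo, band_hi]`` (uV^2)."""
    lo, hi = band
    f = est.frequencies
    if not (f[0] <= lo < hi <= f[-1]):
        raise PeriSeizureError(
            f"band [{lo}, {hi}] Hz outside the frequency grid [{f[0]}, {f[-1]}] Hz"
        )
    mask = (f >= lo) & (f <= hi)
    power = float(np.trapezoid(est.psd[mask], f[mask]))
    return BandPowerResult(band_power=power, band=(float(lo), float(hi)), window=est.window)


def seizure_power(
    rec: EEGRecording,
    induction_s: float,
    band: tuple[float, float] = DEFAULT_BAND,
    analysis_s: float = SEIZURE_ANALYSIS_S,
    pre_filtered: bool = False,
) -> BandPowerResult:
    """Integrated band power over the 30 s following seizure induction.

    This scalar ("EEG power") is the response variable of the encoding model.
    Set ``pre_filtered=True`` to skip :func:`preprocess` when the recording
    has already been filtered.
    """
    if induction_s + analysis_s > rec.duration_s + 1e-9:
        raise WindowError(
            f"analysis window [{induction_s}, {induction_s + analysis_s}) s "
            f"exceeds recording of {rec.duration_s} s"
        )
    clean = rec if pre_filtered else preprocess(rec)
    est = welch_psd(clean, (induction_s, induction_s + analysis_s))
    return band_power(est, band)


def spectrogram(rec: EEGRecording, window: tuple[float, float]) -> Spectrogram:
    """Time-frequency map: one PSD column per 1-s epoch of ``[start, end)``."""
    x = _window_slice(rec, window)
    if len(x) < int(round(rec.fs)):
        raise WindowError("window must span at least 1 s")
    freqs, psd = _segment_periodograms(x, rec.fs)
    times = window[0] + np.arange(psd.shape[0], dtype=float)
    return Spectrogram(frequencies=freqs, times=times, power=psd.T)
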