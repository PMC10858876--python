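"""Dual-excitation fiber-photometry correction and epoch summaries.

The 465 nm channel reports calcium-dependent GCaMP fluorescence plus
bleaching, movement artifacts and noise; the 405 nm (isosbestic) channel
reports the same bleaching and movement but no calcium signal.  The
correction chain, applied independently to each channel and then combined:

1. linear bleach detrend over a 6-min analysis window centered on seizure
   induction, with the line anchored at the *medians* of the first and last
   50 s of that window (robust to calcium transients);
2. z-scoring by the median and standard deviation of the 60 s immediately
   preceding induction;
3. pointwise subtraction of the z-scored 405 trace from the z-scored 465
   trace.

The per-seizure summaries are the mean corrected activity over the 60 s
before induction (``pre_mean``) and over the seizure interval
(``during_mean``); these are the predictors of the encoding model.

Note a structural property of median-baseline z-scoring: because the
pre-seizure mean is computed on the same window that supplies the median
and SD, it can never exceed 1 z-unit (mean minus median is at most one SD
for any sample).  Pre-seizure activity is therefore naturally reported on
a bounded scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import (
    AlignmentError,
    DegenerateBaselineError,
    PeriSeizureError,
    WindowError,
)

__all__ = [
    "PhotometryRecording",
    "CorrectedTrace",
    "EpochActivity",
    "detrend_linear",
    "zscore_baseline",
    "motion_correct",
    "correct_recording",
    "epoch_activity",
]

BASELINE_S = 60.0
ANALYSIS_HALFWIDTH_S = 180.0
FLANK_S = 50.0
MIN_FLANK_S = 10.0


@dataclass
class PhotometryRecording:
    """Paired 465/405 fluorescence traces (a.u.) on a shared time grid."""

    time_s: np.ndarray
    f465: np.ndarray
    f405: np.ndarray
    fs: float
    induction_s: float

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.f465 = np.asarray(self.f465, dtype=float)
        self.f405 = np.asarray(self.f405, dtype=float)
        if not (len(self.time_s) == len(self.f465) == len(self.f405)):
            raise AlignmentError("time, 465 and 405 arrays must have equal length")
        if not self.fs > 0:
            raise PeriSeizureError(f"sampling rate must be positive, got {self.fs}")
        if not (np.all(np.isfinite(self.f465)) and np.all(np.isfinite(self.f405))):
            raise PeriSeizureError("fluorescence traces contain non-finite values")
        if not self.time_s[0] <= self.induction_s <= self.time_s[-1]:
            raise PeriSeizureError(
                f"induction at {self.induction_s} s outside the recorded interval"
            )


@dataclass
class CorrectedTrace:
    """Motion- and bleach-corrected activity in baseline z-units."""

    time_s: np.ndarray
    z: np.ndarray
    baseline_window: tuple[float, float]
    analysis_window: tuple[float, float]


@dataclass
class EpochActivity:
    """Mean corrected activity before and during one seizure (z-units)."""

    pre_mean: float
    during_mean: float


def _analysis_window(
    time_s: np.ndarray, induction_s: float, halfwidth_s: float = ANALYSIS_HALFWIDTH_S
) -> tuple[tuple[float, float], float]:
    """Clip the centered analysis window to the record; scale the flanks.

    Returns ``((start, end), flank_s)``.  When the record is shorter than
    the nominal 6-min window the flanks shrink proportionally, with a 10-s
    floor.
    """
    dt = float(time_s[1] - time_s[0]) if len(time_s) > 1 else 0.0
    start = max(float(time_s[0]), induction_s - halfwidth_s)
    end = min(float(time_s[-1]) + dt, induction_s + halfwidth_s)
    length = end - start
    if length < 100.0:
        raise WindowError(
            f"analysis window of {length:.1f} s too short (< 100 s) for detrending"
        )
    nominal = 2.0 * halfwidth_s
    flank = FLANK_S if length >= nominal else max(MIN_FLANK_S, FLANK_S * length / nominal)
    if length < nominal:
        warnings.warn(
            f"record shorter than the {nominal:.0f}-s analysis window; "
            f"clipped to [{start:.1f}, {end:.1f}) s with {flank:.1f}-s flanks",
            stacklevel=2,
        )
    return (start, end), flank


def detrend_linear(
    values: np.ndarray,
    time_s: np.ndarray,
    analysis_window: tuple[float, float],
    flank_s: float = FLANK_S,
) -> np.ndarray:
    """Remove the bleaching line anchored at the flank medians.

    The line passes through ``(center of first flank, median of first
    flank)`` and ``(center of last flank, median of last flank)`` of the
    analysis window, and is subtracted from the whole series.  Medians make
    the anchor points insensitive to calcium transients inside the flanks,
    unlike an ordinary least-squares fit.
    """
    values = np.asarray(values, dtype=float)
    time_s = np.asarray(time_s, dtype=float)
    start, end = analysis_window
    if end - start < 2 * flank_s:
        raise WindowError(
            f"analysis window of {end - start:.1f} s cannot hold two "
            f"{flank_s:.1f}-s flanks"
        )
    first = (time_s >= start) & (time_s < start + flank_s)
    last = (time_s >= end - flank_s) & (time_s <= end)
    if first.sum() < 2 or last.sum() < 2:
        raise WindowError("too few samples in the detrend flanks")
    # anchor at the mean flank time (= median time on a uniform grid) so a
    # perfectly linear trace is removed exactly
    t1, m1 = float(np.mean(time_s[first])), float(np.median(values[first]))
    t2, m2 = float(np.mean(time_s[last])), float(np.median(values[last]))
    slope = (m2 - m1) / (t2 - t1)
    return values - (m1 + slope * (time_s - t1))


def zscore_baseline(
    values: np.ndarray,
    time_s: np.ndarray,
    induction_s: float,
    baseline_s: float = BASELINE_S,
) -> np.ndarray:
    """z-score by the median and SD of ``[induction - 60 s, induction)``.

    The median (not the mean) anchors the baseline, so sparse calcium
    transients raise the pre-seizure mean instead of being absorbed into
    the reference level.  SD is the ordinary (population) standard
    deviation.
    """
    values = np.asarray(values, dtype=float)
    time_s = np.asarray(time_s, dtype=float)
    if induction_s - baseline_s < time_s[0] - 1e-9:
        raise WindowError(
            f"need {baseline_s:.0f} s of data before induction at {induction_s} s"
        )
    mask = (time_s >= induction_s - baseline_s) & (time_s < induction_s)
    base = values[mask]
    if len(base) < 2:
        raise WindowError("baseline window contains too few samples")
    sd = float(np.std(base))
    if sd == 0.0:
        raise DegenerateBaselineError("baseline standard deviation is zero")
    return (values - float(np.median(base))) / sd


def motion_correct(z465: np.ndarray, z405: np.ndarray) -> np.ndarray:
    """Pointwise isosbestic subtraction: ``z465 - z405``."""
    z465 = np.asarray(z465, dtype=float)
    z405 = np.asarray(z405, dtype=float)
    if z465.shape != z405.shape:
        raise AlignmentError("465 and 405 z-traces must share one grid")
    return z465 - z405


def correct_recording(
    rec: PhotometryRecording, halfwidth_s: float = ANALYSIS_HALFWIDTH_S
) -> CorrectedTrace:
    """Full correction chain for one recording.

    Detrends and z-scores each channel, subtracts the isosbestic trace, and
    returns the corrected activity restricted to the analysis window.  A
    405 channel whose baseline is constant (e.g. motion-free synthetic
    data) carries no artifact information; it is then skipped with a
    warning rather than failing the whole session.
    """
    window, flank = _analysis_window(rec.time_s, rec.induction_s, halfwidth_s)
    d465 = detrend_linear(rec.f465, rec.time_s, window, flank)
    d405 = detrend_linear(rec.f405, rec.time_s, window, flank)
    z465 = zscore_baseline(d465, rec.time_s, rec.induction_s)
    try:
        z405 = zscore_baseline(d405, rec.time_s, rec.induction_s)
    except DegenerateBaselineError:
        warnings.warn(
            "isosbestic channel baseline is constant; skipping motion subtraction",
            stacklevel=2,
        )
        z405 = np.zeros_like(z465)
    z = motion_correct(z465, z405)
    in_window = (rec.time_s >= window[0]) & (rec.time_s < window[1])
    return CorrectedTrace(
        time_s=rec.time_s[in_window],
        z=z[in_window],
        baseline_window=(rec.induction_s - BASELINE_S, rec.induction_s),
        analysis_window=window,
    )


def epoch_activity(
    ct: CorrectedTrace,
    induction_s: float,
    seizure_duration_s: float,
    stim_duration_s: float = 10.0,
) -> EpochActivity:
    """Mean corrected activity pre- and during one seizure.

    ``pre_mean`` averages ``[induction - 60 s, induction)``; ``during_mean``
    averages ``[induction, induction + max(seizure_duration_s,
    stim_duration_s))`` so that a stimulation that provokes no
    after-discharge still yields a defined during-seizure epoch.
    """
    if seizure_duration_s < 0:
        raise PeriSeizureError("seizure duration must be non-negative")
    t = ct.time_s
    pre = (t >= induction_s - BASELINE_S) & (t < induction_s)
    if not pre.any() or t[0] > induction_s - BASELINE_S + 1e-9:
        raise WindowError("corrected trace does not cover the 60-s pre-induction window")
    during_len = max(seizure_duration_s, stim_duration_s)
    during = (t >= induction_s) & (t < induction_s + during_len)
    if not during.any():
        raise WindowError("corrected trace does not cover the during-seizure window")
    return EpochActivity(
        pre_mean=float(np.mean(ct.z[pre])), during_mean=float(np.mean(ct.z[during]))
    )
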