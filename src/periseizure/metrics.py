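"""Seizure-level and behavior-level summary statistics.

After-discharge detection replaces the study's visual seizure call with a
threshold rule on the 1-s 4-14 Hz band-power envelope; its parameters
(threshold in baseline SDs, minimum event length, merge gap) are surrogate
defaults and are echoed into every result.  Sleep metrics operate on
hypnograms of fixed 5-s epochs; behavioral ratios are simple arithmetic
kept here so their conventions (rounding, bounds) live in one place.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from . import eeg
from .errors import PeriSeizureError, WindowError

__all__ = [
    "SeizureOutcome",
    "Hypnogram",
    "FragmentationResult",
    "SLEEP_STATES",
    "detect_afterdischarge",
    "seizure_probability",
    "percent_half_up",
    "fragmentation_index",
    "state_percentages",
    "sucrose_preference",
]

SLEEP_STATES = ("Wake", "NREM", "REM")


@dataclass
class SeizureOutcome:
    """Per-stimulation result: was a seizure provoked, and how long/strong."""

    provoked: bool
    duration_s: float
    band_power: float
    stim_hz: float
    detection_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.duration_s < 0:
            raise PeriSeizureError("ictal duration cannot be negative")
        if self.provoked != (self.duration_s > 0):
            raise PeriSeizureError("provoked flag must equal (duration_s > 0)")


@dataclass
class Hypnogram:
    """Ordered sleep-state labels (Wake/NREM/REM), one per fixed 5-s epoch."""

    states: list[str]
    epoch_s: float = 5.0

    def __post_init__(self) -> None:
        self.states = list(self.states)
        if not self.states:
            raise PeriSeizureError("hypnogram is empty")
        if self.epoch_s <= 0:
            raise PeriSeizureError("epoch length must be positive")
        bad = set(self.states) - set(SLEEP_STATES)
        if bad:
            raise PeriSeizureError(f"unknown sleep states: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.states)


@dataclass
class FragmentationResult:
    """Bouts of a state divided by its total epochs; in (0, 1] when defined."""

    state: str
    n_bouts: int
    n_epochs: int
    index: float
    defined: bool = True


def detect_afterdischarge(
    rec: eeg.EEGRecording,
    induction_s: float,
    stim_duration_s: float,
    k_sd: float = 3.0,
    min_len_s: float = 2.0,
    max_gap_s: float = 2.0,
    band: tuple[float, float] = eeg.DEFAULT_BAND,
    baseline_s: float = 60.0,
    onset_slack_s: float = 5.0,
    stim_hz: float | None = None,
) -> SeizureOutcome:
    """Threshold the post-stimulation band-power envelope to call a seizure.

    The envelope is the per-1-s-epoch integrated 4-14 Hz power of the
    filtered EEG.  The threshold is ``baseline mean + k_sd * baseline SD``
    over the 60 s before induction (with a small numerical floor so a
    noise-free baseline does not trip on filter ringing).  Supra-threshold
    epochs after stimulation offset are merged across gaps of at most
    ``max_gap_s``; the recording counts as *provoked* if a merged run starts
    within ``onset_slack_s`` of stimulation offset and lasts at least
    ``min_len_s``.  The whole merged run is the ictal duration.
    """
    if induction_s - baseline_s < -1e-9:
        raise WindowError(
            f"need {baseline_s:.0f} s of pre-induction baseline, induction at "
            f"{induction_s} s"
        )
    clean = eeg.preprocess(rec)
    offset_s = induction_s + stim_duration_s

    def envelope(window: tuple[float, float]) -> np.ndarray:
        sg = eeg.spectrogram(clean, window)
        mask = (sg.frequencies >= band[0]) & (sg.frequencies <= band[1])
        return np.trapezoid(sg.power[mask, :], sg.frequencies[mask], axis=0)

    base_env = envelope((induction_s - baseline_s, induction_s))
    post_end = math.floor(clean.duration_s - offset_s) + offset_s
    post_env = envelope((offset_s, post_end))
    floor = 1e-6 * max(float(post_env.max(initial=0.0)), float(base_env.max()))
    threshold = max(float(base_env.mean() + k_sd * base_env.std()), floor)

    supra = post_env > threshold
    segments: list[tuple[int, int]] = []  # maximal [start, end) supra runs
    i = 0
    while i < len(supra):
        if supra[i]:
            j = i
            while j < len(supra) and supra[j]:
                j += 1
            segments.append((i, j))
            i = j
        else:
            i += 1
    # merge segments across short dropouts into events
    events: list[list[tuple[int, int]]] = []
    for seg in segments:
        if events and seg[0] - events[-1][-1][1] <= max_gap_s:
            events[-1].append(seg)
        else:
            events.append([seg])

    provoked, duration = False, 0.0
    for event in events:
        start = event[0][0]
        # an isolated blip cannot extend the event: it ends at the last
        # merged segment that itself lasts >= min_len_s
        long_ends = [e for s, e in event if e - s >= min_len_s]
        end = long_ends[-1] if long_ends else event[-1][1]
        if start <= onset_slack_s and (end - start) >= min_len_s:
            provoked, duration = True, float(end - start)
            break

    if stim_hz is None:
        stim_events = [e for e in rec.events if abs(e[0] - induction_s) < 1e-6]
        stim_hz = stim_events[0][2] if stim_events else float("nan")
    power = eeg.seizure_power(clean, induction_s, band=band, pre_filtered=True)
    return SeizureOutcome(
        provoked=provoked,
        duration_s=duration,
        band_power=power.band_power,
        stim_hz=float(stim_hz),
        detection_params={
            "k_sd": k_sd,
            "min_len_s": min_len_s,
            "max_gap_s": max_gap_s,
            "onset_slack_s": onset_slack_s,
            "band": list(band),
            "threshold": threshold,
            "surrogate_for_visual_scoring": True,
        },
    )


def seizure_probability(outcomes: list[SeizureOutcome]) -> float:
    """Percent of stimulations that provoked a seizure: 100 * provoked / total."""
    if not outcomes:
        raise PeriSeizureError("cannot compute a probability from zero stimulations")
    return 100.0 * sum(o.provoked for o in outcomes) / len(outcomes)


def percent_half_up(percent: float) -> int:
    """Nearest-integer percent, rounding halves up (figure-legend style)."""
    return int(math.floor(percent + 0.5))


def fragmentation_index(h: Hypnogram, state: str) -> FragmentationResult:
    """Number of maximal same-state bouts divided by total epochs of that state.

    A bout is a maximal run of consecutive 5-s epochs without a state
    transition.  The index lies in (0, 1]: 1/n for one unbroken bout of n
    epochs, 1.0 when every bout lasts a single epoch.  If the state never
    occurs the result is flagged undefined (index NaN) rather than zero.
    """
    if state not in SLEEP_STATES:
        raise PeriSeizureError(f"unknown state '{state}'")
    n_epochs = sum(s == state for s in h.states)
    if n_epochs == 0:
        return FragmentationResult(state, 0, 0, float("nan"), defined=False)
    n_bouts = sum(1 for key, _ in itertools.groupby(h.states) if key == state)
    return FragmentationResult(state, n_bouts, n_epochs, n_bouts / n_epochs)


def state_percentages(
    h: Hypnogram, phase_mask: np.ndarray | None = None
) -> dict[str, float]:
    """Percent time per sleep state over the masked epochs (sums to 100)."""
    states = np.asarray(h.states)
    if phase_mask is not None:
        phase_mask = np.asarray(phase_mask)
        if phase_mask.dtype == bool:
            if len(phase_mask) != len(states):
                raise PeriSeizureError("boolean mask length mismatch")
            states = states[phase_mask]
        else:
            states = states[phase_mask.astype(int)]
    if len(states) == 0:
        raise PeriSeizureError("phase mask selects no epochs")
    return {s: 100.0 * float(np.sum(states == s)) / len(states) for s in SLEEP_STATES}


def sucrose_preference(sucrose_consumed: float, total_consumed: float) -> float:
    """Sucrose preference index: sucrose intake over total intake, in [0, 1]."""
    if total_consumed <= 0:
        raise PeriSeizureError("total consumption must be positive")
    if not 0 <= sucrose_consumed <= total_consumed:
        raise PeriSeizureError("sucrose consumption must lie in [0, total]")
    return sucrose_consumed / total_consumed
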