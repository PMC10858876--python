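"""Synthetic peri-seizure sessions with known ground truth.

Each simulated session emulates a simultaneous EEG + fiber-photometry
recording around one optogenetically induced seizure:

* **EEG** (1 kHz): Gaussian baseline noise (white by default, 1/f
  optionally), a 10-s sinusoidal stimulation artifact at 5/10/20 Hz, and a
  post-stimulation after-discharge — an amplitude-modulated oscillation
  whose instantaneous frequency sweeps downward inside the 4-14 Hz band.
  The after-discharge *amplitude* is linear in the latent activity level,
  ``amp = scale * (base + beta_pre * latent_pre + beta_during *
  latent_during)``, so its band power is quadratic in the latent — the
  parameter-recovery expectations in the tests follow from that.  Its
  *duration* also grows linearly with the same drive.  A lognormal
  session-to-session gain jitter models biological/electrode variability in
  seizure expression and sets how much seizure-power variance the latent
  can explain.
* **Photometry** (10 Hz per channel, generated already demultiplexed): the
  465 nm channel carries an offset, a linear bleach trend, spontaneous
  calcium activity, a during-seizure surge, shared motion and sensor noise;
  the 405 nm isosbestic channel carries offset, bleach, the same motion and
  its own noise.  Spontaneous activity is a regular train of calcium
  bursts whose duty cycle is chosen so that, after median-baseline
  z-scoring, the mean corrected activity over the 60 s before induction
  equals ``latent_pre`` — that is what makes the latent recoverable by the
  analysis chain.  (Because the analysis z-scores by the baseline's own
  median and SD, recoverable latents are bounded by 1; the cohort
  distribution is truncated accordingly.)
* **Hypnograms**: first-order Markov chains over Wake/NREM/REM in 5-s
  epochs.

Every generator is a pure function of ``(config, seed)``; cohort sessions
get per-session seeds derived from the master seed via
``numpy.random.SeedSequence([master_seed, index])``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal.windows import tukey

from .eeg import EEGRecording
from .errors import ConfigError, PeriSeizureError
from .metrics import SLEEP_STATES, Hypnogram
from .photometry import PhotometryRecording

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedSession",
    "generate_session",
    "generate_cohort",
    "generate_hypnogram",
    "session_seed",
]

STIM_FREQUENCIES = (5.0, 10.0, 20.0)


@dataclass
class SimulationConfig:
    """Parameters of the generative model; defaults mirror the study design.

    Timing: 6-min sessions with induction at the midpoint, 10-s stimulation
    at 20 Hz, 1 kHz EEG, 10 Hz per-channel photometry.  Latent activity
    levels may be pinned (``latent_pre``/``latent_during``); when ``None``
    they are drawn from truncated normals per session.
    """

    # timing / rates
    fs_eeg: float = 1000.0
    fs_photometry: float = 10.0
    session_length: float = 360.0
    induction_time: float = 180.0
    stim_frequency: float = 20.0
    stim_duration: float = 10.0
    afterdischarge_band: tuple[float, float] = (4.0, 14.0)
    # latent -> EEG coupling
    beta_pre: float = 1.0
    beta_during: float = 0.0
    ad_base: float = 0.5
    ad_amp_scale: float = 100.0  # uV per unit of (base + beta.latent)
    ad_gain_jitter_sd: float = 0.06  # lognormal sd of session gain
    duration_base_s: float = 12.0
    duration_gain_s: float = 10.0  # s per unit of latent drive
    # EEG noise and stimulation artifact
    noise_sd_eeg: float = 15.0  # uV
    eeg_noise_color: str = "white"  # "white" or "pink"
    stim_amplitude: float = 300.0  # uV
    # photometry
    offset_465: float = 100.0  # a.u.
    offset_405: float = 80.0
    bleach_slope: float = 3e-4  # fraction of offset per second
    calcium_event_amplitude: float = 5.0  # a.u.
    calcium_noise_sd: float = 0.3  # a.u., smoothed spontaneous wiggle
    calcium_smooth_s: float = 0.5
    burst_period_s: float = 10.0
    motion_sd: float = 0.5  # a.u., shared across channels
    motion_smooth_s: float = 0.3
    noise_sd_photometry: float = 0.2  # a.u., per channel
    # latent distributions (pre truncated to the recoverable range [0, 0.95])
    latent_pre: float | None = None
    latent_during: float | None = None
    latent_pre_mean: float = 0.5
    latent_pre_sd: float = 0.2
    latent_pre_bounds: tuple[float, float] = (0.0, 0.95)
    latent_during_mean: float = 1.5
    latent_during_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if not self.fs_eeg > 200.0:
            raise ConfigError("fs_eeg", f"must exceed 200 Hz, got {self.fs_eeg}")
        if not self.fs_photometry > 0:
            raise ConfigError("fs_photometry", "must be positive")
        if not 0 < self.induction_time < self.session_length:
            raise ConfigError(
                "induction_time",
                f"{self.induction_time} s not inside (0, {self.session_length}) s",
            )
        if not self.stim_duration > 0:
            raise ConfigError("stim_duration", "must be positive")
        if self.stim_frequency not in STIM_FREQUENCIES:
            raise ConfigError(
                "stim_frequency", f"must be one of {STIM_FREQUENCIES} Hz"
            )
        lo, hi = self.afterdischarge_band
        if not 0 < lo < hi < self.fs_eeg / 2:
            raise ConfigError("afterdischarge_band", f"({lo}, {hi}) Hz invalid")
        for name in (
            "noise_sd_eeg",
            "calcium_noise_sd",
            "motion_sd",
            "noise_sd_photometry",
            "ad_gain_jitter_sd",
            "latent_pre_sd",
            "latent_during_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(name, "standard deviations must be non-negative")
        if self.eeg_noise_color not in ("white", "pink"):
            raise ConfigError("eeg_noise_color", "must be 'white' or 'pink'")
        if self.burst_period_s <= 0:
            raise ConfigError("burst_period_s", "must be positive")


@dataclass
class GroundTruth:
    """Latents and derived truths stored alongside each simulated session."""

    latent_pre: float
    latent_during: float
    true_afterdischarge_power: float  # uV^2, tone-equivalent amp^2/2
    true_duration: float  # s
    motion_trace: np.ndarray

    def __post_init__(self) -> None:
        if self.true_duration < 0 or self.true_afterdischarge_power < 0:
            raise PeriSeizureError("ground-truth power/duration must be non-negative")


@dataclass
class SimulatedSession:
    eeg: EEGRecording
    photometry: PhotometryRecording
    truth: GroundTruth


def _smoothed_noise(rng: np.random.Generator, n: int, sigma_samples: float) -> np.ndarray:
    """Unit-SD smoothed Gaussian noise (zero array if degenerate)."""
    raw = rng.normal(size=n)
    if sigma_samples > 0:
        raw = gaussian_filter1d(raw, sigma_samples, mode="reflect")
    sd = raw.std()
    return raw / sd if sd > 0 else np.zeros(n)


def _pink_noise(rng: np.random.Generator, n: int, sd: float) -> np.ndarray:
    """1/f-amplitude Gaussian noise scaled to the requested SD."""
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    shaped = np.fft.irfft(spec / np.sqrt(f), n=n)
    return sd * shaped / shaped.std()


def _burst_train(cfg: SimulationConfig, n: int, latent_pre: float) -> np.ndarray:
    """Periodic calcium-burst indicator with duty tied to the latent level.

    For a two-level trace that is high a fraction ``p`` of the time (with
    p < 1/2 so the median stays at the floor), the baseline-window mean in
    median/SD z-units is sqrt(p / (1 - p)).  Inverting gives
    ``p = L^2 / (1 + L^2)``; the duty is capped at 0.49, so latents above
    ~0.98 saturate in the photometry readout (the EEG coupling does not
    saturate).
    """
    level = max(latent_pre, 0.0)
    duty = min(level**2 / (1.0 + level**2), 0.49)
    period = int(round(cfg.burst_period_s * cfg.fs_photometry))
    high = int(round(duty * period))
    pattern = np.zeros(period)
    pattern[:high] = 1.0
    reps = int(np.ceil(n / period))
    return np.tile(pattern, reps)[:n]


def generate_session(cfg: SimulationConfig, seed: int | None = None) -> SimulatedSession:
    """Generate one coupled EEG + photometry session.

    Deterministic given ``(cfg, seed)``; ``seed`` defaults to ``cfg.seed``.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    # -- latents (fixed draw order keeps the stream stable across options)
    if cfg.latent_pre is None:
        lo, hi = cfg.latent_pre_bounds
        latent_pre = float(
            np.clip(rng.normal(cfg.latent_pre_mean, cfg.latent_pre_sd), lo, hi)
        )
    else:
        latent_pre = float(cfg.latent_pre)
    if cfg.latent_during is None:
        latent_during = float(
            max(rng.normal(cfg.latent_during_mean, cfg.latent_during_sd), 0.0)
        )
    else:
        latent_during = float(cfg.latent_during)
    gain = float(np.exp(rng.normal(0.0, cfg.ad_gain_jitter_sd)))

    drive = cfg.beta_pre * latent_pre + cfg.beta_during * latent_during
    amplitude = cfg.ad_amp_scale * max(cfg.ad_base + drive, 0.0) * gain
    max_duration = cfg.session_length - cfg.induction_time - cfg.stim_duration - 5.0
    true_duration = float(
        np.clip(cfg.duration_base_s + cfg.duration_gain_s * drive, 0.0, max_duration)
    )
    if amplitude == 0.0:
        true_duration = 0.0

    # -- EEG ---------------------------------------------------------------
    n_eeg = int(round(cfg.session_length * cfg.fs_eeg))
    t = np.arange(n_eeg) / cfg.fs_eeg
    if cfg.eeg_noise_color == "pink":
        eeg_trace = _pink_noise(rng, n_eeg, cfg.noise_sd_eeg)
    else:
        eeg_trace = rng.normal(0.0, cfg.noise_sd_eeg, n_eeg)

    stim_on = (t >= cfg.induction_time) & (t < cfg.induction_time + cfg.stim_duration)
    eeg_trace[stim_on] += cfg.stim_amplitude * np.sin(
        2 * np.pi * cfg.stim_frequency * (t[stim_on] - cfg.induction_time)
    )

    ad_start = cfg.induction_time + cfg.stim_duration
    n_ad = int(round(true_duration * cfg.fs_eeg))
    if n_ad > 1 and amplitude > 0:
        lo, hi = cfg.afterdischarge_band
        f_start, f_end = lo + 0.8 * (hi - lo), lo + 0.2 * (hi - lo)
        f_inst = np.linspace(f_start, f_end, n_ad)
        phase = 2 * np.pi * np.cumsum(f_inst) / cfg.fs_eeg
        i0 = int(round(ad_start * cfg.fs_eeg))
        eeg_trace[i0 : i0 + n_ad] += amplitude * tukey(n_ad, 0.2) * np.sin(phase)

    eeg_rec = EEGRecording(
        samples=eeg_trace,
        fs=cfg.fs_eeg,
        events=[(cfg.induction_time, "stimulation", cfg.stim_frequency)],
    )

    # -- photometry --------------------------------------------------------
    n_p = int(round(cfg.session_length * cfg.fs_photometry))
    t_p = np.arange(n_p) / cfg.fs_photometry
    bursts = cfg.calcium_event_amplitude * _burst_train(cfg, n_p, latent_pre)
    wiggle = cfg.calcium_noise_sd * _smoothed_noise(
        rng, n_p, cfg.calcium_smooth_s * cfg.fs_photometry
    )
    motion = cfg.motion_sd * _smoothed_noise(
        rng, n_p, cfg.motion_smooth_s * cfg.fs_photometry
    )
    noise465 = rng.normal(0.0, cfg.noise_sd_photometry, n_p)
    noise405 = rng.normal(0.0, cfg.noise_sd_photometry, n_p)

    seizure = (t_p >= cfg.induction_time) & (
        t_p < cfg.induction_time + cfg.stim_duration + true_duration
    )
    bursts = np.where(seizure, 0.0, bursts)

    baseline = (t_p >= cfg.induction_time - 60.0) & (t_p < cfg.induction_time)
    base_sd = float(np.std((bursts + wiggle + motion + noise465)[baseline]))
    surge = np.where(seizure, latent_during * base_sd, 0.0)

    bleach = 1.0 - cfg.bleach_slope * t_p
    f465 = cfg.offset_465 * bleach + bursts + surge + wiggle + motion + noise465
    f405 = cfg.offset_405 * bleach + motion + noise405

    photo_rec = PhotometryRecording(
        time_s=t_p,
        f465=f465,
        f405=f405,
        fs=cfg.fs_photometry,
        induction_s=cfg.induction_time,
    )
    truth = GroundTruth(
        latent_pre=latent_pre,
        latent_during=latent_during,
        true_afterdischarge_power=amplitude**2 / 2.0,
        true_duration=true_duration,
        motion_trace=motion,
    )
    return SimulatedSession(eeg=eeg_rec, photometry=photo_rec, truth=truth)


def session_seed(master_seed: int, index: int) -> int:
    """Deterministic per-session seed derived from the master seed."""
    state = np.random.SeedSequence([int(master_seed), int(index)]).generate_state(1)[0]
    return int(state) & 0x7FFFFFFF


def generate_cohort(
    cfg: SimulationConfig, n_sessions: int, seed: int | None = None
) -> list[SimulatedSession]:
    """Generate ``n_sessions`` independent sessions from one master seed.

    Latents are drawn i.i.d. per session (pre-seizure: truncated normal,
    mean 0.5, SD 0.2 on [0, 0.95]; during-seizure: normal mean 1.5, SD 0.5
    truncated at 0) unless pinned in the config.
    """
    if n_sessions < 1:
        raise PeriSeizureError(f"n_sessions must be >= 1, got {n_sessions}")
    master = cfg.seed if seed is None else seed
    return [
        generate_session(cfg, session_seed(master, i)) for i in range(n_sessions)
    ]


def generate_hypnogram(
    transition_matrix: np.ndarray,
    n_epochs: int,
    seed: int | None = None,
    initial_state: str = "Wake",
) -> Hypnogram:
    """First-order Markov hypnogram over (Wake, NREM, REM) in 5-s epochs."""
    P = np.asarray(transition_matrix, dtype=float)
    if P.shape != (3, 3):
        raise PeriSeizureError("transition matrix must be 3x3 (Wake, NREM, REM)")
    if np.any(P < 0) or np.any(np.abs(P.sum(axis=1) - 1.0) > 1e-9):
        raise PeriSeizureError("transition matrix rows must be non-negative and sum to 1")
    if n_epochs < 1:
        raise PeriSeizureError(f"n_epochs must be >= 1, got {n_epochs}")
    if initial_state not in SLEEP_STATES:
        raise PeriSeizureError(f"unknown initial state '{initial_state}'")
    rng = np.random.default_rng(seed)
    cum = np.cumsum(P, axis=1)
    state = SLEEP_STATES.index(initial_state)
    draws = rng.random(n_epochs - 1)
    states = np.empty(n_epochs, dtype=int)
    states[0] = state
    for i, u in enumerate(draws):
        state = int(np.searchsorted(cum[state], u, side="right"))
        states[i + 1] = min(state, 2)
    return Hypnogram(states=[SLEEP_STATES[s] for s in states], epoch_s=5.0)
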