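"""Synthetic passive-stretch dynamometry datasets with known ground truth.

Emulates a motor-driven ankle dynamometer delivering constant-velocity
dorsiflexion ramps (20° plantarflexion → 0°) while surface EMG is recorded
from soleus (sol) and medial gastrocnemius (mg).  Each trial carries a
hidden truth record: the joint angle at which the stretch reflex is
mechanically initiated, and the EMG onset that follows one reflex latency
later.  The generator is the ground-truth oracle for every downstream
stage (rejection, onset detection, threshold estimation), so all of its
randomness flows through a single :class:`numpy.random.Generator`.

Conventions
-----------
Angles are degrees of plantarflexion: positive, *decreasing* during a
dorsiflexion stretch.  Times are seconds on a uniform grid at
``sampling_rate``.  EMG amplitudes are arbitrary units; the background
SD defines the unit scale.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as _sig

MUSCLES = ("sol", "mg")

#: spectral support of the simulated surface EMG before any analysis filter
_EMG_BAND = (20.0, 450.0)


class ThresholdOutOfRangeError(ValueError):
    """True reflex threshold lies outside the stretch range of motion."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic subject.

    Defaults mirror the acquisition they emulate: four ramp velocities
    55/110/210/291 °/s, ten stretches per velocity, 20° → 0° range of
    motion reached after a 20–40 ms acceleration phase, and a ~28 ms
    (SD 3 ms, range 23–35 ms) monosynaptic reflex latency.
    """

    sampling_rate: float = 2000.0
    velocities: tuple[float, ...] = (55.0, 110.0, 210.0, 291.0)
    n_trials_per_velocity: int = 10
    start_angle: float = 20.0
    end_angle: float = 0.0
    accel_duration: float = 0.030
    true_threshold_angle: float = 19.0
    threshold_velocity_slope: float = 0.0
    latency: Mapping[str, float] = field(
        default_factory=lambda: {"sol": 0.028, "mg": 0.028}
    )
    latency_sd: float = 0.003
    latency_range: tuple[float, float] = (0.023, 0.035)
    background_sd: float = 1.0
    burst_gain: float = 5.0
    burst_rise_time: float = 0.010
    mvc_rms: Mapping[str, float] = field(
        default_factory=lambda: {"sol": 50.0, "mg": 50.0}
    )
    pre_stretch_duration: float = 0.60
    post_stretch_duration: float = 0.30
    contamination_fraction: float = 0.0
    contamination_level: float = 0.10  # fraction of MVC RMS
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.start_angle <= self.end_angle:
            raise ValueError("start_angle must exceed end_angle (20° → 0° stretch)")
        if any(v <= 0 for v in self.velocities):
            raise ValueError("all velocities must be positive")
        if not 0.0 < self.accel_duration:
            raise ValueError("accel_duration must be positive")
        for m, lat in self.latency.items():
            if not 0.0 <= lat <= 0.050:
                raise ValueError(f"latency[{m!r}]={lat} outside plausible range")
        if self.burst_gain <= 1.0:
            raise ValueError("burst_gain must exceed 1 (burst must rise above background)")
        if not 0.0 <= self.contamination_fraction <= 1.0:
            raise ValueError("contamination_fraction must be a proportion")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class TrialTruth:
    """Hidden ground truth attached to a synthetic trial."""

    true_threshold_angle: float
    true_sr_onset_time: float
    true_emg_onset_time: dict[str, float]
    latency: dict[str, float]
    contaminated: bool = False
    contaminated_muscle: str | None = None


@dataclass
class Trial:
    """One passive-stretch recording: joint angle plus EMG channels."""

    time: np.ndarray
    angle: np.ndarray
    emg: dict[str, np.ndarray]
    nominal_velocity: float
    stretch_onset_time: float
    trial_id: str = ""
    truth: TrialTruth | None = None

    @property
    def sampling_rate(self) -> float:
        return 1.0 / (self.time[1] - self.time[0])


@dataclass
class HReflexTrace:
    """Stimulus-locked EMG trace; the stimulus artifact sits at t = 0."""

    time: np.ndarray
    emg: np.ndarray
    truth_h_latency: float | None = None


@dataclass
class SubjectRecord:
    """A subject's trials plus per-muscle reflex latency and MVC reference."""

    subject_id: str
    trials: list[Trial]
    h_latency: dict[str, float]
    hreflex: dict[str, HReflexTrace]
    mvc_rms: dict[str, float]
    config: SimulationConfig | None = None


# ---------------------------------------------------------------------------
# kinematics


def ramp_angle(cfg: SimulationConfig, velocity: float, t_rel: np.ndarray) -> np.ndarray:
    """Commanded (noiseless) angle trajectory, ``t_rel`` relative to stretch onset.

    Constant acceleration for ``accel_duration`` up to the target velocity,
    then constant velocity until ``end_angle``, then hold.
    """
    t = np.asarray(t_rel, dtype=float)
    a = velocity / cfg.accel_duration
    d_accel = 0.5 * velocity * cfg.accel_duration
    total = cfg.start_angle - cfg.end_angle
    drop = np.zeros_like(t)
    ph_a = (t > 0) & (t <= cfg.accel_duration)
    drop[ph_a] = 0.5 * a * t[ph_a] ** 2
    ph_c = t > cfg.accel_duration
    drop[ph_c] = d_accel + velocity * (t[ph_c] - cfg.accel_duration)
    np.clip(drop, 0.0, total, out=drop)
    return cfg.start_angle - drop


def threshold_crossing_time(cfg: SimulationConfig, velocity: float) -> tuple[float, float]:
    """Time (relative to stretch onset) when the commanded trajectory crosses
    the true reflex threshold for this velocity.

    Returns ``(t_cross, threshold_angle)``.  Raises
    :class:`ThresholdOutOfRangeError` if the threshold lies outside the
    stretch range of motion (the reflex would never fire).
    """
    theta = cfg.true_threshold_angle + cfg.threshold_velocity_slope * velocity
    if not (cfg.end_angle < theta < cfg.start_angle):
        raise ThresholdOutOfRangeError(
            f"threshold {theta:.2f}° outside ({cfg.end_angle}°, {cfg.start_angle}°) "
            f"at {velocity} °/s"
        )
    d = cfg.start_angle - theta
    a = velocity / cfg.accel_duration
    d_accel = 0.5 * velocity * cfg.accel_duration
    if d <= d_accel:
        t = float(np.sqrt(2.0 * d / a))
    else:
        t = cfg.accel_duration + (d - d_accel) / velocity
    return t, theta


from functools import lru_cache


@lru_cache(maxsize=32)
def _butter_sos(order: int, low: float, high: float, fs: float) -> np.ndarray:
    return _sig.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def _band_noise(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to the surface-EMG band."""
    x = rng.standard_normal(n)
    high = min(_EMG_BAND[1], 0.45 * fs)
    sos = _butter_sos(4, _EMG_BAND[0], high, fs)
    y = _sig.sosfilt(sos, x)
    sd = y.std()
    return y / sd if sd > 0 else y


# ---------------------------------------------------------------------------
# generators


def generate_trial(
    cfg: SimulationConfig,
    velocity: float,
    rng: np.random.Generator,
    *,
    latencies: Mapping[str, float] | None = None,
    contaminate: str | None = None,
    trial_id: str = "",
) -> Trial:
    """Simulate one passive-stretch trial at ``velocity``.

    EMG per muscle is band-limited Gaussian background plus an independent
    burst component whose SD ramps linearly from zero to
    ``burst_gain × background_sd`` over ``burst_rise_time``, starting one
    reflex latency after the commanded trajectory crosses the true
    threshold angle.  ``contaminate`` names a muscle to receive an extra
    pre-stretch activation burst (for rejection-rule testing).
    """
    if velocity not in cfg.velocities:
        raise ValueError(f"velocity {velocity} not in cfg.velocities")
    lat = dict(latencies if latencies is not None else cfg.latency)
    fs = cfg.sampling_rate
    t_cross, theta = threshold_crossing_time(cfg, velocity)

    ramp_total = cfg.accel_duration + (
        (cfg.start_angle - cfg.end_angle) - 0.5 * velocity * cfg.accel_duration
    ) / velocity
    duration = cfg.pre_stretch_duration + ramp_total + cfg.post_stretch_duration
    n = int(round(duration * fs)) + 1
    time = np.arange(n) / fs
    stretch_onset = cfg.pre_stretch_duration
    angle = ramp_angle(cfg, velocity, time - stretch_onset)

    sr_onset = stretch_onset + t_cross
    emg: dict[str, np.ndarray] = {}
    emg_onsets: dict[str, float] = {}
    for m in MUSCLES:
        onset_t = sr_onset + lat[m]
        emg_onsets[m] = onset_t
        bg = _band_noise(n, fs, rng) * cfg.background_sd
        burst = _band_noise(n, fs, rng)
        env = np.clip((time - onset_t) / cfg.burst_rise_time, 0.0, 1.0)
        x = bg + burst * env * (cfg.burst_gain * cfg.background_sd)
        if contaminate == m:
            c0 = stretch_onset - 0.45
            c1 = stretch_onset - 0.15
            mask = (time >= c0) & (time < c1)
            x[mask] += _band_noise(int(mask.sum()), fs, rng) * (
                cfg.contamination_level * cfg.mvc_rms[m]
            )
        emg[m] = x

    truth = TrialTruth(
        true_threshold_angle=theta,
        true_sr_onset_time=sr_onset,
        true_emg_onset_time=emg_onsets,
        latency=lat,
        contaminated=contaminate is not None,
        contaminated_muscle=contaminate,
    )
    return Trial(
        time=time,
        angle=angle,
        emg=emg,
        nominal_velocity=velocity,
        stretch_onset_time=stretch_onset,
        trial_id=trial_id,
        truth=truth,
    )


def generate_subject(
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    *,
    subject_id: str = "S00",
) -> SubjectRecord:
    """Simulate a full subject session.

    Ten stretches per velocity (by default) in pseudo-randomized order;
    per-muscle reflex latencies are drawn once from a normal distribution
    (mean = ``cfg.latency``, SD = ``cfg.latency_sd``, clipped to
    ``cfg.latency_range``) and reused in every trial, and a matching
    stimulus-locked H-reflex trace is generated per muscle.  A fraction
    ``contamination_fraction`` of trials (count rounded to nearest) gets a
    pre-stretch activation burst on one randomly chosen muscle.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)

    lat = {}
    for m in MUSCLES:
        draw = rng.normal(cfg.latency[m], cfg.latency_sd)
        lat[m] = float(np.clip(draw, *cfg.latency_range))

    order = np.repeat(np.arange(len(cfg.velocities)), cfg.n_trials_per_velocity)
    rng.shuffle(order)
    n_total = order.size
    n_contam = int(round(cfg.contamination_fraction * n_total))
    contam_idx = set(
        rng.choice(n_total, size=n_contam, replace=False).tolist() if n_contam else []
    )

    trials = []
    for i, vi in enumerate(order):
        v = cfg.velocities[vi]
        contaminate = MUSCLES[int(rng.integers(len(MUSCLES)))] if i in contam_idx else None
        trials.append(
            generate_trial(
                cfg,
                v,
                rng,
                latencies=lat,
                contaminate=contaminate,
                trial_id=f"{subject_id}_t{i:03d}",
            )
        )

    # a stimulus-locked trace only exists for physiologically measurable
    # latencies; degenerate configs (e.g. zero latency) skip it and must
    # analyze with the recorded latency instead
    hreflex = {
        m: generate_hreflex(lat[m], rng, fs=cfg.sampling_rate, noise_sd=cfg.background_sd)
        for m in MUSCLES
        if 0.015 <= lat[m] <= 0.050
    }
    return SubjectRecord(
        subject_id=subject_id,
        trials=trials,
        h_latency=lat,
        hreflex=hreflex,
        mvc_rms=dict(cfg.mvc_rms),
        config=cfg,
    )


def generate_hreflex(
    latency: float,
    rng: np.random.Generator,
    *,
    fs: float = 2000.0,
    noise_sd: float = 1.0,
    pre: float = 0.050,
    post: float = 0.080,
    h_amplitude: float = 15.0,
    h_duration: float = 0.010,
    m_wave_amplitude: float = 0.0,
    m_wave_latency: float = 0.007,
    artifact_amplitude: float = 50.0,
) -> HReflexTrace:
    """Stimulus-locked trace: artifact at t=0, optional M-wave, biphasic
    H-wave whose initial deflection begins exactly at ``latency``.

    Amplitudes are multiples of ``noise_sd``; ``noise_sd=0`` yields a
    noiseless trace (flat outside the deflections).
    """
    if not 0.015 <= latency <= 0.050:
        raise ValueError(f"latency {latency} s outside [0.015, 0.050] s")
    n = int(round((pre + post) * fs)) + 1
    time = np.arange(n) / fs - pre
    x = _band_noise(n, fs, rng) * noise_sd if noise_sd > 0 else np.zeros(n)

    def _biphasic(t0: float, amp: float, dur: float) -> np.ndarray:
        ph = (time - t0) / dur
        w = np.where((ph >= 0) & (ph <= 1), np.sin(2.0 * np.pi * np.clip(ph, 0, 1)), 0.0)
        return amp * w

    art = (time >= 0) & (time < 0.002)
    x[art] += artifact_amplitude * max(noise_sd, 1.0) * np.exp(
        -time[art] / 0.0005
    )
    if m_wave_amplitude > 0:
        x += _biphasic(m_wave_latency, m_wave_amplitude * max(noise_sd, 1.0), 0.006)
    x += _biphasic(latency, h_amplitude * max(noise_sd, 1.0), h_duration)
    return HReflexTrace(time=time, emg=x, truth_h_latency=latency)
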