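"""EMG preprocessing and background-activation trial rejection.

Two stages applied before any onset detection: a zero-phase band-pass
filter (the analysis band, 20–195 Hz by default), and the rejection of
trials whose pre-stretch EMG shows background activation above a set
fraction of the maximal-voluntary-contraction (MVC) RMS.  Zero-phase
filtering matters because onset *timing* is the measurand downstream — a
causal filter would delay every detected onset by its group delay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import signal as _sig

from .synth import Trial, _butter_sos


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass specification; defaults to the 20–195 Hz analysis band."""

    low_cut: float = 20.0
    high_cut: float = 195.0
    order: int = 4
    zero_phase: bool = True

    def validate(self, fs: float) -> None:
        if not 0.0 < self.low_cut < self.high_cut < fs / 2.0:
            raise ValueError(
                f"require 0 < low_cut < high_cut < fs/2, got "
                f"({self.low_cut}, {self.high_cut}) at fs={fs}"
            )


@dataclass(frozen=True)
class RejectionSpec:
    """Background-activation rejection rule.

    A trial is discarded when the sliding-window RMS (window ``rms_window``)
    of any muscle's EMG, anywhere in the ``pre_window`` preceding the
    stretch, exceeds ``mvc_fraction`` of that muscle's MVC RMS.
    """

    rms_window: float = 0.200
    pre_window: float = 0.500
    mvc_fraction: float = 0.05
    mvc_rms: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rms_window <= 0:
            raise ValueError("rms_window must be positive")
        if self.pre_window < self.rms_window:
            raise ValueError("pre_window must cover at least one rms_window")
        if not 0.0 < self.mvc_fraction < 1.0:
            raise ValueError("mvc_fraction must be in (0, 1)")


@dataclass
class DiscardReason:
    trial_id: str
    muscle: str
    max_rms: float
    threshold: float

    def __str__(self) -> str:  # for the analysis log
        return (
            f"trial {self.trial_id}: {self.muscle} pre-stretch RMS "
            f"{self.max_rms:.3g} > {self.threshold:.3g}"
        )


def bandpass(emg: np.ndarray, fs: float, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Butterworth band-pass, forward-backward when ``spec.zero_phase``.

    Raises ``ValueError`` on traces too short for stable filtering.
    """
    spec.validate(fs)
    x = np.asarray(emg, dtype=float)
    sos = _butter_sos(spec.order, spec.low_cut, spec.high_cut, fs)
    # sosfiltfilt pads with 3 * (2 * n_sections + 1) samples per end
    padlen = 3 * (2 * sos.shape[0] + 1)
    if x.size <= max(3 * spec.order, padlen):
        raise ValueError(
            f"trace of {x.size} samples too short for order-{spec.order} band-pass"
        )
    if spec.zero_phase:
        return _sig.sosfiltfilt(sos, x)
    return _sig.sosfilt(sos, x)


def sliding_rms(x: np.ndarray, window_samples: int) -> np.ndarray:
    """RMS over a right-aligned sliding window, evaluated at every sample
    where the window fits.  Output length is ``len(x) - window + 1``."""
    if window_samples < 1 or window_samples > x.size:
        raise ValueError("window does not fit in trace")
    c = np.concatenate(([0.0], np.cumsum(np.asarray(x, dtype=float) ** 2)))
    s = c[window_samples:] - c[:-window_samples]
    return np.sqrt(s / window_samples)


def max_prestretch_rms(trial: Trial, muscle: str, spec: RejectionSpec) -> float:
    """Maximum sliding-window RMS of one muscle over the pre-stretch interval."""
    fs = trial.sampling_rate
    w = int(round(spec.rms_window * fs))
    i1 = int(round(trial.stretch_onset_time * fs))
    i0 = i1 - int(round(spec.pre_window * fs))
    if i0 < 0:
        raise ValueError(
            f"trial {trial.trial_id}: only {i1 / fs:.3f} s of pre-stretch data, "
            f"need {spec.pre_window} s"
        )
    return float(sliding_rms(trial.emg[muscle][i0:i1], w).max())


def reject_trials(
    trials: list[Trial], spec: RejectionSpec
) -> tuple[list[Trial], list[DiscardReason]]:
    """Split trials into kept and discarded by the background-activation rule.

    One contaminated muscle rejects the whole trial.  Reasons record the
    offending muscle and the measured RMS.
    """
    kept: list[Trial] = []
    discarded: list[DiscardReason] = []
    for tr in trials:
        reason = None
        for m in tr.emg:
            if m not in spec.mvc_rms:
                raise KeyError(f"no mvc_rms reference for muscle {m!r}")
            thr = spec.mvc_fraction * spec.mvc_rms[m]
            rms = max_prestretch_rms(tr, m, spec)
            if rms > thr:
                reason = DiscardReason(tr.trial_id, m, rms, thr)
                break
        if reason is None:
            kept.append(tr)
        else:
            discarded.append(reason)
    return kept, discarded
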