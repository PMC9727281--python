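"""Stretch-reflex thresholds, latency correction, and velocity regression.

The stretch reflex threshold (SRT) is the joint angle at the reflex EMG
onset.  Because the EMG onset lags the mechanical reflex initiation by
the monosynaptic latency (~28 ms at the ankle), the uncorrected SRT is
systematically displaced later into the stretch by ``latency x velocity``
degrees.  The latency-corrected threshold reads the angle one reflex
latency *before* the EMG onset:

    SRT           = angle(t_onset)
    SRT_corrected = angle(t_onset - latency)

Per-subject medians at each stretch velocity feed an ordinary
least-squares regression of SRT on velocity; its y-intercept is the
tonic stretch reflex threshold (TSRT), the extrapolated threshold at
zero velocity.  On the 20° → 0° plantarflexion convention a velocity-
independent true threshold theta with latency l gives exactly
SRT(v) = theta - l*v and SRT_corrected(v) = theta.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _st

from .onset import OnsetResult
from .synth import Trial

#: |slope| below this (deg per deg/s) counts as velocity-independent;
#: over the 55–291 °/s study range it bounds the SRT change by 2.36°,
#: within typical within-subject variability
NEAR_ZERO_SLOPE = 0.01


class MissingVelocityError(ValueError):
    """A required stretch velocity has no surviving median SRT."""


@dataclass
class SRTEstimate:
    """Per-trial threshold pair (original and latency-corrected), degrees."""

    muscle: str
    velocity: float
    srt: float
    srt_corrected: float
    onset_time: float
    latency_used: float
    trial_id: str = ""
    onset_method: str = ""
    onset_flags: set[str] = field(default_factory=set)


@dataclass
class VelocityRegression:
    """OLS of median SRT (y, deg) on stretch velocity (x, deg/s)."""

    muscle: str
    method: str  # original | corrected
    velocities: tuple[float, ...]
    medians: tuple[float, ...]
    slope: float
    intercept_tsrt: float
    r_squared: float
    n_velocities: int
    dependence_class: str  # near_zero | positive | negative
    r_squared_degenerate: bool = False


def angle_at_time(trial: Trial, t: float) -> float:
    """Joint angle at time ``t``, linearly interpolated between samples."""
    if t < trial.time[0] or t > trial.time[-1]:
        raise ValueError(
            f"t={t:.4f} s outside trial range "
            f"[{trial.time[0]:.4f}, {trial.time[-1]:.4f}] s"
        )
    return float(np.interp(t, trial.time, trial.angle))


def latency_error(latency: float, velocity: float) -> float:
    """Angular displacement accrued during the reflex latency at constant
    velocity — the systematic error of the uncorrected SRT, in degrees."""
    if latency < 0 or velocity < 0:
        raise ValueError("latency and velocity must be non-negative")
    return latency * velocity


def pathway_error_bound(
    mean_latency: float, fraction: float, max_velocity: float
) -> tuple[float, float]:
    """Worst-case residual error of using the H-reflex latency as the
    stretch-reflex latency.

    The H-reflex is evoked at the popliteal fossa rather than at the
    muscle spindles, so it underestimates the reflex latency by at most
    ``fraction`` of the afferent-efferent arc.  Returns the time bound
    (s) and the corresponding angular bound (deg) at ``max_velocity``.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    dt = fraction * mean_latency
    return dt, dt * max_velocity


def compute_srt(trial: Trial, onset: OnsetResult, latency: float) -> SRTEstimate:
    """Threshold pair for one trial and muscle from a detected onset."""
    if not onset.detected:
        raise ValueError("onset not detected; cannot compute SRT")
    if latency < 0:
        raise ValueError("latency must be non-negative")
    t_corr = onset.onset_time - latency
    if t_corr < trial.time[0]:
        raise ValueError("latency correction reaches before trial start")
    return SRTEstimate(
        muscle="",
        velocity=trial.nominal_velocity,
        srt=angle_at_time(trial, onset.onset_time),
        srt_corrected=angle_at_time(trial, t_corr),
        onset_time=onset.onset_time,
        latency_used=latency,
        trial_id=trial.trial_id,
        onset_method=onset.method,
        onset_flags=set(onset.flags),
    )


def aggregate_medians(
    estimates: list[SRTEstimate],
) -> dict[float, dict[str, float]]:
    """Per-velocity median SRT and SRT_corrected (midpoint convention for
    even counts, i.e. the ordinary sample median)."""
    out: dict[float, dict[str, float]] = {}
    by_v: dict[float, list[SRTEstimate]] = {}
    for e in estimates:
        by_v.setdefault(e.velocity, []).append(e)
    for v, es in sorted(by_v.items()):
        out[v] = {
            "srt": float(np.median([e.srt for e in es])),
            "srt_corrected": float(np.median([e.srt_corrected for e in es])),
            "n": len(es),
        }
    return out


def fit_velocity_regression(
    medians: dict[float, float],
    required_velocities: list[float] | tuple[float, ...],
    muscle: str = "",
    method: str = "",
) -> VelocityRegression:
    """OLS of median SRT on velocity; intercept is the TSRT.

    Refuses to fit when any required velocity is missing (the subject is
    excluded rather than silently regressed on fewer points).  Zero
    y-variance yields slope 0 and a flagged R² of 0.
    """
    missing = [v for v in required_velocities if v not in medians]
    if missing:
        raise MissingVelocityError(
            f"no median SRT at velocities {missing}; subject excluded"
        )
    vs = np.asarray(sorted(required_velocities), dtype=float)
    ys = np.asarray([medians[v] for v in vs], dtype=float)
    degenerate = bool(np.ptp(ys) == 0.0)
    if degenerate:
        slope, intercept, r2 = 0.0, float(ys[0]), 0.0
    else:
        res = _st.linregress(vs, ys)
        slope, intercept, r2 = float(res.slope), float(res.intercept), float(res.rvalue**2)
    if abs(slope) < NEAR_ZERO_SLOPE:
        cls = "near_zero"
    else:
        cls = "positive" if slope > 0 else "negative"
    return VelocityRegression(
        muscle=muscle,
        method=method,
        velocities=tuple(vs),
        medians=tuple(ys),
        slope=slope,
        intercept_tsrt=intercept,
        r_squared=r2,
        n_velocities=len(vs),
        dependence_class=cls,
        r_squared_degenerate=degenerate,
    )
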