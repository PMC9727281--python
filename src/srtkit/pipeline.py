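"""End-to-end analysis: filter → reject → onset → SRT → regression → stats.

`analyze_subject` carries one subject from raw trials to per-velocity
median thresholds and the velocity regression for both methods
(original and latency-corrected).  `analyze_cohort` assembles the
group-level tables: paired method comparisons of slope / R² / TSRT per
muscle and the Friedman velocity effect per muscle and method.  Subjects
lacking a median SRT at any required velocity are excluded from the
group statistics, with the reason logged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import onset as _onset
from . import signal as _signal
from . import srt as _srt
from . import stats as _stats
from .synth import MUSCLES, SubjectRecord, Trial


@dataclass(frozen=True)
class PipelineSpecs:
    """All per-stage parameters for one analysis run."""

    filter: _signal.FilterSpec = _signal.FilterSpec()
    rejection: _signal.RejectionSpec | None = None  # built from subject MVC if None
    aglr: _onset.AGLRSpec = _onset.AGLRSpec()
    sustained_k_sd: float = 2.0
    sustained_hold: float = 0.100
    max_disagreement: float = 0.020
    required_velocities: tuple[float, ...] = (55.0, 110.0, 210.0, 291.0)
    latency_source: str = "estimate"  # estimate (from H-reflex trace) | recorded
    mvc_fraction: float = 0.05
    rms_window: float = 0.200
    pre_window: float = 0.500
    alpha: float = 0.05


@dataclass
class SubjectResult:
    subject_id: str
    estimates: dict[str, list[_srt.SRTEstimate]]  # per muscle
    medians: dict[str, dict[float, dict[str, float]]]  # per muscle
    regressions: dict[tuple[str, str], _srt.VelocityRegression]  # (muscle, method)
    latency: dict[str, float]
    excluded_muscles: dict[str, str]  # muscle -> reason
    log: list[str] = field(default_factory=list)

    def srt_table(self) -> pd.DataFrame:
        rows = []
        for m, ests in self.estimates.items():
            for e in ests:
                rows.append(
                    {
                        "subject": self.subject_id,
                        "trial": e.trial_id,
                        "muscle": m,
                        "velocity_deg_s": e.velocity,
                        "srt_deg": e.srt,
                        "srt_corrected_deg": e.srt_corrected,
                        "onset_time_s": e.onset_time,
                        "latency_s": e.latency_used,
                        "onset_method": e.onset_method,
                        "flagged": "review" in e.onset_flags,
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class CohortResult:
    subjects: list[SubjectResult]
    comparisons: list[_stats.MethodComparison]
    velocity_effects: list[_stats.VelocityEffect]
    log: list[str] = field(default_factory=list)

    def regression_table(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            for (m, method), reg in s.regressions.items():
                rows.append(
                    {
                        "subject": s.subject_id,
                        "muscle": m,
                        "method": method,
                        "slope_deg_per_deg_s": reg.slope,
                        "tsrt_deg": reg.intercept_tsrt,
                        "r_squared": reg.r_squared,
                        "dependence_class": reg.dependence_class,
                    }
                )
        return pd.DataFrame(rows)


def _subject_latency(subject: SubjectRecord, specs: PipelineSpecs, log: list[str]) -> dict[str, float]:
    if specs.latency_source == "recorded":
        return dict(subject.h_latency)
    lat = {}
    for m in MUSCLES:
        trace = subject.hreflex[m]
        lat[m] = _onset.estimate_hreflex_latency(trace)
        log.append(f"{subject.subject_id}: {m} H-reflex latency {lat[m]*1000:.1f} ms")
    return lat


def analyze_subject(subject: SubjectRecord, specs: PipelineSpecs = PipelineSpecs()) -> SubjectResult:
    """Run the per-subject pipeline on already-loaded trials."""
    log: list[str] = []
    latency = _subject_latency(subject, specs, log)

    rej = specs.rejection or _signal.RejectionSpec(
        rms_window=specs.rms_window,
        pre_window=specs.pre_window,
        mvc_fraction=specs.mvc_fraction,
        mvc_rms=subject.mvc_rms,
    )

    # band-pass every channel (zero-phase), then apply the rejection rule
    filtered: list[Trial] = []
    for tr in subject.trials:
        fs = tr.sampling_rate
        emg = {m: _signal.bandpass(x, fs, specs.filter) for m, x in tr.emg.items()}
        filtered.append(
            Trial(
                time=tr.time,
                angle=tr.angle,
                emg=emg,
                nominal_velocity=tr.nominal_velocity,
                stretch_onset_time=tr.stretch_onset_time,
                trial_id=tr.trial_id,
                truth=tr.truth,
            )
        )
    kept, discarded = _signal.reject_trials(filtered, rej)
    for r in discarded:
        log.append(f"{subject.subject_id}: discarded {r}")

    estimates: dict[str, list[_srt.SRTEstimate]] = {m: [] for m in MUSCLES}
    for tr in kept:
        fs = tr.sampling_rate
        for m in MUSCLES:
            x = tr.emg[m]
            primary = _onset.detect_onset_aglr(x, fs, tr.stretch_onset_time, specs.aglr)
            fallback = _onset.detect_onset_sustained_sd(
                x, fs, tr.stretch_onset_time,
                baseline_window=specs.aglr.baseline_window,
                k_sd=specs.sustained_k_sd, hold=specs.sustained_hold,
            )
            result = _onset.reconcile_onsets(primary, fallback, specs.max_disagreement)
            if "review" in result.flags:
                log.append(
                    f"{subject.subject_id}: onset override on {tr.trial_id}/{m} "
                    f"(aglr={primary.onset_time}, fallback={fallback.onset_time})"
                )
            if not result.detected:
                continue
            est = _srt.compute_srt(tr, result, latency[m])
            est.muscle = m
            estimates[m].append(est)

    medians: dict[str, dict[float, dict[str, float]]] = {}
    regressions: dict[tuple[str, str], _srt.VelocityRegression] = {}
    excluded: dict[str, str] = {}
    for m in MUSCLES:
        med = _srt.aggregate_medians(estimates[m])
        medians[m] = med
        for method, key in (("original", "srt"), ("corrected", "srt_corrected")):
            try:
                regressions[(m, method)] = _srt.fit_velocity_regression(
                    {v: d[key] for v, d in med.items()},
                    specs.required_velocities,
                    muscle=m,
                    method=method,
                )
            except _srt.MissingVelocityError as exc:
                excluded[m] = str(exc)
                log.append(f"{subject.subject_id}: {m} excluded — {exc}")
                break

    return SubjectResult(
        subject_id=subject.subject_id,
        estimates=estimates,
        medians=medians,
        regressions=regressions,
        latency=latency,
        excluded_muscles=excluded,
        log=log,
    )


def analyze_cohort(
    subjects: list[SubjectRecord] | list[SubjectResult],
    specs: PipelineSpecs = PipelineSpecs(),
) -> CohortResult:
    """Group-level tables from a list of subjects (raw records or
    already-analyzed results)."""
    results = [
        s if isinstance(s, SubjectResult) else analyze_subject(s, specs)
        for s in subjects
    ]
    log: list[str] = []
    comparisons: list[_stats.MethodComparison] = []
    effects: list[_stats.VelocityEffect] = []
    vs = specs.required_velocities

    for m in MUSCLES:
        complete = [
            r for r in results
            if (m, "original") in r.regressions and (m, "corrected") in r.regressions
        ]
        n_excl = len(results) - len(complete)
        if n_excl:
            log.append(f"{m}: excluded {n_excl} subject(s) lacking all velocities")
        if len(complete) >= 3:
            for var, attr in (
                ("slope", "slope"),
                ("r_squared", "r_squared"),
                ("tsrt", "intercept_tsrt"),
            ):
                a = np.array([getattr(r.regressions[(m, "original")], attr) for r in complete])
                b = np.array([getattr(r.regressions[(m, "corrected")], attr) for r in complete])
                comparisons.append(
                    _stats.compare_paired(a, b, specs.alpha, variable=var, muscle=m)
                )
            for method, key in (("original", "srt"), ("corrected", "srt_corrected")):
                mat = np.array(
                    [[r.medians[m][v][key] for v in vs] for r in complete]
                )
                effects.append(
                    _stats.velocity_effect(mat, vs, specs.alpha, muscle=m, method=method)
                )
        else:
            log.append(f"{m}: fewer than 3 complete subjects; group statistics skipped")

    return CohortResult(results, comparisons, effects, log)
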