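"""Delimited-text dataset layout.

One directory per subject:

    subject_00/
      trial_000.csv ...   columns time_s, angle_deg, emg_sol, emg_mg
      manifest.csv        trial file, nominal velocity, stretch onset, truth
      hreflex_sol.csv     stimulus-locked trace (time_s, emg)
      hreflex_mg.csv
      subject.yaml        recorded latencies, MVC RMS references

A top-level ``manifest.csv`` lists the subject directories.  Floats are
written with fixed precision so identical data yields identical bytes.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synth import MUSCLES, HReflexTrace, SubjectRecord, Trial, TrialTruth

_FLOAT_FMT = "%.8g"


def write_subject(subject: SubjectRecord, out_dir: str | Path) -> Path:
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, tr in enumerate(subject.trials):
        fname = f"trial_{i:03d}.csv"
        df = pd.DataFrame(
            {
                "time_s": tr.time,
                "angle_deg": tr.angle,
                **{f"emg_{m}": tr.emg[m] for m in MUSCLES},
            }
        )
        df.to_csv(d / fname, index=False, float_format=_FLOAT_FMT)
        row = {
            "trial_file": fname,
            "trial_id": tr.trial_id,
            "nominal_velocity_deg_s": tr.nominal_velocity,
            "stretch_onset_time_s": tr.stretch_onset_time,
        }
        if tr.truth is not None:
            row.update(
                {
                    "true_threshold_angle_deg": tr.truth.true_threshold_angle,
                    "true_sr_onset_time_s": tr.truth.true_sr_onset_time,
                    **{
                        f"true_emg_onset_time_{m}_s": tr.truth.true_emg_onset_time[m]
                        for m in MUSCLES
                    },
                    "contaminated": tr.truth.contaminated,
                }
            )
        rows.append(row)
    pd.DataFrame(rows).to_csv(d / "manifest.csv", index=False, float_format=_FLOAT_FMT)
    for m, h in subject.hreflex.items():
        pd.DataFrame({"time_s": h.time, "emg": h.emg}).to_csv(
            d / f"hreflex_{m}.csv", index=False, float_format=_FLOAT_FMT
        )
    meta = {
        "subject_id": subject.subject_id,
        "h_latency_s": {m: float(subject.h_latency[m]) for m in MUSCLES},
        "mvc_rms": {m: float(subject.mvc_rms[m]) for m in MUSCLES},
    }
    (d / "subject.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    return d


def read_subject(subject_dir: str | Path) -> SubjectRecord:
    d = Path(subject_dir)
    meta = yaml.safe_load((d / "subject.yaml").read_text())
    manifest = pd.read_csv(d / "manifest.csv")
    trials = []
    for _, row in manifest.iterrows():
        df = pd.read_csv(d / row["trial_file"])
        truth = None
        if "true_sr_onset_time_s" in row and pd.notna(row.get("true_sr_onset_time_s")):
            truth = TrialTruth(
                true_threshold_angle=float(row["true_threshold_angle_deg"]),
                true_sr_onset_time=float(row["true_sr_onset_time_s"]),
                true_emg_onset_time={
                    m: float(row[f"true_emg_onset_time_{m}_s"]) for m in MUSCLES
                },
                latency=dict(meta["h_latency_s"]),
                contaminated=bool(row["contaminated"]),
            )
        trials.append(
            Trial(
                time=df["time_s"].to_numpy(),
                angle=df["angle_deg"].to_numpy(),
                emg={m: df[f"emg_{m}"].to_numpy() for m in MUSCLES},
                nominal_velocity=float(row["nominal_velocity_deg_s"]),
                stretch_onset_time=float(row["stretch_onset_time_s"]),
                trial_id=str(row["trial_id"]),
                truth=truth,
            )
        )
    hreflex = {}
    for m in MUSCLES:
        path = d / f"hreflex_{m}.csv"
        if not path.exists():
            continue
        df = pd.read_csv(path)
        hreflex[m] = HReflexTrace(
            time=df["time_s"].to_numpy(),
            emg=df["emg"].to_numpy(),
            truth_h_latency=meta["h_latency_s"].get(m),
        )
    return SubjectRecord(
        subject_id=str(meta["subject_id"]),
        trials=trials,
        h_latency={m: float(v) for m, v in meta["h_latency_s"].items()},
        hreflex=hreflex,
        mvc_rms={m: float(v) for m, v in meta["mvc_rms"].items()},
    )


def write_dataset(subjects: list[SubjectRecord], out_dir: str | Path) -> Path:
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in subjects:
        sub_dir = d / s.subject_id
        write_subject(s, sub_dir)
        rows.append({"subject_id": s.subject_id, "subject_dir": s.subject_id})
    pd.DataFrame(rows, columns=["subject_id", "subject_dir"]).to_csv(
        d / "manifest.csv", index=False
    )
    return d


def read_dataset(manifest_path: str | Path) -> list[SubjectRecord]:
    p = Path(manifest_path)
    root = p.parent if p.is_file() else p
    mf = p if p.is_file() else root / "manifest.csv"
    manifest = pd.read_csv(mf)
    return [read_subject(root / row["subject_dir"]) for _, row in manifest.iterrows()]
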