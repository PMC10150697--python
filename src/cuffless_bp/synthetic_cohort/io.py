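"""On-disk format for subject records.

Per subject three plain-text files in a directory:

* ``<id>.csv`` — waveforms, columns ``t_s, ecg, ppg, art``
* ``<id>.truth.csv`` — per-beat ground truth (absent for real imports):
  ``beat_time_s, pat_ms, hr_bpm, sbp, dbp, map``
* ``<id>.meta.yaml`` — sidecar: subject id, per-channel sampling rates,
  artifact log, relevel log, truth file name
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .waveforms import SubjectRecord, SubjectTruth


def write_subject_record(rec: SubjectRecord, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sid = rec.subject_id
    wf = pd.DataFrame({
        "t_s": np.arange(len(rec.art)) / rec.fs_art,
        "ecg": rec.ecg, "ppg": rec.ppg, "art": rec.art,
    })
    wf.to_csv(directory / f"{sid}.csv", index=False, float_format="%.6f")
    truth_file = None
    if rec.truth is not None:
        truth_file = f"{sid}.truth.csv"
        tr = pd.DataFrame({
            "beat_time_s": rec.truth.beat_times,
            "pat_ms": rec.truth.pat_ms,
            "hr_bpm": rec.truth.hr_bpm,
            "sbp": rec.truth.sbp, "dbp": rec.truth.dbp, "map": rec.truth.map,
        })
        tr.to_csv(directory / truth_file, index=False, float_format="%.6f")
    meta = {
        "subject_id": sid,
        "fs_ecg": float(rec.fs_ecg), "fs_ppg": float(rec.fs_ppg),
        "fs_art": float(rec.fs_art),
        "artifact_log": [[float(s), float(e), k] for s, e, k in rec.artifact_log],
        "relevel_log": [[float(t), float(c)] for t, c in rec.relevel_log],
        "truth_file": truth_file,
    }
    (directory / f"{sid}.meta.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    return directory / f"{sid}.csv"


def read_subject_record(directory, subject_id: str) -> SubjectRecord:
    directory = Path(directory)
    meta = yaml.safe_load((directory / f"{subject_id}.meta.yaml").read_text())
    wf = pd.read_csv(directory / f"{subject_id}.csv")
    truth = None
    if meta.get("truth_file"):
        tr = pd.read_csv(directory / meta["truth_file"])
        bt = tr["beat_time_s"].to_numpy()
        rr = np.empty_like(bt)
        if len(bt) > 1:
            rr[:-1] = np.diff(bt)
            rr[-1] = rr[-2]
        else:
            rr[:] = np.nan
        truth = SubjectTruth(
            trajectory=None, beat_times=bt, rr_s=rr,
            hr_bpm=tr["hr_bpm"].to_numpy(), pat_ms=tr["pat_ms"].to_numpy(),
            sbp=tr["sbp"].to_numpy(), dbp=tr["dbp"].to_numpy(),
            map=tr["map"].to_numpy(),
            ppg_amp=np.full(len(bt), np.nan), ppg_refl=np.full(len(bt), np.nan),
        )
    rec = SubjectRecord(
        subject_id=meta["subject_id"],
        fs_ecg=meta["fs_ecg"], fs_ppg=meta["fs_ppg"], fs_art=meta["fs_art"],
        ecg=wf["ecg"].to_numpy(), ppg=wf["ppg"].to_numpy(),
        art=wf["art"].to_numpy(),
        truth=truth,
        artifact_log=[(s, e, k) for s, e, k in meta.get("artifact_log", [])],
        relevel_log=[(t, c) for t, c in meta.get("relevel_log", [])],
    )
    return rec.validate()
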